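"""Statistical kernel shared by every analysis stage.

Exact contingency tests (2x2 and r x c via Freeman-Halton enumeration with
the point-probability ordering, matching R's ``fisher.test``), rank tests,
Benjamini-Hochberg control, Fisher's p-value combination, the Grubbs outlier
test, and survival analysis (Kaplan-Meier / log-rank / univariate Cox).

Survival fitting delegates to lifelines; rank tests and multiplicity control
delegate to scipy / statsmodels. The r x c exact test is implemented here
because the point-probability two-sided rule is the quantity the analyses
report (scipy's r x c method computes a different statistic).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "fisher_exact",
    "wilcoxon_rank_sum",
    "spearman",
    "bh_adjust",
    "fishers_method",
    "grubbs_outliers",
    "km_logrank",
    "cox_univariate",
]

_ENUMERATION_BUDGET = 10_000_000
# relative tolerance when comparing point probabilities; avoids excluding
# tables that tie with the observed one through floating-point noise
_PP_RTOL = 1e-7


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("contingency table entries must be integers")
        t = np.round(t).astype(np.int64)
    if (t < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    if t.sum() == 0:
        raise ValueError("contingency table is empty")
    return t.astype(np.int64)


def _table_count_bound(rows: np.ndarray, cols: np.ndarray) -> float:
    """Upper bound on the number of tables with the given margins."""
    bound = 1.0
    for r in rows[:-1]:
        for c in cols[:-1]:
            bound *= min(r, c) + 1
            if bound > 1e18:
                return bound
    return bound


def _enumerate_pvalue(rows: np.ndarray, cols: np.ndarray, logp_obs: float) -> float:
    """Sum P(T) over all margin-consistent tables with P(T) <= P(observed)."""
    lf = [math.lgamma(i + 1) for i in range(int(rows.sum()) + 1)]
    const = sum(lf[r] for r in rows) + sum(lf[c] for c in cols) - lf[int(rows.sum())]
    nrow, ncol = len(rows), len(cols)
    total = 0.0
    thresh = logp_obs + abs(logp_obs) * _PP_RTOL + 1e-12

    # depth-first fill, row-major over the (nrow-1) x (ncol-1) free cells;
    # the last row/column are forced by the margins
    def rec(i: int, col_rem: np.ndarray, acc: float) -> None:
        nonlocal total
        if i == nrow - 1:
            lp = const - acc - sum(lf[c] for c in col_rem)
            if min(col_rem) >= 0 and lp <= thresh:
                total += math.exp(lp)
            return
        ri = rows[i]

        def fill(j: int, rem_r: int, col_rem: np.ndarray, acc: float) -> None:
            if j == ncol - 1:
                if rem_r <= col_rem[j]:
                    nxt = col_rem.copy()
                    nxt[j] -= rem_r
                    rec(i + 1, nxt, acc + lf[rem_r])
                return
            for v in range(min(rem_r, col_rem[j]) + 1):
                nxt = col_rem.copy()
                nxt[j] -= v
                fill(j + 1, rem_r - v, nxt, acc + lf[v])

        fill(0, ri, col_rem, acc)

    rec(0, cols.astype(np.int64).copy(), 0.0)
    return min(total, 1.0)


def _montecarlo_pvalue(
    rows: np.ndarray, cols: np.ndarray, logp_obs: float, n_iter: int, seed: int
) -> float:
    """Permutation estimate of the point-probability p-value."""
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    lf = [math.lgamma(i + 1) for i in range(int(rows.sum()) + 1)]
    const = sum(lf[r] for r in rows) + sum(lf[c] for c in cols) - lf[int(rows.sum())]
    thresh = logp_obs + abs(logp_obs) * _PP_RTOL + 1e-12
    hits = 0
    for _ in range(n_iter):
        perm = rng.permutation(col_labels)
        tab = np.zeros((len(rows), len(cols)), dtype=np.int64)
        np.add.at(tab, (row_labels, perm), 1)
        lp = const - sum(lf[v] for v in tab.flat)
        if lp <= thresh:
            hits += 1
    return (hits + 1) / (n_iter + 1)


def fisher_exact(table, *, n_iter: int = 200_000, seed: int = 0) -> float:
    """Two-sided exact test of independence for an r x c count table.

    The two-sided p-value is the total probability, under fixed margins, of
    all tables whose point (multivariate hypergeometric) probability does not
    exceed that of the observed table — the Freeman-Halton rule, identical to
    R's ``fisher.test``. Tables too large to enumerate fall back to a seeded
    Monte-Carlo permutation estimate (a warning is emitted).
    """
    t = _validate_table(table)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    # drop empty margins: they contribute nothing to the distribution
    t = t[rows > 0][:, cols > 0]
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    n = int(t.sum())
    lf = [math.lgamma(i + 1) for i in range(n + 1)]
    const = sum(lf[r] for r in rows) + sum(lf[c] for c in cols) - lf[n]
    logp_obs = const - sum(lf[v] for v in t.flat)
    if _table_count_bound(rows, cols) > _ENUMERATION_BUDGET:
        warnings.warn(
            "table too large for exact enumeration; using seeded Monte-Carlo",
            stacklevel=2,
        )
        return _montecarlo_pvalue(rows, cols, logp_obs, n_iter, seed)
    return _enumerate_pvalue(rows, cols, logp_obs)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when m + n <= 20 and there are no ties, otherwise the
    normal approximation with continuity correction (midranks for ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all values tied; rank-sum p-value is 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p for |rho| >= |observed|, conditioning on the ranks."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    hits = 0
    count = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= target:
            hits += 1
        count += 1
    return hits / count


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks) with a two-sided p-value.

    Exact permutation p-value for n <= 8; t-distribution approximation
    otherwise. Constant input is an error (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 for a rank correlation")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rank correlation undefined for constant input")
    rho, p_approx = sps.spearmanr(x, y)
    rho = float(rho)
    if x.size <= 8:
        return rho, _spearman_exact_p(x, y, rho)
    return rho, float(p_approx)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def fishers_method(pvalues) -> float:
    """Combine independent p-values: -2 sum(ln p) ~ chi-square with 2k d.f."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(sps.combine_pvalues(p, method="fisher").pvalue)


def _grubbs_critical(n: int, alpha: float) -> float:
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(values, alpha: float = 0.05) -> np.ndarray:
    """Iterated two-sided Grubbs test; returns a boolean outlier mask.

    At each pass the most extreme remaining value is tested with
    G = max|x - mean| / sd against the t-based critical value; flagged values
    are removed and the test repeated until no value is flagged or fewer than
    three values remain.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d array")
    mask = np.zeros(x.size, dtype=bool)
    active = np.arange(x.size)
    while active.size >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > _grubbs_critical(active.size, alpha):
            mask[active[i]] = True
            active = np.delete(active, i)
        else:
            break
    return mask


@dataclass
class SurvivalFit:
    """Kaplan-Meier curves for two groups with the log-rank comparison."""

    curves: dict = field(repr=False)
    chi2: float = float("nan")
    pvalue: float = float("nan")


def _check_survival(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event", "group"):
        if col not in df.columns:
            raise ValueError(f"survival table must contain a '{col}' column")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    if int(df["event"].sum()) == 0:
        raise ValueError("no events in the survival table")
    return df


def km_logrank(df: pd.DataFrame) -> SurvivalFit:
    """Kaplan-Meier estimates per group and the two-group log-rank test.

    Expects columns ``time`` (positive), ``event`` (0/1) and ``group``.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    df = _check_survival(df)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank comparison needs exactly 2 groups, got {len(groups)}")
    curves = {}
    for g in groups:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[g] = kmf.survival_function_
    a, b = (df[df["group"] == g] for g in groups)
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return SurvivalFit(curves=curves, chi2=float(res.test_statistic), pvalue=float(res.p_value))


@dataclass
class CoxFit:
    hr: float
    ci_low: float
    ci_high: float
    pvalue: float
    coef: float


def cox_univariate(df: pd.DataFrame) -> CoxFit:
    """Univariate Cox proportional-hazards fit on a binary group covariate.

    Efron handling of tied event times; the hazard ratio is for the
    lexicographically larger group label versus the smaller. Requires at
    least one event in each group (a monotone partial likelihood does not
    converge; Firth-type penalization is out of scope).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = _check_survival(df)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("univariate Cox fit expects a binary group covariate")
    for g in groups:
        if int(df.loc[df["group"] == g, "event"].sum()) == 0:
            raise ValueError(
                f"group {g!r} has no events: partial likelihood is monotone "
                "(Firth-type handling is out of scope)"
            )
    model_df = pd.DataFrame(
        {
            "time": df["time"].to_numpy(dtype=float),
            "event": df["event"].to_numpy(dtype=int),
            "x": (df["group"] == groups[1]).to_numpy(dtype=float),
        }
    )
    cph = CoxPHFitter()
    try:
        cph.fit(model_df, duration_col="time", event_col="event")
    except ConvergenceError as exc:  # pragma: no cover - defensive
        raise ValueError(f"Cox fit did not converge: {exc}") from exc
    coef = float(cph.params_["x"])
    ci = cph.confidence_intervals_
    return CoxFit(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(ci.iloc[0, 0])),
        ci_high=float(np.exp(ci.iloc[0, 1])),
        pvalue=float(cph.summary.loc["x", "p"]),
        coef=coef,
    )
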