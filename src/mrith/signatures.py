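"""Single-sample gene-set scoring, cohort Z-scores, and median-split labels.

The per-sample enrichment score (ES) is the rank-weighted running-sum
statistic of single-sample GSEA: genes are ordered by descending abundance
within each sample, set members accumulate weight ``rank_value**alpha``
(the top gene carrying the largest rank value) while non-members accumulate
uniformly, and the ES is the sum of the difference of the two cumulative
fractions over the whole ranked list. The score depends only on the within-
sample gene ranking, so it is invariant to any strictly increasing
per-sample transform of expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ESCAPE_SIGNATURE",
    "SSGSEAScorer",
    "ssgsea_score",
    "zscore_signatures",
    "classify_high_low",
    "patient_consistency",
]

#: 12-gene immune-escape signature (TGF-beta / extracellular-matrix axis
#: genes linked to immune evasion in clear cell renal cell carcinoma).
ESCAPE_SIGNATURE: tuple[str, ...] = (
    "TIMP1", "PXDN", "COL15A1", "OLFML2B", "COL5A2", "DLX5",
    "SOX11", "KLHDC8A", "UNC5A", "ADAMTS14", "MMP11", "FN1",
)


def _resolve_members(
    genes: pd.Index, members, name: str, min_frac_present: float
) -> list[str]:
    members = list(dict.fromkeys(members))  # de-duplicate, keep order
    if not members:
        raise ValueError(f"gene set {name!r} is empty")
    present = [g for g in members if g in genes]
    if not present:
        raise ValueError(f"no gene of set {name!r} is present in the matrix")
    if len(present) < len(members):
        frac = len(present) / len(members)
        if frac < min_frac_present:
            raise ValueError(
                f"only {len(present)}/{len(members)} genes of set {name!r} "
                f"found in the matrix (< {min_frac_present:.0%})"
            )
        warnings.warn(
            f"{len(members) - len(present)} genes of set {name!r} absent "
            "from the matrix; scoring on the remainder",
            stacklevel=3,
        )
    return present


def _es_one_sample(values: np.ndarray, order: np.ndarray, in_set: np.ndarray,
                   alpha: float) -> float:
    # order: gene indices sorted by descending expression (ties broken by
    # gene identifier); rank value n..1 so the top gene weighs most
    n = values.size
    member = in_set[order]
    rank_value = np.arange(n, 0, -1, dtype=float)
    w = rank_value**alpha
    w_in = np.where(member, w, 0.0).cumsum()
    tot_in = w_in[-1]
    if tot_in == 0:
        raise ValueError("gene set has no member in the ranked list")
    n_out = n - member.sum()
    if n_out == 0:
        raise ValueError("gene set covers the whole matrix; ES undefined")
    p_in = w_in / tot_in
    p_out = np.where(~member, 1.0, 0.0).cumsum() / n_out
    return float(np.sum(p_in - p_out))


class SSGSEAScorer(BaseEstimator, TransformerMixin):
    """Score samples against gene signatures with single-sample GSEA.

    Parameters
    ----------
    signatures : dict[str, list[str]]
        Signature name -> member gene identifiers.
    weight_exponent : float, default 0.25
        Exponent on the rank value in the weighted running sum.
    min_frac_present : float, default 0.5
        Minimum fraction of a signature that must be present in the matrix;
        missing members below this are a warning, above it an error.

    The transformer consumes a samples x genes DataFrame (sklearn
    orientation) of raw non-negative abundances and returns a samples x
    signatures DataFrame of enrichment scores.
    """

    def __init__(self, signatures=None, weight_exponent: float = 0.25,
                 min_frac_present: float = 0.5):
        self.signatures = signatures
        self.weight_exponent = weight_exponent
        self.min_frac_present = min_frac_present

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a samples x genes DataFrame")
        if X.shape[1] < 2:
            raise ValueError("need at least 2 genes")
        if (X.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        sigs = self.signatures or {"immune_escape": list(ESCAPE_SIGNATURE)}
        self.members_ = {
            name: _resolve_members(X.columns, genes, name, self.min_frac_present)
            for name, genes in sigs.items()
        }
        self.genes_ = X.columns.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "members_"):
            raise ValueError("scorer is not fitted")
        if not X.columns.equals(self.genes_):
            raise ValueError("gene columns differ from the fitted matrix")
        vals = X.to_numpy(dtype=float)
        # lexicographic gene-id order as the deterministic tie-break
        id_rank = np.argsort(np.argsort(X.columns.to_numpy()))
        out = {}
        for name, members in self.members_.items():
            in_set = X.columns.isin(members)
            col = np.empty(X.shape[0])
            for i in range(X.shape[0]):
                order = np.lexsort((id_rank, -vals[i]))
                col[i] = _es_one_sample(vals[i], order, in_set,
                                        self.weight_exponent)
            out[name] = col
        return pd.DataFrame(out, index=X.index)


def ssgsea_score(matrix: pd.DataFrame, signature, name: str = "signature",
                 weight_exponent: float = 0.25) -> pd.Series:
    """Per-sample enrichment score for one gene set.

    ``matrix`` is genes x samples (the field's on-disk orientation).
    """
    scorer = SSGSEAScorer({name: list(signature)}, weight_exponent=weight_exponent)
    X = matrix.T
    return scorer.fit(X).transform(X)[name]


def zscore_signatures(scores: pd.Series) -> pd.Series:
    """Cohort Z-scores: (ES - mean) / sample sd (ddof=1)."""
    s = pd.Series(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples to Z-score")
    sd = s.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("degenerate signature: zero variance across the cohort")
    return (s - s.mean()) / sd


def classify_high_low(values) -> pd.Series:
    """Median split: strictly above the median -> 'high', else 'low'."""
    s = pd.Series(values, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 values for a median split")
    med = s.median()
    return pd.Series(np.where(s > med, "high", "low"), index=s.index)


def patient_consistency(labels: pd.Series, sheet: pd.DataFrame) -> pd.DataFrame:
    """Collapse region-level high/low labels to a per-patient class.

    All eligible regions high -> ``high``; all low -> ``low``; otherwise
    ``mixed``. Pre-treatment regions of treated patients (patients with any
    post-treatment region) are excluded before tallying, and patients left
    with a single eligible region are flagged ``single_region`` and excluded
    from the cohort tally.
    """
    unknown = labels.index.difference(sheet.index)
    if len(unknown):
        raise ValueError(f"labels for samples absent from the sheet: {list(unknown)}")
    meta = sheet.loc[labels.index]
    treated = set(meta.loc[meta["timepoint"] == "post", "patient"])
    eligible = meta[
        (meta["tissue"] == "tumor")
        & ~((meta["timepoint"] == "pre") & meta["patient"].isin(treated))
    ]
    rows = []
    for patient, sub in eligible.groupby("patient"):
        lab = labels.loc[sub.index]
        if len(lab) == 1:
            rows.append((patient, "single_region", len(lab), True))
            continue
        if (lab == "high").all():
            cls = "high"
        elif (lab == "low").all():
            cls = "low"
        else:
            cls = "mixed"
        rows.append((patient, cls, len(lab), False))
    return pd.DataFrame(
        rows, columns=["patient", "class", "n_regions", "excluded"]
    ).set_index("patient")
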