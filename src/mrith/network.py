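"""Weighted co-expression modules and the immune-escape signature.

An unsigned weighted network is built from Pearson correlations of log2
expression (adjacency ``|cor|**beta``), the soft power beta chosen as the
smallest grid value whose connectivity distribution fits a scale-free law
at the configured R-squared. Genes are clustered on topological-overlap
dissimilarity (average linkage, static cut), each module summarized by its
eigengene (first principal component of the standardized module submatrix),
and modules are annotated by the Spearman correlation of their eigengene
with cohort traits — the module most correlated with the fraction of
neoantigens depleted is the immune-escape module. The module is then
refined to a core signature in which every gene pair maintains Spearman
rho >= 0.6.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from . import stats
from .signatures import classify_high_low, ssgsea_score

__all__ = [
    "filter_genes",
    "pick_soft_power",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "annotate_modules",
    "refine_signature",
    "score_escape",
    "CoexpressionModules",
]


def filter_genes(matrix: pd.DataFrame, coding: pd.Series | None = None,
                 min_frac_expressed: float = 0.05, sd_floor: float = 1.0,
                 pseudocount: float = 1.0) -> pd.DataFrame:
    """Drop low-expressed, invariant and (when flagged) non-coding genes.

    Keeps genes with raw abundance > 0 in at least ``min_frac_expressed``
    of samples and sd of log2(x + pseudocount) strictly greater than
    ``sd_floor``; ``coding`` is an optional gene -> bool protein-coding
    flag. Input is raw (TPM) genes x samples.
    """
    x = matrix.to_numpy(dtype=float)
    expressed_frac = (x > 0).mean(axis=1)
    sd = np.log2(x + pseudocount).std(axis=1, ddof=1)
    keep = (expressed_frac >= min_frac_expressed) & (sd > sd_floor)
    if coding is not None:
        keep &= coding.reindex(matrix.index, fill_value=False).to_numpy(dtype=bool)
    out = matrix[keep]
    if out.empty:
        raise ValueError("no genes survive filtering")
    return out


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R-squared of log10(frequency) on log10(connectivity).

    Connectivities are discretized into ``n_bins`` equal-width bins; the
    mean connectivity and occupancy fraction of each non-empty bin give the
    points of the log-log regression (a straight line under a power law).
    """
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    mids, freqs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (k >= lo) & (k < hi)
        if sel.sum() == 0:
            continue
        mids.append(k[sel].mean())
        freqs.append(sel.mean())
    if len(mids) < 3:
        return 0.0
    lm, lfq = np.log10(mids), np.log10(freqs)
    if np.unique(lm).size < 2 or np.unique(lfq).size < 2:
        return 0.0
    r = np.corrcoef(lm, lfq)[0, 1]
    return float(r * r)


def pick_soft_power(log_matrix: pd.DataFrame, grid=range(1, 21),
                    r2_target: float = 0.8) -> tuple[int, pd.DataFrame]:
    """Choose the soft-thresholding power for an unsigned network.

    For each beta in the grid, adjacency is ``|cor|**beta`` and the fit of
    the connectivity distribution to a scale-free law is scored; the
    smallest beta reaching ``r2_target`` wins, else the argmax with a
    warning. ``log_matrix`` is genes x samples in log2 space.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty soft-power grid")
    cor = np.corrcoef(log_matrix.to_numpy(dtype=float))
    if np.isnan(cor).all():
        raise ValueError("degenerate correlation matrix")
    cor = np.nan_to_num(np.abs(cor), nan=0.0)
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in grid:
        k = (cor**beta).sum(axis=1)
        rows.append((beta, _scale_free_r2(k), float(k.mean())))
    table = pd.DataFrame(rows, columns=["beta", "r2", "mean_k"]).set_index("beta")
    ok = table.index[table["r2"] >= r2_target]
    if len(ok):
        return int(ok[0]), table
    # fall back to the field's tabulated unsigned-network defaults by
    # sample size when no power reaches the scale-free target
    n_samples = log_matrix.shape[1]
    fallback = 9 if n_samples < 20 else 8 if n_samples < 30 else \
        7 if n_samples < 40 else 6
    fallback = min(max(grid), max(min(grid), fallback))
    warnings.warn(
        f"no power reaches scale-free R2 >= {r2_target}; "
        f"falling back to beta={fallback}",
        stacklevel=2,
    )
    return fallback, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with zero diagonal.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L = A @ A``; the diagonal is set to 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(tom: np.ndarray, genes, cut_height: float = 0.9,
                   min_module_size: int = 30) -> pd.Series:
    """Cluster genes on 1 - TOM and assign module labels.

    Average-linkage hierarchical clustering cut at ``cut_height``; clusters
    below ``min_module_size`` go to module 0 (unassigned). Surviving
    modules are renumbered 1..m by decreasing size.
    """
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes.index[sizes >= min_module_size]
    remap = {old: new for new, old in enumerate(
        sorted(keep, key=lambda c: -sizes[c]), start=1)}
    return labels.map(lambda c: remap.get(c, 0)).rename("module")


def module_eigengene(log_matrix: pd.DataFrame, module_genes) -> pd.Series:
    """First principal component of the standardized module submatrix.

    Returned with unit variance (ddof=1) over samples, oriented so its
    correlation with the module's mean expression profile is non-negative.
    Zero-variance genes are dropped with a warning.
    """
    genes = [g for g in module_genes if g in log_matrix.index]
    if not genes:
        raise ValueError("module has no genes present in the matrix")
    sub = log_matrix.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-variance genes dropped "
                      "from eigengene computation", stacklevel=2)
        sub = sub[sd > 0]
        sd = sd[sd > 0]
        if sub.shape[0] == 0:
            raise ValueError("all module genes have zero variance")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # samples x genes SVD; PC1 scores over samples
    u, s, _ = np.linalg.svd(z.T, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    pc1 = pc1 / pc1.std(ddof=1)
    mean_profile = z.mean(axis=0)
    if np.corrcoef(pc1, mean_profile)[0, 1] < 0:
        pc1 = -pc1
    return pd.Series(pc1, index=log_matrix.columns, name="eigengene")


def annotate_modules(eigengenes: pd.DataFrame, traits: pd.DataFrame,
                     module_sizes: pd.Series | None = None,
                     escape_trait: str = "depletion_fraction") -> pd.DataFrame:
    """Label modules by their strongest trait correlations.

    For every (module, trait) pair the Spearman rho of the eigengene with
    the trait is computed; per trait, the argmax-rho module receives the
    trait's label (``immune_escape`` for the neoantigen-depletion trait,
    otherwise ``<trait>-like``). Ties break toward the larger module.
    """
    common = eigengenes.index.intersection(traits.index)
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples to annotate modules")
    rows = []
    for mod in eigengenes.columns:
        for trait in traits.columns:
            t = traits.loc[common, trait]
            if t.nunique() == 1:
                warnings.warn(f"trait {trait!r} has zero variance; skipped",
                              stacklevel=2)
                continue
            rho, p = stats.spearman(eigengenes.loc[common, mod].to_numpy(),
                                    t.to_numpy())
            rows.append((mod, trait, rho, p))
    ann = pd.DataFrame(rows, columns=["module", "trait", "rho", "p"])
    ann["label"] = ""
    for trait, sub in ann.groupby("trait"):
        cand = sub[np.isclose(sub["rho"], sub["rho"].max())]
        if len(cand) > 1 and module_sizes is not None:
            size = cand["module"].map(module_sizes).fillna(0)
            best = size.idxmax()
        else:
            best = cand.index[0]
        name = "immune_escape" if trait == escape_trait else f"{trait}-like"
        ann.loc[best, "label"] = name
    return ann


def refine_signature(log_matrix: pd.DataFrame | None, module_genes,
                     rho_floor: float = 0.6,
                     rho_matrix: pd.DataFrame | None = None) -> list[str]:
    """Greedy core-signature extraction from a co-expression module.

    Genes are ordered by mean pairwise Spearman rho (descending); starting
    from the top gene, each candidate joins the signature iff its rho with
    every already-selected gene is at least ``rho_floor``. The result is
    guaranteed to have min pairwise rho >= ``rho_floor``. A precomputed
    gene x gene rank-correlation matrix can be supplied via ``rho_matrix``.
    """
    source = rho_matrix if rho_matrix is not None else log_matrix
    genes = [g for g in module_genes if g in source.index]
    if len(genes) < 2:
        raise ValueError("module needs >= 2 genes to refine")
    if rho_matrix is not None:
        rho = rho_matrix.loc[genes, genes].to_numpy(dtype=float)
    else:
        sub = log_matrix.loc[genes].to_numpy(dtype=float)
        rho, _ = sps.spearmanr(sub, axis=1)
        rho = np.atleast_2d(rho)
    mean_rho = (rho.sum(axis=1) - 1.0) / (len(genes) - 1)
    order = np.argsort(-mean_rho, kind="stable")
    selected = [order[0]]
    for idx in order[1:]:
        if all(rho[idx, s] >= rho_floor for s in selected):
            selected.append(idx)
    if len(selected) == 1:
        warnings.warn(
            f"no gene pair reaches rho >= {rho_floor}; returning the top gene",
            stacklevel=2,
        )
    return [genes[i] for i in selected]


def score_escape(matrix: pd.DataFrame, signature,
                 weight_exponent: float = 0.25) -> pd.DataFrame:
    """ssGSEA score of a signature with the cohort median-split label."""
    es = ssgsea_score(matrix, signature, name="escape",
                      weight_exponent=weight_exponent)
    return pd.DataFrame({"score": es, "label": classify_high_low(es)})


class CoexpressionModules(BaseEstimator, ClusterMixin):
    """Discover co-expression modules sklearn-style.

    Parameters mirror the network pipeline: ``soft_power`` (None = choose
    from ``soft_power_grid`` by scale-free fit), ``scale_free_r2_target``,
    ``cut_height`` on topological-overlap dissimilarity, and
    ``min_module_size``. ``fit`` expects a samples x genes DataFrame of
    log2 expression.

    Attributes
    ----------
    power_ : int
        Soft power used for the adjacency.
    labels_ : ndarray
        Module id per gene (0 = unassigned).
    modules_ : dict[int, list[str]]
        Module id -> member genes.
    eigengenes_ : DataFrame
        samples x modules eigengene matrix.
    """

    def __init__(self, soft_power=None, soft_power_grid=tuple(range(1, 21)),
                 scale_free_r2_target: float = 0.8, cut_height: float = 0.9,
                 min_module_size: int = 30):
        self.soft_power = soft_power
        self.soft_power_grid = soft_power_grid
        self.scale_free_r2_target = scale_free_r2_target
        self.cut_height = cut_height
        self.min_module_size = min_module_size

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a samples x genes DataFrame")
        if X.shape[1] < 20 or X.shape[0] < 8:
            raise ValueError("need >= 20 genes and >= 8 samples")
        log_matrix = X.T  # genes x samples internally
        if self.soft_power is None:
            self.power_, self.fit_table_ = pick_soft_power(
                log_matrix, grid=self.soft_power_grid,
                r2_target=self.scale_free_r2_target)
        else:
            self.power_ = int(self.soft_power)
            self.fit_table_ = None
        cor = np.corrcoef(log_matrix.to_numpy(dtype=float))
        cor = np.nan_to_num(np.abs(cor), nan=0.0)
        adj = cor**self.power_
        np.fill_diagonal(adj, 0.0)
        tom = tom_similarity(adj)
        module_labels = detect_modules(
            tom, log_matrix.index, cut_height=self.cut_height,
            min_module_size=self.min_module_size)
        self.labels_ = module_labels.to_numpy()
        self.module_labels_ = module_labels
        self.modules_ = {
            int(m): list(module_labels.index[module_labels == m])
            for m in sorted(module_labels.unique()) if m != 0
        }
        self.eigengenes_ = pd.DataFrame(
            {m: module_eigengene(log_matrix, genes)
             for m, genes in self.modules_.items()},
            index=log_matrix.columns,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
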