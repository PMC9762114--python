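"""T cell receptor repertoire metrics.

Works on AIRR-style rearrangement tables (``sample_id``, ``cdr3_aa``,
``v_call``, ``j_call``, ``duplicate_count``). A clonotype is identified by
its CDR3 amino-acid sequence plus V gene by default; the J gene can be
included via ``use_j=True``.

Diversity is Shannon entropy in nats; repertoire overlap is the
Morisita-Horn index (bounded in [0, 1]; the classic Morisita index is
available behind a flag). No depth normalization is applied by default; a
seeded fixed-depth downsampler is provided for cross-sample comparability.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "clone_counts",
    "diversity_summary",
    "morisita_overlap",
    "pairwise_overlap_matrix",
    "track_clonotypes",
    "downsample_counts",
]


def clone_counts(table: pd.DataFrame, sample: str, use_j: bool = False) -> pd.Series:
    """Aggregate a sample's clonotype counts keyed by CDR3aa + V (+ J)."""
    sub = table[table["sample_id"] == sample]
    if sub.empty:
        raise ValueError(f"no clonotypes for sample {sample!r}")
    keys = sub["cdr3_aa"].astype(str) + "|" + sub["v_call"].astype(str)
    if use_j:
        keys = keys + "|" + sub["j_call"].astype(str)
    return sub.groupby(keys.values)["duplicate_count"].sum()


class DiversitySummary(NamedTuple):
    shannon: float
    richness: int
    clone_count: int


def diversity_summary(table: pd.DataFrame, sample: str, use_j: bool = False
                      ) -> DiversitySummary:
    """Shannon entropy (nats), richness (distinct clonotypes) and total
    template count for one sample."""
    counts = clone_counts(table, sample, use_j=use_j).to_numpy(dtype=float)
    p = counts / counts.sum()
    shannon = float(-(p * np.log(p)).sum())
    return DiversitySummary(shannon, int(counts.size), int(counts.sum()))


def morisita_overlap(a: pd.Series, b: pd.Series, classic: bool = False) -> float:
    """Abundance-weighted clonotype overlap between two repertoires.

    Default is the Morisita-Horn index
    ``2 sum(x_i y_i) / ((sum(x^2)/X^2 + sum(y^2)/Y^2) X Y)``; ``classic=True``
    replaces the squared-proportion terms with Simpson indices on
    ``n(n-1)`` sampling (the original Morisita index, which can exceed 1).
    """
    if a.empty or b.empty:
        raise ValueError("both repertoires must be non-empty")
    union = a.index.union(b.index)
    x = a.reindex(union, fill_value=0).to_numpy(dtype=float)
    y = b.reindex(union, fill_value=0).to_numpy(dtype=float)
    X, Y = x.sum(), y.sum()
    if classic:
        lam_x = (x * (x - 1)).sum() / (X * (X - 1))
        lam_y = (y * (y - 1)).sum() / (Y * (Y - 1))
    else:
        lam_x = (x * x).sum() / X**2
        lam_y = (y * y).sum() / Y**2
    denom = (lam_x + lam_y) * X * Y
    if denom == 0:
        return 0.0
    return float(2.0 * (x * y).sum() / denom)


def pairwise_overlap_matrix(table: pd.DataFrame, samples=None, use_j: bool = False,
                            classic: bool = False) -> pd.DataFrame:
    """Symmetric sample x sample Morisita-Horn matrix with unit diagonal."""
    if samples is None:
        samples = sorted(table["sample_id"].unique())
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    reps = {s: clone_counts(table, s, use_j=use_j) for s in samples}
    m = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, s in enumerate(samples):
        for t in samples[i + 1:]:
            v = morisita_overlap(reps[s], reps[t], classic=classic)
            m.loc[s, t] = m.loc[t, s] = v
    return m


def track_clonotypes(table: pd.DataFrame, reference_sample: str, top_k: int = 10,
                     samples=None, use_j: bool = False) -> pd.DataFrame:
    """Relative frequencies of the reference sample's dominant clonotypes.

    Returns a clonotype x sample table of relative frequencies (0 where the
    clone is absent), rows ordered by reference frequency — the input for
    ribbon/alluvial tracking plots.
    """
    if samples is None:
        samples = sorted(table["sample_id"].unique())
    if reference_sample not in samples:
        raise ValueError(f"reference sample {reference_sample!r} not present")
    ref = clone_counts(table, reference_sample, use_j=use_j)
    if top_k > ref.size:
        warnings.warn(
            f"top_k={top_k} exceeds reference richness {ref.size}; truncating",
            stacklevel=2,
        )
        top_k = ref.size
    top = ref.sort_values(ascending=False).head(top_k)
    out = {}
    for s in samples:
        counts = clone_counts(table, s, use_j=use_j)
        freq = counts / counts.sum()
        out[s] = freq.reindex(top.index, fill_value=0.0)
    return pd.DataFrame(out, index=top.index)


def downsample_counts(counts: pd.Series, depth: int, seed: int = 0) -> pd.Series:
    """Subsample a repertoire to a fixed template depth without replacement."""
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds repertoire size {total}")
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(counts.to_numpy(dtype=np.int64), depth)
    out = pd.Series(drawn, index=counts.index)
    return out[out > 0]
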