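"""Intratumoral heterogeneity (ITH) scores across modalities.

* RNA ITH — after log2(x+1) and cohort-wide per-gene median centering, the
  per-patient score is the median over genes of the median absolute pairwise
  log2 difference between regions; it estimates the expected |log2 fold
  change| of a randomly chosen gene between two regions of the same tumor.
* DNA ITH — the ratio of subclonal to clonal driver alterations, an
  alteration being subclonal when present in fewer than half of a patient's
  sampled regions.
* TCR ITH — one minus the fraction of clonotypes shared across regions.

Also: two-cluster stratification of patients on binary genomic features
(driver mutations, HLA LOH, CDKN2A/B loss) with per-feature Fisher tests,
and neighbor-joining trees over regions from alteration presence profiles.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import stats
from .repertoire import clone_counts

__all__ = [
    "eligible_tumor_samples",
    "rna_ith",
    "dna_ith",
    "tcr_ith",
    "cluster_genomic_features",
    "nj_tree",
    "nj_tree_from_distances",
]


def eligible_tumor_samples(sheet: pd.DataFrame) -> pd.DataFrame:
    """Tumor samples eligible for multi-region scoring.

    Pre-treatment samples of treated patients (patients that have any
    post-treatment region) are excluded, so every ITH comparison is between
    concurrent regions of the same tumor.
    """
    tumor = sheet[sheet["tissue"] == "tumor"]
    treated = set(tumor.loc[tumor["timepoint"] == "post", "patient"])
    return tumor[~((tumor["timepoint"] == "pre")
                   & tumor["patient"].isin(treated))]


def rna_ith(matrix: pd.DataFrame, sheet: pd.DataFrame, pseudocount: float = 1.0,
            log_transform: bool = True) -> dict:
    """Per-patient and per-gene RNA heterogeneity scores.

    ``matrix`` is genes x samples raw abundance (TPM/FPKM). Values are
    log2(x + pseudocount) transformed (skip with ``log_transform=False`` if
    already in log space), then median-centered per gene across the cohort
    to remove gene-level bias. For each gene and patient the score is the
    median |pairwise difference| over that patient's tumor-region pairs;
    the patient score is the median over genes and the gene score the
    median over patients. Patients with fewer than two tumor regions are
    returned as NaN and listed under ``flagged``.
    """
    tumor = eligible_tumor_samples(sheet)
    samples = [s for s in matrix.columns if s in tumor.index]
    if not samples:
        raise ValueError("no tumor samples shared between matrix and sheet")
    x = matrix[samples].to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + pseudocount)
    x = x - np.median(x, axis=1, keepdims=True)
    centered = pd.DataFrame(x, index=matrix.index, columns=samples)

    per_gene_patient = {}
    flagged = []
    for patient, sub in tumor.loc[samples].groupby("patient"):
        regs = list(sub.index)
        if len(regs) < 2:
            flagged.append(patient)
            per_gene_patient[patient] = np.full(len(matrix.index), np.nan)
            continue
        diffs = np.abs(
            np.stack([
                centered[a].to_numpy() - centered[b].to_numpy()
                for a, b in itertools.combinations(regs, 2)
            ])
        )
        per_gene_patient[patient] = np.median(diffs, axis=0)
    gp = pd.DataFrame(per_gene_patient, index=matrix.index)
    return {
        "patient_scores": gp.median(axis=0),
        "gene_scores": gp.median(axis=1),
        "gene_by_patient": gp,
        "flagged": flagged,
    }


def dna_ith(mutations: pd.DataFrame, sheet: pd.DataFrame,
            driver_list=None, min_regions: int = 3) -> pd.DataFrame:
    """Subclonal/clonal driver-alteration ratio per patient.

    ``mutations`` is a long table of called alterations with ``patient``,
    ``sample`` and ``gene`` (restricted to ``driver_list`` when given). An
    alteration is subclonal iff its region count is strictly less than half
    the patient's sampled tumor regions. Patients with fewer than
    ``min_regions`` regions, or with no clonal alteration to divide by, get
    NaN and are flagged.
    """
    mut = mutations
    if driver_list is not None:
        mut = mut[mut["gene"].isin(set(driver_list))]
    tumor = eligible_tumor_samples(sheet)
    mut = mut[mut["sample"].isin(tumor.index)]
    rows = []
    for patient, sub in tumor.groupby("patient"):
        n_regions = len(sub)
        pm = mut[mut["patient"] == patient]
        alt_regions = pm.groupby("gene")["sample"].nunique()
        if n_regions < min_regions:
            rows.append((patient, np.nan, 0, 0, "too_few_regions"))
            continue
        if alt_regions.empty:
            rows.append((patient, np.nan, 0, 0, "no_driver_alterations"))
            continue
        subclonal = int((alt_regions < n_regions / 2).sum())
        clonal = int(len(alt_regions) - subclonal)
        if clonal == 0:
            rows.append((patient, np.nan, subclonal, 0, "no_clonal_alterations"))
            continue
        rows.append((patient, subclonal / clonal, subclonal, clonal, ""))
    return pd.DataFrame(
        rows, columns=["patient", "dna_ith", "n_subclonal", "n_clonal", "flag"]
    ).set_index("patient")


def tcr_ith(clonotypes: pd.DataFrame, sheet: pd.DataFrame, use_j: bool = False,
            shared_rule: str = "any_two") -> pd.Series:
    """1 - fraction of clonotypes shared across a patient's tumor regions.

    ``shared_rule='any_two'`` counts a clonotype as shared when detected in
    at least two regions; ``'all'`` requires every region. Empty regions
    are excluded with a warning; patients with fewer than two populated
    regions score NaN.
    """
    if shared_rule not in ("any_two", "all"):
        raise ValueError("shared_rule must be 'any_two' or 'all'")
    tumor = eligible_tumor_samples(sheet)
    out = {}
    for patient, sub in tumor.groupby("patient"):
        sets = []
        for s in sub.index:
            try:
                keys = set(clone_counts(clonotypes, s, use_j=use_j).index)
            except ValueError:
                warnings.warn(f"empty repertoire for region {s!r}; excluded",
                              stacklevel=2)
                continue
            sets.append(keys)
        if len(sets) < 2:
            out[patient] = np.nan
            continue
        union = set().union(*sets)
        if shared_rule == "all":
            shared = set.intersection(*sets)
        else:
            seen_twice = set()
            seen = set()
            for keys in sets:
                seen_twice |= keys & seen
                seen |= keys
            shared = seen_twice
        out[patient] = 1.0 - len(shared) / len(union)
    return pd.Series(out, dtype=float, name="tcr_ith")


def cluster_genomic_features(features: pd.DataFrame, dna_ith_scores: pd.Series,
                             modality_labels: pd.DataFrame | None = None) -> dict:
    """Two-cluster stratification of patients on binary genomic features.

    Hierarchical clustering (Jaccard distance, Ward linkage) of the
    patient x feature 0/1 matrix, cut into two clusters; the cluster with
    the higher median DNA ITH is labeled ``ITH-high``. Per-feature 2x2
    Fisher tests quantify cluster enrichment; when per-modality high/low
    labels are supplied their per-modality Fisher p-values are combined by
    Fisher's method.
    """
    if len(features) < 4:
        raise ValueError("need >= 4 patients to cluster")
    x = features.to_numpy(dtype=bool)
    if (x == x[0]).all():
        raise ValueError("degenerate clustering: all feature rows identical")
    d = pdist(x, metric="jaccard")
    # Ward on the Jaccard distances: average linkage chains badly on sparse
    # binary profiles and tends to split off singletons
    link = hierarchy.linkage(d, method="ward")
    labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
    clusters = pd.Series(labels, index=features.index)
    med = {
        c: dna_ith_scores.reindex(clusters.index[clusters == c]).median()
        for c in (1, 2)
    }
    high_cluster = max(med, key=lambda c: (-np.inf if pd.isna(med[c]) else med[c]))
    named = clusters.map(lambda c: "ITH-high" if c == high_cluster else "ITH-low")

    feature_tests = {}
    in_high = (named == "ITH-high").to_numpy()
    for feat in features.columns:
        v = features[feat].astype(bool).to_numpy()
        table = [
            [int((v & in_high).sum()), int((~v & in_high).sum())],
            [int((v & ~in_high).sum()), int((~v & ~in_high).sum())],
        ]
        feature_tests[feat] = stats.fisher_exact(table)
    result = {
        "clusters": named,
        "feature_pvalues": pd.Series(feature_tests).sort_values(),
        "linkage": link,
        "distance": "jaccard",
        "linkage_method": "average",
    }
    if modality_labels is not None:
        pvals = {}
        for mod in modality_labels.columns:
            lab = modality_labels[mod].reindex(named.index)
            mask = lab.notna()
            hi = (lab[mask] == "high").to_numpy()
            ih = in_high[mask.to_numpy()]
            table = [
                [int((hi & ih).sum()), int((~hi & ih).sum())],
                [int((hi & ~ih).sum()), int((~hi & ~ih).sum())],
            ]
            pvals[mod] = stats.fisher_exact(table)
        result["modality_pvalues"] = pd.Series(pvals)
        result["combined_p"] = stats.fishers_method(list(pvals.values()))
    return result


def _hamming_counts(presence: pd.DataFrame) -> pd.DataFrame:
    x = presence.to_numpy(dtype=bool)
    d = (x[:, None, :] != x[None, :, :]).sum(axis=2).astype(float)
    return pd.DataFrame(d, index=presence.index, columns=presence.index)


def nj_tree_from_distances(dist: pd.DataFrame) -> str:
    """Neighbor-joining tree (Newick) from a symmetric distance matrix."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(dist) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    dm = DistanceMatrix(dist.to_numpy(dtype=float), ids=[str(i) for i in dist.index])
    tree = nj(dm)
    return str(tree).strip()


def nj_tree(presence: pd.DataFrame) -> str:
    """Neighbor-joining region tree from a region x alteration 0/1 matrix.

    Distances are Hamming counts (number of discordant alterations between
    two regions); the unrooted tree is returned as a Newick string.
    """
    if len(presence) < 3:
        raise ValueError("neighbor joining needs >= 3 regions")
    return nj_tree_from_distances(_hamming_counts(presence))
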