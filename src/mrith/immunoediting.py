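"""Neoantigen enumeration, depletion accounting, and HERV immunoediting.

Candidate neoantigens are the 8-11-mer windows of a 17-residue mutant
context that contain the mutated residue; a candidate counts as a binder
when its best MHC class I percentile rank over the patient's alleles is
<= 2 (%Rank, lower = stronger) and as expressed when its source gene
exceeds 1 TPM. Depletion after therapy is quantified per treated region as
the fraction of pre-treatment neoantigens whose supporting mutation is no
longer detected, and every depleted (neoantigen, region) pair is assigned
one mechanism:

* HLA loss of heterozygosity covering a binding allele -> ``evasion_loh``
* purity-corrected expression log2 fold change < -1 -> ``evasion_expression``
* log2 fold change >= 0 with intact HLA -> ``elimination``
* the remaining interval [-1, 0) -> ``ambiguous``

Endogenous retrovirus (HERV) editing follows the same logic at the locus
level: loci whose expression correlates positively with TIL abundance at
BH-FDR < 0.05 are called immunogenic, and editing per treated region is the
median log2 change of those loci versus the matched pre-treatment sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "AMINO_ACIDS",
    "enumerate_peptides",
    "detect_neoantigens",
    "depletion_fraction",
    "fold_change",
    "classify_editing",
    "editing_calls",
    "depletion_clonality",
    "aa_selection",
    "herv_immunogenic",
    "herv_editing",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

EDITING_CLASSES = ("elimination", "evasion_loh", "evasion_expression", "ambiguous")


def enumerate_peptides(context: str, mutant_index: int,
                       lengths=range(8, 12)) -> list[tuple[str, int, int]]:
    """All 8-11-mer windows of a mutant peptide context covering the mutation.

    Parameters
    ----------
    context : str
        Mutant amino-acid context, canonically 17 residues with the mutant
        residue central; shorter contexts (protein termini) are accepted
        with a warning.
    mutant_index : int
        0-based position of the mutant residue within ``context``.

    Returns
    -------
    list of (peptide, start_offset, mutant_position_in_peptide)
    """
    n = len(context)
    if not 0 <= mutant_index < n:
        raise ValueError(f"mutant index {mutant_index} outside context of length {n}")
    bad = set(context.upper()) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues in context: {sorted(bad)}")
    if n < 17:
        warnings.warn(
            f"context shorter than 17 residues ({n}); truncated at a protein terminus",
            stacklevel=2,
        )
    out = []
    for L in lengths:
        for start in range(n - L + 1):
            if start <= mutant_index < start + L:
                out.append((context[start:start + L], start, mutant_index - start))
    return out


def detect_neoantigens(neoantigens: pd.DataFrame, mutation_calls: pd.DataFrame,
                       tpm: pd.DataFrame | None = None, rank_cut: float = 2.0,
                       tpm_cut: float = 1.0) -> pd.DataFrame:
    """Per-sample detection states for candidate neoantigens.

    Parameters
    ----------
    neoantigens : DataFrame
        One row per (mutation_id, peptide, hla_allele) with ``patient``,
        ``percent_rank`` and optionally ``gene``.
    mutation_calls : DataFrame
        Long table of called mutations with ``sample`` and ``mutation_id``.
    tpm : DataFrame, optional
        genes x samples TPM used for the ``expressed`` flag (source-gene
        TPM strictly greater than ``tpm_cut``).

    Returns
    -------
    DataFrame indexed by (patient, mutation_id) x samples with boolean
    detection states; a parallel ``expressed_`` column block when ``tpm``
    is given. A neoantigen is detected in a sample iff its supporting
    mutation is called there and its best %Rank over the patient's alleles
    is <= ``rank_cut`` (boundary inclusive).
    """
    if neoantigens["percent_rank"].isna().any():
        bad = neoantigens.loc[neoantigens["percent_rank"].isna(), "peptide"]
        raise ValueError(f"missing %Rank for peptides: {sorted(set(bad))}")
    best = (
        neoantigens.groupby(["patient", "mutation_id"])
        .agg(percent_rank=("percent_rank", "min"),
             gene=("gene", "first") if "gene" in neoantigens.columns else ("mutation_id", "first"))
        .reset_index()
    )
    best["binder"] = best["percent_rank"] <= rank_cut
    samples = sorted(mutation_calls["sample"].unique())
    called = {
        s: set(mutation_calls.loc[mutation_calls["sample"] == s, "mutation_id"])
        for s in samples
    }
    det = pd.DataFrame(
        {
            s: best["binder"].to_numpy()
            & best["mutation_id"].isin(called[s]).to_numpy()
            for s in samples
        },
        index=pd.MultiIndex.from_frame(best[["patient", "mutation_id"]]),
    )
    if tpm is not None:
        expressed = {
            f"expressed_{s}": tpm[s].reindex(best["gene"]).to_numpy() > tpm_cut
            for s in samples if s in tpm.columns
        }
        det = pd.concat(
            [det, pd.DataFrame(expressed, index=det.index)], axis=1)
    return det


def depletion_fraction(pre_set: set, post_sets: dict) -> tuple[pd.Series, float]:
    """Fraction of pre-treatment neoantigens lost in each treated region.

    Returns the per-region fractions ``|pre \\ post_r| / |pre|`` and their
    mean as the patient-level value.
    """
    pre = set(pre_set)
    if not pre:
        raise ValueError("empty pre-treatment neoantigen set: fraction undefined")
    per_region = pd.Series(
        {r: len(pre - set(post)) / len(pre) for r, post in post_sets.items()},
        dtype=float,
    )
    return per_region, float(per_region.mean())


def fold_change(tpm_post: float, purity_post: float, tpm_pre: float,
                purity_pre: float, eps: float = 0.1) -> float:
    """Purity-corrected expression fold change with a 0.1-TPM pseudo-floor."""
    if purity_post <= 0 or purity_pre <= 0:
        raise ValueError("tumor purity must be positive")
    return (tpm_post / purity_post + eps) / (tpm_pre / purity_pre + eps)


def classify_editing(depleted: pd.DataFrame) -> pd.Series:
    """Assign one editing mechanism to each depleted (neoantigen, region) pair.

    ``depleted`` must carry boolean ``hla_loh`` (loss covering a binding
    allele in that region) and ``log2fc`` (purity-corrected). Precedence:
    LOH first, then strong expression loss (log2FC < -1), then elimination
    (log2FC >= 0), with the unspecified interval [-1, 0) called ambiguous.
    """
    for col in ("hla_loh", "log2fc"):
        if col not in depleted.columns:
            raise ValueError(f"depleted table must carry a '{col}' column")
    if depleted["log2fc"].isna().any():
        raise ValueError("missing fold change (check purity values)")
    loh = depleted["hla_loh"].astype(bool).to_numpy()
    fc = depleted["log2fc"].to_numpy(dtype=float)
    out = np.where(
        loh, "evasion_loh",
        np.where(fc < -1, "evasion_expression",
                 np.where(fc >= 0, "elimination", "ambiguous")),
    )
    return pd.Series(out, index=depleted.index, name="editing_class")


def editing_calls(neoantigens: pd.DataFrame, flags: pd.DataFrame,
                  tpm: pd.DataFrame, sheet: pd.DataFrame,
                  depleted_pairs: pd.DataFrame, rank_cut: float = 2.0,
                  eps: float = 0.1, allele_specific: bool = True) -> pd.DataFrame:
    """Assemble and classify editing calls for depleted (neoantigen, region) pairs.

    ``depleted_pairs`` needs ``mutation_id``, ``region`` (post-treatment
    sample id) and ``pre_sample``. HLA LOH counts against a neoantigen only
    when the lost allele is one that binds it at <= ``rank_cut`` %Rank
    (``allele_specific=False`` falls back to the region-level flag). Fold
    changes are purity-corrected from the genes x samples ``tpm`` and the
    sheet's purities.
    """
    binding = neoantigens[neoantigens["percent_rank"] <= rank_cut]
    alleles_of = binding.groupby("mutation_id")["hla_allele"].agg(set)
    gene_of = neoantigens.drop_duplicates("mutation_id").set_index(
        "mutation_id")["gene"]
    rows = []
    for _, pair in depleted_pairs.iterrows():
        nid, region, pre_s = pair["mutation_id"], pair["region"], pair["pre_sample"]
        gene = gene_of[nid]
        if allele_specific:
            lost = flags.loc[region, "lost_allele"] if flags.loc[region, "hla_loh"] else None
            loh = bool(lost) and lost in alleles_of.get(nid, set())
        else:
            loh = bool(flags.loc[region, "hla_loh"])
        fc = fold_change(
            float(tpm.loc[gene, region]), float(sheet.loc[region, "purity"]),
            float(tpm.loc[gene, pre_s]), float(sheet.loc[pre_s, "purity"]),
            eps=eps,
        )
        rows.append((nid, region, loh, float(np.log2(fc))))
    calls = pd.DataFrame(rows, columns=["mutation_id", "region", "hla_loh",
                                        "log2fc"])
    calls["editing_class"] = classify_editing(calls)
    return calls


def depletion_clonality(pre_set: set, post_sets: dict) -> pd.DataFrame:
    """Per-neoantigen count of treated regions where it is depleted.

    ``clonal`` flags neoantigens depleted in every treated region.
    """
    if len(post_sets) < 2:
        raise ValueError("need >= 2 treated regions to assess clonality")
    pre = sorted(pre_set)
    n_regions = len(post_sets)
    counts = {
        neo: sum(neo not in set(post) for post in post_sets.values()) for neo in pre
    }
    df = pd.DataFrame({"n_regions_depleted": pd.Series(counts, dtype=int)})
    df["clonal"] = df["n_regions_depleted"] == n_regions
    return df


def aa_selection(depleted_residues, preserved_residues) -> pd.DataFrame:
    """Residue-level selection between depleted and preserved neoantigens.

    For each of the 20 amino acids, a 2x2 table (depleted/preserved x
    with/without the residue as the mutant amino acid) yields an odds ratio,
    a two-sided Fisher p and a BH q. Strong positive selection against a
    residue (e.g. hydrophobic phenylalanine) appears as OR > 1 among the
    depleted class.
    """
    dep = [str(r).upper() for r in depleted_residues]
    pres = [str(r).upper() for r in preserved_residues]
    bad = set(dep + pres) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"unknown residues: {sorted(bad)}")
    n_dep, n_pres = len(dep), len(pres)
    rows = []
    for aa in AMINO_ACIDS:
        a = dep.count(aa)
        b = n_dep - a
        c = pres.count(aa)
        d = n_pres - c
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        p = stats.fisher_exact([[a, b], [c, d]])
        rows.append((aa, a, b, c, d, odds, p))
    df = pd.DataFrame(
        rows,
        columns=["residue", "depleted_with", "depleted_without",
                 "preserved_with", "preserved_without", "odds_ratio", "p"],
    ).set_index("residue")
    df["q"] = stats.bh_adjust(df["p"].to_numpy())
    return df


def herv_immunogenic(hervs: pd.DataFrame, til: pd.Series,
                     fdr: float = 0.05) -> pd.DataFrame:
    """Flag HERV loci whose expression tracks TIL abundance.

    Spearman correlation of each locus (rows of the loci x samples matrix)
    against the per-sample TIL score; a locus is immunogenic iff its BH q
    is below ``fdr`` and rho is positive. Constant loci are skipped with a
    warning. The TIL score defaults, upstream, to an immune/T-effector
    ssGSEA signature.
    """
    common = hervs.columns.intersection(til.index)
    if len(common) < 5:
        raise ValueError("need >= 5 shared samples for the TIL correlation")
    t = til.loc[common].to_numpy(dtype=float)
    rows = []
    for locus, expr in hervs[common].iterrows():
        x = expr.to_numpy(dtype=float)
        if np.unique(x).size == 1:
            warnings.warn(f"constant HERV locus {locus!r} skipped", stacklevel=2)
            continue
        rho, p = stats.spearman(x, t)
        rows.append((locus, rho, p))
    df = pd.DataFrame(rows, columns=["locus", "rho", "p"]).set_index("locus")
    if df.empty:
        raise ValueError("no testable HERV loci")
    df["q"] = stats.bh_adjust(df["p"].to_numpy())
    df["immunogenic"] = (df["q"] < fdr) & (df["rho"] > 0)
    return df


def herv_editing(hervs: pd.DataFrame, sheet: pd.DataFrame,
                 immunogenic_loci, eps: float = 0.1,
                 grubbs_alpha: float = 0.05) -> dict:
    """HERV editing per treated region plus per-sample median HERV load.

    Editing for region r is the median over immunogenic loci of
    ``log2((expr_r / purity_r + eps) / (expr_pre / purity_pre + eps))``
    against the patient's matched pre-treatment sample. ``median_herv`` is
    the per-sample median over all loci; samples with outlying median load
    are flagged by an iterated Grubbs test.
    """
    loci = [l for l in immunogenic_loci if l in hervs.index]
    if not loci:
        raise ValueError("no immunogenic loci present: editing undefined")
    tumor = sheet[sheet["tissue"] == "tumor"]
    editing = {}
    for patient, sub in tumor.groupby("patient"):
        pre = sub[sub["timepoint"] == "pre"]
        post = sub[sub["timepoint"] == "post"]
        if pre.empty or post.empty:
            continue
        pre_sample = pre.index[0]
        if pre_sample not in hervs.columns:
            continue
        pre_expr = hervs.loc[loci, pre_sample].to_numpy(dtype=float)
        pre_pur = float(pre.iloc[0]["purity"])
        for s in post.index:
            if s not in hervs.columns:
                continue
            post_expr = hervs.loc[loci, s].to_numpy(dtype=float)
            post_pur = float(sheet.loc[s, "purity"])
            ratio = (post_expr / post_pur + eps) / (pre_expr / pre_pur + eps)
            editing[s] = float(np.median(np.log2(ratio)))
    median_herv = hervs.median(axis=0)
    mask = stats.grubbs_outliers(median_herv.to_numpy(), alpha=grubbs_alpha)
    return {
        "editing": pd.Series(editing, dtype=float),
        "median_herv": median_herv,
        "outlier_samples": list(median_herv.index[mask]),
    }
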