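"""Synthetic multi-regional cohort with known ground truth.

Emulates the data layout of a multi-region renal-cell-carcinoma immunotherapy
study — 29 patients with 3-5 sampled tumor regions each, mostly treated with
checkpoint blockade — so that every downstream stage (expression scoring,
ITH, immunoediting accounting, repertoire metrics, module discovery,
survival stratification) can be exercised and its truth recovery measured
without any external download.

Ground-truth structure planted per stage:

* expression — a latent-factor model: genes of module m follow
  ``sqrt(rho) * f_m + sqrt(1-rho) * noise`` so the intra-module pairwise
  correlation is ``rho`` by construction; a designated trait (the fraction
  of neoantigens depleted) is built from the module factors at configured
  correlations; gene-level multiplicative offsets exercise median-centering.
* mutations/neoantigens — driver alterations clonal (all regions) or
  subclonal (< half of regions); pre-treatment neoantigen candidates with
  %Rank straddling the 2% binding threshold; post-treatment depletion at an
  exact per-region rate with one editing mechanism per depleted neoantigen
  (elimination / HLA-LOH evasion / expression-loss evasion / ambiguous),
  with HLA-loss flags and purity-corrected fold changes consistent with the
  assigned class.
* clonotypes — Zipf-distributed clone abundances with controlled
  inter-region sharing (clones copied across region tables with resampled
  counts), plus peripheral-blood timepoints.
* clinical — exponential survival with a configured hazard ratio between
  signature-high and -low groups and independent censoring.

One global integer seed drives independent per-stage substreams
(``SeedSequence((seed, stage_id))``), so any stage can be regenerated
without the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .immunoediting import AMINO_ACIDS

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort",
           "generate_expression", "generate_mutations", "generate_clonotypes",
           "generate_clinical", "write_cohort"]

_STAGE_IDS = {"expression": 1, "mutations": 2, "clonotypes": 3, "clinical": 4}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation parameters; defaults are the study conditions.

    29 patients (6 untreated) with 3-5 tumor regions each; 1000 genes with
    five planted co-expression modules, the first linked to the neoantigen
    depletion trait; ccRCC-like driver prevalences; 60 pre-treatment
    neoantigens per patient depleted at 30% per region; Zipf clonotype
    abundances (exponent 1.2) with 60% inter-region sharing; exponential
    survival at hazard ratio 1.5 with 30% censoring.
    """

    n_patients: int = 29
    n_untreated: int = 6
    regions_min: int = 3
    regions_max: int = 5
    n_genes: int = 1000
    module_sizes: tuple = (60, 50, 40, 40, 30)
    module_intra_cor: float = 0.8
    module_trait_cor: tuple = (0.8, 0.0, 0.0, 0.0, 0.0)
    driver_genes: dict = field(default_factory=lambda: {
        "VHL": 0.75, "PBRM1": 0.45, "SETD2": 0.30, "BAP1": 0.15,
    })
    subclonal_rate: float = 0.3
    hla_loh_rate: float = 0.25
    cdkn2ab_loss_rate: float = 0.3
    tier_enrichment: float = 3.5
    n_neoantigens_per_patient: int = 60
    depletion_rate: float = 0.3
    depletion_clonal_frac: float = 0.6
    editing_mix: tuple = (0.40, 0.25, 0.25, 0.10)
    clonotype_zipf_exponent: float = 1.2
    n_clonotypes: int = 800
    top_clone_count: int = 20000
    region_sharing: float = 0.6
    survival_hr: float = 1.5
    censor_rate: float = 0.3
    survival_scale: float = 24.0
    seed: int = 0

    def __post_init__(self):
        probs = {
            "subclonal_rate": self.subclonal_rate,
            "hla_loh_rate": self.hla_loh_rate,
            "cdkn2ab_loss_rate": self.cdkn2ab_loss_rate,
            "depletion_rate": self.depletion_rate,
            "depletion_clonal_frac": self.depletion_clonal_frac,
            "region_sharing": self.region_sharing,
            "censor_rate": self.censor_rate,
            "module_intra_cor": self.module_intra_cor,
            **{f"driver_genes[{g}]": p for g, p in self.driver_genes.items()},
        }
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.regions_min < 2:
            raise ValueError("regions_per_patient must be >= 2")
        if self.regions_max < self.regions_min:
            raise ValueError("regions_max < regions_min")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if len(self.module_trait_cor) != len(self.module_sizes):
            raise ValueError("module_trait_cor must match module_sizes in length")
        if any(abs(c) > 1 for c in self.module_trait_cor):
            raise ValueError("module_trait_cor values must lie in [-1, 1]")
        if sum(c * c for c in self.module_trait_cor) > 1:
            raise ValueError("sum of squared module_trait_cor must be <= 1")
        if abs(sum(self.editing_mix) - 1) > 1e-9:
            raise ValueError("editing_mix must sum to 1")
        if len(self.editing_mix) != 4:
            raise ValueError("editing_mix needs 4 proportions")
        if self.clonotype_zipf_exponent <= 0:
            raise ValueError("Zipf exponent must be > 0")
        if self.survival_hr <= 0:
            raise ValueError("hazard ratio must be > 0")
        if not 0 <= self.n_untreated <= self.n_patients:
            raise ValueError("n_untreated out of range")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence((self.seed, _STAGE_IDS[stage]))
        )


def _patients(config: CohortConfig) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(config.n_patients)]


def _patient_layout(config: CohortConfig) -> pd.DataFrame:
    """Deterministic per-patient layout: regions, treatment, ITH tier."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    rows = []
    for i, pid in enumerate(_patients(config)):
        n_regions = int(rng.integers(config.regions_min, config.regions_max + 1))
        treated = i >= config.n_untreated
        tier = "high" if rng.random() < 0.5 else "low"
        rows.append((pid, n_regions, treated, tier))
    return pd.DataFrame(rows, columns=["patient", "n_regions", "treated", "tier"]
                        ).set_index("patient")


def build_sample_sheet(config: CohortConfig) -> pd.DataFrame:
    layout = _patient_layout(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 5)))
    rows = []
    for pid, row in layout.iterrows():
        tp = "post" if row["treated"] else "untreated"
        for r in range(1, int(row["n_regions"]) + 1):
            purity = float(np.round(rng.uniform(0.3, 0.9), 3))
            rows.append((f"{pid}_R{r}", pid, f"R{r}", tp, "tumor", purity))
        if row["treated"]:
            purity = float(np.round(rng.uniform(0.3, 0.9), 3))
            rows.append((f"{pid}_PRE", pid, "PRE", "pre", "tumor", purity))
            rows.append((f"{pid}_PBMC_pre", pid, "PBMC", "pre", "pbmc", np.nan))
            rows.append((f"{pid}_PBMC_post", pid, "PBMC", "post", "pbmc", np.nan))
    return pd.DataFrame(rows, columns=mio.SHEET_COLUMNS).set_index("sample")


def generate_expression(config: CohortConfig, sheet: pd.DataFrame | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Genes x samples TPM matrix with planted modules and a linked trait."""
    if sheet is None:
        sheet = build_sample_sheet(config)
    samples = list(sheet.index[sheet["tissue"] == "tumor"])
    n_s = len(samples)
    rng = config.rng("expression")

    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    module_of = np.zeros(config.n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        module_of[pos:pos + size] = m
        pos += size

    n_mod = len(config.module_sizes)
    factors = rng.standard_normal((n_mod, n_s))
    rho = config.module_intra_cor
    z = rng.standard_normal((config.n_genes, n_s))
    for m in range(1, n_mod + 1):
        sel = module_of == m
        # hub structure: per-gene loadings jitter around sqrt(rho) so the
        # mean intra-module pairwise correlation is ~rho while individual
        # pairs spread, as in real co-expression modules
        load = np.clip(np.sqrt(rho) * (1 + rng.uniform(-0.15, 0.15, sel.sum())),
                       0.0, 0.99)
        z[sel] = load[:, None] * factors[m - 1] + \
            np.sqrt(1 - load**2)[:, None] * z[sel]
    # pervasive weak co-expression in the background, as in real
    # transcriptomes: many small co-regulated groups (all below the module
    # detector's minimum size) of varying strength, which give the
    # connectivity distribution its heavy tail without forming modules
    bg_idx = rng.permutation(np.flatnonzero(module_of == 0))
    pos_bg = 0
    while pos_bg < bg_idx.size:
        size = int(rng.integers(3, 26))
        grp = bg_idx[pos_bg:pos_bg + size]
        level = rng.uniform(0.1, 0.5)
        f = rng.standard_normal(n_s)
        z[grp] = np.sqrt(level) * f + np.sqrt(1 - level) * z[grp]
        pos_bg += size

    # gene-level offsets and scales; module genes always pass the sd filter
    mu = rng.uniform(1.0, 8.0, size=config.n_genes)
    sd = rng.uniform(0.4, 2.0, size=config.n_genes)
    in_module = module_of > 0
    mu[in_module] = rng.uniform(3.0, 8.0, size=in_module.sum())
    sd[in_module] = rng.uniform(1.3, 1.8, size=in_module.sum())

    logx = mu[:, None] + sd[:, None] * z
    tpm = np.maximum(np.exp2(logx) - 1.0, 0.0)

    # a few background genes expressed in almost no samples (filter fodder)
    bg = np.flatnonzero(~in_module)
    rare = rng.choice(bg, size=max(1, len(bg) // 30), replace=False)
    for g in rare:
        off = rng.random(n_s) < 0.97
        tpm[g, off] = 0.0

    coding = np.ones(config.n_genes, dtype=bool)
    noncoding = rng.choice(bg, size=max(1, len(bg) // 20), replace=False)
    coding[noncoding] = False

    # trait built from the module factors at the configured correlations
    c = np.asarray(config.module_trait_cor, dtype=float)
    resid = np.sqrt(max(0.0, 1.0 - float(c @ c)))
    trait_raw = c @ factors + resid * rng.standard_normal(n_s)
    # monotone map onto a plausible depletion-fraction scale (rank-preserving)
    trait = 1.0 / (1.0 + np.exp(-trait_raw))

    matrix = pd.DataFrame(tpm, index=pd.Index(genes, name="gene"),
                          columns=samples)
    truth = {
        "gene_module": pd.Series(module_of, index=genes, name="module"),
        "coding": pd.Series(coding, index=genes, name="coding"),
        "factors": pd.DataFrame(factors.T, index=samples,
                                columns=[f"M{m + 1}" for m in range(n_mod)]),
        "trait": pd.Series(trait, index=samples, name="depletion_fraction"),
        "trait_raw": pd.Series(trait_raw, index=samples),
    }
    return matrix, truth


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_mutations(config: CohortConfig, sheet: pd.DataFrame | None = None
                       ) -> dict:
    """Driver alterations, region flags, neoantigen tables and depletion truth."""
    if sheet is None:
        sheet = build_sample_sheet(config)
    layout = _patient_layout(config)
    rng = config.rng("mutations")
    mix = np.asarray(config.editing_mix, dtype=float)

    mut_rows, neo_rows, tpm_rows, flag_rows = [], [], [], []
    clonality_truth, class_truth, dep_truth = {}, {}, {}
    patient_state: dict[str, dict] = {}

    # pass 1: per-patient layout, drivers, LOH/9p flags and depleted sets
    for pid, lay in layout.iterrows():
        n_regions = int(lay["n_regions"])
        regions = [f"{pid}_R{r}" for r in range(1, n_regions + 1)]
        treated = bool(lay["treated"])
        tier_hi = lay["tier"] == "high"
        # the ITH-high phenotype carries more subclonal alterations and is
        # enriched for SETD2/BAP1 mutation, HLA LOH and CDKN2A/B (9p) loss
        boost = config.tier_enrichment if tier_hi else 1.0 / config.tier_enrichment

        # driver small variants: clonal = all regions, subclonal = < half;
        # VHL stays essentially truncal (clonal) as in real ccRCC, keeping a
        # clonal denominator for the DNA ITH ratio
        for gene, prev in config.driver_genes.items():
            tier_linked = gene in ("SETD2", "BAP1")
            p_alt = min(1.0, prev * (boost if tier_linked else 1.0))
            if rng.random() >= p_alt:
                continue
            truncal_weight = 0.15 if gene == "VHL" else 1.0
            sub_rate = min(0.9, config.subclonal_rate * boost * truncal_weight)
            mut_id = f"{pid}_{gene}"
            if rng.random() < sub_rate and n_regions >= 3:
                kmax = (n_regions - 1) // 2
                k = int(rng.integers(1, kmax + 1))
                present = list(rng.choice(regions, size=k, replace=False))
                clonality_truth[mut_id] = "subclonal"
            else:
                present = regions
                clonality_truth[mut_id] = "clonal"
            for s in present:
                mut_rows.append((pid, s, gene, mut_id))
            if treated:
                mut_rows.append((pid, f"{pid}_PRE", gene, mut_id))

        # HLA LOH is a patient-level, tier-linked event hitting a subset of
        # regions (clonal in most carriers); decided before editing so that
        # LOH-mediated evasion can only occur where an allele was lost
        loh_regions: set = set()
        if rng.random() < min(1.0, config.hla_loh_rate * boost):
            if rng.random() < 0.7:
                loh_regions = set(regions)
            else:
                k = int(rng.integers(1, n_regions))
                loh_regions = set(rng.choice(regions, size=k, replace=False))

        # CDKN2A/B (9p) loss: patient-level, tier-linked; clonal in half of
        # the carriers, otherwise confined to a random subset of regions
        cdkn_regions: set = set()
        if rng.random() < min(1.0, config.cdkn2ab_loss_rate * boost):
            if rng.random() < 0.5:
                cdkn_regions = set(regions)
            else:
                k = int(rng.integers(1, n_regions))
                cdkn_regions = set(rng.choice(regions, size=k, replace=False))

        # neoantigens: clonal supporting mutations, %Rank straddling 2;
        # depletion at an exact per-region rate, a clonal core plus
        # region-private losses
        n_neo = config.n_neoantigens_per_patient
        neo_ids = [f"{pid}_NEO{i + 1:03d}" for i in range(n_neo)]
        n_dep = int(round(config.depletion_rate * n_neo)) if treated else 0
        n_clonal_dep = int(round(config.depletion_clonal_frac * n_dep))
        dep_clonal = list(rng.choice(neo_ids, size=n_dep, replace=False))
        clonal_set = set(dep_clonal[:n_clonal_dep])
        private_pool = [i for i in neo_ids if i not in clonal_set]
        depleted_in: dict[str, set] = {}
        for s in regions:
            extra = list(rng.choice(private_pool, size=n_dep - n_clonal_dep,
                                    replace=False)) if n_dep > n_clonal_dep else []
            depleted_in[s] = clonal_set | set(extra)
        if treated:
            dep_truth[pid] = {s: len(depleted_in[s]) / n_neo for s in regions}

        patient_state[pid] = {
            "regions": regions, "treated": treated,
            "loh_regions": loh_regions, "cdkn_regions": cdkn_regions,
            "neo_ids": neo_ids,
            "binder_rank": np.round(rng.uniform(0.05, 2.0, size=n_neo), 3),
            "tpm_pre": np.round(rng.uniform(2.0, 50.0, size=n_neo), 3),
            "depleted_in": depleted_in,
        }

    # cohort-level mechanism allocation: the evasion_loh share of the
    # configured editing mix is assigned to neoantigens whose depleted
    # regions all lost an HLA allele; everything else draws from the
    # remaining classes at their renormalized proportions
    all_depleted, eligible = [], []
    for pid, st in patient_state.items():
        ever = sorted(set().union(*st["depleted_in"].values())
                      if st["depleted_in"] else set())
        st["ever_depleted"] = ever
        for nid in ever:
            gone_in = {s for s in st["regions"] if nid in st["depleted_in"][s]}
            all_depleted.append(nid)
            if gone_in and gone_in <= st["loh_regions"]:
                eligible.append(nid)
    target_loh = int(round(mix[1] * len(all_depleted)))
    chosen_loh = set(
        rng.choice(eligible, size=min(target_loh, len(eligible)),
                   replace=False)) if eligible else set()
    rest_classes = np.array(["elimination", "evasion_expression", "ambiguous"])
    rest_mix = np.array([mix[0], mix[2], mix[3]])
    rest_mix = rest_mix / rest_mix.sum()
    for nid in all_depleted:
        class_truth[nid] = ("evasion_loh" if nid in chosen_loh
                            else str(rng.choice(rest_classes, p=rest_mix)))

    # pass 2: emit neoantigen records, mutation calls and class-consistent TPM
    for pid, st in patient_state.items():
        regions, treated = st["regions"], st["treated"]
        depleted_in = st["depleted_in"]
        lost_allele, kept_allele = f"{pid}_HLA2", f"{pid}_HLA1"
        pre_sample = f"{pid}_PRE" if treated else None
        if pre_sample:
            pur_pre = float(sheet.loc[pre_sample, "purity"])
        for i, nid in enumerate(st["neo_ids"]):
            gene = f"NEOG_{nid}"
            context = _random_peptide(rng, 17)
            start = int(rng.integers(0, 9))  # 9-mer windows covering center
            peptide = context[start:start + 9]
            allele = (lost_allele if class_truth.get(nid) == "evasion_loh"
                      else kept_allele)
            neo_rows.append((pid, nid, gene, context, 8, peptide,
                             8 - start, allele, st["binder_rank"][i]))
            # decoy candidate above the binding threshold
            if rng.random() < 0.2:
                neo_rows.append((pid, nid, gene, context, 8,
                                 context[start + 1:start + 10], 7 - start,
                                 kept_allele,
                                 float(np.round(rng.uniform(2.01, 10.0), 3))))
            # supporting mutation: clonal pre-treatment, dropped where depleted
            if treated:
                mut_rows.append((pid, pre_sample, gene, nid))
            for s in regions:
                if nid not in depleted_in.get(s, set()):
                    mut_rows.append((pid, s, gene, nid))
            # per-sample TPM consistent with the editing class
            tpm_pre_i = float(st["tpm_pre"][i])
            if pre_sample:
                tpm_rows.append((gene, pre_sample, tpm_pre_i))
            for s in regions:
                if not treated:
                    tpm_rows.append((gene, s, tpm_pre_i))
                    continue
                pur_post = float(sheet.loc[s, "purity"])
                if nid in depleted_in[s]:
                    cls = class_truth[nid]
                    lfc = {
                        "elimination": rng.uniform(0.0, 1.0),
                        "evasion_loh": rng.uniform(-0.5, 1.0),
                        "evasion_expression": rng.uniform(-4.0, -1.2),
                        "ambiguous": rng.uniform(-0.9, -0.1),
                    }[cls]
                else:
                    lfc = rng.uniform(-0.3, 0.3)
                base = tpm_pre_i / pur_pre + 0.1
                tpm_post = max(0.0, pur_post * (np.exp2(lfc) * base - 0.1))
                tpm_rows.append((gene, s, float(tpm_post)))

        for s in regions:
            loh = s in st["loh_regions"]
            flag_rows.append((s, pid, loh, lost_allele if loh else "",
                              s in st["cdkn_regions"]))

    mutations = pd.DataFrame(mut_rows,
                             columns=["patient", "sample", "gene", "mutation_id"])
    neoantigens = pd.DataFrame(neo_rows, columns=[
        "patient", "mutation_id", "gene", "context17", "mutant_index",
        "peptide", "mutant_pos", "hla_allele", "percent_rank"])
    tpm_long = pd.DataFrame(tpm_rows, columns=["gene", "sample", "tpm"])
    neo_tpm = tpm_long.pivot_table(index="gene", columns="sample", values="tpm",
                                   fill_value=0.0)
    flags = pd.DataFrame(flag_rows, columns=[
        "sample", "patient", "hla_loh", "lost_allele", "cdkn2ab_loss"]
    ).set_index("sample")
    truth = {
        "alteration_clonality": clonality_truth,
        "editing_class": class_truth,
        "depletion_fraction": dep_truth,
        "tier": layout["tier"].to_dict(),
    }
    return {"mutations": mutations, "neoantigens": neoantigens,
            "neo_tpm": neo_tpm, "flags": flags, "truth": truth}


_V_GENES = [f"TRBV{i}" for i in range(1, 31)]
_J_GENES = [f"TRBJ{i}-{j}" for i in (1, 2) for j in range(1, 7)]


def _zipf_counts(rng: np.random.Generator, n: int, exponent: float,
                 top: int) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    counts = np.maximum(1, np.round(top * ranks**-exponent)).astype(np.int64)
    return rng.permutation(counts)


def _fresh_clones(rng: np.random.Generator, n: int) -> list[tuple[str, str, str]]:
    """Batch of random clonotypes (CDR3 amino-acid string + V/J labels)."""
    if n == 0:
        return []
    lengths = rng.integers(10, 17, size=n)
    chars = rng.choice(list(AMINO_ACIDS), size=(n, 14))
    vs = rng.choice(_V_GENES, size=n)
    js = rng.choice(_J_GENES, size=n)
    return [
        ("C" + "".join(chars[i, :lengths[i] - 2]) + "F", str(vs[i]), str(js[i]))
        for i in range(n)
    ]


def generate_clonotypes(config: CohortConfig, sheet: pd.DataFrame | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """AIRR-style clonotype tables with Zipf abundances and planted sharing."""
    if sheet is None:
        sheet = build_sample_sheet(config)
    layout = _patient_layout(config)
    rng = config.rng("clonotypes")
    rows = []
    sharing_truth = {}
    for pid, lay in layout.iterrows():
        n_regions = int(lay["n_regions"])
        regions = [f"{pid}_R{r}" for r in range(1, n_regions + 1)]
        base = _fresh_clones(rng, config.n_clonotypes)

        def derived(share_prob: float) -> list:
            keep = rng.random(len(base)) < share_prob
            fresh = iter(_fresh_clones(rng, int((~keep).sum())))
            return [c if k else next(fresh) for c, k in zip(base, keep)]

        region_clones = {regions[0]: list(base)}
        for s in regions[1:]:
            region_clones[s] = derived(config.region_sharing)
        if bool(lay["treated"]):
            # matched pre-treatment tumor sample shares clones like a region
            region_clones[f"{pid}_PRE"] = derived(config.region_sharing)
            for s in (f"{pid}_PBMC_pre", f"{pid}_PBMC_post"):
                region_clones[s] = derived(0.5)
        for s, clones in region_clones.items():
            counts = _zipf_counts(rng, len(clones),
                                  config.clonotype_zipf_exponent,
                                  config.top_clone_count)
            for (cdr3, v, j), c in zip(clones, counts):
                rows.append((s, cdr3, v, j, int(c)))
        pattern: dict[str, list[str]] = {}
        for s in regions:
            for cdr3, v, _j in region_clones[s]:
                pattern.setdefault(f"{cdr3}|{v}", []).append(s)
        sharing_truth[pid] = pattern
    table = pd.DataFrame(rows, columns=mio.AIRR_COLUMNS)
    # collapse accidental duplicate keys within a sample
    table = (table.groupby(["sample_id", "cdr3_aa", "v_call", "j_call"],
                           as_index=False)["duplicate_count"].sum())
    return table[mio.AIRR_COLUMNS], {"sharing": sharing_truth}


def generate_clinical(config: CohortConfig, n: int | None = None
                      ) -> tuple[pd.DataFrame, dict]:
    """Exponential survival with a configured hazard ratio and censoring."""
    rng = config.rng("clinical")
    n = config.n_patients if n is None else int(n)
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    group = np.array(["high" if i < n // 2 else "low" for i in range(n)])
    base_rate = 1.0 / config.survival_scale
    rate = np.where(group == "high", base_rate * config.survival_hr, base_rate)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(n) < config.censor_rate
    time = np.where(censored, rng.random(n) * t_event, t_event)
    time = np.maximum(time, 1e-6)
    df = pd.DataFrame({
        "subject": subjects,
        "time": np.round(time, 4),
        "event": (~censored).astype(int),
        "group": group,
    })
    return df, {"group": dict(zip(subjects, group)), "hr": config.survival_hr}


@dataclass
class SyntheticCohort:
    config: CohortConfig
    sheet: pd.DataFrame
    expression: pd.DataFrame
    mutations: pd.DataFrame
    neoantigens: pd.DataFrame
    neo_tpm: pd.DataFrame
    flags: pd.DataFrame
    clonotypes: pd.DataFrame
    survival: pd.DataFrame
    truth: dict


def generate_cohort(config: CohortConfig | None = None, **kwargs) -> SyntheticCohort:
    """Generate every table of the synthetic cohort from one config."""
    if config is None:
        config = CohortConfig(**kwargs)
    sheet = build_sample_sheet(config)
    expression, expr_truth = generate_expression(config, sheet)
    mut = generate_mutations(config, sheet)
    clonotypes, clono_truth = generate_clonotypes(config, sheet)
    survival, surv_truth = generate_clinical(config)
    truth = {"expression": expr_truth, "mutations": mut["truth"],
             "clonotypes": clono_truth, "clinical": surv_truth}
    return SyntheticCohort(
        config=config, sheet=sheet, expression=expression,
        mutations=mut["mutations"], neoantigens=mut["neoantigens"],
        neo_tpm=mut["neo_tpm"], flags=mut["flags"], clonotypes=clonotypes,
        survival=survival, truth=truth,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write every cohort table plus the truth JSON and module GMT."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_expression(cohort.expression, out / "expression.tsv")
    mio.write_sample_sheet(cohort.sheet, out / "sample_sheet.tsv")
    mio.write_mutations(cohort.mutations, out / "mutations.tsv")
    mio.write_neoantigens(cohort.neoantigens, out / "neoantigens.tsv")
    cohort.neo_tpm.to_csv(out / "neoantigen_tpm.tsv", sep="\t",
                          index_label="gene")
    cohort.flags.reset_index().to_csv(out / "region_flags.tsv", sep="\t",
                                      index=False)
    mio.write_clonotypes(cohort.clonotypes, out / "clonotypes.tsv")
    mio.write_survival(cohort.survival, out / "survival.tsv")
    modules = cohort.truth["expression"]["gene_module"]
    sets = {f"module_{m}": list(modules.index[modules == m])
            for m in sorted(modules.unique()) if m != 0}
    mio.write_gmt(sets, out / "planted_modules.gmt")
    config_dict = dataclasses.asdict(cohort.config)
    (out / "truth.json").write_text(json.dumps(
        {"config": _jsonable(config_dict), "truth": _jsonable(cohort.truth)},
        indent=1, default=str))
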