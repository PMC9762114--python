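# mrith — multi-regional tumor/immune heterogeneity analysis

Clear cell renal cell carcinoma (ccRCC) tumors are spatially heterogeneous:
different regions of one tumor can differ in their driver mutations, their
immune microenvironment, and their T cell repertoires, and this intratumoral
heterogeneity (ITH) shapes how tumors escape immune attack during checkpoint
blockade. `mrith` implements the analysis stages of a multi-regional
tumor/immune study as a tested, reusable Python package, for computational
biologists working with per-region expression matrices, mutation calls,
neoantigen candidate tables, and TCR clonotype tables:

* **ITH scores per modality.**
  RNA ITH is the expected absolute log2 fold change of a random gene between
  two regions of the same tumor: after per-gene median centering of
  log2(x+1) expression, per gene the median |pairwise region difference| is
  taken, then the median over genes.
  DNA ITH = (# subclonal driver alterations)/(# clonal), an alteration being
  *subclonal* when present in fewer than half of a patient's regions.
  TCR ITH = 1 − |shared clonotypes| / |union of clonotypes| across regions.
  All scores are median-split into high/low.
* **Signature scoring** by single-sample GSEA: per sample, genes are ranked
  by descending abundance and the enrichment score is
  ES = Σᵢ [P_in(i) − P_out(i)] with P_in weighted by rank^0.25 — a
  rank-based score invariant to monotone per-sample transforms. The 12-gene
  immune-escape signature (TIMP1 … FN1) ships with the package.
* **Immunoediting accounting.** Candidate neoantigens are the 8–11-mer
  windows of a 17-residue mutant context containing the mutated residue
  (32 windows for a central mutant), detected when MHC-I %Rank ≤ 2 and
  expressed when gene TPM > 1. Depletion per treated region is
  |pre \ post| / |pre|; each depleted neoantigen is assigned one mechanism:
  HLA-LOH evasion, expression-loss evasion (purity-corrected log2FC < −1),
  immune elimination (log2FC ≥ 0, HLA intact), or ambiguous. HERV editing
  applies the same logic to TIL-correlated ("immunogenic") retroviral loci.
* **Co-expression modules** (WGCNA-style): unsigned adjacency |cor|^β with
  β chosen by scale-free fit, topological-overlap clustering, module
  eigengenes, trait annotation (the module most correlated with the
  fraction of neoantigens depleted is the immune-escape module), and greedy
  refinement to a core signature with all pairwise Spearman ρ ≥ 0.6.
* **Statistical kernel**: exact r×c Fisher tests (Freeman–Halton, matching
  R's `fisher.test`), Wilcoxon, Spearman, Benjamini–Hochberg, Fisher's
  p-value combination, Grubbs outliers, Kaplan–Meier/log-rank and
  univariate Cox (via lifelines).
* **A synthetic multi-regional cohort generator** with full ground truth
  (planted modules, clonal/subclonal drivers, editing mechanisms, clonotype
  sharing, survival hazard ratio), so every stage is testable end to end
  without any data download.

## Worked example

Simulate a cohort and score its heterogeneity from the shell:

```bash
mrith simulate --seed 17 --outdir cohort
mrith ith --expr cohort/expression.tsv --maf cohort/mutations.tsv \
      --tcr cohort/clonotypes.tsv --sheet cohort/sample_sheet.tsv \
      --drivers VHL,PBRM1,SETD2,BAP1 --out ith
head -4 ith/ith_scores.tsv
```

```
patient  rna_ith  dna_ith  tcr_ith  rna_ith_label  dna_ith_label  tcr_ith_label
P01      1.186    3.0      0.621    low            high           high
P02      1.192    0.0      0.628    low            low            high
P03      1.245    2.0      0.630    low            high           high
```

P01 carries three subclonal driver alterations per clonal one (DNA ITH 3.0,
classified high), while P02's drivers are fully clonal (DNA ITH 0). A TCR
ITH of 0.62 means 62% of clonotypes were confined to a single region.

The same from Python, with module discovery on the planted co-expression
structure:

```python
import numpy as np
import mrith
from mrith import network

cohort = mrith.generate_cohort(mrith.CohortConfig(seed=17))
expr = network.filter_genes(cohort.expression,
                            coding=cohort.truth["expression"]["coding"])
model = network.CoexpressionModules().fit(np.log2(expr + 1).T)
model.power_        # 5  (smallest beta with scale-free R^2 >= 0.8)
model.modules_      # {1: [...60 genes], 2: [...50 genes], ...}
```

The module whose eigengene best tracks the fraction of neoantigens depleted
is annotated `immune_escape` (`network.annotate_modules`), and
`network.refine_signature` reduces it to a core set whose minimum pairwise
Spearman ρ is ≥ 0.6 — the procedure that yields the packaged 12-gene
immune-escape signature on real cohorts.

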