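# Methods

This note documents the models, rules and numerical choices behind each
analysis stage, what the synthetic cohort emulates (and what it does not),
and the design decisions taken where more than one reading was defensible.

## Heterogeneity scores

**RNA ITH.** Expression is log2(x + 1) transformed (pseudocount 1 on
TPM/FPKM; configurable) and median-centered per gene across the cohort's
eligible tumor samples, which removes any gene-level multiplicative bias.
For each gene and patient, the score is the median of |pairwise
differences| over all region pairs; the patient score is the median over
genes (the expected |log2 fold change| of a randomly chosen gene between
two regions), and the gene score the median over patients. Pre-treatment
samples of treated patients are excluded from all multi-region scoring so
that comparisons are between concurrent regions only. Patients with fewer
than two eligible regions are returned as NaN and flagged.

**DNA ITH** is the ratio of subclonal to clonal driver alterations, an
alteration being subclonal iff its region count is strictly below half the
patient's sampled regions (so 2 of 4 regions is clonal). A minimum of
three regions is required — "enough biopsies" is not otherwise
quantifiable — and patients with no clonal alteration have an undefined
ratio and are flagged rather than scored.

**TCR ITH** is 1 − |shared| / |union| over clonotypes keyed by CDR3
amino-acid sequence + V gene (the J gene can be added via `use_j`; V+CDR3
is the default because clonotype callers disagree on J-level resolution).
"Shared" defaults to *detected in at least two regions*; the stricter
*all regions* reading is available via `shared_rule="all"`.

**Genomic-feature clustering.** Patients are clustered on binary flags
(driver mutations; HLA LOH; CDKN2A/B loss — a patient is wildtype only if
every region is wildtype) using Jaccard distances. Ward linkage is used:
average linkage chains badly on sparse binary profiles and tends to split
off singletons instead of producing two interpretable groups. The cluster
with the higher median DNA ITH is labeled ITH-high; per-feature 2×2 Fisher
tests quantify enrichment, and when per-modality high/low labels are
supplied their p-values are combined by Fisher's method (−2Σln p ~ χ²₂ₖ);
no other reading of "combined" testing is well defined.

**Region trees.** Neighbor joining on Hamming distances (counts of
discordant alterations) between region presence/absence profiles, written
as Newick. NJ reproduces any additive metric exactly, which the tests
verify on a four-taxon matrix with known branch lengths.

## Signature scoring

Single-sample GSEA: per sample, genes are ordered by descending raw
abundance (deterministic tie-break on the gene identifier); the gene at
descending position i carries rank value N − i + 1 and weight
(rank value)^α with α = 0.25. The enrichment score is the sum over the
ranked list of the difference between the weighted in-set cumulative
fraction and the uniform out-of-set cumulative fraction — the full
running-sum integral, not its maximum deviation. Ranks are taken on raw
abundance; any strictly increasing per-sample transform (including log)
leaves the score unchanged, which is property-tested. Cohort Z-scores use
the sample (n−1) standard deviation. Median splits label values strictly
above the median "high"; ties at the median are "low", keeping "high"
strictly above threshold. Signature genes missing from the matrix are
dropped with a warning if at least half the set remains, otherwise an
error names the signature.

## Immunoediting

Candidate peptides are all 8–11-mer windows of the 17-residue mutant
context that cover the mutated residue; a central mutant admits
8 + 9 + 8 + 7 = 32 windows. Detection requires the supporting mutation to
be called in the sample (DNA-level operationalization of "undetectable";
an expression-level alternative would conflate transcriptional silencing
with clonal loss) and best %Rank over the patient's alleles ≤ 2
(boundary inclusive); "expressed" additionally requires source-gene
TPM > 1 (strict).

Depletion per treated region is |pre \ post| / |pre|; the patient value is
the mean over regions. Each depleted (neoantigen, region) pair receives
exactly one mechanism, in precedence order: HLA LOH covering a binding
allele → `evasion_loh`; purity-corrected log2 fold change < −1 →
`evasion_expression`; log2FC ≥ 0 → `elimination`; the remaining interval
[−1, 0) → `ambiguous` (its fate is otherwise unspecified; we surface it
rather than silently binning it). Fold changes are
(TPM_post/purity_post + ε)/(TPM_pre/purity_pre + ε) with ε = 0.1 TPM
guarding against division by zero. LOH is allele-specific by default — a
lost allele only counts against neoantigens it binds at ≤ 2 %Rank — with a
region-level fallback via `allele_specific=False`.

Residue-level selection compares the mutant amino acid composition of
depleted versus preserved neoantigens: per residue a 2×2 table, odds
ratio, two-sided Fisher p and BH q.

HERV loci are immunogenic when their expression correlates positively with
a TIL-abundance score at BH-FDR < 0.05 (Spearman); the TIL score defaults
to an immune/T-effector ssGSEA signature since no particular estimator is
canonical. HERV editing per treated region is the median log2 change of
immunogenic loci versus the matched pre-treatment sample, purity-corrected
with the same ε. Samples with outlying median HERV load are flagged by an
iterated two-sided Grubbs test at α = 0.05.

## Co-expression modules

Genes are filtered to those expressed (raw > 0) in ≥ 5% of samples, with
sd of log2(TPM+1) strictly greater than 1, and flagged protein-coding.
The network is unsigned (|cor|^β on Pearson correlations of log2
expression); unsigned is the method's default and the choice is recorded.
The soft power is the smallest grid value (default 1–20) whose
connectivity distribution fits a scale-free law at R² ≥ 0.8. The fit bins
connectivity into 10 equal-width bins and regresses log10(bin frequency)
on log10(mean bin connectivity); equal-width (not equal-count) binning is
required — equal-count bins have constant frequency by construction and no
regression is possible. When no power reaches the target, the tabulated
sample-size defaults for unsigned networks are used (β = 6 at ≥ 40
samples) rather than the argmax of a noisy fit curve.

Topological overlap is TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)
with L = A², diagonal 1. Modules come from average-linkage clustering of
1 − TOM with a static cut (default height 0.9 — low enough to separate
blocks whose cross-TOM is ≈ 0.1, high enough to keep genuine modules
intact; configurable) and a 30-gene minimum size; smaller clusters are
unassigned (module 0). Static cutting replaces the dynamic hybrid tree
cut: it is simpler and deterministic, at the cost of less adaptive module
boundaries. Eigengenes are the first principal component of the per-gene
z-scored module submatrix, scaled to unit variance and sign-oriented to
correlate positively with the module's mean expression profile.

Modules are annotated per trait by the Spearman correlation of their
eigengene: the argmax-ρ module takes the trait's label, the neoantigen
depletion-fraction trait defining the immune-escape module; ties break
toward the larger module. Refinement is greedy: order genes by mean
pairwise Spearman ρ descending, seed with the top gene, and admit each
next gene iff its ρ with every selected gene is ≥ 0.6 — the stated sort
criterion does not uniquely determine an algorithm, and this reading
guarantees the documented invariant (min pairwise ρ ≥ floor) by
construction.

## Statistical kernel

The r×c exact test enumerates all tables with the observed margins and
sums the probabilities of those whose point (multivariate hypergeometric)
probability does not exceed the observed one — the Freeman–Halton rule
with the point-probability ordering, which reproduces R's `fisher.test`
(0.0357 and 0.0302 on the two TIL-pathology tables, printed as 0.036 and
0.03). A relative tolerance of 1e−7 on log-probabilities protects ties
from floating-point noise. Tables whose enumeration would exceed 10⁷
candidates fall back to a seeded Monte-Carlo permutation estimate with a
warning. Wilcoxon is exact by enumeration for m + n ≤ 20 without ties,
otherwise normal with continuity correction on midranks. Spearman p is by
exact permutation for n ≤ 8, otherwise the t approximation. BH is the
standard step-up with monotonicity. Survival: Kaplan–Meier product-limit
curves, the standard log-rank χ²₁, and univariate Cox by partial-likelihood
maximization with Efron tie handling (the common software default);
a group without events makes the partial likelihood monotone and is
rejected with an explicit error (Firth-type penalization is out of scope).

## Synthetic cohort

The generator emulates the *layout and planted structure* of a
multi-regional ccRCC immunotherapy cohort: 29 patients (6 untreated, 23
post-therapy with a matched pre-treatment sample), 3–5 tumor regions each,
tumor purities in [0.3, 0.9]. One integer seed drives independent
per-stage substreams (`SeedSequence((seed, stage_id))`), so any stage can
be regenerated alone and all outputs are bit-reproducible.

*Expression* uses a latent-factor model: module genes load on a shared
factor with per-gene loadings jittered ±15% around √ρ (hub structure;
mean intra-module pairwise correlation ≈ ρ, default 0.8), background
genes form many small (< 30-gene) weak groups of varying strength — the
pervasive weak co-expression of real transcriptomes, and what gives the
connectivity distribution the heavy tail a scale-free fit needs. The
default 1000 genes with five modules (60/50/40/40/30) are a desk-scale
stand-in for a ~20k-gene transcriptome: downstream stages consume module
structure, not genome size. A depletion-fraction trait is built from the
module factors at configured correlations (default: module 1 at 0.8,
rest 0) and mapped monotonically onto [0, 1]. Gene-level offsets (μ ~
U(1,8) in log2) exercise median centering; a few near-silent and
non-coding genes exercise the filters.

*Mutations/neoantigens.* Driver prevalences are ccRCC-like (VHL 0.75,
PBRM1 0.45, SETD2 0.30, BAP1 0.15). Each patient has a planted ITH tier;
high-tier patients have more subclonal alterations and are enriched
(×3.5) for SETD2/BAP1 mutation, HLA LOH, and CDKN2A/B loss — a deliberately
strong contrast so that the two phenotypes are separable by unsupervised
clustering of binary flags, which is what the tier-recovery tests measure.
VHL keeps a strong truncal weight so the DNA ITH denominator rarely
vanishes. Every patient gets 60 pre-treatment neoantigens (random 17-mers,
central mutant, %Rank straddling the 2% threshold, plus non-binding
decoys). Depletion is planted at an exact per-region rate (default 0.3),
with a clonal core (60% of depleted neoantigens lost in every region) plus
region-private losses. Mechanisms are allocated at the cohort level so
realized proportions match the configured editing mix (default 0.40
elimination / 0.25 LOH evasion / 0.25 expression evasion / 0.10
ambiguous): the LOH-evasion quota goes only to neoantigens whose depleted
regions all lost an HLA allele, and their binding allele is set to the
lost one; fold changes are drawn inside each class's defining interval.
This makes the classifier's truth agreement exact by construction —
the tests therefore validate rule implementation and plumbing, not
robustness to borderline fold changes, which real data would contribute.

*Clonotypes.* Zipf rank-abundance (exponent 1.2, top clone 20,000
templates, 800 clones per sample); each non-base region keeps a base
clone with probability `region_sharing` (default 0.6) and replaces the
rest with fresh clones, counts resampled; matched pre-treatment and
peripheral-blood samples included. Sharing extremes map exactly to TCR
ITH 0 and 1.

*Clinical.* Exponential event times with the high-signature group's
hazard = HR × baseline (default HR 1.5, baseline mean 24 months);
independent censoring marks each subject censored with probability
`censor_rate` at a uniform fraction of its event time.

What the generator does **not** emulate: read-level noise, alignment or
calling artifacts, real HLA typing, copy-number segmentation, borderline
editing fold changes, batch effects, or inter-gene correlation beyond the
factor structure. Passing truth-recovery tests therefore demonstrates
correctness of the computations under the stated models, not performance
on raw sequencing data.

## Problem sizes and runtime

The default test suite and the acceptance script run on one CPU in a few
minutes: cohorts of 29 patients / 1000 genes, 20-seed module-recovery
replicates, 100-replicate Cox calibration at n = 500, and exhaustive 2×2
Fisher verification to total 40. These sizes were chosen to make the
stochastic checks statistically meaningful while staying desk-scale.

## Known limitations

* The static tree cut needs a sensible `cut_height` for very tight or very
  loose networks; the dynamic hybrid cut of the reference implementation
  adapts better on real data.
* The r×c exact test is exponential in table size; beyond the enumeration
  budget the Monte-Carlo fallback returns a seeded estimate, not an exact
  value.
* Cox fitting is univariate by design; multivariable or stratified models
  are out of scope.
* The 85→12-gene refinement on the real cohort is not reproducible without
  the controlled-access data; the package guarantees the refinement
  invariant (min pairwise ρ ≥ 0.6) and recovers planted trait-linked
  modules instead.
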