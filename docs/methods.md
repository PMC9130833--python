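# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Tissue-specificity screen

**Replicate averaging and filtering.** The entry object is a genes x samples
FPKM matrix with a sample-to-tissue map. Replicates are averaged per tissue
on the raw FPKM scale (arithmetic mean); genes whose mean FPKM is below 1 in
*every* tissue are removed. The boundary is literal: a gene with a tissue
mean exactly 1 is retained, since removal requires being strictly below the
threshold everywhere. Missing values are not permitted; imputation is out of
scope.

**The tau index.** For per-tissue means x_1..x_N,

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1),

which is 0 for uniform expression and 1 when a single tissue carries all
expression. tau is computed on raw tissue means; a `log2p1` option exists but
is off by default because the screen's downstream rules (FPKM > 1, rank)
operate on the raw scale. An all-zero profile has no defined tau and is
reported as missing (such genes cannot survive the filter anyway).

**Candidate selection.** The top `top_fraction` (default 20%) of filtered
genes by tau are candidates; the count is `ceil(top_fraction * G)`. Ties at
the boundary tau are resolved deterministically: strictly-greater genes are
all included, then remaining slots are filled in lexicographic gene-id order.

**The three-rule caller.** A candidate is specific to tissue t when its mean
FPKM there is strictly greater than `fpkm_min` (default 1) *and* t falls
within the top `rank_k` (default 3) of the gene's profile under dense
descending ranks — so tissues tied at rank `rank_k` are all admitted. A gene
may therefore be called specific to up to three tissues (more only under
ties). Raising `fpkm_min` or lowering `rank_k` can only remove calls.

**Recovery scoring.** `evaluate_tsg_recovery` scores calls against planted
truth over the planted genes' (gene, tissue) assignments: recall is the
fraction of planted assignments recovered; precision is the fraction of calls
made on planted genes that hit a planted assignment. Calls on non-planted
genes are reported separately (`background_genes_called`,
`overall_pair_precision`) rather than folded into precision, because the
top-fraction candidate rule admits a fixed share of the filtered panel
regardless of how many genes are genuinely specific: whenever the filtered
universe exceeds `planted / top_fraction`, some background genes are
screened, and each surviving background candidate necessarily passes the
FPKM rule at its own maximum. Whole-call-set precision therefore measures
the candidate-fraction choice, not the caller's localisation accuracy; both
numbers are emitted so the distinction is visible.

## Differential expression (adipose group vs rest)

Counts are normalised with median-of-ratios size factors: s_j is the median
over genes (restricted to genes positive in every sample) of
k_gj / geometric-mean_g. Per gene, the test compares normalised group means
under a negative-binomial model:

- dispersion alpha is a method-of-moments estimate from the pooled
  within-group variance of normalised counts,
  alpha = (var_w - m * mean(1/s)) / m^2, floored at 1e-8;
- the statistic is a Wald ratio of the log-mean difference with the delta
  method standard error, se(log mu)^2 = (sum_j 1/(mu s_j) + n alpha) / n^2,
  with a pseudo-count of 0.5 on both group means (also used for the reported
  log2 fold change);
- the statistic is referred to a Student t distribution with n1 + n2 - 2
  degrees of freedom. The normal reference is anti-conservative at small n
  (measured ~0.08 rejection at alpha = 0.05 on 6 vs 6 null simulations)
  because the plug-in dispersion's sampling noise is unaccounted; the t
  reference on the dispersion estimate's residual df restores calibration
  (~0.05) while the statistic itself is unchanged.

All-zero genes are reported with p = 1 and log2FC = 0. Benjamini-Hochberg
adjustment (via statsmodels) gives `p_adjusted`; genes with padj below alpha
split into higher/lower sets by fold-change sign. This is a defined,
desk-scale NB test: numeric agreement with shrinkage-based DE packages is
not claimed, though a cross-check against an independent NB implementation
(pyDESeq2) on planted data shows closely matching significant sets and fold
changes. Multi-factor designs, shrunken fold changes and outlier filtering
are out of scope.

## Expression profiles

Correlation, outlier screening and clustering all operate on log2(FPKM + 1).
Pearson correlations between tissue columns are computed over a gene subset
(typically the tissue-specific set) with the exact t-transform two-sided
p-value on n - 2 df; zero-variance profiles are reported missing.

The PCA outlier screen projects samples onto (PC1, PC2) of the gene-centred
log matrix and flags samples whose Euclidean distance to their tissue
centroid exceeds median + `k_mads` * MAD (default 3) of all within-tissue
distances. The source study only reports *that* outliers were removed, not
how; this rule is an explicit, tunable substitute. Tissues with a single
sample have distance 0 and are never flagged. Note the rule is centroid
based: a badly corrupted replicate also shifts its own tissue centroid, so
tight neighbours can be flagged with it.

Tissues are clustered by average linkage on 1 - Pearson r; the dendrogram is
emitted as a Newick string and `forms_clade` tests whether a tissue set is
exactly the leaf set of some node.

## qPCR relative quantification

Replicate Cts are averaged on the Ct scale (not per-replicate folds), then
dCt = mean Ct(target) - mean Ct(reference) per tissue,
ddCt = dCt(tissue) - dCt(calibrator), fold = 2^-ddCt. Amplification
efficiency is fixed at 2; efficiency-corrected models are out of scope. The
calibrator tissue is an explicit required parameter. A tissue lacking the
reference gene is reported missing rather than failing the run.

## Indel population genetics and association

Printed genotype-frequency tables are first converted back to integer counts
(round each freq * n; absorb a unit discrepancy into the class with the
largest rounding remainder), because statistics computed on 3-decimal
frequencies drift in the third decimal. From counts, with p = freq(D):

    homozygosity = p^2 + q^2     expected heterozygosity = 1 - (p^2 + q^2)
    effective alleles = 1 / (p^2 + q^2)
    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2

Marker-diversity tables in this literature conventionally print homozygosity
under "Ho" and the effective allele number under "Ne"; `diversity_table`
emits those column names while the dataclass fields are named by formula.
Hardy-Weinberg equilibrium is a chi-square goodness-of-fit with expected
counts (n p^2, 2npq, n q^2) and df = 1; an expected class below 1 raises a
reliability flag. The chi-square p-values are properties of the data, not
reproduction targets: published HWE p-values from web calculators often come
from unstated procedures (exact tests, corrections) and need not match.

Association runs an independent two-sample t-test per genotype pair within
each (sex, trait) stratum, excluding genotype groups with fewer than `min_n`
(default 3) individuals. The pooled/Welch variant is gated by a mean-centred
Levene test at 0.05 — consistent with the mixed pattern recoverable from
published association tables — and `ttest_from_summary` reproduces either
variant from printed (mean, SE, n) summaries, recovering SD as SE * sqrt(n).

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults define the study conditions: 14 tissues whose first
three are adipose depots, 2-11 replicates per tissue drawn uniformly, 2,000
genes, ~5% planted single-tissue-specific genes (round-robin over tissues) at
a 50x home-tissue boost, and a 23-gene core planted specific in all three
adipose depots (16 protein-coding + 7 lncRNA, mirroring the screened
composition). Background genes are log-normal: per-gene baseline
(ln-mean -1.1, ln-sd 1.5, i.e. median FPKM ~0.33 so most of the panel sits
below the screening filter, as in whole-annotation screens), per-tissue
effect (ln-sd 0.35) and replicate noise (ln-sd 0.25). Planted genes are
near-silent off-home (median FPKM 0.1), the realistic profile of genuinely
tissue-restricted genes. Biotypes follow a 59/15/2/24 percent mix
(protein-coding/lncRNA/miRNA/other); planted genes draw from an
lncRNA-enriched mix, reproducing the higher tissue specificity of non-coding
genes.

Counts are negative-binomial with log-normal gene base means (median ~100),
log-normal library-size factors (ln-sd 0.15) and dispersion 0.1; genes
flagged DE carry a 4-fold change in the adipose samples (the shared adipose
core is always up; background DE genes split evenly up/down). The expression
and count generators share one seeded planting routine, so the adipose core
is simultaneously tissue-specific and higher-expressed — making the
"specific AND higher" intersection a known 23-gene set.

Genotypes are multinomial draws from (p^2 + fpq, 2pq(1-f), q^2 + fpq)
(truncated/renormalised), traits are base + genotype effect + Gaussian noise.

Not emulated: read-level sequencing artefacts, batch/study effects across
pooled public data sets, gene length and GC biases inside FPKM, linkage
between markers, covariate structure in traits, and real bovine gene models.
Passing tests therefore demonstrate correctness of the statistics and the
screening logic under the stated generative assumptions, not robustness to
the heterogeneity of pooled public transcriptomes.

## Numerical and reproducibility choices

- All generators take explicit seeds and use independent sub-streams of one
  `SeedSequence`; no global RNG state. Identical config + seed reproduces
  every output byte for byte (TSVs are written with a fixed float format and
  the run manifest records a SHA-256 checksum per file).
- Test-suite and example problem sizes (2,000-gene panels, 1,000-gene DE
  simulations, 6 vs 6 count designs) were chosen as the smallest designs at
  which the calibration and recovery properties are stable across seeds.
- Degenerate inputs are defined rather than fatal wherever a convention
  exists: monomorphic genotype tables (homozygosity 1, PIC 0), all-zero
  genes in DE (p = 1), all-zero tau profiles (missing), single-sample
  tissues in the outlier screen (never flagged), missing reference gene in
  one tissue of a Ct table (missing row).

## Known limitations

- The DE test has no dispersion shrinkage; at very small n its power profile
  differs from shrinkage-based tools even though calibration holds.
- The top-fraction candidate rule ties the number of tissue-specific calls
  to the filtered panel size, not to the evidence; this is inherent to the
  screen being implemented and is why recovery precision is defined over
  planted genes (see above).
- The PCA outlier rule uses only two components and a global MAD threshold;
  strongly structured panels may need per-tissue thresholds.
- PIC and the diversity identities are implemented for the biallelic case
  only.
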