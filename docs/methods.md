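# Methods

This note records the statistical models implemented in `twaskit`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
written down.

## Synthetic cohort

**Genotypes.** Haplotypes follow a first-order Markov allele-copy chain
within LD blocks: allele *j* copies allele *j−1* with probability ρ,
otherwise it is a fresh Bernoulli draw at that SNP's allele frequency
(uniform over `maf_range` per SNP). Two independent haplotypes sum to an
unphased dosage in {0, 1, 2}. At equal allele frequencies the
adjacent-allele correlation is exactly ρ and LD decays geometrically
(r_ij = ρ^|i−j|) inside a block; blocks are independent and never span
chromosomes. A Gaussian-copula construction was considered and rejected:
thresholding attenuates a latent correlation ρ to an allele-scale Pearson
correlation of roughly (2/π)·asin(ρ), so the generator would not deliver
the block correlation it advertises. The copy chain is positive
semidefinite by construction and hits the nominal ρ.

**Variant filters.** MAF ≥ 0.05, exact Hardy–Weinberg P ≥ 10⁻⁵ (conditional
enumeration of heterozygote counts given allele counts, two-sided), and an
optional external reference frequency ≥ 0.01 — the standard pre-processing
for expression-panel genotypes. The exact test is used rather than the χ²
approximation because the threshold sits in the far tail where the
approximation is unreliable at panel sample sizes.

**Expression.** For isoform *k* of a gene, y_k = Xβ_k + ε_k with X the
column-standardized cis dosages (gene body ± 1 Mb), β_k supported on
`n_causal` SNPs and rescaled so the *realized* var(Xβ_k)/var(y_k) equals
the target cis-h² exactly; residuals have equicorrelation `resid_cor`
across a gene's isoforms. Gene expression is the unweighted row-sum of its
isoform columns, which preserves the opposing-isoform cancellation
mechanism: with `opposing=True` the second isoform carries −β₁, so the
gene-level genetic component vanishes while each isoform's remains.
Optional generic covariates (standard normal, random loadings) are added
on top and returned so residualization has something to remove; they stand
in for clinical covariates, genotype PCs and expression latent factors,
which are out of scope to estimate.

**Trait and GWAS.** The joint standardized SNP effect is
b = Σ_k α_k β_k + d (mediated plus direct), trait variance normalized to 1,
so h² = bᵀVb and h²_med = b_medᵀVb_med are quadratic forms in the LD
matrix. Summary statistics are drawn either analytically,
z ~ MVN(√n·Vb, V), or by simulating n standardized genotype rows from
N(0, V), forming the phenotype, and computing marginal correlations; the
two modes agree in distribution and are cross-checked in tests.

**Default study condition** (`PipelineConfig`): 400 reference individuals
(inside the 108–574 per-tissue range of large post-mortem expression
panels), GWAS n = 100,000 (cancer-scale), 2 chromosomes × 150 SNPs at
20 kb spacing, blocks of 15 SNPs with ρ = 0.8, MAF ∈ [0.05, 0.5], 20 genes
× 2 isoforms, 2 causal cis-SNPs and cis-h² = 0.25 per isoform, residual
isoform correlation 0.3, 30% of genes mediated through their first isoform
(half of those opposing), target h²_med = 0.15 with 0.10 of direct
polygenic heritability. These values are fixed once as a realistic desk-
scale analogue of a multi-tissue TWAS; they are not tuned per experiment.

## Expression models

Two families per feature, best-of-family by cross-validated R²:

1. **Elastic net** (mixing 0.5, penalty path by inner 3-fold CV) per
   feature.
2. **Multi-response elastic net** across a gene's isoforms (joint
   row-sparsity), which borrows strength when isoforms share cis
   architecture.

`cv_r2` is the squared Pearson correlation between out-of-fold predictions
and observed expression over a 10-fold outer split; every fold refits the
full family (including its inner penalty search) on the training portion
only. Predictions are formed as X·coef on globally centered data,
*excluding* per-fold intercepts: a fold's intercept is its training mean,
which is negatively correlated with the held-out fold mean, and including
it inflates null cv_r2 several-fold (squared correlation counts both
signs). Squared correlation was chosen over 1 − SSE/SST for scale
robustness. Ties between families break toward fewer nonzero weights.
Weights are stored on the standardized-genotype scale and the burden test
consumes them on that same scale. Retention is strict: cv_r2 > 0.01.

## Association

`z_assoc = wᵀz / √(wᵀVw)`; wᵀVw ≤ 10⁻¹² raises a degenerate-model error.
GWAS alleles are harmonized to the panel beforehand (sign flips for
ref/alt swaps; strand-ambiguous A/T and C/G SNPs dropped by default).

**Two-stage isoform testing.** Stage 1 screens genes with the Cauchy
combination (ACAT) of their isoforms' raw P-values — exact for one input,
valid under dependence — adjusted by Benjamini–Hochberg across genes.
Stage 2 applies within-gene Bonferroni to isoforms of screened genes.
"Transcriptome-wide significant" means both adjusted values < 0.05.
Gene-level (TWAS) records use plain BH.

**Permutation filter.** For significant features only, weight values are
reassigned to SNP positions uniformly at random B = 10,000 times with z
and V held fixed; p = (1 + #{|z_perm| ≥ |z_obs|})/(B + 1). With fewer than
3 weighted SNPs all m! arrangements are enumerated exactly. Calibration
tests use B = 999 (a fine enough P-value grid for a KS test at 2,000
features), a problem-size choice; the analysis default stays 10,000.

**Effective sample size.** Because the burden χ² has expectation 1 + NCP
with NCP linear in GWAS n, pct = 100·[(mean χ²_iso − 1)/(mean χ²_twas − 1)
− 1] estimates the relative effective-N gain. Gene pairs enter when either
arm has χ² > 1 (the `union` rule; `per_arm` filtering is a flag). SE by
leave-one-gene-out jackknife, Wald 95% CI. Note the χ² > 1 truncation
biases the estimator toward zero when most genes are null; the doubling
check therefore uses a signal-dominant gene set (200 genes, latent effect
sd 2), mirroring the filtered association set the statistic is meant for.

## Fine-mapping

Burden z-scores of features at a locus (single-linkage clusters of
significant features whose gene bodies lie within 1 Mb) are modeled as
z ~ MVN(0, Ω) under the null, with Ω the correlation of genetically
predicted expression. A causal configuration S adds low-rank signal:
z ~ MVN(0, Ω + v·Ω[:,S]Ω[S,:]). Because Ω⁻¹Ω[:,S] is a selection matrix,
each Bayes factor reduces to |S|-dimensional algebra
(−½log|I + vΩ_SS| + ½z_Sᵀ(I/v + Ω_SS)⁻¹z_S), so enumeration is O(|S|³)
per configuration regardless of locus size; tests verify exact agreement
with full-covariance enumeration at k ≤ 10. Priors are non-informative:
each feature causal independently with probability 1/k; the null
configuration is included in the normalization, keeping PIPs calibrated
under no signal. The slab variance v (z-scale) defaults to 40 — at GWAS
n ≈ 10⁵ this corresponds to per-feature effects of a few hundredths of a
phenotypic SD — and is config-exposed, as is `max_causal` (default 1,
enumeration supported to the feature count). The 90% credible set is the
smallest PIP-ranked prefix reaching 0.90 of the non-null posterior mass,
ties broken lexicographically; if total mass is zero all features are
returned with a flag.

## QTL mapping and colocalization

cis-QTLs are mapped by OLS of expression on allelic dosage (0/1/2) within
TSS ± 1 Mb, with covariates entering as joint regressors; the
implementation projects both dosage and expression off the covariates
(Frisch–Waugh) and a test asserts exact equality with the explicit joint
fit, including SEs and t-based P-values. Monomorphic SNPs are skipped and
logged.

Colocalization reuses the spike-and-slab enumeration on SNP z-scores, one
trait at a time (prior 1/m per SNP, up to 2 causal SNPs, eCAVIAR's default
assumption). CLPP is the inner product of the two per-SNP marginal
posteriors. Loci are pre-pruned of near-duplicate SNPs (|r| > 0.99,
greedy) and capped at 100 SNPs (strongest combined |z| kept) — the pruning
rule is this package's decision, recorded here because reference
implementations do not print theirs. The colocalization call requires all
three strict conditions: GWAS P < 5×10⁻⁸, QTL P < 10⁻⁶, CLPP > 0.01.

## Mediated heritability

E[χ²_j] = 1 + n·(ω·expr_score_j + γ·ld_score_j), where
ld_score_j = Σ_i r²_ij and expr_score_j = Σ_f Σ_i r²_ij β²_if smears each
feature's squared cis effects (LASSO-estimated in the pipeline; true
effects in the recovery studies, which isolate the regression from LASSO
shrinkage) across LD. Then h²_med = ω·Σ_f h²_cis,f, h²_nonmed = γ·M, and
the reported ratio is h²_med/h². Fitting is two-pass weighted least
squares: an OLS pass predicts each SNP's mean χ², and the second pass
weights by 1/(2·mean²), the large-sample χ² variance — the convention of
LD-score-family regressions. SEs come from a leave-one-block-out jackknife
over 20 contiguous SNP blocks; the Wald test compares ratio/SE to a
standard normal. A negative fitted h² flags the estimate and suppresses
the ratio. Multi-tissue score meta-analysis is reduced to simple averaging
across replicate score tables.

The recovery studies use independent AR1 blocks (ρ = 0.8, matching the
package-wide LD condition; at weak LD the expression score has too little
leverage for desk-scale SNP counts), 5,000 SNPs, 100 single-causal-SNP
features, GWAS n = 50,000. Under these conditions the ratio estimator is
unbiased with sampling sd ≈ 0.06.

## Comparison statistics

Independent GWAS loci are either user-supplied LD blocks (BED, converted
to 1-based inclusive at the boundary and unit-tested) or distance clumps
of genome-wide-significant SNPs (strict P < 5×10⁻⁸) within 1 Mb. A locus
is tagged by a method iff one of its significant features' gene bodies
lies within 1 Mb of the locus bounds. Percent increases are
100·(new/ref − 1), reported to one decimal. The 2×2 enrichment test
(e.g., strongly constrained genes, s_het > 0.1, among each method's hits)
uses the continuity-corrected χ² — which reproduces the published
constraint-enrichment P-value to its printed precision, whereas the
uncorrected statistic does not — and switches to Fisher's exact test when
any expected cell is below 5.

## What passing tests do and do not show

The generator produces block-LD hard-call genotypes, Gaussian expression
with exact planted cis-h², and summary statistics consistent with the LD
used downstream. It does not emulate: read-level quantification noise or
normalization artifacts, real LD (long-range, variable block structure),
population structure or relatedness, allele-frequency/effect-size
coupling, binary-trait ascertainment, or mismatched reference-vs-GWAS LD.
Calibration and recovery results therefore validate the statistical
machinery under its own assumptions, not robustness to those real-data
complications. Discovery counts at desk scale (tens of genes, hundreds of
SNPs) are illustrative; only the published-count arithmetic is exact.

## Problem sizes

Test-suite and acceptance studies run at: 2,000 features for null
calibration (KS), 500 replicates for two-stage error control and
credible-set coverage, 200 replicates for the mediation type-I check, 50
for partial-mediation recovery, 20 for the effective-N doubling check, and
500 for each mechanism demonstration; the end-to-end pipeline runs at its
default configuration. These sizes keep the full suite at a few minutes on
one CPU while leaving Monte-Carlo error well inside each asserted margin.
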