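# Methods

This note documents the models, defaults and numerical choices behind
`lipidratios`, and what the synthetic-data experiments do and do not
demonstrate.

## Ratio phenotypes

A ratio is defined by disjoint numerator and denominator species sets
(single species, whole classes, or composites such as `Total PE Ether` =
PE(O) + PE(P)). Per sample the raw ratio is (Σ numerator)/(Σ denominator);
within a side, missing members count as zero unless every member is
missing. The phenotype is the log2 ratio, centered and scaled to unit
sample SD (n−1 denominator) over non-missing entries; the per-ratio
(mean, sd) are stored so the raw ratio is recoverable to machine
precision. Nonpositive concentrations are treated as missing for ratio
purposes (log undefined), whereas class sums keep zeros — an asymmetry
users should be aware of when a species is exactly zero. Standardization
makes the phenotypes invariant to global rescaling of the concentration
matrix, which is what lets differently calibrated cohorts be compared
after harmonization.

The packaged definition table contains 82 ratios. Fifty carry labels
printed in the source tables and figures (`provenance=printed`); the
remaining 32 are reconstructed pathway-consistent pairs (substrate/product
or pathway end-points, e.g. SM/Cer, CE/COH, ether vs diacyl species
pairs) added to reach the stated panel size (`provenance=reconstructed`).
Analyses that depend on exact panel membership should treat the
reconstructed rows as placeholders, not as the study's definitions.

## Harmonization

All corrections are multiplicative, because concentrations are positive
and calibration errors are scale-like.

* Reference correction: factor_s = median(reference samples)/consensus_s;
  the matrix is **divided** by the factor, so corrected reference medians
  equal the consensus exactly.
* Matched sub-cohorts: greedy 1:1 nearest-neighbour matching without
  replacement, exact on sex and disease flags, Euclidean on standardized
  (age, BMI, total cholesterol), ties broken by lexicographic sample id
  (determinism over optimality — at the default 1,000 pairs, the factor is
  a ratio of medians and is insensitive to the matching algorithm).
  Cohort B is **multiplied** by median_A/median_B, aligning B to A.
* PQC centering: per (species, batch) factor = batch PQC median / global
  PQC median; dividing each batch by its factor equalizes per-batch PQC
  medians, and the operation is idempotent. A (species, batch) cell with
  no usable PQC median is left uncorrected with a warning.

Pipeline order is PQC centering → cohort alignment; the reverse order
would let batch structure leak into the matched-median factors.

## Association and p-gain

The standardized ratio is the regression **response** and the obesity
marker the predictor ("SD-change per unit WC"), adjusting for age and
sex, complete-case per fit. Component "lipids" are the ratio's side sums,
log2-standardized and fitted with the identical model. BH adjustment is
applied within the ratio family and within the component family; p-gain
defaults to the BH-adjusted p-values (the published worked examples are
reproduced from BH-corrected values), with `use_adjusted=False` for raw
p-values. The significance threshold is 10 × the number of tests — 820
for 82 ratios, and 10 × the number of genome-wide-significant SNPs in the
SNP-level context; both use the same operation with a caller-supplied
count.

Sex interactions use the fully interacted model
`ratio ~ WC + age + sex + WC:sex + age:sex`, chosen so the joint model's
implied per-sex slopes coincide exactly with sex-stratified fits (the
tests assert this identity); whether the original analysis also
interacted age with sex is not documented, and this is the one form that
makes the two routes agree.

## LSEA

Per-species t-statistics come from the association module (species ~
outcome + age + sex); LSEA never refits. The score is
Σt / sqrt(ΣC) over the covariate-adjusted residual correlation matrix
restricted to the set, with p = P(χ²₁ ≥ score²) (equivalently the
two-sided normal tail of the score). No shrinkage is applied to C (a flag
exists but defaults off). The χ² null is a large-sample result; set sizes
are reported so users can judge small sets.

The correlation adjustment is exactly what buys null calibration: on
synthetic data with within-class correlation 0.6 and no outcome effect,
the adjusted score's type-I error at 0.05 is within 3 Monte-Carlo SE of
0.05 over 2,000 sets, while a naive sqrt(set size) denominator rejects
~20–25% of null sets. Because sets drawn from one dataset share its
t-statistics, the calibration experiment spreads the 2,000 sets over 100
independent datasets (20 sets each, n = 1,000 samples): with fewer, larger
datasets the empirical rate has far more than binomial spread and the
measurement is uninformative.

## GWAS

QC defaults mirror the standard array pipeline: samples dropped at > 3%
missingness or heterozygosity beyond 5 SD; variants at call rate < 95%,
MAC < 10, Hardy-Weinberg p < 5 × 10⁻⁴ (Pearson 1-df χ², monomorphic → p=1,
computed on rounded hard calls with a warning for fractional dosages),
palindromic SNPs with MAF > 0.4, and post-imputation MAC < 5 or
imputation r² < 0.3.

The GRM is K = ZZᵀ/m over (dosage − 2p)/sqrt(2p(1−p)) columns with
missing dosages mean-imputed; LOCO GRMs are assembled from per-chromosome
cross-products so the genotype matrix is standardized once. Genomic PCs
are the top-10 eigenvectors (× sqrt eigenvalue, largest-magnitude loading
positive) of a GRM built from an **LD-pruned** panel (greedy r² ≤ 0.2
within a trailing window). Pruning matters here: at desk-scale panels
(n/m near 1) an unpruned LD block can dominate the GRM spectrum, so PC1
becomes the block genotype and the PC adjustment absorbs true locus
effects. PCs are computed once from the all-chromosome (pruned) GRM, not
per LOCO piece, matching standard practice.

Phenotypes are OLS residuals on age, sex, age², age·sex, age²·sex and the
10 PCs, then rank-based inverse-normal transformed (Blom offsets,
Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks for ties).

The mixed model y = Xβ + g + e with g ~ N(0, σg²K) is fitted EMMA-style:
per chromosome the LOCO GRM is eigendecomposed once, REML profiles
δ = σe²/σg² by golden-section search on log δ ∈ [−10, 10] (tolerance
1e-6), and every variant on that chromosome is tested by a GLS Wald test
at the fixed δ̂ (variance re-estimated per variant from weighted
residuals; t reference with n − 2 df). Null-model variance components are
reused for all variants on a chromosome rather than re-estimated per SNP;
at the panel sizes involved the difference is far below the Monte-Carlo
noise of any downstream check. Genome-wide significance is p < 5 × 10⁻⁸.

## Synthetic data

One master seed feeds named substreams (species bases, cohort A, cohort
B, genetics, expression), so adding a stage never perturbs earlier draws
and equal seeds give bit-identical output.

* Lipidome: log2 concentration = per-species base (Uniform(−2, 8)) +
  bio_sd·(√ρ·class factor + √(1−ρ)·noise) with ρ = 0.6 and bio_sd = 0.5,
  plus per-class WC effects (β·(WC − 93) in log2 per cm), sex effects,
  optional WC×sex interactions, per-(species, batch) offsets
  (SD 0.25 log2), and the cohort's global scale factor. Defaults: 735
  species in 39 classes; ether classes fall and TG/DG rise with WC.
* PQC samples carry only base + batch offset + technical noise (SD 0.05);
  reference samples share the cross-cohort base expectation times the
  cohort scale factor, which is exactly what reference correction is
  meant to remove.
* Covariates: age ~ N(50, 12) truncated at 25; sex Bernoulli(0.5); WC
  sex-dependent normal (98 ± 12 / 88 ± 13 cm); BMI and WHR are
  near-deterministic functions of WC (pairwise r > 0.95), mirroring their
  use as interchangeable outcomes. Distributional details beyond summary
  statistics are not published; these are loose matches, not fits.
* Genotypes: Binomial(2, MAF) dosages, MAF ~ Uniform(0.05, 0.5),
  contiguous chromosome blocks, a 10-variant LD block sharing haplotypes
  with the causal SNP (copy probability 0.85, pairwise r² ≳ 0.5). The
  causal SNP (MAF 0.3) adds +a to numerator-class and −a to
  denominator-class log2 concentrations per alternate allele (a = 0.15
  by default) — an opposing-effect ratio locus; an optional polygenic
  background (default h² = 0.2 of the log2 ratio) is spread over the
  remaining variants.
* Expression: two-group log-normal with a per-gene shift vector
  (group sizes default 74/74, matching a strain-panel design).

What passing tests show — and do not. The generator reproduces the
*statistical structure* the methods assume (within-class correlation,
batch/reference structure, opposing-effect locus, near-collinear obesity
markers); it makes no attempt to match real concentration scales,
published regression betas, realistic LD beyond one block, or
population stratification. Calibration and recovery on these simulations
therefore validate the implementation and its assumptions, not the
biological conclusions of any particular cohort.

## Validation experiment sizes

Chosen as the smallest designs whose Monte-Carlo error cleanly resolves
each question:

* LSEA calibration: 100 datasets × 20 sets, n = 1,000 (see above).
* REML heritability recovery: 50 replicates at n = 1,000, m = 2,000; at
  n = 500 the variance-ratio estimate has a small convexity bias
  (~−0.007) comparable to the 50-replicate Monte-Carlo spread, which
  would make the 3-SE check uninformative.
* Causal-locus pilot: 20 seeds at n = 4,000, m = 5,000, a = 0.15,
  testing the causal chromosome against its LOCO GRM.
* Null GWAS calibration: genomic inflation λ averaged over three
  independent n = 1,000 / m = 5,000 panels (a single median-based λ has
  Monte-Carlo SE ≈ 0.03).

## Known limitations

* The lyso single-chain position defaults to *sn-1* when no `[sn1]`/`[sn2]`
  tag is present.
* HWE is only defined on hard calls; heavily imputed dosages make the
  rounded-call test approximate.
* The matched-subcohort procedure assumes both cohorts share at least one
  (sex × disease-flag) stratum and errors otherwise.
* REML assumes a single random effect; no dominance, GxE or multiple
  variance components.
* `variant_qc` applies both QC stages' thresholds in one pass; a variant
  can fail several filters and per-filter counts overlap.
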