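# Methods

## The additive polygenic null

All four classifiers ask the same question: given the joint distribution of
standardized polygenic score and standardized phenotype expected under a
purely additive polygenic architecture, is this individual's pair
improbable? The null model is

- dosages: G<sub>ij</sub> ~ Binomial(2, f<sub>j</sub>) independently per
  variant (Hardy–Weinberg proportions, no linkage disequilibrium),
- score: PS<sub>i</sub> = Σ β<sub>j</sub> G<sub>ij</sub>, standardized to
  z<sub>PS</sub>,
- phenotype: z = √r²·z<sub>PS</sub> + √(1−r²)·ε, ε ~ N(0,1), standardized,

so (z<sub>PS</sub>, z<sub>pheno</sub>) is bivariate normal with correlation
ρ = √r². The simulator's `genotype_level=False` fast path draws
z<sub>PS</sub> ~ N(0,1) directly; it is distributionally exact for
everything downstream of the score and is used for the 2,000–10,000
replicate rank nulls where genotype simulation would dominate runtime. The
genotype-level path is the default for single cohorts because the method it
calibrates is explicitly a genotype-level simulation.

Calibration simulations match the variance explained *observed* in the
analysed cohort (squared correlation of the pair table, clipped to
[10⁻⁴, 0.99]), mirroring the estimate-then-simulate design the framework
follows.

## Phenotype preparation

`adjust_and_standardize` residualises on an OLS design (intercept +
covariates, categorical columns dummy-coded), optionally applies the
rank-inverse normal transformation (RINT), then scales to mean 0, SD 1.
Order is residualise → RINT → standardize, i.e. rank-inverse normalised
*residuals*. RINT uses Blom normal scores Φ⁻¹((rank − 3/8)/(n + 1/4)) with
average ranks for ties; the offset choice is conventional, not dictated by
the framework. Standardisation uses the sample SD (ddof = 1) throughout.
Rank-deficient designs are rejected with the collinear columns named;
zero-variance residuals (phenotype exactly explained by covariates) are an
error rather than a silent zero vector.

## The four classifiers

**Mahalanobis.** Σ and the centre are estimated (sample covariance,
n − 1) from an *independent* simulated null cohort, never from the cohort
being classified — estimating Σ on data containing the very outliers being
sought would inflate it. D² has the closed-form χ²(2 df) tail
p = exp(−D²/2); the scipy survival function is used and agrees with the
closed form to ≤ 10⁻¹². A joint rule requires |residual z| > 2, removing
individuals whose D² is large only because both score and phenotype are
extreme *in agreement* (consistent with the additive model: D² decomposes
as z<sub>PS</sub>² + z<sub>resid</sub>², so a point far along the
regression line can reach small p without any prediction error).
Thresholds: α = 10⁻³ (primary) and 0.05/n (stringent).

**Residual regression.** Deviator iff |z| > k, k ∈ {2, 3}, where z is the
standardized residual of the score–phenotype regression. Under the null
the flag rate is 2Φ(−k) regardless of regression direction.

*Direction of the regression.* The package defaults to regressing
**phenotype on score**: its residual is the individual's deviation from
the polygenic *prediction*, which is the quantity the classification is
about, and its per-individual magnitude for a planted 4-SD deviator is
≈ 4/√(1−ρ²) ≈ 4.9 SD. The transposed regression (score on phenotype) is
retained via `residual_direction="score_on_pheno"`; its residual mixes the
phenotype deviation with score noise (planted 4-SD deviators land at only
≈ ρ·4/√(1−ρ²) ≈ 2.7 SD), which halves sensitivity at the |z| > 2 joint
rule and leaves ~1 in 100 strong deviators invisible to every method. The
same `residual z` and the shared aligned rule |z| < 1 use this default.

**GRS-rank empirical p.** B replicate cohorts are simulated; in each,
phenotypes are stored ordered by score rank (ties broken by a seeded random
permutation). The observed phenotype at rank k is compared with the B null
values at that rank; with extremity measured two-sided about the per-rank
null *median* (the natural centre of an asymmetric per-rank distribution),
p = (r + 1)/(B + 1) where r counts replicates at least as extreme. The
smallest attainable p is exactly 1/(B + 1), so α must satisfy
α > 1/(B + 1) to be reachable (B = 10,000 supports α = 10⁻³ and even
1/10,000). One-sided modes (`sided="lower"/"upper"`) are provided. The
store holds a B × n float32 matrix (~80 MB at B = 10,000, n = 10⁶/B); above
a memory cap the store is backed by an on-disk memmap (`store_path=`)
rather than silently swapping.

**Centile fences.** The score is cut into equal-count bins (default 100,
"centiles"; configurable for small cohorts) in stable sort order; within
each bin, phenotype quartiles Q1/Q3 are computed with linear interpolation
between order statistics (the quantile rule is a package choice) and
individuals outside [Q1 − k·IQR, Q3 + k·IQR], k ∈ {1.5, 3}, are flagged.
For a normal within-bin phenotype the k = 1.5 fences flag ≈ 0.7% in
expectation; finite-bin quartile noise pushes the realised rate slightly
higher (~0.74% at 1,000 per bin).

**Statuses.** Every classifier partitions the cohort into
deviator_low / deviator_high / aligned (|z| < 1, the shared enrichment
comparison group) / intermediate. Direction defaults to the phenotype-sign
rule (below vs above the cohort mean); a residual-sign alternative
(`direction_rule="residual"`) is available because the phenotype rule can
label an individual with a below-average score but positive prediction
error as "low". The GRS-rank method directions by the sign of
(observed − per-rank median), which is its own natural axis. Exact
phenotype zeros fall back to the residual sign.

## Synthetic studies and what they do (not) show

`generate_synthetic_study` plants deviators by adding ±shift_sd (default
4 phenotype SD — the scale of a fully penetrant monogenic effect or a
severe environmental insult) to randomly chosen individuals *before* final
standardisation; optional `skew` applies x → exp(0.5x) first (LDL-C-like
right skew, magnitude chosen to visibly break normality while keeping
tails finite); optional `sexed=(r2_m, r2_f)` gives the two sexes different
variance explained. Truth labels let sensitivity/specificity be measured
exactly.

The generator emulates: the bivariate score–phenotype geometry at a chosen
r² (0.316 by default, a height-like value; 0.167 is an LDL-C-like value),
Hardy–Weinberg dosages at frequencies in (0.01, 0.5), planted low/high
deviators, skew, and sex structure. It does **not** emulate linkage
disequilibrium, ascertainment or participation bias, genotyping error,
score-weight uncertainty, population stratification, or realistic covariate
structure (covariates in synthetic runs are pure noise if supplied).
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under the stated null — not that any particular real cohort
satisfies that null.

## Enrichment statistics

Odds ratios are ad/bc with the Haldane–Anscombe +0.5 applied to every cell
when any cell is zero (deviator groups are tiny, zero cells routine), Wald
95% CIs on the log scale, and p from Fisher's exact test (default) or a
logistic Wald test — the framework's own estimator is not pinned down, so
both are exposed. Continuous outcomes are RINTed by default so the status
coefficient is in outcome-SD units; a perfect fit (zero residual variance)
reports the exact coefficient with a degenerate CI instead of dividing by
zero. Disease-risk logistic models flag complete separation or
non-convergence (`converged=False`, NaN estimate) rather than raising,
since a deviators-all-cases table is a legitimate finding, not a bug. With
no covariates the logistic OR equals the contingency-table OR (checked to
10⁻⁶ in the tests). No multiple-testing correction is applied to
enrichment p-values.

## Pipeline and reproducibility

One root seed is expanded via `numpy.random.SeedSequence` into named child
seeds (cohort, Mahalanobis null, rank null, tie-breaks), all logged in
`manifest.json` beside input checksums and thresholds. Output tables are
written with fixed float formatting, so identical configs and seeds
reproduce byte-identical files. Sex-stratified mode re-standardizes and
classifies each sex independently (each stratum gets its own calibration
simulations at its own observed r²). Plots are optional and can never
change the exit status.

## Problem sizes used in validation

Unit and integration tests run cohorts of 2,000–50,000 with B ≤ 2,000 rank
replicates; the end-to-end checks use n = 20,000 (calibration, planted
recovery), n = 100,000 (null tail rates), and the 10,000-person demo with
B = 2,000. These sizes give sampling error comfortably inside the asserted
tolerances (e.g. binomial SE of the 4.55% residual rate at n = 10⁵ is
0.07%) while keeping the full suite under a few minutes on one core.

## Known limitations

- No allele harmonisation: weights and dosages must share effect-allele
  orientation; no strand flipping is attempted.
- Simulated variants are independent; LD-induced score variance structure
  is not represented.
- The Mahalanobis χ² calibration assumes bivariate normality; for heavily
  skewed phenotypes use RINT or rely on the centile/GRS-rank methods.
- The GRS-rank p-value floor 1/(B+1) makes very small α unreachable at
  small B; the classifier does not warn when α < 1/(B+1) beyond flagging
  zero deviators.
- Enrichment models assume independent individuals (no relatedness
  adjustment).
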