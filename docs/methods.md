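# Methods

This note documents the statistical models, the synthetic-data world, the
numerical choices, and the limits of what a green test establishes.

## Trait construction

Urinary iAs, MMA and DMA concentrations (µg/L) pass a detection filter
(all three strictly above 0.1 µg/L; exclusions tallied per species), are
converted to percentages of their sum, and enter analysis through a
two-stage transform:

1. **Stage 1.** `logit(p/100)` is regressed on covariates *jointly* with a
   polygenic variance component by ML (fixed effects profiled by GLS at
   every variance evaluation). Residuals are trait minus the fixed-effect
   predictions — not BLUP-corrected — matching the common SOLAR-style
   workflow and keeping stage 2 well-posed. The base design has 14
   non-intercept columns: centered age, age², male, age×sex, age²×sex,
   smoking (former, current), education ≥12 y, BMI ≥30, alcohol (former,
   current), region (OK, DK; AZ reference), and log total urine arsenic in
   µg/g creatinine. Sensitivity variants swap single terms (BMI
   continuous, BMI×sex, selenium, creatinine-as-covariate, no dilution
   adjustment). Age is centered at the sample mean before polynomials to
   reduce collinearity; reference levels are fixed (female, never-smoker,
   never-drinker, <12 y, BMI<30, Arizona) so column meanings are
   deterministic.
2. **Stage 2.** Rank-based inverse normal with the Blom offset,
   `Probit[(rank − 3/8)/(n + 1/4)]`, average ranks for ties.
   `inverse_normal` returns the literal Blom scores; the pipeline then
   standardizes them so the final trait has exactly mean 0, variance 1
   (rank order unchanged — raw Blom scores have variance slightly below 1
   at finite n). This controls residual kurtosis (|excess| < 0.2 at the
   cohort scale n ≈ 2,900), which the boundary LRT needs.

`pct_variance_explained = 1 − var(residuals)/var(trait)` is reported on
the logit scale; it is invariant to affine rescaling of the trait.

## Variance components

The covariance model is `Σ σ²_k M_k`: additive = 2Φ from the recursive
kinship algorithm, optional QTL = Π̂(t), optional household = same-household
indicator, residual = I. ML (not REML), stage-2 fixed effects limited to an
intercept because covariates were removed in stage 1.

Numerics:

- Likelihood factorizes exactly over pedigree connected components;
  equal-sized blocks are evaluated as one LAPACK-batched Cholesky. This is
  an algebraic identity, not an approximation, and is what makes the
  replicate-heavy null simulations affordable on one CPU.
- Variances are optimized as log-variances (L-BFGS-B, bounds
  `[1e-8, 1e3] × var(y)`, ftol 1e-11) from three deterministic starts:
  equal split, 90/10 and 10/90 of phenotypic variance between residual and
  the rest. No randomness: fits are deterministic given data.
- **Boundary handling.** Log-scale parameters never reach zero, so any
  non-residual component estimated below 2% of phenotypic variance
  triggers a refit with that component pinned at exactly 0; the pinned fit
  is kept whenever it costs < 1e-6 log-likelihood units. This
  likelihood-equivalence rule (rather than a parameter threshold) makes
  the boundary flag exact and gives the LRT a genuine point mass at zero.
- SE of h² by the delta method on the inverse numerical observed
  information of the free variances (central differences); reported as
  missing whenever any fitted component sits at the boundary, where the
  quadratic approximation is invalid.
- Testing h² = 0 (or σ²_q = 0) uses the boundary-corrected null:
  p = ½·P(χ²₁ ≥ LRT) for LRT > 0 and exactly 0.5 at LRT = 0. A full-model
  likelihood below the null beyond 1e-6 raises an optimization-failure
  error rather than being clamped silently. When a household component is
  included it is kept in both the full and the σ²_g-constrained model, so
  the test remains a one-component boundary test.
- Stratified (per-region) fits compute kinship on the full pedigree and
  subset it per stratum, so within-stratum relatives connected through
  out-of-stratum ancestors keep their relatedness; related pairs spanning
  strata are dropped and tallied.

## IBD estimation

An exact Lander–Green inheritance-vector HMM per connected family: one bit
per non-founder meiosis (2^m states, default limit m ≤ 16, i.e. 8
non-founders; larger families raise a capability error advising splitting
— this deliberately replaces MCMC samplers, trading pedigree size for
determinism and testability). Marker genotypes are unphased; the emission
sums over founder-allele assignments via the founder-allele graph, with
founder allele frequencies counted from genotyped founders (0.5
pseudo-count for alleles seen only in non-founders; uniform fallback).
Transitions use the Haldane map θ = ½(1 − e^(−2d/100)) per meiosis,
applied bit-by-bit in O(m·2^m); the map is sex-averaged. Forward–backward
posteriors are available at markers and at arbitrary cM positions
(including beyond the terminal markers), and
`π̂_ij = E[shared alleles IBD]/2` under the posterior. Expectation over
positions with no marker information equals 2Φ, and at a fully informative
marker multipoint and single-point IBD coincide — both are tested.

A Mendelian audit precedes IBD: child–parent transmission violations are
listed and the offending trio genotypes blanked; the overall blanking rate
is reported. Unlikely-double-recombinant blanking is not applied by
default (no published rule to follow).

## Linkage scan and empirical LOD adjustment

The polygenic null is fitted once per trait; at each grid position
(default 1–2 cM; the published peaks are reported at integer cM) the
(additive, QTL, residual) model is fitted and
`LOD = max(0, logL_full − logL_null)/ln 10`. Peaks are local maxima ≥ 1.9
(suggestive) or ≥ 3.3 (significant), annotated with the nearest marker.

The correction constant c: R replicates (desk default 1,000; cohort-scale
analyses use ≈10,000) of a fully informative marker — every
founder carries two globally unique alleles, so its IBD matrix is exact —
gene-dropped unlinked to the trait; the QTL model is fitted at each with
the same boundary-constrained optimizer, so the point mass at 0 is
represented. c is the least-squares through-the-origin fit of the
theoretical conditional-positive quantiles `χ²₁(p)/(2 ln 10)`,
p = 0.50…0.95 step 0.05, on the empirical positive-LOD quantiles. Fewer
than 10 positive null LODs is an error (increase R). `c × LOD` is
reported rounded half-up to 2 decimals; `c ∈ [0.95, 1.05]` is surfaced as
a boolean "raw LODs well calibrated" diagnostic only.

Two empirical findings shaped the tests (both cross-checked against a
brute-force multi-restart ML oracle, so they are properties of the model,
not the optimizer):

- The trait-conditional null calibration is asymptotic in the *number of
  families*. At n ≈ 180–360 measured c for an exactly inverse-normal trait
  ranges ~0.89–1.17 across trait realizations; at 100 sibships of 5
  (n = 700) with R = 1,000 it is ~1.05. The calibration check therefore
  uses the larger fixture.
- Direction of miscalibration depends on the *mechanism* of
  non-normality: i.i.d. individual-level heavy tails (e.g. exponentiating
  the trait) deflate the null LOD distribution at desk scale (c > 1),
  whereas familial variance heterogeneity — a per-family lognormal scale,
  marginal excess kurtosis 3(e^{4s²}−1) ≈ 9.7 at s = 0.6 — inflates it
  (c ≈ 0.2–0.8). The latter is how real untransformed biomarker traits
  typically violate normality in family samples and is the package's
  "heavy-tailed untransformed trait" (`simulate.heavy_tailed_trait`).

## Synthetic world

Defaults state the emulated study, not knobs: 40 families from a
three-generation template (founder couple, 5 adult sibs, 3 married-in
spouses with 2 children each, plus one second-spouse half-sib branch →
~18 individuals/family, 400–800 total), giving parent–offspring, sibling,
half-sib, avuncular and cousin classes; regions assigned per family
AZ/OK/DK ≈ 0.43/0.39/0.18. Markers: 2 chromosomes × 12 STRs, spacings
Beta-rescaled to mean 10 cM within [2.4, 24.1]; 4 equifrequent alleles
(founder heterozygosity 0.75, inside the reported 0.69–0.76). Genotypes by
gene dropping with Haldane recombination; an optional QTL is dropped as a
fully informative pseudo-locus through the same meioses, so marker–QTL
linkage is physical. Phenotypes: two latent log-ratios
L_iAs = ln(iAs/DMA), L_MMA = ln(MMA/DMA) with means ln(7.7/78.4),
ln(13.6/78.4) and SDs 0.50/0.36 (matching the published medians and IQRs),
each decomposed into covariate share (15.5%/19.4%), polygenic h²
(0.53/0.50) and noise; the softmax of (L_iAs, L_MMA, 0) closes the
composition to 100 exactly and induces the observed negative %DMA
correlations. Covariate marginals (age 56±8, BMI 31±6, smoking/alcohol/
education frequencies, lognormal total arsenic with median 12.9 µg/g)
roughly match the cohort tables without attempting joint realism.
Concentrations multiply the composition by (total arsenic −
arsenobetaine) × creatinine. Every dataset carries a TruthRecord
(per-individual genetic/QTL/covariate/noise components and parameters).

What the generator does **not** emulate: genotyping error beyond the
optional injector, assortative mating, inbreeding, joint covariate
structure, exposure geography, X-linked loci, or selection of families
through probands. A green recovery test therefore establishes estimator
correctness under the stated model, not robustness to those features.

Note on observed vs latent heritability: the analyzed trait
logit(%MMA/100) = L_MMA − ln(1 + e^{L_iAs}) mixes both latents, so its
heritability is mildly attenuated relative to the latent truth (mean
estimates across seeds ≈ 0.52/0.43/0.47 for truths 0.53/0.50 and the
derived %DMA); recovery tests use 2-SE tolerances or the direct
`simulate_trait` path accordingly.

## Known limitations

- Exact IBD limits families to ≤ 8 non-founders (16 meioses); real
  cohort pedigrees often exceed this and need MCMC IBD samplers instead.
  Split large pedigrees or raise `bit_limit` at exponential cost.
- ML (not REML) variance components; with intercept-only stage 2 the
  difference is a small downward bias in variance estimates.
- The SE of h² is unavailable at boundary estimates by design.
- The correction-constant estimator is quantile-based and needs R large
  enough that upper-decile noise is small (~±0.075 at R = 1,000).
- One measurement per individual; no longitudinal or multivariate traits.
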