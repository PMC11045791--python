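# Methods

This note documents the models and procedures implemented in `exogene`,
the defaults chosen where the underlying study design left them open,
and what the synthetic-data experiments do and do not establish.

## Exposure scoring

Long-term exposure is the mean annual lbs/acre over the window
[1974, diagnosis year − lag], lag 10 years by default (prodromal
period). Two conventions required a decision:

- **Absent years count as zero** — the denominator is the full window
  length, not the number of active years. Counting only active years
  would score a single heavy year above decades of moderate exposure.
- **log(1 + x)** is used for the log transform so that zero exposure maps
  to zero; the SD scaling of each pesticide × location term divides by
  the cohort SD *without centering*, preserving the natural zero of "no
  exposure". Residential and workplace terms enter separately, so
  exposure at both locations scores strictly higher than the same
  exposure at one.
- The summary weighted sum is again scaled to cohort SD; the **display
  scale** adds the offset that puts the cohort mean at 1 (1 = cohort
  reference level). Prioritization thresholds operate on this scale. The
  cohort here is the *analysis cohort* (subjects with both scores,
  unrelated, in an analysis subpopulation), so scores are anchored to
  the set actually analysed.

Cluster discovery uses average-linkage hierarchical clustering on
1 − Pearson r (merges allowed while linkage correlation exceeds the
cut-point, default 0.45). Average linkage is a deliberate choice; the
cut-point, betas and member list are configuration inputs — the betas
come from an external pesticide–PD meta-analysis in the real design and
are synthetic here.

## Progression scoring

The longitudinal model is

    UPDRS_ij = x_ij'β + b0_i + b1_i · t_ij + ε_ij,   (b0, b1) ~ N(0, G),

fitted by REML (statsmodels MixedLM) with unstructured 2×2 G. The
empirical-Bayes slope is the BLUP deviation
G Z_i'(Z_i G Z_i' + σ²I)⁻¹(y_i − X_i β̂); tests verify the fitted values
against this closed form directly. Residualizing the EB slopes on the
covariates (OLS, intercept included) gives mean-zero residuals; the
display score is 1 + residual/SD. Subjects with one visit contribute to
the fit but receive no score (configurable; two or more visits define
"has a progression score"). When the covariates explain the slopes to
numerical precision, the SD normalization would amplify float noise, so
residual SDs below 1e-10 of the response scale are treated as zero and
all display scores set to 1.

## Enrichment testing

The pooled two-proportion z-test is the primary statistic, two-sided,
with the directional requirement cohort frequency > reference frequency
for the "enriched" flag. AN is 2 × samples passing the 10× depth rule at
the site in that subpopulation. alpha = 0.05 with **no multiple-testing
correction** — this mirrors the source design and is a caveat, not an
endorsement: with hundreds of tests a real analysis should expect
~alpha/2 × tests false directional discoveries even at perfect
calibration.

**Small-count caveat.** Against a reference of AN ≈ 10⁵, a cohort of
~640 alleles cannot measure ultra-rare frequencies: a single observed
allele at reference frequency 10⁻⁴ is already "significant" under the
z-test, making the test structurally anti-conservative in that regime
(and z-test and Fisher-exact decisions diverge on up to ~20% of
small-count grids; both facts are asserted in the test suite). The
synthetic generator therefore draws background frequencies log-uniformly
over MAF 10⁻³–0.2, where the normal approximation is defensible and the
null simulation is calibrated (measured type-I ≈ 3–4% at alpha 5%).

## Relatedness

PI_HAT uses the classical method-of-moments IBS→IBD decomposition
(PLINK's estimator without its finite-sample frequency corrections),
clamped to [0, 1]; empirically unbiased to ±0.02 for unrelated pairs at
5,000 sites. Exclusion is strictly greater than 0.05, removing the
member of the most flagged pairs first (max-degree greedy; ties broken
by subject id — who to drop is unspecified in the source design). The
generator's default SNP matrix is 20,000 sites: at 5,000 sites the
estimator's noise tail (sd ≈ 0.008) crosses the 0.05 threshold for
~0.2% of pairs, which over the ~10⁵ pairs of a full cohort would
falsely exclude many subjects; 20,000 sites restores the behavior of
the array-scale data (470k SNPs) the threshold was designed for.

## Prioritization and ranking

Carrier averages are arithmetic means of display scores over a variant's
carriers inside the analysis cohort, per subpopulation. Thresholds are
inclusive (≥ 1). The composite normalization divides each carrier
average by its maximum over the prioritized set — "normalized" is not
further specified in the source design; max-scaling keeps scores in
(0, 1], preserves ranking under common rescaling, and equals 1 only for
a variant attaining both maxima. Gene composites average member entries,
with a variant enriched in both subpopulations contributing one entry
per subpopulation. CADD bins: [0,10), [10,20], (20,∞), with 10 and 20
inclusive in the middle bin ("10 or more", "20 or more" define the
deciles). The additivity check (multi- vs single-variant carriers)
uses a Welch t-test on per-subject mean composites; the source design
names no test.

## Synthetic cohort generator

Defaults emulate the study shape: 757 subjects, ancestry fractions
0.83/0.17 (European/Hispanic, the 320:66 analysis ratio), up to 3
visits with follow-ups independently retained at 0.7, an 85-gene panel
in groups of 14+13+18+36+4, a 10-pesticide cotton cluster among 30
pesticides in 3 co-application clusters, and a gnomAD-style reference
table (AN 113,000/35,000).

Choices the study does not constrain, fixed once here:

- **UPDRS variance components**: slope SD 3.0, intercept SD 8.0,
  residual SD 2.0 points. These give per-subject slope reliability of
  ~0.7–0.8 at ≤ 3 visits — an informative but visibly shrunken EB score,
  consistent with treating the residualized slope as a usable
  progression measure.
- **Within-cluster correlation** is specified on the observed scale: the
  generator inverts the lognormal attenuation so realized pairwise r of
  long-term averages matches the configured target (default 0.6).
- **Carrier bias**: planted variants choose carriers with weight
  exp(bias · (exposure z + slope z)), bias 1.5 by default. The real
  magnitude of this association is unknown; the tilt is a controllable
  mechanism, not an estimate.
- **Planted allele frequencies** U(0.003, 0.01) with enrichment fold 8 —
  large enough for several carriers per variant at subpopulation sizes
  of tens to hundreds, so recovery is power-limited by the method, not
  by Poisson noise on one carrier.
- Planted CADD scores follow a 14%/31%/56% mixture over the <10 / 10–20 /
  >20 bins.

Ground truth (true slopes, cotton-cluster latent exposure factors,
planted carrier sets, related pairs with expected PI_HAT 1.0 or 0.5) is
recorded in a `TruthBundle` for recovery tests.

**What the generator does not emulate:** linkage disequilibrium beyond
planted relatedness, genotype missingness, real genome coordinates,
measurement error in the exposure GIS chain, informative dropout, or
non-linear progression. Passing recovery tests therefore demonstrates
that the pipeline correctly extracts the signal *it defines*, under
idealized sampling — not that the design has comparable power on real
data, where exposure misclassification and confounding will dominate.

## Problem sizes in tests and the acceptance script

The shipped experiments use cohorts of 100–400 subjects, panels of
30–140 variants, and 200-replicate calibration loops; these sizes make
every Monte-Carlo bound in the test suite comfortably stable while the
whole suite runs in well under a minute of compute per module. The
acceptance script runs the full pipeline at n = 386 (the analysis-cohort
scale of the emulated study) with 20 planted variants.

## Known limitations

- The two-proportion test inherits the design's vulnerability to
  reference/cohort platform differences; the generator's null draws
  cohort genotypes at exactly the recorded reference frequencies, which
  real data never does.
- The composite ranking depends on the (undocumented) normalization
  convention; rankings are stable under common rescaling but not across
  alternative normalizations (z-scaling would reorder sets whose two
  score distributions differ in spread).
- Published per-variant composite scores cannot be recomputed from
  public information (the underlying exposure and clinical tables are
  not deposited); the packaged ranking table is used as a transcription
  for report-recount checks only.
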