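# Methods

## Problem and scope

`mrisubtype` implements an analysis pipeline for asking whether the effect of
a symptomatic treatment (donepezil vs placebo) in mild cognitive impairment
(MCI) depends on the patient's baseline MRI pattern of atrophy. The pipeline
covers: (1) derivation of two continuous subtyping dimensions and of the
categorical atrophy subtypes from visual-rating scores; (2) annualized MRI
and cognitive change outcomes; (3) treatment-by-dimension interaction
regressions and subtype-by-treatment ANCOVA; (4) a synthetic two-visit
randomized-trial generator so that every stage is testable, calibrated and
able to demonstrate recovery of known effects without access to any real
trial data. Image processing is out of scope: the input boundary is a
regional morphometry table (Desikan-atlas volumes/thicknesses, totals, ICV)
as exported by standard surface-reconstruction software, plus a clinical
table.

## Subtyping dimensions

**Severity** is the BV/CSF index: total brain volume (grey + white matter)
divided by total CSF volume. Lower values mean more global atrophy (toward a
typical-AD-like pattern); higher values mean minimal atrophy. Age-banded
thresholds convert the index into four descriptive bands (no/mild/moderate/
severe atrophy); the canonical published thresholds are not restated here,
so the shipped config carries clearly marked placeholder values and the
bands are used for description and plotting only, never for inference.

**Typicality** is the hippocampus-to-cortex ratio: the mean of left and
right hippocampal volume divided by the unweighted mean, over three cortical
aggregates (middle frontal, inferior parietal, superior temporal), of each
aggregate's left/right mean volume (two-level averaging, not a volume sum).
Low values indicate relatively more hippocampal atrophy (limbic-predominant-
like); high values indicate relative hippocampal sparing. "Middle frontal"
is not a single Desikan label and is defined in the config as the sum of the
caudal and rostral middle frontal parcels per hemisphere. With realistic
regional volumes the ratio sits near 0.2; published descriptive tables in
this literature sometimes print values near 0.1 after x100 scaling, a
magnitude that is not reproducible under the two-level-averaging definition
— the package follows the definition and applies the x100 scaling only in
display contexts. Both dimensions are ratios and therefore self-normalizing
for head size, so they are computed from unadjusted volumes.

## Categorical subtypes

Visual-rating scores are thresholded: mean of left/right MTA against an
age-banded cut (>= 1.5 at ages 45-74, >= 2.0 at 75-84, >= 2.5 at 85-94), PA
and GCA-F against >= 1 at any age. Continuous (model-estimated) scores are
thresholded directly without rounding to half steps, since rounding would
move borderline cases across a >= comparison. Left/right MTA are combined by
arithmetic mean — the dominant convention in the subtyping literature, using
both hemispheres. The three booleans map totally onto four labels: abnormal
MTA with abnormal PA and/or GCA-F = typical AD; abnormal MTA alone =
limbic-predominant; abnormal PA and/or GCA-F with normal MTA =
hippocampal-sparing; all normal = minimal atrophy. Ages outside 45-94 raise
an error rather than extrapolating the rule table.

## Efficacy outcomes

The MRI outcomes are annualized percentage changes (APC, %/year):

    APC = (followup - baseline) / baseline x (365 / MRI interval in days) x 100

for ICV-adjusted hippocampal volume, ICV-adjusted lateral-ventricle volume,
ICV-adjusted total grey matter, and the AD-signature cortical thickness
(mean over entorhinal, inferior temporal, middle temporal and fusiform of
the per-region left/right mean thickness; never ICV-adjusted, as thickness
does not scale with head size). Negative APC means loss; expanding
ventricles give positive APC. The annualization constant is exactly 365
days. APCs beyond +/-100 %/year are arithmetically possible (a measure more
than doubling) and produce a warning, not an error, and no clamping.
Cognitive outcomes use the percentage change (PC) without annualization.

ICV adjustment uses the residual approach: the OLS slope of each volume on
ICV is estimated once on the baseline visit of the analyzed cohort (or a
user-supplied fit sample, e.g. controls) and the same slope and centring are
applied at both visits. Using per-visit slopes would inject fit noise into
the change scores. A consequence worth knowing: the adjustment shifts the
APC denominator, so the APC of an adjusted volume is not bit-identical to
the APC of the raw volume even when the adjustment is noise-free;
`derive_measures(adjust_icv=False)` exposes the unadjusted path.

## Inferential models

For each outcome y, the interaction regression is

    y ~ treatment + severity + typicality + age [+ field strength]
        + severity:treatment + typicality:treatment

with treatment a 0/1 dummy (0 = placebo) and field strength included only
for MRI outcomes, both fitted by OLS (statsmodels). The two interaction
coefficients are the effects of interest. Optional backward selection scores
sub-models by BIC under a marginality constraint (an interaction is never
retained without both main effects); age and field strength are forced. The
default strategy enumerates all marginality-respecting sub-models
exhaustively — with at most five candidate terms this is at most a few dozen
fits and is exactly optimal. The greedy alternative eliminates one term at a
time (the removal giving the lowest BIC) down to the empty candidate set and
returns the best model visited along the path; returning the path optimum
rather than stopping at the first local minimum makes the greedy route
deterministic and equal to the exhaustive optimum whenever the candidate
effects are well separated. Ties break toward fewer terms, then
lexicographically.

The categorical analysis is a fully between-subjects two-factor ANCOVA
(subtype x arm) with age (and field strength for MRI outcomes) as
covariates, Type-II sums of squares — chosen because subtype cells in such
cohorts are heavily unbalanced, and switchable in principle since the SS
convention is a reporting choice. Post hoc donepezil-vs-placebo contrasts
within each subtype are evaluated at mean covariate values and
Benjamini-Hochberg-adjusted within the per-outcome family (the narrowest
defensible family definition). A subtype with an empty or singleton cell
yields an undefined contrast and a warning rather than an error. BH
adjustment is the standard step-up procedure (statsmodels), validated in the
tests against a hand-coded oracle.

Baseline group comparisons use one-way ANOVA by default (Kruskal-Wallis per
variable via config, since no normality rule is imposed) for continuous
variables and the chi-square test (no continuity correction) for
categorical ones. All model fits are complete-case for the variables of that
model, and every result reports the n actually used; there is no imputation,
mirroring a per-protocol analysis.

## Synthetic cohort generator

The generator emulates a two-arm, double-blind, 12-month trial in amnestic
MCI with MRI at baseline and follow-up. Defaults are the emulated study's
conditions: n = 173 with 48% randomized to active treatment; age 73.8 (6.6)
years truncated to [51, 94] (trial entry requires age > 50 and the rating
rule table supports ages up to 94); 26% of subjects on 3 T scanners;
baseline hippocampus 6270 (905) mm3, total grey matter ~552,000 mm3,
lateral ventricles ~36,600 mm3 (log-normal), AD-signature thickness ~2.6 mm,
BV/CSF index 28.9 (12.9). The follow-up MRI interval is ~357 +/- 14 days for
most subjects with a 10% fraction uniform in 6-11 months, and the APC
computation uses the realized interval, as in the emulated design.

Two latent dimensions (severity, typicality) are bivariate Gaussian with
configurable correlation (default 0 — the framework treats the axes as
separate, and independence is the neutral default). They load on the
baseline volumes so that the realized BV/CSF index equals the configured
severity distribution exactly (CSF is derived from BV and the index) and the
realized hippocampus-to-cortex ratio increases with latent typicality.
Volumes (not thicknesses) are partially scaled by ICV so the residual
adjustment has real work to do. Only the regions used downstream
(hippocampus, lateral ventricles, the typicality and signature regions,
totals, ICV) receive structured signal; the remaining Desikan columns are
filled with calibrated noise so the schema stays complete.

The true annualized rate of each MRI efficacy measure is a linear predictor
in the subject's **realized** baseline-derived severity and typicality (not
the latent z-scores), age, a Gaussian heterogeneity term, and — in the
active arm — a main treatment effect plus treatment-by-severity and
treatment-by-typicality terms. Driving the rates with the realized
dimensions means the analysis model is exactly correctly specified, so the
fitted interaction coefficients are unbiased for the injected values (no
errors-in-variables attenuation); this is the property the recovery and
type-I-error harnesses rely on. Default effect sizes echo the coefficient
magnitudes reported for this design (e.g. typicality-by-treatment 16.4
%/year per unit ratio and severity-by-treatment 0.11 %/year per index unit
on the AD-signature APC; -101.8 on the ventricular APC); the null generator
zeroes every treatment-related coefficient. Follow-up values are baseline x
(1 + rate/100 x interval/365) plus Gaussian measurement noise.

Visual ratings are monotone noisy linear transforms — MTA of the
hippocampal deficit (plus a small age slope), PA and GCA-F of the cortical
latents — clipped to their scale bounds. The links are a declared stand-in:
the real joint distribution of ratings given regional volumes is unknown,
and clipping introduces a known truncation at the scale ends. Link
parameters are set so that a cohort selected for amnestic MCI classifies
predominantly as minimal-atrophy and limbic-predominant, with
hippocampal-sparing and typical AD together rare — the composition such
inclusion criteria produce. Cognitive scores get baseline distributions
matching the emulated trial's descriptives and small annual percentage
changes with configurable treatment effects (default 0).

What the generator does **not** emulate: realistic spatial covariance of the
full atlas, scanner- or site-effects beyond a field-strength label, dropout,
floor/ceiling structure of cognitive tests beyond clipping, and any
non-linear dose-response. Passing tests therefore demonstrate correctness of
the pipeline's arithmetic and the statistical calibration of its inference
under a well-specified linear world — not that real trial data satisfy these
models.

## Numerical and design choices

* Residual-variance edge cases are errors, not silent results: constant ICV
  in the fit sample, fit samples smaller than 3, zero baselines in change
  scores, single-arm model fits, rank-deficient designs (reported with the
  aliased terms named).
* A BV/CSF value exactly on a severity-band boundary falls in the
  less-atrophic band; an MTA mean exactly at its cut is abnormal (both are
  >= comparisons, as the rules are stated).
* The simulated measurement noise is modest (sub-percent scan-rescan error);
  combined with effect sizes echoing the reported coefficients this yields a
  higher model R^2 than observational cohorts show. Calibration conclusions
  (type-I error, CI coverage) are insensitive to this scale choice.
* Monte-Carlo problem sizes in the test suite: 2000 null cohorts of n = 200
  for type-I error; 600 cohorts of n = 2000 for recovery bias and CI
  coverage (a binomial coverage estimate from substantially fewer replicates
  has Monte Carlo error comparable to the acceptance band itself); 500 toy
  datasets for the selection-strategy equivalence; 100 cohorts of n = 173
  for the scenario composition check.
* All randomness flows from explicit integer seeds (numpy Generator); a
  pipeline run records its seed, config digest and per-output content
  digests in a JSON manifest, and identical runs produce byte-identical
  CSVs.

## Known limitations

* Severity-band thresholds are placeholders until the canonical age-adjusted
  values are supplied via config.
* The CSF compartmentalization behind `csf_total` (ventricular + sulcal vs
  total extracerebral) is taken as given in the input column; the index is
  only as comparable as that column's provenance.
* "Mixed ANOVA" designs with a within-subject factor are out of scope: both
  factors here are between-subject, and no repeated-measures or
  mixed-effects models are fitted.
* The backward-selection criterion (BIC) is one defensible choice among
  several; AIC is available via argument.
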