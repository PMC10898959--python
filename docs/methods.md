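# Methods

This note documents the models, the synthetic-data conditions, the
numerical choices, and the known limitations of `airmasld`.

## Outcome definition and cohort construction

MASLD is classified as sonographic hepatic steatosis plus at least one of
five cardiometabolic criteria: (1) BMI ≥ 23 kg/m² or waist circumference
> 94 cm (men) / > 80 cm (women); (2) fasting glucose ≥ 100 mg/dL or HbA1c
≥ 5.7% or diabetes history/treatment; (3) SBP ≥ 130 or DBP ≥ 85 mmHg or
antihypertensive treatment; (4) TG ≥ 150 mg/dL or lipid-lowering
treatment; (5) HDL ≤ 40 (men) / ≤ 50 (women) mg/dL or lipid-lowering
treatment.  Steatosis with all five criteria definitively false is
cryptogenic steatotic liver disease and is excluded from the analysis
cohort.  Classification is three-valued: a criterion is *unknown* when its
observed components are all false but a component is missing, and a record
whose category cannot be decided is UNDETERMINED.  Consequently a single
definitively-true criterion decides MASLD even when other criteria cannot
be evaluated.  "BP ≥ 130/85" is read as SBP ≥ 130 **or** DBP ≥ 85, the
standard cardiometabolic-criteria reading.

The exclusion cascade is sequential: missing exposure/sonography →
duplicate records (earliest checkup kept) → age < 18 → undetermined MASLD
status → missing alcohol information → cirrhosis/HCC history → hepatitis →
excessive alcohol (≥ 2 drinks/day on ≥ 3 days/week for > 1 year; any
missing component makes the flag missing, except never-drinkers, who are
false without quantities) → significant sonographic abnormality →
cryptogenic SLD.  Each record is counted at the *first* rule it triggers,
which makes the per-rule counts additive — the convention consistent with
published enrollment-flow diagrams whose counts sum exactly to the final
cohort size.

Exposure windows: the W-year average is the arithmetic mean of the W·12
calendar months strictly before the index checkup month (the index month
itself is excluded).  If fewer than 90% of those months are present the
exposure is treated as missing and feeds the first exclusion rule; the
threshold is configurable, and 90% was chosen to tolerate sparse
monitoring-station dropout without biasing the mean.

Covariate encoding: age continuous; sex, marriage, education, income,
smoking, alcohol status, four diet-frequency items, regular exercise and
enrollment year as dummy-coded categoricals.  Missing marriage, education
and income become an explicit `unreported` level; other categorical
missingness (rare by construction) is imputed to the modal category.
Reference levels — female, single, college-or-higher, lowest income band,
never-smoker, never-drinker, seldom intake, no exercise, earliest
enrollment year — are recorded in the column dictionary so odds ratios are
interpretable.  Hypertension, diabetes and dyslipidemia are deliberately
not adjusted for: they are components of the outcome definition.  The
descriptive ALT upper limit of normal defaults to 40 U/L (configurable;
descriptive use only).

## Link families and selection

Four exposure encodings are supported: linear; threshold
(hinge (x−c)₊, zero at and below the cutpoint); interaction
([x, 1{x ≥ c}, x·1{x ≥ c}], allowing a slope change and a level shift);
and restricted cubic splines with k ∈ {3..7} knots in the Harrell
truncated-power form, normalised by (t_k − t₁)² for conditioning.  The
boundary conventions (hinge = 0 at x = c; interaction indicator = 1 at
x = c) are arbitrary but fixed and tested.  Knots default to the standard
quantile tables (k = 3: 10/50/90th percentiles; k = 4: 5/35/65/95; …),
configurable.

Selection per pollutant:

1. Box-Tidwell: Wald p-value of the x·ln x term in a logistic model with
   x and covariates; p ≥ 0.05 retains the linear link.  Wald rather than
   likelihood-ratio is the conventional reading of "significance of an
   interaction term"; an LR variant is available behind a flag.
   Non-positive exposures are shifted by 1 − min(x) before the log.
2. Empirical logit: 100 percentile bins (quantile binning; heavy ties can
   merge bins), per-bin logit ln((cases+0.5)/(n−cases+0.5)).  The
   continuity correction keeps every bin finite.
3. Segmented search: continuous broken-stick on the binned curve,
   weighted by bin sizes.  For fixed c the model is linear in its other
   parameters, so the profile over c is minimised on a grid of interior
   bin means (restricted to the 5th–95th percentile of bin means to avoid
   boundary degeneracy) followed by bounded golden-section refinement.
   Grid ties break toward the smaller c; the refined point is kept only
   when it does not increase the SSE, so the fit is never worse than its
   own search.  Fitting on binned logits (rather than raw records) mirrors
   classical NLIN-style practice on logit probability plots and gives a
   smooth, well-posed objective; continuity is imposed in the *search*,
   and any genuine discontinuity is left to the interaction candidate at
   the model-selection stage.
4. AIC with parsimony: candidates within 10 AIC of the minimum are equally
   fitted and the simplest is chosen (threshold < interaction < RCS,
   fewer knots simpler).  Equality is judged against the minimum rather
   than pairwise, since pairwise chains can be intransitive.  The linear
   fit is reported in the AIC table but is not an eligible winner at this
   stage — it already failed the linearity gate, and the AIC comparison is
   defined among the non-linear families (a flag restores the plain rule).
   Selection uses covariate-adjusted AICs; unadjusted AICs are reported.
   The 3–7-knot scan runs only when the 4-knot spline survives the first
   comparison, mirroring the sequential description of the procedure.

## Joint model and derived quantities

The six-pollutant model is a single logistic regression with every
pollutant's selected basis, covariates and enrollment year.  Segment aORs
per 1 µg/m³: linear/threshold/interaction segments use the relevant slope
(for a threshold pollutant below its cutpoint the aOR is structurally 1
with a zero-width interval); spline segments use the
observed-exposure-weighted average derivative of the fitted logit with a
delta-method CI.  The average-derivative definition was an open design
choice — published per-unit aORs inside spline segments do not state their
construction, and degenerate printed intervals there suggest a different
or rounded construction — so an endpoint-contrast alternative
((f(hi)−f(lo))/(hi−lo)) is available behind a flag and the two can differ.

Predicted exposure–response curves hold every other design column at its
sample mean (observed proportions for dummies), the only reading of
"covariates at their means" that keeps the prediction inside the model
space; curves are invariant to re-coding of dummy reference levels
(tested).  AIC comparisons between model variants are guarded by a cohort
fingerprint (hash of ids and outcomes), since AIC is only comparable on
identical data.  VIF_j = 1/(1−R²_j) from regressing design column j on all
others plus an intercept; tolerance = 1/VIF; perfect collinearity reports
an infinite VIF rather than raising.

## Synthetic cohort: what it emulates and what it does not

The generator reproduces, at configurable n, the statistical structure the
analysis assumes for a Taiwanese paid-health-checkup population:

* **Exposure.** Six pollutants with 3-year-mean moments matching the
  reference population (PM₂.₅ 30.6 ± 6.6, PM₁₀ 51.7 ± 13.0, CO 704 ± 235
  — deliberately in µg/m³ as printed — O₃ 52.8 ± 6.5, SO₂ 10.8 ± 4.0,
  NO₂ 37.5 ± 9.6 µg/m³) and a Gaussian-copula correlation structure whose
  PM₂.₅–PM₁₀ (0.77) and PM₁₀–SO₂ (0.68) entries match the reference
  values; the remaining entries are typical urban-monitoring values
  (traffic pollutants positively correlated, O₃ weakly negative with NO₂
  and CO) chosen once and verified positive definite.  Monthly series mix
  a persistent person-level component (default 80% of window-mean
  variance, representing where a person lives) with an AR(1)
  month-to-month component (ρ = 0.9), both sharing the cross-pollutant
  correlation; weights are solved so the trailing 36-month mean has
  exactly the configured SD, which makes 1- to 4-year windows differ
  realistically.  Within-person temporal variance is not an observed
  quantity — ρ and the persistent fraction are free knobs, not facts.
  Negative draws truncate at zero (physical constraint; at the default
  moments the truncated mass is < 1% for every pollutant).
* **Outcome.** latent logit = intercept + Σ_j f_j(3-year mean_j) +
  covariate effects, with f_j configurable per pollutant as linear, hinge,
  two-segment-with-jump, or spline.  The default truths emulate the
  reported shapes (PM₂.₅ hinge at 34.64 µg/m³; PM₁₀/CO two-segment at
  57.93/643.6; O₃/SO₂/NO₂ splines, SO₂ null) with slopes on the scale of
  the reported adjusted odds ratios.  The intercept is calibrated by
  bisection so the expected prevalence among participants surviving the
  exclusion cascade equals the target (default 0.406), including a
  closed-form correction for cryptogenic removals.
* **Labels are decided downstream, not by the generator.** Cases receive
  steatosis and labs drawn from case-stratum distributions (bumping BMI
  into 23–25 kg/m² for the rare case whose draws satisfy no criterion);
  non-cases receive control-stratum labs without steatosis, except a small
  configurable fraction (default 2.46%) converted to cryptogenic SLD
  (steatosis, all criteria forced false).  The MASLD classifier applied to
  the generated table therefore reproduces the latent outcome exactly on
  the retained set.
* **Exclusions.** Per-rule flags are drawn independently of the outcome at
  marginal fractions emulating the published enrollment flow (hepatitis
  11.4%, undetermined MASLD fields 9.2%, missing alcohol 6.2%, …).

Not emulated: spatial exposure surfaces or geography (exposure dependence
is purely statistical), measurement error in ultrasonography, outcome-
dependent selection into checkups, within-criterion lab correlation
structure beyond the case/control strata, and secular exposure trends
(monthly means are stationary, so enrollment-year adjustment is exercised
but carries no true signal).  Passing tests therefore demonstrate that the
*pipeline* recovers known structure under the assumed data-generating
process, not that the epidemiological findings themselves generalise.

## Simulation studies and problem sizes

The characterisation studies run at sizes chosen to keep the full suite
fast while leaving the Monte-Carlo error well below the decision margins:
inflection recovery over 200 hinge-truth cohorts of n = 20,000 (criterion:
median |ĉ − c| under 10% of the exposure IQR; observed ≈ 5%); link-family
selection over 100 linear-truth and 100 hinge-truth seeds of n = 20,000
(≥ 90% correct; observed ≈ 95% and 100%); Box-Tidwell type-I error over
500 null seeds of n = 50,000 (nominal 0.05 ± 0.02); and per-coefficient
95% CI coverage in the joint six-pollutant model over 200 seeds of
n = 20,000 (band 0.92–0.98).  Moment and calibration checks use one shared
n = 50,000 cohort.

## Known limitations

* The marginal binned-logit curve of one pollutant absorbs the effects of
  correlated co-pollutants; with the full six-pollutant truth the
  single-pollutant inflection estimate is accordingly shifted relative to
  the planted cutpoint (visible in the acceptance output).  This mirrors
  the method itself, which estimates inflections marginally before the
  joint fit.
* Segment aORs inside spline links depend on the chosen summary
  (average derivative vs endpoint contrast); both are emitted.
* The broken-stick search assumes a single breakpoint; multiple
  simultaneous breakpoints and Bayesian changepoint inference are out of
  scope, as are penalised splines and pollutant–pollutant interaction
  terms.
* Heavy exposure ties can merge percentile bins, reducing the effective
  bin count below 100.
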