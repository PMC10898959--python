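# airmasld

Non-linear exposure–response modelling between long-term ambient air
pollution and metabolic dysfunction-associated steatotic liver disease
(MASLD), as a tested, reusable Python pipeline.

Epidemiological dose–response analyses routinely assume that each 1 µg/m³
of exposure multiplies the odds of disease by a constant factor
(proportional odds).  For several pollutants that assumption fails: the
risk may be flat up to a threshold, change slope at an inflection point, or
curve smoothly.  This package implements a stepwise procedure that
*discovers* the functional form — the "link function" — connecting each
pollutant's 3-year average residential concentration to the log-odds of
MASLD, and then fits one joint logistic model containing all six routinely
monitored pollutants (PM₂.₅, PM₁₀, CO, O₃, SO₂, NO₂), each through its
selected encoding.  It is aimed at environmental epidemiologists and
biostatisticians who need threshold/segment-specific odds ratios rather
than a single per-unit estimate.

Because health-checkup cohorts of this kind are not publicly deposited, the
package ships a first-class synthetic-cohort generator that emulates the
relevant statistical structure (correlated monthly exposure series,
covariates, cardiometabolic labs, sonographic steatosis, configurable true
link per pollutant, enrollment-flow exclusions), so every stage of the
pipeline can be validated against known ground truth.

## The method

For a binary outcome Y (MASLD) and exposure x, the logistic linear
predictor is

    logit P(Y=1 | x, z) = α + f(x) + γᵀz

where z are adjustment covariates and f is one of four families:

1. **linear** — f(x) = βx (proportional odds);
2. **threshold** — f(x) = β·max(0, x − c): flat baseline below the
   inflection point c, linear above;
3. **interaction** — f(x) = β₁x + β₂·1{x ≥ c} + β₃·x·1{x ≥ c}: separate
   slopes below/above c with a level shift;
4. **RCS** — a restricted cubic spline with k ∈ {3..7} knots (Harrell
   basis: piecewise cubic, C², linear beyond the boundary knots).

Selection is stepwise per pollutant:

1. **Box-Tidwell gate** — test the Wald significance of x·ln x alongside x;
   if not significant at α = 0.05, keep the linear link and stop.
2. **Empirical-logit curve** — cut the exposure into 100 percentile bins
   and compute the continuity-corrected logit ln((cases+½)/(non-cases+½))
   per bin.
3. **Inflection search** — fit a continuous broken-stick
   a + b₁x + (b₂−b₁)(x−c)₊ to the binned curve by bin-size-weighted
   non-linear least squares, profiling c over a grid of interior bin means
   with local refinement.
4. **AIC with parsimony** — fit the threshold(ĉ), interaction(ĉ) and
   4-knot RCS candidates (the linear fit is reported alongside); any
   candidate within 10 AIC of the minimum is "equally fitted" and the
   simplest wins (threshold < interaction < RCS, fewer knots simpler).  If
   the 4-knot RCS survives, the 3–7-knot ladder is scanned with the same
   rule.

The joint six-pollutant model then combines the selected encodings plus
covariates and enrollment year.  Segment-wise adjusted odds ratios per
1 µg/m³ come with delta-method 95% CIs (for splines: the
observed-exposure-weighted average derivative of the fitted logit over the
segment).  Collinearity is reported as tolerance/VIF per term and Fisher-z
intervals for pairwise Pearson correlations.  Sensitivity variants:
exposure categorised at the inflection points, all links forced linear,
and pollutant subsets (e.g. dropping PM₁₀).

## Worked example

```python
import pandas as pd
import airmasld as am

cfg = am.SimConfig(n_participants=20_000, seed=7)
parts, expo, truth = am.generate_cohort(cfg)
wide = am.window_average_table(expo, parts, years=3)
cohort, cascade = am.apply_exclusions(pd.concat([parts, wide], axis=1))
covs, _ = am.encode_covariates(cohort)

sel = am.select_link(cohort, "pm25", covs)
specs = {p: am.select_link(cohort, p, covs).chosen for p in am.POLLUTANTS}
model = am.fit_multipollutant(cohort, specs, covs)
```

Output for this seed:

```
retained 13201 of 20000; MASLD prevalence 40.0%
Box-Tidwell p = 1.13e-13
estimated inflection c = 33.46 ug/m3
adjusted AIC table: {'linear': 15980.9, 'threshold': 16006.7,
                     'interaction': 15924.7, 'rcs4': 15922.5}
chosen link: interaction
pm25 below 33.46: aOR 1.020 (1.006-1.035)
pm25 above 33.46: aOR 1.034 (1.009-1.059)
best-link AIC 15016.8
```

Reading this: the cohort generator plants a hinge-shaped truth for PM₂.₅ at
34.64 µg/m³; the Box-Tidwell test decisively rejects proportional odds
(p ≈ 10⁻¹³), the segmented search recovers an inflection near the true
value, and the 4-knot spline's AIC edge over the interaction encoding
(2.2 < 10) is not enough to justify the extra complexity, so the simpler
two-segment encoding is selected.  In the joint model the per-µg/m³
adjusted odds ratio above the inflection (1.034) exceeds the one below it.

The same stages are available from a shell:

```sh
airmasld simulate --n 20000 --seed 7 --out sim/
airmasld build --participants sim/participants.csv --exposure sim/exposure.csv \
               --window-years 3 --out built/
airmasld select --cohort built/cohort.csv --pollutant all --out selected/
```

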