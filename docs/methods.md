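# Methods

## Index computation

Pulse pressure is derived per reading as SBP − DBP; a reading with
SBP ≤ DBP is physiologically invalid and rejected with its position in
the series. Indices operate on the observed reading sequence exactly as
recorded — no interpolation, resampling onto the nominal grid, or
rounding before computation. SD uses the n − 1 denominator; SV and ARV
divide by n − 1 over the n − 1 successive differences, so ARV is the
plain mean absolute successive difference. CV requires a positive mean.
At least two readings are required (every successive-difference index
needs one pair). These conventions imply the order relations
ARV ≤ SV (power-mean inequality), ARV ≤ MSC ≤ DMM and SD ≤ DMM, which
the property tests sweep.

Values are kept as floating-point mmHg throughout; the report writer
rounds only in the display copies (ORs/AUCs to 3 decimals, cut-offs to
integers, everything else to 1 decimal), matching the conventional
presentation of clinical BPV tables.

## Sampling-completeness screen

The nominal schedule is one reading every `interval_hours` (default 4)
from hour 0 through `window_hours` (default 72) inclusive — 19 slots.
Whether the first slot falls at hour 0 or hour 4 is a genuinely open
charting convention; we take inclusive endpoints and expose the count
through the policy, since no index formula depends on it. A series is
analyzable when it has at least `min_fraction` (default 0.8) of the
expected slots and no gap between successive readings exceeding
`max_gap_hours` (default 8, twice the nominal interval). Clinical
registries exclude patients with "inadequate" or interrupted reading
sequences without publishing a numeric rule; these two thresholds are
this package's explicit, configurable quantification of that screen.
Rejections carry machine-readable reasons (`too_few_readings`,
`gap_too_large`) that feed the exclusion-flowchart accounting:
patients in = patients analyzed + Σ per-category exclusions.

## Outcome rules

Plain dichotomization: unfavorable iff mRS ≥ 3 at the follow-up
horizon. Severity-adjusted rule: unfavorable iff (mRS 2–6 and admission
NIHSS ≤ 7) or (mRS 3–6 and NIHSS 8–14) or (mRS 4–6 and NIHSS > 14).
Band edges are integer-inclusive, so the three NIHSS bands partition
0–42 exactly. The rule is applied literally, which leaves e.g. mRS 3
with NIHSS 20 favorable; the exhaustive truth-table test pins this
behavior. The severity-adjusted rule enters only model M3; it is
evaluated at both horizons, with NIHSS always the admission value.

## Inference choices

- Logistic fits are maximum likelihood via Newton/IRLS (statsmodels),
  convergence at max coefficient change < 1e-8 or 100 iterations.
  Complete-case per model. Perfect separation is flagged
  (`converged=False`) rather than raised, so a model suite returns
  partial results; a singular design raises.
- Odds ratios are reported per 10 mmHg by dividing the PPV predictor by
  10 before fitting (equivalently exp(10β) per mmHg); the scaling is
  applied to the PPV predictor only, not to covariates such as mean PP
  or age. Confidence intervals and p-values are Wald with z = 1.96 —
  the reporting convention of the tables this pipeline mirrors; profile
  or likelihood-ratio intervals are deliberately out of scope.
- Spearman correlations use midranks (scipy), p from the t
  approximation on n − 2 df; constant vectors are an error rather than
  a NaN. Mann–Whitney U reports min(U_a, U_b); exact enumeration when
  both groups have n ≤ 8 and no ties, otherwise the normal
  approximation with tie and continuity corrections. Group-comparison
  p-values in the baseline table use the U test for every variable,
  binary flags included (on 0/1 data the rank test reduces to a
  proportion comparison); a chi-square alternative was considered and
  rejected to keep one consistent column.
- ROC: empirical curve over observed thresholds with the rule "predict
  unfavorable if score ≥ cut-off". AUC is the Mann–Whitney win fraction
  (ties ½), computed from integer win counts so tie-free data give
  exact ratios. The AUC interval and the test of AUC = 0.5 use the
  DeLong placement-value variance, implemented here (no installed
  package exposes it). Youden's J = max(sens + spec − 1); the reported
  cut-off is the smallest observed score attaining the maximum, which
  makes ties deterministic.

## Synthetic cohorts

The generator emulates the structure of a ~200-patient stroke-unit
registry: per-patient PP level normal with mean 57 and SD 14 mmHg
across patients; within-patient fluctuation scale drawn uniformly from
5–25 mmHg per patient, which puts the cohort mean of per-patient PP SD
near 15 mmHg — between the values typical of thrombolysed and
non-thrombolysed subgroups; readings are level + independent Gaussian
noise at the 19 nominal 4-h slots (an AR(1) option with configurable ρ
adds serial correlation for sensitivity work), optional linear drift,
and per-slot dropout (default 0.05; the admission reading is always
kept, and true per-slot completeness of such registries is simply
unknown — the resolved value is echoed in `spec.json`). SBP/DBP are
reconstructed around a drawn MAP as SBP = MAP + ⅔PP, DBP = MAP − ⅓PP,
so SBP − DBP reproduces the simulated PP exactly and the standard
MAP identity holds.

The unfavorable-outcome probability follows a logistic model on the
patient's *realized* index value (default: PP SD, slope ln(4.8)/10 per
mmHg, i.e. OR 4.8 per 10 mmHg) plus optional covariate effects; using
the realized rather than latent index makes the unadjusted logistic fit
correctly specified, so recovery simulations measure estimation error,
not errors-in-variables attenuation. The intercept (−2.75) places
default prevalence near 40 % unfavorable. The 30- and 90-day outcomes
share a Gaussian copula (ρ = 0.9). mRS is then drawn within the
favorable (0–2) or unfavorable (3–6) band, and admission NIHSS from a
severity ramp in mRS (normal around 2 + 2.5·mRS, clipped to 0–42), so
both outcome rules are exercised across all their branches. Covariates
use registry-typical rates (age 68 ± 13, 47 % female, thrombolysis
20 %, comorbidity rates 9–66 %).

What passing tests on these cohorts do **not** show: real BP series
have circadian structure, treatment-driven trends and informative
missingness none of which the default generator produces; covariates
are drawn independently of the index, so confounding is absent unless
injected through the outcome-model betas. Recovery and calibration
results therefore validate the estimator machinery, not any clinical
effect size.

## Problem sizes and numerics

Recovery runs 200 cohorts of n = 203 (the registry-scale cohort size)
and checks mean OR within 15 % of 4.8 with Wald coverage in
0.93–0.97; null calibration uses 500 replicates and a KS test against
uniform. Oracle sweeps use 1,000 random series of length 2–30 against a
pure-Python loop implementation at 1e-10 relative tolerance. Index
inequality checks allow 1e-9 absolute slack for floating-point ties.
Degenerate inputs fail loudly: fewer than 2 readings, constant vectors
in rank tests, single-class outcomes, singular designs, cohorts under
10 patients, or an outcome model that produces one class only.

## Known limitations

- PP only; SBP/DBP/MAP variability indices and ambulatory-monitor
  weighting schemes are out of scope, as are ordinal mRS (shift)
  analyses, survival models, multiple imputation and multiplicity
  correction.
- Wald inference can be anti-conservative in small subgroups; the
  thrombolysed subgroup of a ~200-patient cohort is near that edge, so
  subgroup model output should be read with care (the pipeline reports
  n_used and convergence per model).
- The DeLong p-value for AUC = 0.5 is asymptotic; with very few events
  the interval endpoints are clipped to [0, 1] rather than
  logit-transformed.
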