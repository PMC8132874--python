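# Methods

This note documents the models, parameter choices and numerical
conventions behind `thermoagree`, and what the synthetic cohorts do and do
not establish about real bedside data.

## Sensor model

The double sensor is modeled as a steady-state series thermal circuit: the
heat flux through the insulating layer between the two thermistors equals
the flux through the tissue under the skin, giving the algebraic estimate
`Tcore = Th1 + (Ks/Kg)·(Th1 − Th2)`. No transient heat-conduction dynamics
are modeled. The device vendor does not publish `Ks` and `Kg`; only their
ratio matters, so `ks_over_kg` is a configuration parameter (default 0.5,
strictly positive). Because the simulator produces sensor pairs through
the exact algebraic inverse (`th1 = tcore − offset`,
`th2 = th1 − offset/ratio`), every downstream statistic is invariant to the
chosen ratio; the round-trip identity is property-tested across ratios
0.01–100 to 1e−9 °C. A ratio of zero is rejected at configuration time:
it would collapse the estimate to the bare skin temperature and make the
forward model non-invertible.

Sensor readings outside a [15, 45] °C plausibility corridor (detached
sensor, logger glitch) are *flagged*, not dropped — the 2-SD artifact
filter is deliberately the only exclusion step in the pipeline.

## Synthetic cohorts

Each patient's *true* core trajectory follows the TTM protocol as a
continuous piecewise-linear curve: induction from 35.5 °C at 1.5 °C/h
(post-arrest patients are typically mildly hypothermic; neither value is
protocol-prescribed, both are configurable), a 24 h plateau at exactly
33 °C, rewarming at exactly 0.25 °C/h to 37 °C, then a 24 h hold.
Optional stationary AR(1) jitter (SD 0.05 °C, autocorrelation 0.99 per
step) avoids a perfectly deterministic plateau; it is set to 0 in analytic
tests.

The recorded streams add, per patient:

| parameter | default | meaning |
|---|---|---|
| `sensor_bias_sd` | 0.45 °C | SD of the patient-level systematic sensor offset, drawn N(0, σ²) once per patient |
| `lag_range_min` | U(0, 10) min | pure time shift of the sensor signal behind the core (slow heat transport to the forehead); per-patient, constant in time |
| `ds_noise_sd`, `ds_noise_tau_s` | 0.25 °C, 600 s | Ornstein–Uhlenbeck (AR(1)) sensor drift — vasomotion-like, slow |
| `oet_noise_sd` | 0.15 °C | white reading noise on the 30-min reference |
| `artifact_prob`, `artifact_magnitude_sd` | 0.05, 3.0 °C | per pairing epoch: probability of an additive Gaussian shock applied to all sensor samples in that epoch |
| `ambient_mean`, `ambient_sd` | 25.22, 1.48 °C | slowly varying ambient channel (recorded, not used in analysis) |

The sensor drift is **correlated** (correlation time 600 s, well beyond the
60 s pairing window) rather than white. This is both physically motivated —
perfusion changes are slow — and required for internal consistency: white
1 Hz noise would average to ≈0.03 °C inside the pairing window, whereas the
intended pooled paired-difference SD decomposes as
√(0.45² + 0.25² + 0.15²) ≈ 0.54 °C, i.e. the 0.25 °C component must
survive window averaging. With these defaults a 20-patient cohort's pooled
difference SD after artifact filtering lands in roughly [0.45, 0.62] °C
across seeds, bracketing the ≈0.53 °C scale typical of forehead-vs-core
comparisons during TTM.

The between/within split (0.45 between patients vs 0.25 + 0.15 within) is
a modeling choice: published summaries pool all pairs and do not constrain
the decomposition.

Determinism: one master seed per cohort; patient seeds derive from
`SeedSequence([master, patient_index])`. Identical configuration and seed
reproduce a cohort bit-identically across processes.

What the simulator does **not** emulate: nonlinear or time-varying lag
(observed clinically in individual patients), drug-induced vasomotion
shifts, BMI/skin-perfusion effects on the gradient, device feedback
control, clock drift between loggers, and non-Gaussian heavy-centered
difference distributions. Passing tests therefore demonstrate the
*statistical machinery* is correct and calibrated under a plausible
generative model — not that a particular physical sensor meets the ±0.5 °C
criterion on real patients.

## Pairing and the artifact rule

Stream cadences are matched by reducing the sensor-derived core signal to
the mean over a 60 s window centered on each reference tick (one candidate
pair per tick; empty windows are skipped and counted). The window mean is
robust to 1 Hz timing jitter and preserves the 30-min cadence; a
nearest-sample mode is available for sensitivity analysis. Cross-logger
clock alignment is assumed perfect.

The artifact rule flags a pair when its difference deviates from the mean
difference by more than twice the SD, with mean and SD computed **once**
over the pooled dataset (cohort analyses pool pairs; a per-patient variant
and a zero-centered variant exist behind configuration switches). The rule
is intentionally not iterated — re-application would keep shaving the
tails. On clean Gaussian differences it removes ≈4.55 % (the 2σ tail),
which is the filter's floor, not a defect.

Detection of injected artifacts is bounded by the shock distribution:
Gaussian shocks (SD 3 °C) frequently fall inside the 2-SD corridor, so the
expected detection rate under the defaults is only ≈57 %, while shocks
clearly beyond the corridor are caught reliably. Tests assert exactly
that attainable behavior.

## Agreement statistics

- Differences are sensor minus reference throughout.
- Limits of agreement use the fixed multiplier 1.96, so
  `midpoint(LoA) = bias` and `width(LoA) = 3.92·SD` are exact identities
  (property-tested). The bias CI is the exact t interval; each LoA bound's
  CI uses the Bland–Altman large-sample SE
  `SD·√(1/n + 1.96²/(2(n−1)))`.
- The ICC is the single-measure, two-way mixed, **consistency** form
  ICC(3,1) = (MSB − MSE)/(MSB + MSE), insensitive to a constant offset
  between methods; its 95 % CI uses the F method on (n−1, n−1) degrees of
  freedom. The absolute-agreement form ICC(A,1) is available behind a
  flag. Both match `pingouin.intraclass_corr` to float precision in the
  cross-check tests, and the point estimate matches an elementwise
  sum-of-squares oracle to 1e−10.
- Cicchetti labels use half-open bins [0, 0.4) poor, [0.4, 0.6) moderate,
  [0.6, 0.75) good, [0.75, 1] excellent — this covers the gaps the usual
  verbal statement leaves between 0.59/0.6 and 0.74/0.75.
- The ±0.5 °C coverage counts |d| ≤ threshold inclusively.
- Degenerate inputs: all-equal differences make the paired t statistic
  undefined — the report carries NaN plus an explanatory note rather than
  failing (a zero bias is checked separately). An ICC on identical
  columns with between-subject spread is exactly 1; all-identical data
  reject. Zero-spread detection uses an all-values-equal test, not
  `sd == 0`, to be robust to floating-point rounding of constant vectors.
- Rounding happens only at serialization (2 decimals for °C, t and ICC;
  2 significant figures for p), never inside computations.

Known limitation, intentionally out of scope: pooling repeated pairs from
the same patient understates LoA width relative to a within-subject
repeated-measures correction, and the pooled paired t-test treats pairs as
independent. Both match the common (if imperfect) practice this pipeline
reproduces.

## Study sizing

`icc_sample_size` implements the asymptotic method used by standard ICC
sample-size calculators (Zou's formula): `g(p) = ln(1 + k·p/(1−p))` is
treated as normal with variance `2k/((k−1)(n−1))`, the test is one-sided
by default (directional hypothesis ICC > p0; a two-sided switch exists),
and the returned n is minimal by explicit scan of the power function. The
formula's power agrees with a Monte-Carlo oracle (bivariate simulation +
one-sided F-method test) within 3 points at moderate n, and the
Monte-Carlo power at the returned n hits the target within 3 points.

Exploratory note: at power 0.90 and one-sided alpha 0.05 with k = 2,
hypotheses (p0 = 0.6, p1 = 0.9) — "good" against "excellent" reliability —
yield n = 16. Which hypotheses any particular study assumed is generally
not printed, so no specific pair is asserted in tests.

## Problem sizes used in tests and the acceptance script

Cohort-level statistical tests share one simulated 20-patient, 48 h, 1 Hz
cohort (a session fixture). The ICC reproduction averages 20 simulated
1,319-pair datasets; the LoA reproduction averages 50; type-I calibration
uses 1,000 null sets of 40–50 differences; the Monte-Carlo power oracle
uses 5,000 simulated studies. These sizes put Monte-Carlo error well below
each assertion's tolerance while keeping a full run in seconds.
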