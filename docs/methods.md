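# Methods

This note documents the models, numerical choices and limitations behind
`hrvsurv`, in the order the pipeline runs.

## Beat series and R-peak detection

A recording is an ordered series of beat times (s) with pulse-to-pulse
intervals (PPI, ms); the invariant `beat_times[k+1] − beat_times[k] =
ppi[k]/1000` is enforced to 1 µs. When the input is a raw single-lead ECG
(default 1024 Hz), R peaks are found with a simplified
derivative–square–integrate emphasis: the squared first derivative is
smoothed with a 150-ms moving window, peaks are picked above 30% of the
99th percentile of that envelope with a refractory period (`min_rr_ms`,
default 300 ms), and each detection is refined to the raw-signal maximum
within min(150 ms, `min_rr_ms`/2). On clean or synthetic traces this
recovers beat times to well under 1 ms at 1024 Hz; it is *not* a
clinical-grade detector (no noise tracking, no arrhythmia logic), which is
acceptable because real recordings enter the pipeline as R-R files
produced by dedicated hardware.

An optional ectopic filter (`filter_ectopic`, off by default) drops beats
whose PPI deviates more than 20% from an 11-beat running median.

## Tachogram resampling

The spectral estimator needs an evenly sampled signal; the beat series is
not one. Each PPI is anchored at the time of its opening beat and
interpolated with a natural cubic spline, sampled at `n_points` uniform
instants across the first `segment_seconds` of the recording (defaults
2048 points / 288 s ⇒ 7.111 Hz; a configurable offset selects a later
segment). Cubic splines are standard HRV practice: smoother than
staircase interpolation and with O(h⁴) error, which keeps attenuation of a
0.25-Hz oscillation sampled at ~1.25 Hz beat rate near 1% in power.
Recordings shorter than the segment raise a coverage error rather than
silently zero-padding.

## Spectral density and band powers

The resampled tachogram is mean-removed, Hamming-tapered and Fourier
transformed into a one-sided density in ms²/Hz. Two corrections follow:

1. division by the taper's mean-square value (incoherent gain), the
   textbook compensation for window attenuation when the quantity of
   interest is integrated power, and
2. an exact renormalization so the trapezoidal integral of the density
   over (0, Nyquist] equals the variance of the mean-removed tachogram.

The second step is deliberate: a taper reweights samples, so step 1 alone
preserves total power only in expectation — for a white-noise tachogram a
single realization deviates by several percent. Band powers are
meaningful fractions of signal variance only under an exact Parseval
contract, so the package enforces it pathwise. For a sinusoid of
amplitude A the integrated power remains A²/2 to well under 1% at interior
band frequencies.

Band integration treats the density as piecewise linear with interpolated
band-edge values, making integrals exactly additive over adjacent bands.
Bands: TP (0, 0.4] Hz excluding the DC bin, LF 0.04–0.15 Hz, HF
0.15–0.4 Hz, all configurable. The ratio LFP/HFP and the natural logs
lnTP, lnHFP, ln(LFP/HFP) are derived afterwards; a zero denominator or a
non-positive power yields NaN (an "undefined" flag), never an exception.

Known resolution limit: oscillations slower than ~0.04 Hz complete fewer
than 12 cycles in a 288-s segment and their power cannot be recovered to
2%; no index here uses them, but the total-power band necessarily carries
this imprecision for very-low-frequency content. Only the window
attenuation is compensated; no separate correction for the interpolation
low-pass effect is applied, which slightly attenuates components near the
HF upper edge.

## Synthetic beat series and ECG

`simulate_rr` builds PPI as `base + Σ Aᵢ·sin(2πfᵢt) + σ·ε` evaluated at
accumulated beat times (defaults: 800-ms base, 0.1 Hz/8 ms and
0.25 Hz/10 ms components, σ = 2 ms, 300 s). Each sinusoid's band power is
A²/2, giving the whole spectral chain a closed-form oracle. `simulate_ecg`
renders a Gaussian-bump P-QRS-T template (R width 8 ms) at each beat time;
the trace ends one median PPI after the last beat.

## Synthetic cohorts

`simulate_cohort` emulates a 138-patient advanced-cancer hospice
population:

- **Marginals** (defaults from the published descriptive table): age
  ~N(67.6, 12.6²); male 76/138; muscle power ~N(3.5, 1.15²) clipped to
  0–5; cognitive impairment 57/138; edema 73/138; jaundice 52/138; ascites
  43/138; ECOG 3–4 88/138. The log-HRV indices are two-component Gaussian
  mixtures with the published event/non-event group means and SDs and
  weights 29/138, 109/138 (lnHFP: 0.92 ± 2.26 and 2.25 ± 3.07, so
  P(lnHFP < 2) ≈ 0.51).
- **Outcome**: death within 7 days follows a logistic model in the two
  final-model predictors, log-odds `β₀ + ln(3.80)·[lnHFP<2] +
  ln(3.42)·[ECOG 3–4]`; β₀ is solved numerically so the marginal event
  rate is 29/138 = 21%. The implied theoretical AUC of the fitted risk is
  0.707.
- **Joint structure**: covariates are drawn independently except
  (lnHFP<2, ECOG 3–4), which admit a configurable odds-ratio association
  via the Plackett construction (default 1.0, i.e. independent).
  Continuous lnHFP is drawn from the mixture *conditional* on the drawn
  side of the cut (batched rejection sampling). The real joint
  distribution of predictors is unrecoverable from published summaries —
  this is the main respect in which the generator is idealized, so
  AUC-level agreement with the original study is a soft check, not a
  reproduction.
- **Survival days**: events die uniformly on days 1–7; non-events survive
  `7 + G` days with G geometric, its rate solved so the cohort median is
  20 days; administrative censoring at day 180. Only the median (and its
  rough CI) of the original survival distribution is published, so the
  tail shape is a modelling choice.

All generators are deterministic per seed (`numpy.random.default_rng`).

## Association analysis

- **2×2 tables / odds ratios**: OR = ad/bc with the log-scale Wald CI
  `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`. A zero cell flags the estimate
  undefined; the Haldane 0.5 correction is available behind a flag but off
  by default. Point estimates are method-invariant; CI method is a
  reporting choice (profile-likelihood intervals, as some software prints,
  differ in the second decimal).
- **Logistic regression**: maximum likelihood via statsmodels, Wald
  inference. Separation is reported honestly: a raised separation error or
  absurd standard errors (> 10³) set `converged=False` with a diagnostic
  instead of returning silent garbage.
- **Stepwise selection**: forward entry at Wald p < 0.15, backward
  elimination at p > 0.15, then "manual-style" pruning of terms with
  p > 0.05 one at a time. Deterministic given the candidate order; ties
  break by list position. With 5–6 candidates a run costs a few dozen
  IRLS fits.
- **Cutpoint discovery**: the event is regressed on a penalized cubic
  B-spline (10 basis functions) of the continuous index plus linear
  adjustment terms (binomial GLM-GAM). The penalty weight is chosen by
  grid search over 17 log-spaced values minimizing the effective-dof AIC
  (the installed statsmodels' built-in penalty optimizer does not support
  binomial families; AIC and GCV select nearly identical weights here).
  The cutpoint is where the centred partial log-odds crosses zero, linear-
  interpolated on a 512-point grid and rounded to the nearest 0.5 for
  clinical use (configurable). Two guards return a "no cutoff" flag
  instead of a spurious crossing: a materiality threshold (excursion
  < 0.1 on the log-odds scale) and a flatness test (the centred smooth
  nowhere exceeds 2 pointwise SEs, with the centring contrast propagated
  through the parameter covariance). An explicit intercept always sits in
  the parametric part because the spline basis spans no constant.
- **Hosmer–Lemeshow**: deciles of fitted risk; when the model produces
  fewer distinct fitted values than requested groups (two binary
  predictors give ≤ 4 risk strata) patients are grouped by distinct value
  instead; χ² on (groups − 2) df; fewer than 3 strata is untestable.
- **Kaplan–Meier**: product-limit estimator (lifelines); the median is the
  first time survival drops to ≤ 0.5, flagged undefined if never reached;
  the median CI uses the log(−log) (exponential Greenwood) band.
- **Missing data**: listwise deletion with a logged count, in tables and
  fits alike.

## Prediction evaluation

The ROC sweeps all distinct score thresholds (predict positive at
score ≥ t). The AUC is the trapezoid integral, which equals the
tie-corrected pairwise concordance statistic exactly; its 95% CI is
DeLong's structural-components variance. The optimal operating point
minimizes √[(1−sens)² + (1−spec)²] (distance to the top-left corner),
ties broken toward higher specificity after rounding distances to 15
decimals. Sensitivity, specificity, PPV and NPV carry Wilson-score 95%
CIs (Clopper–Pearson available); zero denominators flag the metric
undefined. `predictive_values_from_prevalence` gives the Bayes-rule
PPV/NPV for arbitrary prevalence. For the final two-binary-predictor
model the fitted risk takes at most 4 values, so the ROC has at most 5
vertices; the single-cell clinical rule (index below cut AND ECOG 3–4) is
evaluated as a 0/1 score through the same machinery.

## Pipeline, formats, reproducibility

The driver chains descriptives → univariate ORs → cutpoint →
dichotomization → stepwise selection → calibration → Kaplan–Meier →
evaluation, and writes `report.json`, `report.md` and `roc_vertices.csv`.
Reports embed the config hash, seed and package version and contain no
timestamps, so a (config, seed) pair reproduces byte-identical output.
Formats are plain text throughout: R-R files (one ms value per line, `#`
comments), ECG as one- or two-column text, cohorts as CSV with a
documented column dictionary, configuration as YAML validated against the
dataclass schema (unknown keys are errors naming the key).

## What the tests do and do not show

The test suite validates the machinery against closed forms, hand
calculations, brute-force oracles and parameter-recovery/coverage
simulations, and soft-checks the end-to-end behaviour on cohorts
generated under the published model (problem sizes: 10 replicates of
n = 5000 for recovery, 200 replicates of n = 138 for interval coverage,
n = 2000 for the smoother and evaluation checks — large enough for stable
estimates while keeping the default suite under half a minute). Because
the generator draws most covariates independently of outcome and of each
other, passing tests demonstrate correctness of the *methods*, not
clinical validity on real patients: real cohorts have correlated
symptoms, informative censoring, measurement artifacts in the ECG, and an
unknown joint predictor distribution. Quantities that depend on the
original patient-level data (the multivariable odds ratios themselves,
the study's AUC, its calibration p-value, the exact cutpoint) are
therefore checked only for consistency, not equality.
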