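# Methods

## Signal model and preprocessing

A recording is a uniform 500 Hz series of (time, gaze x, gaze y, pupil
diameter) with a shared per-sample validity mask. Cleaning applies four
rules in a fixed order; each marks samples invalid, never deletes them, so
the time base and the gaze channels stay aligned.

1. **Amplitude** — diameter < 0.1 mm is flagged (strict `<`; a value exactly
   at the threshold is kept). Non-finite samples are invalid by definition.
2. **Velocity** — between consecutive *currently retained* samples, speeds
   |Δp|/Δt strictly above 10 mm/s flag both endpoints. Δt is the actual gap
   between retained neighbours, not the nominal 2 ms, so gaps opened by rule
   1 do not inflate speeds. A 10⁻⁹ relative guard keeps values sitting
   exactly on the threshold regardless of binary representation. The rule is
   a single identification pass; re-applying it can flag further samples
   (blink flanks are in practice removed completely because every
   consecutive pair along a flank is super-threshold).
3. **Fragments** — maximal valid runs spanning ≤ 10 ms (inclusive), bounded
   by invalid samples or the trace edge, are flagged.
4. **Downsampling** — retained samples are averaged in non-overlapping
   100 ms windows anchored at the recording's first timestamp; a window with
   no retained sample is NaN. The output records how many source samples
   entered each window, which makes the block average exactly
   mass-conserving (the count-weighted mean of windows equals the mean of
   retained samples).

Rules 1 and 3 are idempotent; all rules only ever shrink the valid set. On
an artifact-free recording the pipeline is exactly plain block averaging.

## Epoching and response extraction

Epochs span −1000…+2000 ms around stimulus onset on the 100 ms grid (window
starts relative to the window containing the onset). Baseline is each
trial's mean over the ten windows from −800 to +200 ms — the second
preceding the pupillary response, whose latency is ~200 ms; trials keep
their own baseline so slow drift (hippus) cancels. Trials are excluded when
no window survives inside the 0–1000 ms presentation window, or when the
baseline is entirely missing (a baseline-less peak is undefined; this
extends the presentation-window rule and is counted in the reported
exclusion fraction). The response measure is the signed extremum of the
per-category *average* trace (not per-trial extrema averaged) in
+200…+2000 ms: most negative change for constriction categories, most
positive for the dark response. The search-window end is a free parameter;
2 s covers the full constriction-and-recovery at the ~4 s stimulus spacing.
Normalized responses divide each peak by |light-response peak|, making
amplitudes unitless and invariant to overall pupil reactivity. Resting
diameter is the mean of per-trial baseline means.

Two estimator properties worth knowing:

- **Binning attenuation.** Averaging in 100 ms windows shrinks a kernel
  extremum by 0–3.3% depending on where onset falls within a window (1.7%
  on average for the default kernel); `simulate.binned_peak_factor` computes
  the phase-averaged factor. Noise-free recovery tests compare against this
  measurement-resolution truth.
- **Peak-picking bias.** Taking an extremum of a noisy average inflates
  response magnitudes slightly, and more for flatter (smaller) responses.
  At the default noise level this contributes ≈ +0.002 mm to the
  sun-minus-scrambled difference — detectable when averaging hundreds of
  replicates, but an order of magnitude below the between-subject standard
  error of a single 41-subject cohort. It is intrinsic to the extremum
  statistic, not to this implementation.

## Gaze dispersion

Valid gaze samples inside stimulus windows are pooled across trials
(irrespective of category) and summarized by the bivariate confidence
ellipse area, `π · q · √det(S)`, with S the unbiased sample covariance and
q the χ² quantile with 2 df. The level defaults to the conventional 95%
(q = 5.9915) and is recorded in the output; the large-sample χ² form is
used instead of the small-sample F-based ellipse because subjects
contribute thousands of pooled samples, where the two differ negligibly.

## Inference layer

All frequentist statistics are computed from explicit sums of squares /
moment formulas and verified against independent references to 6 decimals.
Choices that matter:

- **t-tests** are pooled-variance Student by default (the published df of
  39 for groups of 18 and 23 implies pooling); Welch is available behind a
  flag. Effect sizes: Cohen's d (pooled SD) and dz.
- **Mixed ANOVA** uses the classical split-plot decomposition with weighted
  (Type II) sums of squares when groups are unbalanced — identical to
  pingouin; JASP-style Type III differs slightly in the presence of an
  interaction. Between effects are tested against subjects-within-groups,
  within and interaction effects against condition × subjects-within-groups.
- **Chi-square** is the Pearson statistic without continuity correction
  (the corrected statistic does not reproduce the published gender
  comparison).
- **Bayes factors**: t-tests use the JZS default — Cauchy(0, √2/2) prior on
  the standardized effect — integrating the noncentral-t likelihood against
  the prior by adaptive quadrature split at the likelihood mode (stable to
  |t| of several hundred). Correlations integrate the exact sampling
  density of r against a uniform prior on ρ (the stretched-beta default of
  width 1). ANOVA terms get a unit-information BIC approximation, labeled
  as such in every result; the model-averaged g-prior machinery of
  point-and-click Bayesian ANOVA tools is intentionally not replicated, so
  ANOVA lgBF values are indicative rather than exact.
- **Power**: exact two-tailed noncentral-t power with noncentrality
  d·√(n₁n₂/(n₁+n₂)); the sensitivity analysis inverts it by Brent root
  finding (e.g. smallest detectable d = 0.90 at n = 18 vs 23, power 0.80,
  α = 0.05).
- **Evidence labels** follow |lgBF| > 0.5 / 1 / 2 for substantial / strong
  / decisive, sign-aware; the boundary value itself counts as evidence
  (inclusive), so lgBF = −0.5 reads "substantial for H0".
- No multiple-comparison correction is applied anywhere; reports say so.
- AQ-50 scoring: 1 point per item answered in the autistic-keyed direction
  (slightly and strongly score identically); the standard 24-agree /
  26-disagree key ships as a data resource. Incomplete questionnaires raise
  rather than producing a biased total.

## Synthetic data

The generator is the ground-truth authority for every pipeline test. A
recording is

baseline + Σ event kernels + hippus + band-limited noise,

with gaze as Gaussian scatter. Parameters (units, defaults, rationale):

- **Kernel**: Erlang/gamma-shaped impulse response,
  `(s/p)^k · exp(k(1−s/p))` for s = t − latency, latency 200 ms, time to
  peak p = 700 ms, shape k = 10 — the standard smooth unimodal pupil
  response with exact analytic peak normalization, so the configured signed
  amplitude *is* the kernel extremum. The single-gamma form was chosen over
  a difference of gammas because it normalizes exactly and recovery to
  baseline within ~2 s matches the event-related dynamics being emulated.
- **Design**: 1 s stimuli, onsets every 4 s on average (uniform 3–5 s
  jitter, quantized to the sample grid), 13 trials per category by default.
- **Amplitudes** (mm, signed): sun −0.35, moon −0.30, scrambled −0.20,
  bright −0.70, dark +0.25 for a generic subject; two-group cohorts draw
  subject amplitudes from group distributions in which the autistic group
  has an enhanced light response (−0.85 vs −0.70, SD 0.20), a matched
  sun-vs-scrambled difference (0.15 mm in both groups, SD 0.10), an
  equivalent dark response, a larger resting diameter (4.1 vs 3.8 mm) and a
  higher trial-loss rate (15.5% vs 5.3%). Trial-to-trial amplitude scatter
  (SD 0.03 mm) is an assumption, not an estimate — within-subject
  variability is rarely reported.
- **Noise**: Gaussian, SD 0.02 mm, low-pass filtered over 25 ms and
  rescaled. White noise at the 2 ms spacing would imply sample-to-sample
  speeds of ~14 mm/s — beyond the physiological range and rejected
  wholesale by the velocity rule — whereas real tracker noise is
  band-limited.
- **Hippus**: a 0.2 Hz sinusoid, amplitude 0.05 mm, random phase — slow
  drift that stresses per-trial baseline referencing.
- **Gaze**: isotropic Gaussian, group-mean scatter 0.9 deg (autistic) vs
  0.7 deg (comparison) chosen so that mean ellipse areas fall in the
  reported ~14 vs ~9 deg² range; per-subject scatter is lognormal around
  the group mean (log-SD 0.5, variance-preserving offset) because measured
  dispersion varies strongly and skewed across subjects — without it,
  between-subject variance of the ellipse area would be degenerate.
- **Artifacts**: blinks collapse the trace to 0 linearly over 20 ms
  (≈200 mm/s flanks — both the amplitude and velocity rules fire), plateau
  for 80–200 ms, and recover; a configurable fraction hide a ≤8 ms island
  of plausible samples that only the fragment rule catches. Whole-trial
  dropouts wipe onset−200…onset+1200 ms, losing every presentation-window
  sample while leaving enough baseline to attribute the exclusion to the
  presentation-window rule. Every corrupted sample is recorded, so tests
  can assert 100% rejection recall and exact exclusion accounting. Blink
  rate defaults to 10/min.

What the generator does *not* emulate: saccade-induced pupil artifacts and
foreshortening (gaze and pupil are independent), luminance dependence of
noise, drift in tracker calibration, binocular disparities, and any
systematic latency or shape difference between groups or categories
(responses differ in amplitude only). Passing tests therefore demonstrate
correctness of the measurement pipeline and calibration of the statistics
under this generative model — not robustness to every artifact structure of
real recordings.

## Scaled replication and problem sizes

The end-to-end replication suite simulates 200 cohorts of 18 + 23 subjects
with 4 trials per category (full recordings at 500 Hz, the complete
pipeline per subject), checks that the within-subject sun-vs-scrambled
effect is detected in ≥95% of cohorts, that the light/dark group
interaction is detected at the rate the injected effect size predicts via
the noncentral-t power function, and that the mean recovered effect matches
the injected effect at measurement resolution to well within a single
cohort's standard error. Null calibration of the ANOVAs uses 2000
replicates (type-I error within [0.04, 0.06] at α = 0.05). Unit tests use
smaller designs; the analysis drivers run one 13-trial cohort at full
scale.

## Known limitations

- The velocity rule's single-pass semantics can leave a theoretical
  residue after extreme, non-blink-shaped transients; a fixpoint variant
  would remove more but is not what the procedure describes.
- ANOVA Bayes factors are BIC approximations (see above).
- Epoch windows assume ≥1 s lead-in and ≥2 s tail around each event;
  events closer to the recording edge are dropped with a warning rather
  than zero-padded.
- The AQ scorer expects the full 50-item adult/adolescent key; other AQ
  variants need a caller-supplied key.
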