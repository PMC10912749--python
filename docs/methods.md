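# Methods

## The analysis in brief

The pipeline treats remote PD motor assessment as four stages: raw
session streams → per-task features → repeated-holdout classification
under three clinical labelling schemes → Shapley-based feature/task
importance with a single-task ablation.  Raw patient recordings are not
distributable, so the package ships a synthetic-cohort generator whose
streams carry the same statistical structure the analysis assumes; every
downstream stage runs identically on real session files matching the
documented JSON schema.

## Synthetic cohort model

One latent severity `s ∈ [0, 1]` per subject drives all effects.  Every
derived generative parameter is monotone in `s`; per-task noise is
independent given `s`, so features correlate through severity without
being copies of one another.

Label model: the motor score is `round(clip(68·s + ε, 0, 68))` with
`ε ~ N(0, 4)`, anchored to the 0–68 score range observed in PD clinic
cohorts; the Hoehn & Yahr stage is a fixed monotone binning of `s` with
cut points (0.25, 0.7, 0.85, 0.95), skewed toward stage 2 as clinic
stage distributions are; controls are stage 0 by convention.  Severity
is drawn from Beta(2.0, 2.3) for patients and Beta(1.3, 9.0) for
controls, which puts the group score means near 32 and 9 and leaves the
two distributions overlapping in the mild range — controls with elevated
scores are a deliberate property, not an artifact.

Stream effects (defaults in `GeneratorConfig`, units noted there):

- **Tapping (tasks 1, 2, 5)** — renewal process with interval mean
  μ(s) = 0.35·(1 + 0.8·s) s, gamma-distributed with CV 0.2, inflated
  within-session by a fatigue drift of up to 35% at s = 1; tap positions
  jitter around target centres with σ(s) = 8·(1 + 2.5·s) pts (misses
  emerge when jitter exceeds the 45 pt radius); alternation errors
  (same-side double taps) occur with probability 0.25·s.
- **Tremor (tasks 3, 4)** — baseline sensor noise plus, for patients
  only, a sinusoid at a subject-specific frequency drawn uniformly from
  the classical 4–6 Hz PD tremor band with amplitude 1.2·s m/s².
  Controls produce noise only, whatever their latent `s`; this is the
  group-specific signature that separates mild patients from controls
  with similar scores.
- **Tracing/drawing (tasks 6–8)** — the reference shape plus jitter,
  with the drawn radius shrinking linearly by up to 50% per session at
  s = 1 (micrographia) and angular/tracing velocity decaying at the same
  scale.  The spiral is traced at constant arc speed, so its velocity
  slope is zero at s = 0 while its centroid-distance slope is inherently
  positive (the spiral grows outward); severity shrinks it.
- **Coordination (task 9)** — the left index finger traces its trail
  cleanly; the right-hand trace lags by 0.4·s seconds with independent
  jitter.
- **Gait/foot tapping (tasks 10, 11)** — impulse trains; gait velocity
  v(s) = 1.0·(1 − 0.5·s) m/s over the fixed 6 m course (3 m out + 3 m
  back), with the first and last step peaks bracketing the walk so the
  peak span recovers the walking time; heel-tap cadence slows like the
  tapping interval.

All randomness flows from one root seed through `SeedSequence` spawning
(one child stream per subject), so a config byte-determines the cohort.

What the generator does **not** emulate: device-specific noise spectra,
tremor harmonics and asymmetry, freezing/festination episodes, turning
dynamics in gait, learning effects across sessions, and any
non-monotone relation between symptoms and severity.  Passing tests
therefore demonstrate correctness of the pipeline's computations and
recoverability of planted monotone effects — not clinical performance on
real recordings.  In particular, the synthetic cohort is more separable
than a real clinic cohort, so classification accuracies on it sit well
above those achievable on real data; the qualitative ordering (binary
diagnosis easier than multi-class severity) is the meaningful output.

## Extraction choices

- All slope features are ordinary least squares of a response against
  time.  Tapping frequency uses 1 s non-overlapping windows from session
  start (short sessions still yield ≥ 5 points); centroid-distance
  series are resampled at 3 Hz; angular velocity uses 0.3 s intervals of
  the unwrapped polar angle about the drawn centroid, sign-normalized to
  the dominant drawing direction so clockwise and counter-clockwise
  drawings compare.
- Paired-tap policy: invalid taps are skipped (they neither pair nor
  reset the alternation); a same-side valid tap replaces the pending
  tap; a pair completes whenever the next valid tap is on the opposite
  circle.  This is the most permissive rule consistent with "outside the
  circle or out of order does not count", and equals the
  maximal-alternating-run brute force on all short sequences.
- Tap bias sums distances over *all* taps (valid and missed) to the
  nearest circle centroid; trail bias is the per-sample *mean* distance
  to the nearest reference point, making it invariant to stream sampling
  rate (a documented divergence from the summed tap bias).
- Interval variance uses the population convention (divide by n).
- Tremor spectra: the power spectrum is the sum of per-axis boxcar
  periodograms of mean-removed acceleration, and the tremor frequency is
  the power-weighted mean over 1–12 Hz.  A magnitude-based spectrum was
  rejected because rectification (|sin|, or the gravity cross-term)
  doubles the apparent frequency of a single-axis oscillation; the
  per-axis sum reports a pure 5 Hz tremor as 5 Hz.  Zero in-band power
  flags the frequency absent; sampling below Nyquist for the band is an
  error.
- Peak counting (foot taps, steps) uses prominence-filtered local maxima
  with a floor of max(2 × MAD of the magnitude, 30% of the tallest
  excursion) — the MAD alone under-thresholds when impulses are sparse
  and tall — and minimum separations of 0.25 s (foot) / 0.4 s (gait).
- Rotation features are the SD of each Euler angle; task-5 duration is
  last tap time minus first.  Target circles count their boundary as
  inside.
- Undefined features (absent session, too few samples, degenerate
  geometry) are NaN at extraction and imputed with the column median
  when the cohort table is assembled, with per-subject imputation counts
  retained in the label block.

## Classification protocol

Repeated 9:1 holdout (100 repeats by default), stratified when every
class has ≥ 2 members and the test set can hold all classes, otherwise
plain random splitting.  Hyperparameters are tuned by grid search with
inner cross-validation on the training split only — tuning never touches
the held-out 10%.  Linear families (single-layer linear network trained
with cross-entropy via SGD, SVM, logistic regression) see z-scored
features fit on the training split; tree ensembles consume raw features.
Grids are deliberately small and published in `build_models`.  Metrics
follow the accuracy and weighted-average definitions in the README, with
0 substituted for undefined per-class ratios.  Split sequences depend
only on the seed and the label vector, so ablation arms with different
feature sets share identical splits.

## Shapley estimation

Feature absence is realized by substituting the cohort-median background
vector.  For M ≤ 12 features, attributions are exact subset-enumeration
Shapley values; above that, antithetic permutation sampling (each sampled
permutation paired with its reverse, 32 permutations by default).  Both
estimators satisfy local accuracy exactly — per permutation the marginal
contributions telescope from the background output to the sample's
output — which the tests assert to 1e-10.  Explanations are computed on
the full cohort for the best model family (by mean holdout accuracy)
refit on all data; multi-class rankings order features by the per-class
sum of mean absolute values, ties broken lexicographically by feature
name.  Task importance keeps only the global top-10 features (k
configurable) so a task with many weak features cannot outrank a task
with a few strong ones.

## Problem sizes

The default cohort mirrors a single-centre study (50 PD / 29 HC).  The
benchmark suite uses a 200-subject cohort at 20 holdout repeats for the
separability check, a 120-subject cohort for the single-task severity
scenario, and 25 repeats across all five model families in the
acceptance script — sizes chosen to make Monte-Carlo error small relative
to the asserted margins while keeping the full analysis runnable on one
CPU in minutes.

## Known limitations

Severity is a single scalar; real PD symptom profiles are
multidimensional (tremor-dominant vs akinetic-rigid phenotypes are not
distinguishable here).  The generator's effect sizes are plausible but
not calibrated to published kinematic distributions, because the study
conditions being emulated report none.  Hand dominance, medication state
and time-of-day effects are not modelled.  The Shapley background is a
single median vector; distributional backgrounds would change absolute
attribution values (not the rankings the tests rely on).
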