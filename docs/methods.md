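# Methods

This note documents the models behind each stage, the parameter defaults
and their units, the design choices made where several reasonable
options existed, and what validation on synthetic cohorts does and does
not establish about real recordings.

## Coordinate and unit conventions

Images use the (x rightward, y downward) convention; because phototaxis
makes the *vertical* axis biologically meaningful, every vertical
feature negates y so that "up" in the water column is positive. Frames
are 0-based. Speeds are mm/s (`px_per_mm` is required configuration;
default 10 px/mm), angular velocities rad/s, ages and lifespans days,
intensities 8-bit grayscale. Track duration is `(n_frames − 1)/fps`, so
at 25 fps a 251-frame track is exactly 10.0 s.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not the optics of a real rig.

**Kinematics.** Each animal follows a correlated random walk: per-frame
speed is gamma-distributed with mean `max(0, baseline_speed +
speed_age_slope·age)` and coefficient of variation `speed_cv` (default
0.3); heading diffuses with wrapped-Gaussian increments of SD
`heading_sd` (default 0.3 rad/frame). Defaults — 5 mm/s baseline
declining 0.05 mm/s per day, 1.5 mm body length growing 0.03 mm/day —
describe a healthy adult cohort in which speed falls and size rises
across the lifespan, the two signals an age clock must exploit. Walls
reflect the heading *before* the step is taken, so displacement
magnitude is preserved exactly; with `min_separation_px` set, starts are
rejection-sampled to full separation and a step is re-aimed (reversed,
then random, 8 tries) whenever it would bring two animals closer than
the floor, with "no worsening" accepted when already squeezed. This is
what "non-overlapping cohort" means here; it is a simulation device, not
a claim about real tanks.

**Stimuli.** Inside scheduled windows (defaults from the standard
protocol: weak light 20–30 s, strong light 40–50 s, vibration 70–80 s of
a 2-minute recording) speed is multiplied by `stimulus_response_gain`
(default 2.0). During light windows the heading additionally relaxes
toward "up" at rate `drift_strength` (default 0.25/frame) and toward
"down" for 10 s after light-off. The drift magnitude is a free
parameter: no quantitative literature value is asserted, so it is
exposed as configuration rather than hard-coded. Because the gain
rescales the step length while the drift only redirects it, the
post/pre speed ratio recovers the configured gain exactly in the
noise-free limit — the anchor the stimulus-feature tests use.

**Presentation.** Real animals present either their near-circular top
(transverse) or elongated side (sagittal) profile to the camera. The
generator draws the presentation per frame (Bernoulli, p = 0.5) and sets
the ellipse aspect to 0.95 (transverse) or 0.22 (sagittal). The two
values were chosen from ellipse geometry so that smooth-boundary
circularity lands clearly above 0.92 and below 0.58 respectively — the
published classifier thresholds — and are fixed in the defaults.

**Rendering.** Animals are bright (intensity 200) filled oriented
ellipses composited by max over a flat dark background (30) with static
debris discs (90); Gaussian noise with SD `noise_sd` (default 5) is
added per frame and the result clipped to uint8. Bright-on-dark is the
fixed polarity; recordings with the opposite polarity are handled by the
`invert` flag of the video reader. Not modelled: motion blur, molting
and egg-sac morphology, water-flow advection, illumination gradients,
partial occlusion in depth. Consequently, passing the tracking tests
shows the algorithmic chain is correct and well-calibrated — it does not
bound performance on real footage with genuine overlap, which the
original platform itself handles by accepting fragmented trajectories.

**Lifespans** are i.i.d. draws from exponential, Weibull or Gompertz
hazards (defaults: Gompertz a = 0.002/day, b = 0.08/day, median ≈ 42
days, a realistic laboratory-cohort scale), with optional administrative
and random right-censoring.

## Tracking

**Background.** Pixel-wise mean over frames 0, s, 2s, … (stride s = 25,
i.e. one frame per second at 25 fps). On short clips the sampled animal
positions leave faint ghosts in the mean; these are static by
construction and removed by the excursion floor below.

**Segmentation.** Components of |frame − background| above threshold.
The threshold is Otsu's method on the difference image by default (no
published value exists to adopt), with a fixed-value override and a
`min_contrast` floor (20) so that blank difference images yield no
detections. Components outside [`min_area_px`, `max_area_px`] are
dropped.

**Circularity.** Raw circularity is 4πA/P². Rasterized boundaries
systematically overestimate perimeter, so a drawn disc scores ≈ 0.89,
not 1. The *normalized* circularity divides the raw value by the raw
circularity of an ideal rasterized disc of equal area (cached by
quantized radius), restoring ≈ 1.0 for discs; the 0.92/0.58 plane
thresholds are applied to this normalized value. Both dialects are
available (`normalize_circ`).

**Linking.** Greedy mutual-nearest-neighbor per frame transition:
candidate pairs must pass the centroid-distance gate
(`max_link_dist_px` = 20) and the area-ratio gate (`max_size_ratio` = 5 —
wide enough to admit the ~4× apparent-area jump when the presentation
flips between frames); pairs are accepted in order of (distance, |area
difference|, detection index, track id). Unmatched detections open new
tracks; a track unmatched for more than `max_gap_frames` (2) terminates.
On separated cohorts this equals the globally optimal assignment (the
test suite checks it against exhaustive enumeration on ≤ 3 animals × ≤ 6
frames); in genuinely ambiguous crossings greedy may split or swap —
accepted, since the downstream statistics treat multiple fragments of
one animal as separate trajectories anyway.

**Filtering.** Tracks shorter than 10 s are discarded. A second floor,
`min_net_disp_px` on the *maximum excursion from the start position*,
rejects residual static blobs (background ghosts, debris edges); maximum
excursion rather than end-to-start displacement is used because a
diffusing animal frequently returns near its origin over a minute.

## Features

Position series are smoothed with a centered 3-point moving average;
the one edge sample per side whose window is truncated is dropped so
every reported step uses fully smoothed endpoints. Kinematic rates
divide by the actual frame interval, so gap-tolerant tracks remain
correct. Note one bias this implies: on strongly curved paths smoothing
shortens chords, deflating mean speed by O(heading_sd²) (~2% at the
default heading diffusion). Stimulus features therefore use *unsmoothed*
displacements — a step change in speed at a window boundary must not be
blurred across it — and each step is attributed to the time of its end
frame, matching the generator's update order exactly.

The 21 natural features are: mean/median/SD of speed; mean/SD of
|angular velocity|; mean |vertical velocity|; mean height above the
arena floor; fraction of time in the upper half; net-to-gross
displacement ratio; path length; transverse- and sagittal-plane areas
(means over frames the circularity classifier resolves; missing, never
zero, when a plane is absent); mean major and minor axes; aspect ratio;
and the six ethogram probabilities. Track duration is carried as
metadata, not as a feature. The 12 stimulus features are pre-window mean
speed (10 s before onset, matching the inter-stimulus spacing),
in-window mean speed, their ratio, and mean signed vertical velocity,
for each of the three stimuli.

**Ethogram.** A fixed-precedence cascade on body-length-normalized speed
(body length = per-track median major axis) and angular velocity:
Pause (≤ 0.2 BL/s), else Spin (≥ 2π rad/s), else Turn (≥ π/2 rad/s),
else FwdRun (≥ 2 BL/s), else FwdSlow (≤ 1 BL/s), else Fwd. The
thresholds are configuration with these defaults, calibrated on
synthetic cohorts; no published values exist. State probabilities are
frame fractions and always sum to 1.

## Survival

Census counts over a short clip take the median across frames; any
frame-to-frame disagreement raises an overlap flag that routes the
observation to the curation ledger (a CSV of day → curated count,
replacing the original GUI while keeping provenance). Counts convert to
records by the right-endpoint convention — each unit decrease emits a
death at the *later* census day, survivors are censored at study end —
so deaths + censored always equals the initial cohort.

Kaplan–Meier estimation and five parametric families use lifelines; the
Gompertz fitter (hazard a·e^{bt}) is a lifelines extension defined here,
and the censored gamma likelihood (shape/rate) is maximized directly
with SEs from a finite-difference Hessian, since lifelines ships
neither. The generalized gamma uses the (μ, σ, Q) form in which Q = 0 is
log-normal and Q = 1 is Weibull; because its likelihood surface is
multimodal, the fit is warm-started from the fitted Weibull and
log-normal mapped into GG space, which also guarantees the nesting
inequality (GG log-likelihood ≥ Weibull, gamma, log-normal) numerically.
The log-rank statistic is computed in closed form (hypergeometric
variance, 1 df) and cross-checked against lifelines in the tests; AIC =
2k − 2·loglik is the headline ranking criterion with BIC also reported,
ties broken by family name.

## Phenotypic clock

`PhenotypicClock` / `ClockResults` follow the model/results pattern:
construction binds data and configuration, `fit()` returns an immutable
results object with metrics, diagnostics and prediction methods.

Training: ages are binned at `age_bin_days` (5 d) for both the
age-group imputer and stratified 5-fold splitting (bins with fewer rows
than folds merge downward); within each training fold, group-mean
imputation and (optionally) SMOGN are fitted on the training rows only —
the suite asserts the fold imputers equal brute-force training-only
means, the leakage guard. Five regressor families are available with
small fixed hyperparameter grids selected by an inner 3-fold CV; the
final model refits on all rows. Held-out metrics pool out-of-fold
predictions; adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) with p = the
number of feature columns presented to the model (explicitly: not the
post-resampling row count).

**SMOGN.** Rarity is defined on a √n-bin histogram of the target:
relevance = 1 − count/max-count, rare above 0.8. Rare bins are topped up
to the median common-bin count by interpolating a rare row toward one of
its k = 5 nearest rare neighbors (SMOTER step, shared interpolation
factor for X and y) when that neighbor is nearer than the median of the
k distances, else jittering with Gaussian noise of 0.01 × feature SD.
Originals are never altered; everything is seeded.

**Importance.** Two dialects are reported separately because the
literature conflates them: *permutation* (shuffle one held-out column
per fold, no refit) and *refit* (rerun the CV without the feature).
Both measure the increase in held-out RMSE.

**Phenotypic age.** Delta = predicted − chronological, summarized per
condition with SEM; the aging rate is the origin-forced slope Σxy/Σx²
(x chronological, y predicted) with SE √(RSS/(n−1))/√Σx², labelled as a
standard error. The intervention direction tests construct "healthier"
and "toxic" cohorts by pairing the features generated at age a∓10 with
chronological label a; a transform toward younger phenotypes (faster,
smaller) lowers predicted age monotonically.

## Orchestration

`run_pipeline` executes simulate → track → features → survival (and
optionally clock) with atomic writes (temp file + rename, so a crashed
stage never clobbers a completed artifact), optional resume from
existing outputs, and a manifest of config hash, package version,
timestamps and SHA-256 checksums of every input/output. Deterministic
stages reproduce identical checksums under a fixed seed; the timestamps
live only in the manifest body, outside the checksum map used for
comparison. Tables are UTF-8 comma-separated CSV with header and '.'
decimal; `validate_tables` distinguishes I/O errors, schema mismatches
and invariant violations machine-readably.

## Problem sizes used in validation

The test and acceptance runs use sizes chosen to make each statistical
check decisive at desk scale: a rendered 20-animal × 60 s × 25 fps
cohort for tracking recovery; n = 10 000 draws for the KM median;
2000 null replicates for log-rank calibration; n = 5000 per family for
parameter self-recovery; six ages × 25 animals (150 trajectories) for
clock training; a 10-animal × 30 s video plus n = 2000 lifespans for the
end-to-end chain.

## Known limitations

- Identity is not maintained through genuine occlusion; one animal may
  yield several trajectories, by design.
- The synthetic renderer's simplifications (listed above) mean synthetic
  recovery rates are an upper bound on real-footage performance.
- The ethogram thresholds and linking gates are calibration defaults,
  not biologically derived constants; they are all configuration.
- Tree-based clocks shrink predictions toward the training mean at the
  age extremes, slightly flattening the aging-rate slope; the control
  calibration test bounds this effect rather than removing it.
- Interval-censored likelihoods and frailty models are out of scope; a
  death between censuses is assigned to the later census day.
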