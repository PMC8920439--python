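# waterflea

Desk-scale phenotyping of swimming *Daphnia*-like animals: multi-animal
video tracking, behavioral feature extraction, lifespan modelling, and a
**phenotypic-age clock** that scores interventions days before they show
up in survival curves.

## Who this is for

Labs running lifespan/healthspan assays on small aquatic animals record
backlit arena video of dozens of animals per tank, day after day. This
package turns such recordings (or their simulated equivalents) into
quantitative biology:

1. **Tracking** (`waterflea.tracking`) — a temporal-mean background
   (average of every 25th frame) removes stationary structure; connected
   components of the background-subtracted frame become blob detections
   (centroid, area, perimeter, ellipse axes, circularity 4πA/P²);
   greedy mutual-nearest-neighbor linking with distance and size gates
   builds trajectories; tracks shorter than 10 s are discarded.
2. **Features** (`waterflea.features`) — per trajectory, 21
   natural-swimming features (speed/angular-velocity statistics,
   vertical distribution, net-to-gross displacement, plane-specific body
   sizes split by circularity thresholds 0.92/0.58, and occupancy
   probabilities of a six-state ethogram: FwdRun, Fwd, FwdSlow, Turn,
   Spin, Pause) plus 12 stimulus-response features (pre/post mean speed,
   their ratio, and signed vertical velocity for weak light, strong
   light, and vibration windows).
3. **Survival** (`waterflea.survival`) — automated census counts with a
   human-in-the-loop curation ledger, Kaplan–Meier estimation, the
   two-group log-rank test, and censoring-aware maximum-likelihood fits
   of seven lifespan families (exponential, Weibull, gamma, generalized
   gamma, log-logistic, log-normal, Gompertz) ranked by AIC.
4. **Clock** (`waterflea.clock`) — `PhenotypicClock(features, ages).fit()`
   trains an age regressor (LASSO, elastic net, random forest, gradient
   boosting, or RBF-SVM) with per-(feature, age-group) mean imputation,
   optional SMOGN oversampling of rare-age rows, and age-stratified
   5-fold cross-validation; the fitted `ClockResults` reports adjusted
   R²/RMSE, feature importances, per-condition phenotypic-age deltas
   (predicted − chronological) and origin-forced aging-rate slopes
   Σxy/Σx².
5. **Synthetic cohorts** (`waterflea.synthdata`) — a seeded generator
   producing ground-truthed trajectories (correlated random walk with
   age-dependent speed decline and body growth, phototactic drift and
   speed gain during stimulus windows), rendered grayscale video, and
   parametric lifespans, so every stage above can be validated exactly.

## Worked example

```python
import waterflea as wf
from waterflea.tracking import track_video, TrackingParams

cfg = wf.CohortConfig(n_animals=20, duration_s=60, seed=5,
                      min_separation_px=40.0, noise_sd=5.0)
truth = wf.simulate_trajectories(cfg, age_days=20.0)
video = wf.render_video(truth)                   # (1500, 480, 640) uint8
tracks, bg = track_video(video, fps=25, stride=25,
                         trk_params=TrackingParams(min_net_disp_px=5.0))
print(len(tracks))                               # 20
```

All 20 animals are recovered as single tracks; against ground truth the
per-frame centroid RMSE is **0.12 px** with **100%** of true time-points
covered. Fitting lifespans simulated from a Gompertz hazard
(h(t) = a·e^{bt}, a = 0.002, b = 0.08):

```python
import numpy as np
rec = wf.simulate_survival(cfg, 2000)
res = wf.LifespanModel(rec).fit()
print(res.summary())
```

```
Lifespan model: n=2000, events=2000, KM median=41.95 d
family                  loglik         AIC      dAIC
gompertz              -8037.49    16078.98      0.00
generalized_gamma     -8064.86    16135.71     56.73
weibull               -8204.01    16412.03    333.05
...
```

The Kaplan–Meier median (41.95 d) matches the closed-form Gompertz
median ln(1 + (b/a)·ln 2)/b = 41.97 d, and the generating family wins
the AIC ranking. A gradient-boosting clock trained on a six-age
synthetic cohort reaches held-out adjusted R² ≈ 1.00 (RMSE 0.2 d), an
origin-forced control slope of 1.00, and scores cohorts constructed with
younger/older phenotypes at −10.1/+9.9 days of phenotypic age.

A `waterflea` console script wraps the same stages
(`simulate`, `track`, `features`, `survive`, `clock train/predict`,
`run`, `validate`); `waterflea run --config cfg.json` executes the whole
pipeline and writes a manifest with per-artifact SHA-256 checksums that
reproduce exactly under a fixed seed.

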