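# Methods

This note documents the model implemented by `throwcast`, the parameters it
exposes, what the synthetic generator does and does not emulate, and the
numerical choices behind the implementation. All problem sizes quoted here
(trials per cohort, resampling length, marker count, and so on) are this
package's own defaults, chosen to keep every analysis runnable on one CPU in
seconds to minutes; each is configurable.

## 1. Problem statement

A thrower performs repeated overarm throws at a target board 6 m away.
Each trial yields 3-D trajectories of 18 joint-markers and 5 ball-surface
markers at 120 Hz. The question: at which time in the action, and from which
part of the body, can a linear decoder predict the **lateral landing side**
(Right vs Left of a thrower-specific midline) of the ball?

The two-class side outcome (rather than elevation or target quadrant) is
used because lateral error is driven mainly by release direction, whereas
vertical error confounds release speed, angle, and height; the lateral task
gives the cleanest intrinsic baseline (section 6).

## 2. Data model

* **Markers** (fixed order): `l_foot, r_foot, l_ankle, r_ankle, l_knee,
  r_knee, l_hip, r_hip, l_shoulder, r_shoulder, l_elbow, r_elbow, l_wrist,
  r_wrist, l_hand, r_hand, cv7, head`.
* **Segments** (partition, 4+2+3+3+3+3): trunk = shoulders + hips; head =
  `cv7` + `head`; each arm = elbow/wrist/hand; each leg = knee/ankle/foot.
* **Frame**: x = thrower's right (+), y = toward the board (+), z = up (+).
* **Board**: plane y = 6 m; four targets at ±0.40 m lateral and 0.70 m
  vertical spacing around a center offset `center_x = −0.20 m` (configurable
  `BoardGeometry`).
* **Files**: long or wide CSV with a `#`-prefixed metadata header; units may
  be mm (converted to m on read). C3D input raises a clear error pointing at
  the optional `ezc3d` dependency when it is not installed.

## 3. Preprocessing

| Step | Parameter | Default | Why |
| --- | --- | --- | --- |
| Gap filling | max fillable run | 6 frames (50 ms) | cubic-spline interpolation is reliable only for short occlusions; longer runs mark the marker unfillable |
| Low-pass filter | Butterworth order / cut-off | 5 / 15 Hz | standard for human movement at 120 Hz: keeps throwing dynamics (< 10 Hz), removes marker jitter; applied forward-backward (`filtfilt`) for zero phase lag so event *times* are not biased |
| Differentiation | scheme | forward difference × 120 | velocities live on inter-sample midpoints; adequate after filtering |
| Ball center | sphere radius | 0.045 m | the center of a sphere of known radius is fit per frame to the visible surface markers by Gauss–Newton least squares; with 3 visible markers the two mirror solutions are disambiguated by continuity with the previous center |

Zero-lag filtering matters: a causal filter of the same order would delay
the hand-speed peak by several frames and bias every release time.

## 4. Key events and exclusions

* **Onset**: the hand-speed profile after the hand rises 5 cm above hip
  height is intersected with the tangent at 20% of its local maximum; the
  tangent's zero crossing (or the last sub-tangent sample) is the onset.
* **Release**: the first frame where the hand–ball distance exceeds its
  pre-throw baseline by 3 cm seeds a ±0.25 s window; release is the
  hand-speed maximum in that window (speed peaks when the hand stops
  accelerating the ball).
* **Impact**: each ball coordinate over 0.15–0.45 s post-release is fit by
  a quadratic in time (drag-free ballistics is exactly quadratic); the fit
  is extrapolated at most 0.300 s to the board plane. The landing point is
  the (x, z) of the crossing.
* **Exclusions** (per trial, with a recorded reason): unfillable joint
  tracking, hand lost around release, > 25% missing ball flight frames,
  a pre-throw step flag, no board-plane crossing, or implausible release
  speed (> 30 m/s).

## 5. Labels: the gray band

The participant's midline is the mean landing x over **all** good trials.
Trials landing within a band of width 0.225 m centered there are labeled
`Band` and excluded from classification; the rest are `Right` / `Left`.
The band removes trials whose side is within measurement error of the
midline, which would otherwise put a floor on every misclassification
error. Shrinking the band only converts `Band` labels; it never flips a
side.

## 6. Features, stPCA, LDA

Each good, labeled trial is resampled (linear interpolation) to
`N = 100` points on a window of length equal to the participant's mean
throw duration, aligned so the window *ends at release* — the decoder only
ever sees information available before the ball leaves the hand.

A **predictor space** is (spatial unit) × (temporal window):

* spatial: one of 18 markers, or one of 6 segments;
* temporal: time-decile d (samples 10(d−1)…10d) or time-through d
  (samples 0…10d).

Features stack positions and velocities of all included marker coordinates
at all included samples: `N_F = 3 coords × 2 kinds × N_markers × N_samples`
(e.g. trunk × through-decile-10 → 3·2·4·100 = 2400; one marker × one decile
→ 60).

Because `N_F` far exceeds the trial count, features are reduced by
**spatiotemporal PCA**: PCA on the trial-by-feature matrix, keeping the
leading components that account for 98% of variance. Components embed
temporal structure (a component is itself a mini spatiotemporal pattern).
Scores feed a two-class **linear discriminant analysis** with classical
pooled covariance (divisor n − 2), a tiny ridge (1e-8) for numerical
safety, and empirical class priors. Performance is estimated by
**leave-one-out cross-validation**. By default the stPCA basis is fit once
on all trials (an unsupervised step, so leakage is negligible); a stricter
`nested_pca` mode refits the basis inside every fold.

The **ball baseline** applies the same LOOCV LDA to six features the ball
itself provides at release: 3-D position and velocity. Since those six
numbers determine a drag-free flight completely, this is the intrinsic
ceiling of the task. The **misclassification index** normalizes body
performance by it:

```
MI = (ME_body − ME_ball) / (1 − ME_ball)
```

`MI = ME_body` when the ball baseline is perfect; `MI = 0` when the body is
exactly as informative as the ball. A cell is **predictable** when its
accuracy exceeds 80%, i.e. `MI < 0.20` when `ME_ball = 0`.

LOOCV is computed by exact rank-one downdates of the pooled scatter matrix
rather than n refits; the tests verify equality with the naive per-fold
refit and agreement with scikit-learn's LDA on balanced classes.

## 7. Synthetic generator

`simulate_participant` produces a cohort of trials with full ground truth
(onset/release/impact times, side, landing point, release state). Defaults:

| Parameter | Default | Meaning |
| --- | --- | --- |
| `n_trials` | 100 | one participant's session |
| `duration_range_s` | 0.8–1.8 | throw duration support |
| `release_speed_range` | 9–14 m/s | forward release speed (flight times ≈ 0.42–0.76 s) |
| `lateral_speed_range` | 0.5–1.2 m/s | magnitude of side-signed lateral release velocity |
| `informative_markers` | `l_ankle` from decile 6 (0.08 m), `r_wrist` from decile 9 (0.04 m) | class-dependent lateral ramps injected into body markers |
| `noise_sigma` / `noise_cutoff_hz` | 2 mm / 1 Hz | slow soft-tissue-like drift on body markers |
| `jitter_sigma` | 0.5 mm | white measurement jitter on all markers |
| `ball_noise_sigma` | 0.5 mm | jitter on ball markers (rigid-body fit residual scale) |
| `gap_rate` / `max_gap_run` | 0.002 / 6 | random occlusion runs |

Design points worth knowing:

* **Side is decoupled from the tracked arm.** The lateral component of the
  ball's release velocity is produced by a wrist/finger "snap" that the 18
  tracked markers do not record. Without injected informative markers, the
  body is therefore at chance by construction — a true null generator
  (`null_config()`), used to verify that the pipeline does not hallucinate
  predictability.
* **Informative markers** diverge laterally with the side label from a
  configurable onset decile, with a smooth ramp, so ground truth about
  *where and when* information exists is exact.
* Kinematics are minimum-jerk segments (lift, reach-back, forward
  projection) with the hand-speed peak at release.

What the generator does **not** emulate: air drag and ball spin-lift,
inter-joint coordination variability, fatigue or learning trends across
trials, marker-set soft-tissue artifacts beyond low-frequency drift, and
anthropometric diversity (one standard body). It is a test harness for the
analysis pipeline, not a biomechanical digital twin.

## 8. Numerical choices

* Sphere fits are batched Gauss–Newton over all frames simultaneously.
* `filtfilt` uses even-symmetric padding (3 × order) to suppress edge
  transients.
* PCA uses SVD on the mean-centered trial matrix; component signs are fixed
  (largest-magnitude loading positive) so results are reproducible across
  BLAS builds.
* All randomness flows from one root seed through `numpy.random.default_rng`;
  derived seeds are drawn below 2^31. Repeated runs are byte-identical.
* LDA ties on the decision boundary resolve deterministically to the
  second class in sorted label order.

## 9. Limitations

* Two classes only; the data model supports four targets, but multi-class
  decoding is not exercised.
* The quadratic flight model ignores drag — appropriate for a ~6 m, <1 s
  flight of a smooth ball, and consistent with the release-state baseline.
* LOOCV requires at least 3 trials per class; maps report cells with
  degenerate folds as unavailable (NaN) rather than guessing.
* The per-participant gray band makes labels participant-relative; results
  should not be pooled across participants without noting that midlines
  differ.
* Performance on real motion-capture data will depend on marker placement
  fidelity and occlusion patterns harsher than the generator's defaults.
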