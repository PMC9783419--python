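# Methods

This note documents the models, numerical choices and limitations behind
`rehabscore`. It is the package's own account; every number quoted here is
produced by the test suite or `scripts/acceptance.py`.

## Pipeline model

A subject performs a battery of assessment movements (default: 32 tasks,
20 upper-limb and 12 lower-limb) while wearing inertial sensors (joint
angle in degrees, angular velocity in deg/s, linear acceleration in m/s²,
sampled at 30 Hz) and, for finger tasks, a five-channel flex glove
(flexion fraction 0-1). Each movement attempt is scored against the
clinician's standard execution of the same task ("template"):

1. every channel is smoothed by a centered moving average;
2. effective movement cycles are extracted from the angular-speed
   magnitude;
3. per feature channel, the DTW distance to the template's reference
   channel is computed (squared Euclidean local distance, step set
   {(1,0),(0,1),(1,1)}, no global window);
4. distances are normalized by the feature's no-movement distance X_max
   and fused with entropy-method weights into a 0-100 score;
5. the 32 quality scores feed an RBF support vector regression (SVR)
   that predicts the physician's FMA totals;
6. agreement between predictions and physician labels is quantified by
   calibration regression, Bland-Altman limits of agreement and a
   Student's t comparison of assessment durations.

## Synthetic data generator

No patient recordings are distributed, so the generator defines the
conditions the pipeline is validated under.

**Templates.** The joint angle follows one raised-cosine cycle
θ(t) = A/2·(1 − cos 2πt/T): smooth, bell-shaped velocity, closed-form
derivatives — a reasonable idealization of a guided reach. Angular
velocity and acceleration channels are the exact analytic derivatives
(acceleration uses a lever arm of 0.2-0.4 m to convert angular to linear
acceleration); flex channels are raised cosines with per-finger
amplitudes in 0.5-0.9. Amplitude A is drawn per movement from 30-90°;
everything is deterministic given (movement_id, seed).

**Severity degradation.** A latent severity s ∈ [0, 1] (0 healthy, 1 no
voluntary movement) maps to signal changes via a `SeverityProfile`:

| parameter | default map | rationale |
| --- | --- | --- |
| amplitude attenuation | factor 1 − 0.8·s about the starting posture | severe paresis leaves ~20% excursion |
| time dilation | 1 + s (up to 2× slower) | impaired movement is slower |
| tremor | 2°·s at 5 Hz, consistent across channels | action-tremor band |
| sensor noise | Gaussian, SD 0.5° (scaled per channel's units) | realistic IMU noise after filtering |

Dilated recordings have their angular-velocity (÷dilation) and
acceleration (÷dilation²) channels rescaled so a slower execution also
moves more slowly. A severity-0 profile with zero noise reproduces the
template bit-exactly (tested). The map was chosen once so that DTW
distance is monotone in severity; it is not a biomechanical model — no
compensation strategies, spasticity patterns or multi-joint coupling.

**Physician rater model.** Each of the 50 FMA motor items scores
latent = (1 − s) + N(0, rater_sd), thresholded at 1/3 and 2/3 (equal
a-priori bands on the unit latent scale) into 0/1/2. Default rater_sd is
0.1: with zero rater noise all items cross their cutpoints at the same
severity and the total collapses to {0, 50, 100}; 0.1 restores the
item-level heterogeneity a real rater exhibits while keeping the total
monotone in severity. There are no per-item difficulty offsets — items
are exchangeable, which real FMA items are not.

**Durations.** System measurement time ~ N(12.82, 6.61²) min and
physician time ~ N(21.26, 7.79²) min, each left-clipped at 3 min to avoid
non-physical draws. The reported system time adds a fixed 1-minute
preparation overhead (donning devices, opening software), which
`time_comparison` applies by default — so the reported system mean is
13.82 min against the physician's 21.26 min.

**What passing tests show.** The generator produces monotone, learnable
severity signatures with homogeneous item behaviour; passing the
end-to-end agreement checks demonstrates the pipeline's internal
consistency under those conditions, not clinical validity on real
patients (whose compensation movements, sensor-placement errors and
heterogeneous item difficulty the generator deliberately omits).

## Preprocessing choices

* Moving-average window: 5 samples (~0.17 s at 30 Hz) — short enough to
  preserve movement morphology. At the boundaries the window shrinks to
  the available samples rather than zero-padding; zero-padding would
  attenuate edges and inflate DTW distances. The filter is linear
  (property-tested).
* Cycle extraction: active where the smoothed angular-speed magnitude
  strictly exceeds 0.1 × its global maximum; gaps < 0.3 s merged;
  segments < 0.5 s dropped. Indices are 0-based, segments half-open.
  A flat-zero recording yields no segments (nothing moved).

## DTW and scoring

* The accumulated-cost recursion is the plain three-step DP; the first
  row/column are running sums. Backtracking breaks ties diagonal >
  vertical > horizontal (shortest paths). Admissible path lengths are
  max(M, N) ≤ L ≤ M + N − 1, *including* the extreme staircase path,
  which the step rules admit.
* An exhaustive path-enumeration oracle (no memoization, M·N ≤ 64)
  verifies the DP exactly on random instances.
* X_max is computed per feature as the DTW distance between the
  reference channel and a constant sequence pinned at its initial value
  ("no movement at all"). Per-feature rather than per-movement X_max
  keeps each channel's normalization in its own units.
* Templates store the clinician recording *after* the same preprocessing
  applied to patient data (filter + effective-cycle extraction), so an
  attempt identical to the clinician's scores exactly 0 deviation.
* Normalized deviations are clipped to [0, 1]: wild tremor can exceed the
  no-movement distance, and clipping keeps the fused score in 0-100.
* Entropy weights: column shares p_ij = x_ij / Σ_i x_ij (uniform for an
  all-zero column), normalized entropy e_j = −(1/ln n) Σ p ln p with
  0·ln 0 := 0, weights δ_j ∝ 1 − e_j. A constant column (e_j = 1) gets
  zero weight; if *every* column is uninformative the weights fall back
  to uniform. Weights are calibrated per movement on the training
  cohort's normalized-deviation matrix (the sample the method needs; the
  choice of calibration sample is a design decision).
* Multiple extracted cycles (repeated attempts): the per-feature *median*
  DTW distance across cycles is used, then one score is formed — robust
  to a single aborted repetition and keeps the reported feature distances
  consistent with the reported score. No extracted cycle at all (no
  effective movement) falls back to comparing the whole recording.
* Score orientation: the literal fused deviation assigns 100 to "no
  movement at all"; since higher FMA means better function, the
  complement (quality) is what feeds the mapping model. Both are exposed.

## FMA mapping

* Three independent SVR models (total/upper/lower) mirror the three
  separately reported regressions; exact additivity
  total = upper + lower is therefore not enforced (observed mean gap on
  held-out synthetic subjects is < 5 points, tested).
* RBF kernel; features standardized; grid C ∈ {1, 10, 100},
  γ ∈ scale-heuristic × {0.1, 1, 10}, ε ∈ {0.5, 1, 2} FMA points; 5-fold
  CV with a seeded shuffled split keeps training deterministic. The grid
  is small by design — the feature-target link is smooth and monotone, so
  a desk-scale search suffices.
* Predictions are continuous (not rounded to FMA integers) and clamped to
  the target's range. Constant training labels produce a
  constant-predicting model with a warning.
* Models persist as versioned JSON (scaler, kernel parameters, support
  vectors, dual coefficients); prediction is evaluated in-package from
  the kernel expansion and cross-checked against scikit-learn's SVR to
  1e-9, so a saved model round-trips exactly and the file stays
  human-auditable.
* Train/test protocol: the package reports whatever split the caller
  provides; the shipped example and acceptance checks use a seeded
  80/40 held-out split, labelled as such.

## Agreement statistics

* Deviation sign is physician − system; relative deviation is
  100·deviation/physician with zero-physician records excluded and
  counted (substituting a value would silently bias the relative stats).
* Limits of agreement at mean ± 1.96·SD (sample SD, n − 1); within-limit
  counting is inclusive at the boundary. On 100,000 simulated Gaussian
  deviations the within-limit fraction is 95.0% ± 0.5% (tested).
* Slope CI from the t distribution with n − 2 df; two-sided p for
  slope ≠ 0.
* Timing uses Student's pooled two-sample t by default (Welch and paired
  variants are flags); the comparison was modelled as two independent
  groups. The +1 min preparation offset defaults on (see Durations).

## Problem sizes

Validation uses cohorts of 120 simulated subjects (the study scale for
this protocol), 30-seed severity sweeps, 200 random DTW oracle instances
(lengths ≤ 7) and 100,000-draw Monte-Carlo calibration of the limits of
agreement; the full suite runs in well under a minute on one CPU thanks
to the JIT-compiled DP kernel.

## Known limitations

* Synthetic kinematics are single-channel-family raised cosines; no
  multi-sensor fusion, no magnetometer/orientation estimation, no
  compensation-movement modelling.
* The rater model treats FMA items as exchangeable with a shared latent;
  real items differ in difficulty and discriminability.
* The effective-movement extractor is threshold-based; highly tremulous
  recordings can fragment into several cycles (mitigated by the median
  rule).
* Entropy weights depend on the calibration cohort; very small cohorts
  (< 2 subjects) keep uniform weights.
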