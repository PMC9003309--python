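# Methods

## The estimation problem

`imugait` estimates lower-body kinematics during treadmill-style walking from
seven body-worn IMUs (lumbar/sacrum, both thighs, shanks and feet) without
magnetometers. Each sensor provides 3-axis angular rate (rad/s) and specific
force (m/s², a stationary level sensor reads +9.81 on its up-axis) at a
common 200 Hz timebase. The method jointly estimates, per recording window:

* a keyframe-rate (default 20 Hz) trajectory of orientation, velocity and
  position per sensor, plus one constant gyro and accelerometer bias per
  sensor and window;
* the static calibration: the vector from each sensor origin to each adjacent
  joint center (12 vectors: lumbar→{right,left} hip, thigh→{hip,knee},
  shank→{knee,ankle}, foot→ankle, both sides) and the hinge-axis direction of
  each spanned joint (12 axes), all in sensor frames.

The joint estimate is the minimizer of a stacked whitened nonlinear
least-squares objective with four residual families:

1. **Inertial (preintegration).** The bias-corrected gyro/accel samples of
   each keyframe interval, integrated under gravity g = (0,0,−9.81) m/s²,
   must carry state k into state k+1. The 9-dimensional residual (rotation
   log-error, velocity, position) uses the standard on-manifold
   preintegration with first-order bias Jacobians. Whitening:
   σ_rot = σ_gyro·√(Δt·dt), σ_vel = σ_accel·√(Δt·dt), σ_pos = σ_vel·Δt,
   with Δt the keyframe interval and dt the sample interval.
2. **Joint center.** For each joint with flanking sensors A and B,
   r = (p_A + R_A s_A) − (p_B + R_B s_B) at every keyframe (σ_jc = 5 mm).
3. **Hinge.** r = R_A a_A − R_B a_B: both sensors must agree on the world
   direction of the hinge axis. The knee is a tight hinge
   (σ = 0.05 rad); the hip and ankle are *noisy* pseudo-hinges
   (σ = 0.3 rad) — loose enough to admit non-hinge motion, present because
   they are what pins the otherwise non-identifiable relative heading
   between the sensors flanking those joints during near-planar gait.
   Axis unknowns carry a unit-norm residual (σ = 1e−3) and their sign
   ambiguity is resolved at extraction: the knee axis sign is chosen so the
   knee hinge angle is predominantly positive (knees flex; they do not
   hyperextend), and hip/ankle axes are aligned with their side's knee axis.
4. **Priors.** Gaussian priors on the four hip-connected joint-center
   vectors (walking task only, from the calibration task, covariance
   inflated ×4 to hedge task-to-task soft-tissue differences); gauge priors
   pinning the lumbar first-keyframe position, heading **and velocity**
   (σ = 1e−4 each) — the velocity gauge is needed because a common constant
   world-velocity offset, i.e. a linear position ramp shared by all sensors,
   is an exact flat direction of the inertial + joint-center system that
   position and heading priors alone do not remove; weak zero-mean biases
   priors (σ = 0.02 rad/s, 0.2 m/s²); and a weak zero-mean prior
   (σ = 0.3 m) on the eight *non-hip* joint-center vectors. The last bounds
   the along-hinge-axis component of those vectors, which pure hinge motion
   cannot observe; derived joint angles are invariant to that component
   (the frame construction orthogonalizes it away), so the regularization
   only keeps the optimizer from wandering on a flat manifold. The four
   hip-connected vectors are deliberately left unregularized: their
   medial/lateral flat direction under 1-DOF gait is a property of the
   model that the package demonstrates, and it is handled by the
   calibration-task priors instead.

### Solver

Levenberg–Marquardt on the damped normal equations with analytic sparse
Jacobians (right-multiplicative SO(3) perturbations, re-linearized each
accepted step). Unknowns are ordered keyframe-major so the normal matrix is
banded with a dense bias/calibration border; natural-order sparse LU then
factorizes with minimal fill (about 40× faster than fill-reducing orderings
here). Convergence: absolute cost change ≤ 1e−6, relative change ≤ 1e−4, or
10,000 iterations, whichever fires first; the criterion that fired is
recorded. Damping: λ multiplied by 10 on rejection, divided by 3 on
acceptance, floor 1e−12; if no improving step exists at any damping the
point is declared stationary. The cost over accepted steps is nonincreasing
by construction.

Initialization: roll/pitch from the mean specific force over the first
0.5 s (heading zero by convention), orientation dead-reckoned from the gyro
at full rate and subsampled; positions, velocities and biases zero; hinge
axes at the first-keyframe world x-axis mapped into each sensor frame;
joint-center vectors zero, or at the prior mean where priors exist.

Calibration covariances are Gauss–Newton marginals ((JᵀJ)⁻¹ blocks at the
optimum, computed by sparse back-substitution).

### Task drivers

* **Calibration task** (`run_calibration` / `CalibrationModel`): solves the
  full problem on a hip-DOF-exciting recording with no hip priors. Only the
  knee and ankle hinge residuals are applied: a proper calibration motion
  explores the hip's three DOFs, which both makes the hip pseudo-hinge
  unnecessary for identifiability and would give it a large misalignment
  floor. An under-excitation detector (singular values of the centered
  lumbar-to-thigh relative rotation-vector cloud; warning below 0.05 rad)
  flags motions that leave the hip-center vectors non-identifiable.
* **Walking task** (`run_walking` / `WalkingModel`): the recording is cut
  into near-equal windows (default 60, ~30 s at the study rate), each solved
  independently with hip priors and all six hinges, followed by the drift
  heuristic; per-window angle series are concatenated downstream.

### Drift-correction heuristic

Without magnetometers the hip internal/external rotation angle can drift
linearly in time (relative-heading flat direction, local minima). Once a
window converges: derive both hips' I/E series; fit y = m·x + b + e by OLS;
if both |m| < m* (default 0.05 deg/s ≈ 1.5° over a 30 s window — well below
physiological I/E trends; the threshold is configurable) accept; otherwise
set the slope to zero (y′ = b + e), induce y′ by rotating the side's
thigh/shank/foot states about the world vertical through that hip's current
center (the unique transformation that alters I/E while preserving the
vertical datum and all knee angles), and re-solve. Passes repeat while the
re-converged cost changes by ≥ 1% (the compared quantity is the scalar
objective; the loop caps at 10 passes and returns the best-cost solution).

## Anatomical frames and angles

All segment frames are x-right, y-anterior, z-proximal. The frame
constructor f(x, z) keeps x fixed, orthogonalizes z, and completes y by
cross products. The pelvis frame uses x = normalized right-minus-left
hip-center vector (from calibration) and z = the average world-vertical
expressed in the lumbar sensor frame (whole-recording average by default) —
the method has no absolute pelvis reference, so hip angles carry a static
datum offset that the evaluation removes via mean alignment. Thigh/shank
frames take z from the difference of their two joint-center vectors and x
from the knee hinge axis.

Hip angles follow the ISB (Wu) convention and knee angles Grood–Suntay,
both with +z proximal in every segment; with e1 = proximal x and
e3 = distal z, the joint-coordinate-system decomposition is the intrinsic
x-y-z Cardan sequence. Left-side ab/adduction and internal/external
rotation are sign-mirrored so positive means flexion/adduction/internal for
both sides. The decomposition raises within 1e−6 deg of the |β| = 90°
gimbal; gait never approaches it.

## Evaluation

`relative_series` shifts an estimate by the constant mean difference so its
mean equals the reference's (exactly); relative RMSE and peak error are
computed on that aligned series, absolute RMSE on the raw one. Gait cycles
are delimited by knee maximum-flexion events of the reference
(`scipy.signal.find_peaks` gated by a 0.6 s minimum separation and 10°
prominence so the stance-phase bump is not counted); phase is linear 0–100%
between events. Soft-tissue profiling bins the signed error (estimate −
reference) by phase; stance/swing summaries use the generator's (or
user-supplied) event split, and the hysteresis area is the signed shoelace
area of the closed mean-estimate vs mean-reference curve (zero for any pure
offset). Soft-tissue summaries are computed on the mean-aligned estimate,
consistent with how estimates are compared to references throughout.

## The synthetic-data generator

The generator is the package's test bed and defines the study conditions.

* **Skeleton**: pelvis width 0.24 m, thigh 0.42 m, shank 0.43 m,
  left/right symmetric; hips are 3-DOF ball joints, knees and ankles pure
  hinges about the segment x-axis.
* **Walking** (default 200 Hz, cadence 100 steps/min): low-harmonic
  periodic profiles, antiphase left/right. Knee flexion is a 3-harmonic
  cosine series with a dominant ~63° swing peak at cycle phase 0 (≈ toe
  off) and a small stance bump; hip F/E amplitude 18° about a −8° mean;
  hip ab/ad 4° and I/E 3° (identically zero under the `degenerate_1dof`
  flag); ankle 8°. The pelvis oscillates a few cm / 1–2° at the cycle rate
  with zero-mean heading (bounded displacement, as on a treadmill). Swing
  occupies the first 40% of the cycle from toe off.
* **Calibration** (default 60 s): slow multi-frequency sinusoids sweeping
  every hip channel ≥ 30° peak-to-peak and the knee through ≥ 60°, under a
  2 s ramp-in so the trial starts at rest, with 1° non-hinge wobble at knee
  and ankle (a real functional calibration is never a perfect hinge; the
  wobble is also what makes the along-axis joint-center components
  observable) and large trunk sweeps (roll/pitch 20°, yaw 25°, a few cm of
  translation). The trunk motion is essential: with a static pelvis the
  lumbar-to-hip-center vectors are structurally non-identifiable — the
  whole leg chain can translate to compensate.
* **Sensor model**: mounts are fixed rotations (up to ~25°, optionally
  randomized ±10°) and lever arms per segment. Signals are synthesized
  *discretely consistently*: the gyro sample at k is the exact SO(3)
  increment Log(R_kᵀR_{k+1})/dt and the specific force is constructed so
  the discrete strapdown recursion reproduces the continuous truth poses
  exactly at the sample grid (the marginally-stable alternating mode of the
  velocity recursion is removed against a central-difference reference).
  Noise-free closed-loop oracles are therefore exact to round-off rather
  than O(dt²); at 200 Hz the difference from instantaneous-rate sampling is
  far below every tolerance used. Noise model: white gyro/accel noise
  (default RMS 0.01 rad/s and 0.1 m/s²) plus one constant bias per sensor
  (0.002 rad/s, 0.02 m/s², drawn once per trial), all seeded.
* **Soft tissue**: a C¹ gait-phase-locked rotation of the thigh (−1/2) and
  shank (+1/2) mounts about the flexion axis, so the knee-angle-equivalent
  perturbation equals the stated stance/swing levels (default +3°/−2°,
  smoothstep transitions of 5% cycle width; the offset passes through the
  level midpoint at the phase boundaries). Ground truth stays at the
  skin-free skeleton — the mismatch is the artifact under study.

What the generator does *not* emulate: joint translations, time-varying
mounts outside the soft-tissue model, scale-factor/axis-misalignment sensor
errors, gyro bias instability, foot-ground impact transients, or
subject-to-subject kinematic variability. Passing closed-loop tests
therefore demonstrates correctness of the estimator and its
identifiability properties under the stated model, not field accuracy on
human data.

## What anchors relative heading (and when it fails)

Closed-loop experiments with the generator show that the lumbar-thigh
relative heading is informed by three mechanisms of very different
strength: (1) the hip pseudo-hinge (axis misalignment grows directly with
heading error, but only insofar as the trunk rotates — with a perfectly
motionless pelvis the *estimated* lumbar-side axis can absorb any heading
rotation exactly, which is why this is a practical rather than structural
property); (2) the joint-center constraint coupled with hip-center
translation (pelvic sway moves the hip centers by centimeters, and a
heading-rotated leg misplaces them); and (3) the inertial coupling of those
translations. Under the generator's default walking conditions mechanisms
(2)-(3) already pin heading; in the degenerate limit (1-DOF hips,
motionless pelvis) every family except the hip hinge is exactly blind to a
leg-heading rotation, which the property tests demonstrate directly. Real
gait sits between these regimes, and residual heading freedom surfaces as
the slow hip internal/external-rotation drift that the correction heuristic
removes.

## Numerical choices and edge cases

* fs must be an integer multiple of the keyframe rate; trailing samples
  beyond the last keyframe interval are not used by the optimizer.
* Window planning tiles sample indices near-equally (lengths differ by ≤ 1;
  earlier windows take the extra sample).
* The frame constructor rejects axis pairs with |sin∠| ≤ 1e−6 or
  near-zero length (< 1e−8).
* OLS drift fits require ≥ 2 samples and a non-constant time vector.
* `correction_loop` recomputes the input's true cost from its states, so an
  externally modified "solution" cannot satisfy the accept-only-improving
  contract vacuously.
* Determinism: every stochastic component (noise, bias draws, mount
  randomization) flows from explicit integer seeds through
  `numpy.random.default_rng`.

## Problem sizes used in the shipped checks

The test suite solves the calibration recovery at the full study scale
(60 s at 200 Hz, 20 Hz keyframes ≈ 76,000 unknowns, both noise-free and
noisy), walking as two 30 s windows, the medial/lateral non-identifiability
demonstration on 10 s of degenerate gait with 10 random initializations,
and the soft-tissue demonstration on 30 s. `scripts/acceptance.py` uses
30 s calibration/walking trials, 15 s windows, an 18 s soft-tissue trial
and 4 initializations for the dispersion checks — moderate sizes chosen so
the whole script completes in a few minutes on one CPU while measuring the
same quantities.

## Known limitations

* Biases are constant per window with weak priors; long windows with real
  bias instability would need a random-walk bias model.
* The hip pseudo-hinge axis is a modeling device: during strongly non-hinge
  hip motion its residual floor can bias the solution slightly (it is
  excluded from the calibration task for exactly this reason).
* Relative (mean-aligned) angles are the accuracy-bearing output; absolute
  hip angles carry the pelvic-vertical datum offset by construction.
* Knee ab/adduction and internal/external rotation are computed but carry
  no accuracy contract (the reference model of interest treats the knee as
  1-DOF).
* The evaluation assumes estimate and reference share a timebase; no
  resampling is provided.
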