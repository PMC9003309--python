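# imugait

Magnetometer-free, self-calibrating lower-body kinematics from body-worn
IMUs.

Seven inertial sensors (lumbar/sacrum, both thighs, shanks and feet) are
enough to track hip and knee joint angles during walking — but only if two
problems are solved: nobody knows exactly how each sensor sits on its
segment, and without magnetometers there is no heading reference, so the
relative yaw between sensors is not directly observable. `imugait`
addresses both with a constrained joint-center-of-rotation model: per
recording window it jointly estimates every sensor's pose trajectory
together with the static *calibration* — the vectors s⃗ from each sensor to
its adjacent joint centers and each joint's hinge-axis direction, all in
sensor frames — by sparse nonlinear least squares (Levenberg–Marquardt)
over four residual families:

* **inertial**: preintegrated gyro/accel constraints between keyframe
  states under gravity;
* **joint center**: the sensors flanking a joint must place it at the same
  world point, (p_A + R_A s⃗_A) − (p_B + R_B s⃗_B) = 0;
* **hinge**: R_A a⃗_A = R_B a⃗_B — tight at the knee, deliberately *loose*
  ("noisy hinge") at the hip and ankle, where it exists to pin relative
  heading during near-planar gait;
* **priors**: hip-connected joint-center vectors from a separate
  calibration motion, plus gauge fixing.

Pure walking is nearly 1-DOF at the hip, which makes the medial/lateral
hip-center placement *practically non-identifiable* — hence the prior
model: a functional calibration motion that excites all three hip DOFs is
solved first, and its four hip-connected vectors (with Gauss–Newton
covariances) become priors for the walking windows. Residual heading drift
appears as a linear trend in hip internal/external rotation; a six-step
heuristic detects it (OLS slope per hip, threshold m* = 0.05 deg/s),
flattens it, rotates the leg's sensor chain about the vertical through the
hip center, and re-optimizes.

Hip angles are reported in the ISB (Wu) convention and knee angles in the
Grood–Suntay joint coordinate system (+z proximal in all segments; with
e1 = proximal x and e3 = distal z this is the intrinsic x-y-z Cardan
sequence), positive flexion/adduction/internal rotation bilaterally. The
package ships a full synthetic gait simulator (truth kinematics → forward
kinematics → inverse sensor model, with noise, mount randomization and
gait-phase-locked soft-tissue perturbations) and an evaluation module
(absolute/relative RMSE and peak error after constant mean alignment,
knee-max-flexion gait segmentation, phase-binned soft-tissue error
profiles).

Audience: biomechanists and movement scientists prototyping wearable
motion capture, and anyone needing a fully closed-loop test bed for
magnetometer-free kinematic estimators.

## Worked example

```python
import numpy as np
from imugait import (CalibrationModel, WalkingModel, generate_trial,
                     compare)
from imugait.angles import concatenated_angles, truth_angle_series

# synthesize a calibration motion and a walking trial (noise-free here)
cal_trial  = generate_trial("calibration", seed=1, duration=30.0)
walk_trial = generate_trial("walking", seed=1, duration=30.0)

# 1) self-calibrate: joint-center vectors + hinge axes, with uncertainties
cal = CalibrationModel(cal_trial.array).fit()
print(cal.summary())

# 2) walking estimation with the calibration priors + drift correction
res = WalkingModel(walk_trial.array, cal.priors(), n_windows=2).fit()

# 3) compare derived knee flexion/extension against the generator's truth
knee = concatenated_angles(res.windows, "knee")
half = walk_trial.array.n_samples // 2
idx = np.concatenate([s0 + np.arange(0, half, 10) for s0 in (0, half)])
truth = truth_angle_series(walk_trial, "knee", "r", idx)
c = compare(knee["r"].flexion, truth.flexion)
print(f"knee F/E absolute RMSE {c.absolute_rmse:.2f} deg, "
      f"relative RMSE {c.relative_rmse:.2f} deg")
```

Output (abridged):

```
Self-calibration results
========================
converged: relative after 23 iterations, cost 82.54

hip-connected joint-center vectors (sensor frame, m) [1-sigma, mm]:
    lumbar -> hip_r  [+0.115 +0.096 -0.062] +/-  6.2
    lumbar -> hip_l  [-0.124 +0.077 -0.070] +/-  6.3
   thigh_r -> hip_r  [-0.026 +0.047 +0.204] +/-  3.6
   thigh_l -> hip_l  [+0.033 -0.069 +0.207] +/-  3.8

hip excitation singular values (rad):
  hip_r: [0.341 0.246 0.237]
  hip_l: [0.333 0.241 0.24 ]
knee F/E absolute RMSE 0.16 deg, relative RMSE 0.01 deg
```

The calibration recovers the sensor-to-hip-center vectors to a few mm — the
generator's true `lumbar -> hip_r` here is [+0.115 +0.096 −0.061] m
(`cal_trial.truth_calibration`) — and the walking estimate tracks the true
knee flexion essentially exactly on noise-free data; with the default
sensor noise the errors grow to the degree scale. The excitation singular
values confirm all three hip DOFs were explored (each well above the
0.05 rad under-excitation warning threshold).

The same flow is available from the shell:

```sh
imugait simulate --kind calibration --seed 1 --out cal.h5
imugait simulate --kind walking --seed 1 --out walk.h5 --truth-prefix truth
imugait calibrate --data cal.h5 --out calibration.json
imugait estimate --data walk.h5 --calibration calibration.json --out sol.npz --n-windows 2
imugait angles --solution sol.npz --out-prefix angles
imugait evaluate --estimated angles_knee_r.csv --reference truth_knee_r.csv --out metrics.json
```

(`imugait pipeline --config cfg.yaml` wires all of it from one YAML file.)

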