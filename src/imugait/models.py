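"""Model / results API over the calibration and walking estimators.

`CalibrationModel` and `WalkingModel` are thin, statsmodels-flavoured
front-ends: a model is constructed from data (a :class:`~imugait.io.SensorArray`)
plus configuration, ``fit()`` runs the sparse nonlinear least-squares
estimation and returns a results object carrying the estimates, their
uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angles import JointAngleSeries, concatenated_angles, hip_angles, knee_angles
from .calibration import HIP_JC_KEYS, CalibrationParameters, Priors
from .errors import ArgumentError
from .estimator import (
    NoiseConfig,
    Solution,
    WalkingSolution,
    hip_excitation_singular_values,
    run_calibration,
    run_walking,
)
from .io import SensorArray


class CalibrationModel:
    """Self-calibration from a hip-DOF-exciting functional motion.

    Parameters
    ----------
    array : SensorArray
        Synchronized seven-sensor recording of the calibration motion.
    config : NoiseConfig, optional
        Residual weights.
    keyframe_rate : float
        State rate of the underlying trajectory estimate (Hz).
    """

    def __init__(self, array: SensorArray, config: NoiseConfig | None = None,
                 keyframe_rate: float = 20.0) -> None:
        self.array = array
        self.config = config or NoiseConfig()
        self.keyframe_rate = keyframe_rate

    def fit(self) -> "CalibrationResults":
        calib, sol = run_calibration(
            self.array, cfg=self.config, keyframe_rate=self.keyframe_rate,
            return_solution=True,
        )
        return CalibrationResults(model=self, params=calib, solution=sol)


@dataclass
class CalibrationResults:
    """Calibration estimates with Gauss-Newton uncertainties."""

    model: CalibrationModel
    params: CalibrationParameters
    solution: Solution

    def priors(self, inflation: float = 4.0) -> Priors:
        """Walking-task priors on the four hip-connected vectors."""
        return Priors.from_calibration(self.params, inflation=inflation)

    def hip_excitation(self) -> dict[str, np.ndarray]:
        return hip_excitation_singular_values(self.solution)

    def summary(self) -> str:
        lines = [
            "Self-calibration results",
            "========================",
            f"converged: {self.solution.convergence} after "
            f"{self.solution.iterations} iterations, cost {self.solution.cost:.4g}",
            "",
            "hip-connected joint-center vectors (sensor frame, m) [1-sigma, mm]:",
        ]
        for key in HIP_JC_KEYS:
            v = self.params.jc[key]
            cov = self.params.jc_cov.get(key)
            sd = "   n/a" if cov is None else \
                "+/- %4.1f" % (1000 * np.sqrt(np.trace(cov) / 3))
            lines.append(
                f"  {key[0]:>8s} -> {key[1]:<6s} [{v[0]:+.3f} {v[1]:+.3f} {v[2]:+.3f}] {sd}"
            )
        sv = self.hip_excitation()
        lines.append("")
        lines.append("hip excitation singular values (rad):")
        for side in ("r", "l"):
            lines.append("  hip_%s: %s" % (side, np.array2string(sv[side], precision=3)))
        for w in self.params.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)


class WalkingModel:
    """Windowed walking-task estimation with drift correction.

    Requires hip-vector priors (a :class:`Priors`, usually from
    ``CalibrationResults.priors()``): pure walking does not identify the
    medial/lateral hip-center placement on its own.
    """

    def __init__(
        self,
        array: SensorArray,
        priors: Priors,
        config: NoiseConfig | None = None,
        n_windows: int = 60,
        keyframe_rate: float = 20.0,
        m_star: float = 0.05,
        drift_correction: bool = True,
    ) -> None:
        if priors is None:
            raise ArgumentError("WalkingModel requires hip-vector priors")
        self.array = array
        self.priors = priors
        self.config = config or NoiseConfig()
        self.n_windows = n_windows
        self.keyframe_rate = keyframe_rate
        self.m_star = m_star
        self.drift_correction = drift_correction

    def fit(self) -> "WalkingResults":
        wsol = run_walking(
            self.array, self.priors, cfg=self.config, n_windows=self.n_windows,
            keyframe_rate=self.keyframe_rate, m_star=self.m_star,
            drift_correction=self.drift_correction,
        )
        return WalkingResults(model=self, windows=wsol)


@dataclass
class WalkingResults:
    """Concatenated per-window walking estimates."""

    model: WalkingModel
    windows: WalkingSolution
    _hip: dict = field(default=None, repr=False)
    _knee: dict = field(default=None, repr=False)

    def hip_angles(self) -> dict[str, JointAngleSeries]:
        if self._hip is None:
            self._hip = concatenated_angles(self.windows, "hip")
        return self._hip

    def knee_angles(self) -> dict[str, JointAngleSeries]:
        if self._knee is None:
            self._knee = concatenated_angles(self.windows, "knee")
        return self._knee

    def summary(self) -> str:
        ws = self.windows.windows
        lines = [
            "Walking-task estimation results",
            "===============================",
            f"windows: {len(ws)}  keyframe rate: {self.model.keyframe_rate} Hz  "
            f"m*: {self.model.m_star} deg/s",
        ]
        for i, w in enumerate(ws):
            lines.append(
                f"  window {i:2d}: cost {w.cost:10.4g}  {w.convergence:<14s} "
                f"iters {w.iterations}"
            )
        hip = self.hip_angles()
        knee = self.knee_angles()
        lines.append("")
        for side in ("r", "l"):
            lines.append(
                f"  side {side}: knee F/E ROM {np.ptp(knee[side].flexion):5.1f} deg, "
                f"hip F/E ROM {np.ptp(hip[side].flexion):5.1f} deg"
            )
        return "\n".join(lines)
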