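"""Comparison of IMU-derived joint angles against a reference.

Because the magnetometer-free method has no absolute pelvis datum, estimates
carry a static offset against any external reference.  The *relative* series
shifts the estimate by the constant mean difference,

    alpha_rel[k] = alpha[k] + mean(beta - alpha),

so that mean(alpha_rel) == mean(beta) exactly; relative RMSE and peak error
are then waveform errors with datum offsets removed, while absolute RMSE
keeps them.  Gait cycles are delimited by successive knee maximum-flexion
events of the reference (approximately toe off), and soft-tissue artifacts
are profiled as the mean signed error per gait-phase bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ArgumentError, SegmentationError


@dataclass
class ComparisonResult:
    """Error statistics of one angle channel against a reference (deg)."""

    joint: str
    side: str
    channel: str
    absolute_rmse: float
    relative_rmse: float
    peak_error: float
    mean_offset: float
    n_samples: int


@dataclass
class GaitCycleSet:
    """Cycles delimited by knee max-flexion events of the reference angle."""

    events: np.ndarray  # sample indices of knee maximum flexion
    cycles: list[tuple[int, int]]  # half-open index ranges
    phase: np.ndarray  # per-sample phase, 0-100 %, NaN outside cycles


@dataclass
class SoftTissueProfile:
    """Mean signed error (IMU - reference) by gait-phase bin."""

    bin_edges: np.ndarray  # %, length n_bins + 1
    bin_mean_error: np.ndarray  # deg, length n_bins
    stance_mean: float  # deg
    swing_mean: float  # deg
    hysteresis_area: float  # deg^2, signed loop area of mean IMU vs ref curve
    swing_phase_end: float  # %, phase where swing ends and stance begins


def relative_series(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Shift ``alpha`` by the constant mean difference so its mean matches
    ``beta``'s."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha.shape != beta.shape or alpha.size < 1:
        raise ArgumentError("series must be nonempty and of equal length")
    return alpha + np.mean(beta - alpha)


def compare(
    alpha: np.ndarray, beta: np.ndarray,
    joint: str = "", side: str = "", channel: str = "",
) -> ComparisonResult:
    """Absolute RMSE of alpha vs beta, plus relative RMSE and peak error of
    the mean-aligned series."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha.shape != beta.shape or alpha.size < 1:
        raise ArgumentError("series must be nonempty and of equal length")
    a_rel = relative_series(alpha, beta)
    return ComparisonResult(
        joint=joint, side=side, channel=channel,
        absolute_rmse=float(np.sqrt(np.mean((alpha - beta) ** 2))),
        relative_rmse=float(np.sqrt(np.mean((a_rel - beta) ** 2))),
        peak_error=float(np.max(np.abs(a_rel - beta))),
        mean_offset=float(np.mean(beta - alpha)),
        n_samples=alpha.size,
    )


def side_average(results: list[ComparisonResult]) -> dict[str, float]:
    """Mean of each statistic across results (e.g. the two sides)."""
    return {
        "absolute_rmse": float(np.mean([r.absolute_rmse for r in results])),
        "relative_rmse": float(np.mean([r.relative_rmse for r in results])),
        "peak_error": float(np.mean([r.peak_error for r in results])),
    }


def range_of_motion(series: np.ndarray) -> float:
    """Whole-series range max - min (deg)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ArgumentError("empty series")
    return float(np.max(series) - np.min(series))


def per_cycle_rom(series: np.ndarray, cycles: GaitCycleSet) -> np.ndarray:
    """One range-of-motion value per detected gait cycle (deg)."""
    return np.array([range_of_motion(series[s:e]) for s, e in cycles.cycles])


def detect_cycles(
    knee_reference: np.ndarray,
    fs: float,
    min_separation: float = 0.6,
    min_prominence: float = 10.0,
) -> GaitCycleSet:
    """Segment gait cycles at knee maximum-flexion events (~ toe off).

    ``min_separation`` (s) and ``min_prominence`` (deg) gate the peak picker
    so the smaller stance-phase flexion bump is not counted.  Phase is
    linearly interpolated 0-100 % between consecutive events.
    """
    y = np.asarray(knee_reference, dtype=float)
    if y.size < 3:
        raise SegmentationError("series too short to segment")
    peaks, _ = find_peaks(
        y, distance=max(1, int(round(min_separation * fs))), prominence=min_prominence
    )
    if peaks.size < 2:
        raise SegmentationError(
            f"found {peaks.size} knee max-flexion events; need at least 2"
        )
    phase = np.full(y.size, np.nan)
    cycles = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        cycles.append((int(a), int(b)))
        phase[a:b] = 100.0 * (np.arange(a, b) - a) / (b - a)
    return GaitCycleSet(events=peaks, cycles=cycles, phase=phase)


def soft_tissue_profile(
    imu_knee: np.ndarray,
    ref_knee: np.ndarray,
    cycles: GaitCycleSet,
    n_bins: int = 20,
    swing_phase_end: float = 40.0,
) -> SoftTissueProfile:
    """Per-phase-bin mean signed error (IMU - reference) across cycles.

    The cycle starts at knee max flexion (~ toe off), so phase
    [0, swing_phase_end) is swing and the rest stance; pass the generator's
    (or gait-event-derived) split when available.  The hysteresis area is the
    signed shoelace area of the closed mean-IMU vs mean-reference curve over
    the phase bins — zero for any pure offset, nonzero when the error
    pattern differs between the two halves of the cycle.
    """
    if n_bins < 4:
        raise ArgumentError("need at least 4 phase bins")
    imu = np.asarray(imu_knee, dtype=float)
    ref = np.asarray(ref_knee, dtype=float)
    if imu.shape != ref.shape or imu.shape != cycles.phase.shape:
        raise ArgumentError("series and cycle phase must have equal length")
    mask = ~np.isnan(cycles.phase)
    phase = cycles.phase[mask]
    err = (imu - ref)[mask]
    imu_m, ref_m = imu[mask], ref[mask]
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    bin_err = np.array([err[idx == i].mean() if np.any(idx == i) else np.nan
                        for i in range(n_bins)])
    bin_imu = np.array([imu_m[idx == i].mean() if np.any(idx == i) else np.nan
                        for i in range(n_bins)])
    bin_ref = np.array([ref_m[idx == i].mean() if np.any(idx == i) else np.nan
                        for i in range(n_bins)])
    swing = phase < swing_phase_end
    x, y = bin_ref, bin_imu
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return SoftTissueProfile(
        bin_edges=edges,
        bin_mean_error=bin_err,
        stance_mean=float(err[~swing].mean()),
        swing_mean=float(err[swing].mean()),
        hysteresis_area=area,
        swing_phase_end=swing_phase_end,
    )
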