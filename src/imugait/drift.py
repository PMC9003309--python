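"""Detection and correction of hip internal/external-rotation drift.

Magnetometer-free estimation has no absolute heading; during near-1-DOF
walking the relative heading between the lumbar and thigh sensors is only
weakly pinned (by the loose hip pseudo-hinge), so the optimizer can settle in
local minima where the derived hip internal/external rotation angle drifts
linearly in time — a gait no human walks.  The heuristic:

1. derive both hips' internal/external rotation angle series;
2. fit ``y = m x + b + e`` to each by ordinary least squares;
3. if both ``|m| < m*``, accept the solution and stop;
4. otherwise flatten the trend (``y' = b + e``, i.e. ``y - m x``);
5. rotate the side's thigh/shank/foot states about the world vertical
   through that hip's center so the flattened angles are induced; and
6. re-run the optimizer from this new state,

repeating while the re-converged cost differs from the previous converged
cost by at least 1%, with a hard cap of 10 passes (best-cost solution is
returned if the loop oscillates).  The returned solution never has a higher
cost than the input.

``m*`` defaults to 0.05 deg/s (about 1.5 deg across a 30 s window) — well
below any physiological internal/external rotation trend on that timescale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._so3 import rotz
from .errors import ArgumentError
from .estimator import Solution, solve_lm

logger = logging.getLogger("imugait")

M_STAR_DEFAULT = 0.05  # deg/s

_SIDE_OF = {"left": "l", "right": "r", "l": "l", "r": "r"}


@dataclass
class DriftFit:
    """Ordinary-least-squares linear trend of one hip's I/E angle series."""

    m: float  # deg/s
    b: float  # deg
    e: np.ndarray  # deg, residuals y - (m x + b)
    x: np.ndarray  # s, the time vector the fit used
    side: str
    m_star: float = M_STAR_DEFAULT

    @property
    def exceeds(self) -> bool:
        return abs(self.m) >= self.m_star


def fit_linear_drift(
    t: np.ndarray, y: np.ndarray, side: str = "r", m_star: float = M_STAR_DEFAULT
) -> DriftFit:
    """OLS fit y = m t + b + e of an internal/external rotation series (deg)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2 or t.size != y.size:
        raise ArgumentError("need at least two (t, y) samples of equal length")
    if np.ptp(t) == 0:
        raise ArgumentError("constant time vector")
    A = np.column_stack([t, np.ones_like(t)])
    (m, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    e = y - (m * t + b)
    return DriftFit(m=float(m), b=float(b), e=e, x=t, side=_SIDE_OF[side], m_star=m_star)


def flatten_drift(fit: DriftFit) -> np.ndarray:
    """Drift-free series y' = b + e (equivalently y - m x)."""
    return fit.b + fit.e


def rotate_distal_chain(sol: Solution, side: str, fit: DriftFit) -> Solution:
    """Rotate one side's thigh/shank/foot states about the world vertical
    through that hip's (time-varying) center so the linear I/E trend is
    removed; the lumbar and contralateral states are untouched.

    The applied heading angle at keyframe time t_k is ``-m t_k`` for the right
    side and ``+m t_k`` for the left (the left side's internal rotation is
    sign-mirrored), so the re-derived angles equal ``y - m x``.
    """
    side = _SIDE_OF[side]
    out = Solution(
        trajectories=dict(sol.trajectories),
        calibration=sol.calibration,
        cost=sol.cost,
        convergence=sol.convergence,
        iterations=sol.iterations,
        estimate=sol.estimate.copy() if sol.estimate is not None else None,
        problem=sol.problem,
    )
    if fit.m == 0.0:
        return out
    thigh = sol.trajectories[f"thigh_{side}"]
    s_hip = sol.calibration.jc[(f"thigh_{side}", f"hip_{side}")]
    hip_w = thigh.p + np.einsum("kij,j->ki", thigh.R, s_hip)  # (K, 3)
    sgn = -1.0 if side == "r" else 1.0
    phi = sgn * np.deg2rad(fit.m) * thigh.times  # rad per keyframe
    Rz = rotz(phi)  # (K, 3, 3)
    from .estimator import StateTrajectory, _SID_INDEX  # local to avoid cycle at import

    for sid in (f"thigh_{side}", f"shank_{side}", f"foot_{side}"):
        traj = sol.trajectories[sid]
        newR = Rz @ traj.R
        newp = hip_w + np.einsum("kij,kj->ki", Rz, traj.p - hip_w)
        newv = np.einsum("kij,kj->ki", Rz, traj.v)
        out.trajectories[sid] = StateTrajectory(
            sensor_id=sid, times=traj.times.copy(), R=newR, v=newv, p=newp,
            bg=traj.bg.copy(), ba=traj.ba.copy(),
        )
        if out.estimate is not None:
            s = _SID_INDEX[sid]
            out.estimate.R[s] = newR
            out.estimate.p[s] = newp
            out.estimate.v[s] = newv
    return out


def hip_ie_series(sol: Solution) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(t, internal/external angle) per side, derived from the solution."""
    from .angles import hip_angles

    series = hip_angles(sol)
    return {side: (series[side].t, series[side].internal) for side in ("r", "l")}


def correction_loop(
    problem,
    sol: Solution,
    m_star: float = M_STAR_DEFAULT,
    max_passes: int = 10,
) -> Solution:
    """Run the six-step drift-removal heuristic to convergence.

    ``sol`` must be a converged solution of ``problem``.  Passes repeat while
    the slope test fails and the re-converged cost changed by at least 1%
    relative to the previous converged cost; at most ``max_passes`` passes
    are made, after which the best-cost solution is returned with a warning.
    The result's cost never exceeds the input's.
    """
    current = sol
    if current.estimate is not None:
        # the caller may have modified the states since the solve (e.g. an
        # injected perturbation): trust the state, not the stored cost
        r = problem.residuals(current.estimate)
        actual = 0.5 * float(r @ r)
        if abs(actual - current.cost) > 1e-9:
            current.cost = actual
    best = current
    prev_converged = None
    for pass_no in range(1, max_passes + 1):
        ie = hip_ie_series(current)
        fits = {s: fit_linear_drift(*ie[s], side=s, m_star=m_star) for s in ("r", "l")}
        logger.info(
            "drift pass %d: slopes r=%.4f l=%.4f deg/s (m*=%.4f)",
            pass_no, fits["r"].m, fits["l"].m, m_star,
        )
        if not (fits["r"].exceeds or fits["l"].exceeds):
            return current if current.cost <= best.cost else best
        if prev_converged is not None:
            rel_change = abs(prev_converged - current.cost) / max(prev_converged, 1e-300)
            if rel_change < 0.01:
                break  # heuristic stopped changing the converged solution
        rotated = current
        for s in ("r", "l"):
            if fits[s].exceeds:
                rotated = rotate_distal_chain(rotated, s, fits[s])
        prev_converged = current.cost
        current = solve_lm(problem, init=rotated.estimate)
        if current.cost < best.cost:
            best = current
    else:
        logger.warning(
            "drift heuristic hit the %d-pass cap; returning best cost", max_passes
        )
    return best
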