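"""On-disk exchange of calibration, solutions and angle series.

Calibration is exchanged as JSON (vectors in m, unit axes, covariances
row-major); window solutions as .npz bundles; angle series as
``t,fe,aa,ie`` CSV in degrees.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .angles import JointAngleSeries
from .calibration import AXIS_KEYS, JC_KEYS, CalibrationParameters, Priors
from .errors import FormatError
from .estimator import Solution, StateTrajectory, WalkingSolution
from .io import PLACEMENTS


def _key(k: tuple[str, str]) -> str:
    return f"{k[0]}|{k[1]}"


def _unkey(s: str) -> tuple[str, str]:
    a, b = s.split("|")
    return (a, b)


def calibration_to_json(calib: CalibrationParameters, path) -> str:
    data = {
        "jc": {_key(k): calib.jc[k].tolist() for k in JC_KEYS},
        "axes": {_key(k): calib.axes[k].tolist() for k in AXIS_KEYS},
        "jc_cov": {_key(k): np.asarray(v).ravel().tolist()
                   for k, v in calib.jc_cov.items()},
        "warnings": list(calib.warnings),
    }
    with open(path, "w") as f:
        json.dump(data, f, indent=1)
    return str(path)


def calibration_from_json(path) -> CalibrationParameters:
    with open(path) as f:
        data = json.load(f)
    try:
        jc = {_unkey(k): np.asarray(v, float) for k, v in data["jc"].items()}
        axes = {_unkey(k): np.asarray(v, float) for k, v in data["axes"].items()}
        cov = {_unkey(k): np.asarray(v, float).reshape(3, 3)
               for k, v in data.get("jc_cov", {}).items()}
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: not a calibration JSON ({exc})") from exc
    return CalibrationParameters(jc=jc, axes=axes, jc_cov=cov,
                                 warnings=list(data.get("warnings", [])))


def priors_to_json(priors: Priors, path) -> str:
    data = {
        _key(k): {"mean": m.tolist(), "cov": c.ravel().tolist()}
        for k, (m, c) in priors.hip_jc.items()
    }
    with open(path, "w") as f:
        json.dump(data, f, indent=1)
    return str(path)


def priors_from_json(path) -> Priors:
    with open(path) as f:
        data = json.load(f)
    return Priors(
        hip_jc={
            _unkey(k): (np.asarray(v["mean"], float),
                        np.asarray(v["cov"], float).reshape(3, 3))
            for k, v in data.items()
        }
    )


def solution_to_npz(wsol: WalkingSolution, path) -> str:
    arrays: dict[str, np.ndarray] = {
        "window_start_times": np.asarray(wsol.window_start_times),
        "n_windows": np.asarray(len(wsol.windows)),
    }
    for i, sol in enumerate(wsol.windows):
        arrays[f"w{i}_cost"] = np.asarray(sol.cost)
        arrays[f"w{i}_iterations"] = np.asarray(sol.iterations)
        arrays[f"w{i}_convergence"] = np.asarray(sol.convergence)
        for sid in PLACEMENTS:
            tr = sol.trajectories[sid]
            for name in ("times", "R", "v", "p", "bg", "ba"):
                arrays[f"w{i}_{sid}_{name}"] = getattr(tr, name)
        arrays[f"w{i}_jc"] = np.stack([sol.calibration.jc[k] for k in JC_KEYS])
        arrays[f"w{i}_axes"] = np.stack([sol.calibration.axes[k] for k in AXIS_KEYS])
    np.savez_compressed(path, **arrays)
    return str(path)


def solution_from_npz(path) -> WalkingSolution:
    with np.load(path, allow_pickle=False) as z:
        n = int(z["n_windows"])
        windows = []
        for i in range(n):
            trajs = {}
            for sid in PLACEMENTS:
                trajs[sid] = StateTrajectory(
                    sensor_id=sid,
                    times=z[f"w{i}_{sid}_times"],
                    R=z[f"w{i}_{sid}_R"],
                    v=z[f"w{i}_{sid}_v"],
                    p=z[f"w{i}_{sid}_p"],
                    bg=z[f"w{i}_{sid}_bg"],
                    ba=z[f"w{i}_{sid}_ba"],
                )
            calib = CalibrationParameters(
                jc={k: z[f"w{i}_jc"][j] for j, k in enumerate(JC_KEYS)},
                axes={k: z[f"w{i}_axes"][j] for j, k in enumerate(AXIS_KEYS)},
            )
            windows.append(
                Solution(
                    trajectories=trajs, calibration=calib,
                    cost=float(z[f"w{i}_cost"]),
                    convergence=str(z[f"w{i}_convergence"]),
                    iterations=int(z[f"w{i}_iterations"]),
                )
            )
        starts = z["window_start_times"].tolist()
    return WalkingSolution(windows=windows, window_start_times=starts)


def angles_to_csv(series: JointAngleSeries, path) -> str:
    pd.DataFrame(
        {"t": series.t, "fe": series.flexion, "aa": series.abduction,
         "ie": series.internal}
    ).to_csv(path, index=False, float_format="%.10g")
    return str(path)


def angles_from_csv(path, joint: str = "", side: str = "") -> JointAngleSeries:
    df = pd.read_csv(path)
    missing = [c for c in ("t", "fe", "aa", "ie") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return JointAngleSeries(
        t=df["t"].to_numpy(float), flexion=df["fe"].to_numpy(float),
        abduction=df["aa"].to_numpy(float), internal=df["ie"].to_numpy(float),
        joint=joint, side=side,
    )
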