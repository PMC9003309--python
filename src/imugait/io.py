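"""Reading, writing, validation and windowing of multi-sensor IMU recordings.

The canonical exchange dialect is CSV: one file per sensor with a one-line
header ``t,gx,gy,gz,ax,ay,az`` where ``t`` is seconds from recording start,
``g*`` are gyroscope rates in rad/s and ``a*`` are specific forces in m/s^2
(a stationary, level sensor reads +9.81 m/s^2 on its up axis).  A single HDF5
container with layout ``/sensors/<sensor_id>/{t,gyro,accel}`` is supported for
long trials.

Seven placements make up a full lower-body array: ``lumbar``, ``thigh_r``,
``thigh_l``, ``shank_r``, ``shank_l``, ``foot_r``, ``foot_l``.  All seven are
recorded against a synchronized timebase, which :func:`assemble_array`
verifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import (
    ArgumentError,
    EmptyInputError,
    FormatError,
    SyncError,
    TopologyError,
)

PLACEMENTS = ("lumbar", "thigh_r", "thigh_l", "shank_r", "shank_l", "foot_r", "foot_l")

_CSV_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az"]
_DT_TOL = 1e-6  # s, max deviation of any sample interval from 1/fs


@dataclass
class ImuRecording:
    """One sensor's synchronized gyro/accel streams.

    Parameters
    ----------
    sensor_id : str
        One of :data:`PLACEMENTS`.
    t : ndarray, shape (N,)
        Seconds from recording start; strictly increasing and uniform.
    gyro : ndarray, shape (N, 3)
        Angular rate, rad/s, sensor frame.
    accel : ndarray, shape (N, 3)
        Specific force, m/s^2, sensor frame.
    fs : float
        Sample rate in Hz.  Inferred from the median sample interval when
        omitted.
    """

    sensor_id: str
    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    fs: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.ascontiguousarray(self.t, dtype=float)
        self.gyro = np.ascontiguousarray(self.gyro, dtype=float)
        self.accel = np.ascontiguousarray(self.accel, dtype=float)
        if self.sensor_id not in PLACEMENTS:
            raise TopologyError(
                f"unknown sensor placement {self.sensor_id!r}; expected one of {PLACEMENTS}"
            )
        n = self.t.shape[0]
        if n < 2:
            raise EmptyInputError(f"{self.sensor_id}: need at least 2 samples, got {n}")
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise FormatError(
                f"{self.sensor_id}: gyro/accel must be (N, 3) matching t (N={n})"
            )
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise SyncError(f"{self.sensor_id}: timestamps are not strictly increasing")
        if not self.fs:
            self.fs = 1.0 / float(np.median(dt))
        if np.max(np.abs(dt - 1.0 / self.fs)) >= _DT_TOL:
            raise SyncError(
                f"{self.sensor_id}: sample intervals deviate from 1/fs by more than {_DT_TOL} s"
            )
        if not (np.all(np.isfinite(self.gyro)) and np.all(np.isfinite(self.accel))):
            raise FormatError(f"{self.sensor_id}: non-finite gyro/accel samples")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class SensorArray:
    """The full seven-sensor lower-body array on a common timebase."""

    recordings: dict[str, ImuRecording]

    def __post_init__(self) -> None:
        missing = [p for p in PLACEMENTS if p not in self.recordings]
        extra = [p for p in self.recordings if p not in PLACEMENTS]
        if missing or extra:
            raise TopologyError(f"placements missing={missing} unexpected={extra}")
        t0 = self.recordings[PLACEMENTS[0]].t
        for pid, rec in self.recordings.items():
            if rec.t.shape != t0.shape or np.max(np.abs(rec.t - t0)) > _DT_TOL:
                raise SyncError(f"{pid}: timestamps differ from the array timebase")

    def __getitem__(self, sensor_id: str) -> ImuRecording:
        return self.recordings[sensor_id]

    @property
    def t(self) -> np.ndarray:
        return self.recordings[PLACEMENTS[0]].t

    @property
    def fs(self) -> float:
        return self.recordings[PLACEMENTS[0]].fs

    @property
    def n_samples(self) -> int:
        return self.recordings[PLACEMENTS[0]].n_samples

    @property
    def duration(self) -> float:
        return self.recordings[PLACEMENTS[0]].duration

    def slice(self, start: int, end: int) -> "SensorArray":
        """Sub-array over sample indices [start, end), timestamps re-zeroed."""
        recs = {}
        for pid, rec in self.recordings.items():
            recs[pid] = ImuRecording(
                sensor_id=pid,
                t=rec.t[start:end] - rec.t[start],
                gyro=rec.gyro[start:end],
                accel=rec.accel[start:end],
                fs=rec.fs,
            )
        return SensorArray(recs)


@dataclass
class WindowPlan:
    """Near-equal tiling of [0, N) into half-open index ranges."""

    n_windows: int
    bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        starts = [b[0] for b in self.bounds]
        ends = [b[1] for b in self.bounds]
        if len(self.bounds) != self.n_windows:
            raise ArgumentError("bounds do not match n_windows")
        if any(e <= s for s, e in self.bounds):
            raise ArgumentError("empty window in plan")
        if any(ends[i] != starts[i + 1] for i in range(len(self.bounds) - 1)):
            raise ArgumentError("windows do not tile contiguously")
        lengths = [e - s for s, e in self.bounds]
        if max(lengths) - min(lengths) > 1:
            raise ArgumentError("window lengths differ by more than 1 sample")


def read_imu_csv(path, sensor_id: str) -> ImuRecording:
    """Read one sensor's recording from the documented CSV dialect."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) < 2:
        raise EmptyInputError(f"{path}: fewer than 2 samples")
    t = df["t"].to_numpy(dtype=float)
    t = t - t[0]
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    return ImuRecording(sensor_id=sensor_id, t=t, gyro=gyro, accel=accel)


def write_imu_csv(rec: ImuRecording, path) -> str:
    """Write a recording to CSV at full float precision; returns the path."""
    df = pd.DataFrame(
        {
            "t": rec.t,
            "gx": rec.gyro[:, 0],
            "gy": rec.gyro[:, 1],
            "gz": rec.gyro[:, 2],
            "ax": rec.accel[:, 0],
            "ay": rec.accel[:, 1],
            "az": rec.accel[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return str(path)


def assemble_array(recs: list[ImuRecording]) -> SensorArray:
    """Assemble seven recordings into a synchronized :class:`SensorArray`."""
    seen: dict[str, ImuRecording] = {}
    for rec in recs:
        if rec.sensor_id in seen:
            raise TopologyError(f"duplicate placement {rec.sensor_id!r}")
        seen[rec.sensor_id] = rec
    return SensorArray(seen)


def plan_windows(array: SensorArray, n_windows: int) -> WindowPlan:
    """Tile the array's samples into ``n_windows`` near-equal index ranges.

    When N is not divisible the earlier windows receive the extra sample, so
    lengths differ by at most one.
    """
    n = array.n_samples
    if n_windows < 1:
        raise ArgumentError("n_windows must be >= 1")
    if n_windows > n:
        raise ArgumentError(f"n_windows={n_windows} exceeds N={n}")
    edges = np.linspace(0, n, n_windows + 1).round().astype(int)
    bounds = [(int(edges[i]), int(edges[i + 1])) for i in range(n_windows)]
    return WindowPlan(n_windows=n_windows, bounds=bounds)


def write_array_hdf5(array: SensorArray, path) -> str:
    """Write a full array to an HDF5 container (layout in the module docstring)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("sensors")
        for pid, rec in array.recordings.items():
            g = grp.create_group(pid)
            g.create_dataset("t", data=rec.t)
            g.create_dataset("gyro", data=rec.gyro)
            g.create_dataset("accel", data=rec.accel)
            g.attrs["sensor_id"] = pid
            g.attrs["fs"] = rec.fs
    return str(path)


def read_array_hdf5(path) -> SensorArray:
    """Read a full array from the HDF5 container layout."""
    recs = []
    with h5py.File(path, "r") as f:
        if "sensors" not in f:
            raise FormatError(f"{path}: missing /sensors group")
        for pid in f["sensors"]:
            g = f["sensors"][pid]
            recs.append(
                ImuRecording(
                    sensor_id=str(g.attrs.get("sensor_id", pid)),
                    t=g["t"][()],
                    gyro=g["gyro"][()],
                    accel=g["accel"][()],
                    fs=float(g.attrs.get("fs", 0.0)),
                )
            )
    return assemble_array(recs)
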