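"""Vectorized SO(3) primitives used by the synthesis and estimation code.

All functions broadcast over a leading batch dimension: rotation matrices are
``(..., 3, 3)`` arrays and rotation vectors ``(..., 3)`` arrays.  Matrices map
*sensor-frame* coordinates to *world-frame* coordinates (columns are the
sensor axes expressed in the world frame).  Perturbations are right-applied:
``R <- R @ expm(delta)``.

scipy's Rotation is used where convenient; the right Jacobian and its inverse
are written out because scipy does not expose them.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

_EPS = 1e-12


def hat(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric matrix (batched): hat(v) @ u = v x u."""
    v = np.asarray(v, dtype=float)
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def expm(phi: np.ndarray) -> np.ndarray:
    """Matrix exponential of hat(phi) (batched rotation vectors)."""
    phi = np.asarray(phi, dtype=float)
    flat = phi.reshape(-1, 3)
    return Rotation.from_rotvec(flat).as_matrix().reshape(phi.shape[:-1] + (3, 3))


def logm(R: np.ndarray) -> np.ndarray:
    """Rotation vector of a (batched) rotation matrix."""
    R = np.asarray(R, dtype=float)
    flat = R.reshape(-1, 3, 3)
    return Rotation.from_matrix(flat).as_rotvec().reshape(R.shape[:-2] + (3,))


def right_jacobian(phi: np.ndarray) -> np.ndarray:
    """Right Jacobian J_r of SO(3): expm(phi + d) ~ expm(phi) expm(J_r d)."""
    phi = np.asarray(phi, dtype=float)
    th = np.linalg.norm(phi, axis=-1)
    Ph = hat(phi)
    Ph2 = Ph @ Ph
    th = th[..., None, None]
    small = th < 1e-6
    th_safe = np.where(small, 1.0, th)
    a = np.where(small, 0.5 - th**2 / 24.0, (1.0 - np.cos(th_safe)) / th_safe**2)
    b = np.where(small, 1.0 / 6.0 - th**2 / 120.0, (th_safe - np.sin(th_safe)) / th_safe**3)
    eye = np.broadcast_to(np.eye(3), Ph.shape)
    return eye - a * Ph + b * Ph2


def right_jacobian_inv(phi: np.ndarray) -> np.ndarray:
    """Inverse of the right Jacobian of SO(3)."""
    phi = np.asarray(phi, dtype=float)
    th = np.linalg.norm(phi, axis=-1)
    Ph = hat(phi)
    Ph2 = Ph @ Ph
    th = th[..., None, None]
    small = th < 1e-6
    th_safe = np.where(small, 1.0, th)
    cot_term = np.where(
        small,
        1.0 / 12.0 + th**2 / 720.0,
        (1.0 / th_safe**2) - (1.0 + np.cos(th_safe)) / (2.0 * th_safe * np.sin(th_safe)),
    )
    eye = np.broadcast_to(np.eye(3), Ph.shape)
    return eye + 0.5 * Ph + cot_term * Ph2


def yaw_of(R: np.ndarray) -> np.ndarray:
    """Heading angle (rad) of the rotated x-axis about world z."""
    R = np.asarray(R, dtype=float)
    return np.arctan2(R[..., 1, 0], R[..., 0, 0])


def rotz(angle: float | np.ndarray) -> np.ndarray:
    """Rotation matrix/matrices about world z (batched over scalars)."""
    a = np.asarray(angle, dtype=float)
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out
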