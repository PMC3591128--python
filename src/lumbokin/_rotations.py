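"""Batched rotation-vector utilities (Rodrigues form).

The equilibrium solver evaluates energies on large batches of perturbed
states for finite differencing, so these helpers broadcast over arbitrary
leading axes: inputs of shape ``(..., 3)`` produce matrices ``(..., 3, 3)``.
Small-angle limits use series expansions to stay smooth through zero.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-8


def rotvec_to_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rotation matrix of a rotation vector (axis * angle, radians)."""
    r = np.asarray(rotvec, dtype=float)
    theta = np.linalg.norm(r, axis=-1, keepdims=True)
    small = theta[..., 0] < _EPS
    # sin(t)/t and (1-cos t)/t^2, series-expanded near zero
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(small[..., None], 1.0 - theta[..., 0:1] ** 2 / 6.0, np.sin(theta) / theta)
        b = np.where(
            small[..., None],
            0.5 - theta[..., 0:1] ** 2 / 24.0,
            (1.0 - np.cos(theta)) / theta**2,
        )
    rx, ry, rz = r[..., 0], r[..., 1], r[..., 2]
    zeros = np.zeros_like(rx)
    K = np.stack(
        [
            np.stack([zeros, -rz, ry], axis=-1),
            np.stack([rz, zeros, -rx], axis=-1),
            np.stack([-ry, rx, zeros], axis=-1),
        ],
        axis=-2,
    )
    eye = np.broadcast_to(np.eye(3), K.shape)
    return eye + a[..., None] * K + b[..., None] * (K @ K)


def matrix_to_rotvec(R: np.ndarray) -> np.ndarray:
    """Rotation vector (axis * angle) of a rotation matrix, batched.

    Valid for angles in [0, pi); the model's quasi-static range keeps
    rotations far below that bound.
    """
    R = np.asarray(R, dtype=float)
    trace = np.trace(R, axis1=-2, axis2=-1)
    cos_t = np.clip((trace - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_t)
    skew = np.stack(
        [
            R[..., 2, 1] - R[..., 1, 2],
            R[..., 0, 2] - R[..., 2, 0],
            R[..., 1, 0] - R[..., 0, 1],
        ],
        axis=-1,
    )
    small = theta < _EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(small, 0.5 + theta**2 / 12.0, theta / (2.0 * np.sin(theta)))
    return skew * scale[..., None]


def rotate_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Single rotation matrix about a (unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return rotvec_to_matrix(axis * angle_rad)
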