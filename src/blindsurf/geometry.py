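"""Quaternion and rigid-body helpers.

Convention used throughout the package: quaternions are scalar-first
``(w, x, y, z)`` and represent *active*, right-handed rotations about the
origin.  A pose is a unit quaternion plus a translation; the rotation is
applied to the origin-centred ligand model first, the shift second.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "normalize_quats",
    "quat_mul",
    "quat_conj",
    "quat_to_matrix",
    "rotate_vectors",
    "axis_angle_quat",
    "random_unit_quats",
    "uniform_in_sphere",
    "IDENTITY_QUAT",
]

IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])

_UNIT_TOL = 1e-9


def normalize_quats(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def check_unit(q: np.ndarray, tol: float = _UNIT_TOL) -> None:
    """Raise ``ValueError`` if any quaternion is not unit length within *tol*."""
    norms = np.linalg.norm(np.asarray(q, dtype=float), axis=-1)
    if not np.allclose(norms, 1.0, atol=tol, rtol=0.0):
        raise ValueError(f"non-unit quaternion (|q| deviates by {np.abs(norms - 1.0).max():.3g})")


def quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a * b`` (apply ``b`` first, then ``a``). Broadcasts."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def quat_conj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices for scalar-first unit quaternions, shape ``(..., 3, 3)``."""
    q = np.asarray(q, dtype=float)
    w, x, y, z = (q[..., i] for i in range(4))
    xx, yy, zz = x * x, y * y, z * z
    wx, wy, wz = w * x, w * y, w * z
    xy, xz, yz = x * y, x * z, y * z
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1.0 - 2.0 * (yy + zz)
    m[..., 0, 1] = 2.0 * (xy - wz)
    m[..., 0, 2] = 2.0 * (xz + wy)
    m[..., 1, 0] = 2.0 * (xy + wz)
    m[..., 1, 1] = 1.0 - 2.0 * (xx + zz)
    m[..., 1, 2] = 2.0 * (yz - wx)
    m[..., 2, 0] = 2.0 * (xz - wy)
    m[..., 2, 1] = 2.0 * (yz + wx)
    m[..., 2, 2] = 1.0 - 2.0 * (xx + yy)
    return m


def rotate_vectors(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` (``(n, 3)``) by quaternions ``q`` (``(..., 4)``).

    Returns ``(..., n, 3)``: every quaternion applied to every vector.
    """
    m = quat_to_matrix(q)
    v = np.asarray(v, dtype=float)
    return np.einsum("...ij,nj->...ni", m, v)


def axis_angle_quat(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Unit quaternion for rotation by *angle* (rad) about *axis* (unit, ``(...,3)``)."""
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle, dtype=float)
    half = 0.5 * angle
    return np.concatenate(
        [np.cos(half)[..., None], np.sin(half)[..., None] * axis], axis=-1
    )


def random_unit_quats(u: np.ndarray) -> np.ndarray:
    """Map uniforms ``u`` of shape ``(..., 3)`` to quaternions uniform on SO(3).

    Shoemake's subgroup algorithm; deterministic in the supplied uniforms so
    replica random streams stay counter-addressable.
    """
    u = np.asarray(u, dtype=float)
    u1, u2, u3 = u[..., 0], u[..., 1], u[..., 2]
    a = np.sqrt(1.0 - u1)
    b = np.sqrt(u1)
    t2 = 2.0 * np.pi * u2
    t3 = 2.0 * np.pi * u3
    return np.stack(
        [b * np.cos(t3), a * np.sin(t2), a * np.cos(t2), b * np.sin(t3)], axis=-1
    )


def uniform_in_sphere(u: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Map uniforms ``(..., 3)`` to points uniform in the sphere (center, radius)."""
    u = np.asarray(u, dtype=float)
    r = radius * np.cbrt(u[..., 0])
    cos_t = 2.0 * u[..., 1] - 1.0
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    phi = 2.0 * np.pi * u[..., 2]
    d = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=-1)
    return np.asarray(center, dtype=float) + r[..., None] * d


def clamp_to_sphere(points: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radially project points outside the sphere back onto its boundary."""
    p = np.asarray(points, dtype=float)
    v = p - center
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    scale = np.where(norm > radius, radius / np.maximum(norm, 1e-300), 1.0)
    return center + v * scale
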