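"""Small rigid-body helpers shared across modules."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping ``mobile`` onto ``reference``.

    Returns a proper rotation (det = +1); reflections are corrected by sign
    flip of the smallest singular direction.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if S[-1] < 1e-12 and S[0] > 0 and np.count_nonzero(S > 1e-8 * S[0]) < 2:
        raise ValueError("degenerate (collinear) point set: rotation underdetermined")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    x, y, z = axis / n
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)


def rotation_vector(R: np.ndarray) -> np.ndarray:
    """Axis-angle vector (axis * angle, radians) of a rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_matrix(R).as_rotvec()


def orthonormalize(M: np.ndarray) -> np.ndarray:
    """Nearest proper rotation to an arbitrary 3x3 matrix (via SVD)."""
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R
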