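"""Low-level vector geometry used throughout the package.

All functions operate on numpy arrays of shape ``(3,)`` (single points) or
``(n, 3)`` (point sets) and use radians for angles.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "norm",
    "unit",
    "angle",
    "dihedral",
    "rotation_about_axis",
    "place_atom",
    "kabsch",
    "apply_transform",
    "rmsd",
    "wrap_angle",
]


def norm(v: np.ndarray) -> float:
    return float(np.linalg.norm(v))


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize near-zero vector")
    return v / n


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + np.pi, 2.0 * np.pi) - np.pi)
    return float(w) if w.ndim == 0 else w


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians."""
    u = unit(a - b)
    v = unit(c - b)
    return float(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral a-b-c-d in radians, in (-pi, pi]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def rotation_about_axis(axis: np.ndarray, theta: float) -> np.ndarray:
    """3x3 rotation matrix about a (unit) axis through the origin."""
    u = unit(axis)
    c = np.cos(theta)
    s = np.sin(theta)
    ux, uy, uz = u
    cross = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * cross + (1.0 - c) * np.outer(u, u)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, ang: float, tors: float) -> np.ndarray:
    """Place atom D given atoms a-b-c, |c-D| = bond, angle(b,c,D) = ang and
    dihedral(a,b,c,D) = tors (NeRF construction)."""
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d2 = bond * np.array([
        -np.cos(ang),
        np.cos(tors) * np.sin(ang),
        -np.sin(tors) * np.sin(ang),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def kabsch(mobile: np.ndarray, ref: np.ndarray, weights=None):
    """Optimal rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` minimizes the
    (weighted) RMSD to ``ref``. Uses the SVD formulation with the usual
    reflection correction.
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {ref.shape}")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * ref).sum(axis=0)
    P = mobile - mc
    Q = ref - rc
    H = (w[:, None] * P).T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = P @ R.T + rc
    val = float(np.sqrt((w * ((moved - ref) ** 2).sum(axis=1)).sum()))
    return R, t, val


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))
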