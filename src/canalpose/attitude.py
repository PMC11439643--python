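"""SVD plane fitting, normal-sign canonicalization and cohort statistics.

The canal plane is the total-least-squares plane of the trimmed
centerline: centre the points, take the SVD of the centred matrix, and
read the normal off the right-singular direction of the smallest
singular value.  Because an SVD normal is sign-ambiguous, normals are
canonicalized to fixed hemispheres (lateral canals point infero-, the
vertical canals postero-) before any averaging; the mean canal normal is
the normalized vector sum V_avg = sum(v_i) / ||sum(v_i)||.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_DEG = 180.0 / np.pi


@dataclass
class PlaneFitResult:
    centroid: np.ndarray
    normal: np.ndarray                  # unit, sign-ambiguous
    singular_values: np.ndarray         # descending
    rms_distance: float                 # mm

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)


@dataclass
class CanalAttitude:
    """Oriented canal-plane normal in the standard frame."""

    side: str
    canal: str
    normal: np.ndarray                  # unit, standard frame, canonical sign
    normal_image: np.ndarray            # same vector in image coordinates
    direction_angles: tuple[float, float, float]  # degrees vs +X, +Y, +Z
    n_points: int = 0
    rms_distance: float = 0.0


@dataclass
class CohortSummary:
    """Aggregate over subjects: mean normals, spread, dihedral angles."""

    mean_normals: dict[tuple[str, str], np.ndarray]
    deviation: dict[tuple[str, str], tuple[float, float]]   # (mean deg, SD deg)
    dihedral_mean_of_subjects: dict[tuple, float]
    dihedral_of_mean_normals: dict[tuple, float]
    n_subjects: dict[tuple[str, str], int] = field(default_factory=dict)


def fit_plane_svd(points: np.ndarray) -> PlaneFitResult:
    """Total-least-squares plane of >= 3 non-collinear points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need an (n>=3, 3) point array")
    centroid = pts.mean(axis=0)
    B = pts - centroid
    U, S, Vt = np.linalg.svd(B, full_matrices=False)
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise ValueError("degenerate point set: points are collinear")
    normal = Vt[-1]
    rms = float(S[-1] / np.sqrt(len(pts)))
    return PlaneFitResult(centroid=centroid, normal=normal,
                          singular_values=S, rms_distance=rms)


def local_plane_normals(points: np.ndarray, window: int) -> list[np.ndarray]:
    """Sliding-window (stride 1) SVD plane normals along an ordered path.

    Consecutive window normals are sign-aligned to each other (the first
    window's sign is left for the caller to canonicalize).  A path
    shorter than the window degrades to a single global fit.
    """
    pts = np.asarray(points, dtype=float)
    if window < 5:
        raise ValueError("window must be at least 5 points")
    if len(pts) < window:
        warnings.warn("path shorter than window; falling back to a global fit",
                      stacklevel=2)
        return [fit_plane_svd(pts).normal]
    normals = []
    for start in range(len(pts) - window + 1):
        n = fit_plane_svd(pts[start:start + window]).normal
        if normals and np.dot(n, normals[-1]) < 0:
            n = -n
        normals.append(n)
    return normals


#: sign rules per canal: ordered (component index, required sign) in the
#: standard frame (X superior, Y anterior, Z rightward).  Lateral canal
#: normals point inferiorly (X < 0); vertical canal normals point
#: posteriorly (Y < 0), with ties resolved superiorly (X > 0).
_SIGN_RULES = {
    "lateral": ((0, -1.0), (1, -1.0), (2, 1.0)),
    "anterior": ((1, -1.0), (0, 1.0), (2, 1.0)),
    "posterior": ((1, -1.0), (0, 1.0), (2, 1.0)),
}


def orient_normal(normal: np.ndarray, side: str, canal: str) -> np.ndarray:
    """Canonically sign a canal normal (standard frame)."""
    v = np.asarray(normal, dtype=float)
    if np.linalg.norm(v) < 1e-12:
        raise ValueError("zero vector cannot be oriented")
    if canal not in _SIGN_RULES:
        raise ValueError(f"unknown canal {canal!r}")
    for comp, sign in _SIGN_RULES[canal]:
        if v[comp] != 0.0:
            return v if np.sign(v[comp]) == sign else -v
    return v


def average_unit_normals(normals: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """V_avg: normalized vector sum of unit normals."""
    arr = np.asarray(normals, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if len(arr) == 0:
        raise ValueError("no normals to average")
    total = arr.sum(axis=0)
    norm = np.linalg.norm(total)
    if norm <= 1e-6:
        raise ValueError("incoherent normals - check sign canonicalization")
    return total / norm


def direction_angles(v: np.ndarray) -> tuple[float, float, float]:
    """Angles (deg) between a unit vector and the +X, +Y, +Z axes."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero vector has no direction angles")
    if abs(n - 1.0) > 1e-3:
        raise ValueError(f"vector norm {n:.4f} too far from 1")
    u = np.clip(v / n, -1.0, 1.0)
    return tuple(float(np.arccos(c) * _DEG) for c in u)


def dihedral_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle in degrees between two (canonically oriented) plane normals."""
    a = np.asarray(n1, dtype=float)
    b = np.asarray(n2, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero vector")
    c = np.clip(np.dot(a / na, b / nb), -1.0, 1.0)
    return float(np.arccos(c) * _DEG)


def deviation_stats(normals: list[np.ndarray] | np.ndarray,
                    mean: np.ndarray) -> tuple[float, float]:
    """Mean and population SD (deg) of angles between normals and their mean."""
    arr = np.asarray(normals, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if len(arr) == 0:
        raise ValueError("no normals")
    if len(arr) == 1:
        return 0.0, 0.0
    angles = np.array([dihedral_angle(v, mean) for v in arr])
    return float(angles.mean()), float(angles.std())
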