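"""The standard spatial coordinate system (canal-eyeball frame).

The lateral (transverse) reference plane passes through the tops of the
two common crura and the lowest supporting point of the eyeballs; it is
reported to be parallel to the Frankfort plane, making it a usable
substitute when bony landmarks are outside the imaging field of view.
Frame axes: X = lateral-plane normal (superior positive), Z = crus-top
line (rightward positive), Y = coronal-plane normal (anterior positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volume_io import BinaryMask

_TOL = 1e-9


@dataclass
class Plane3:
    """A plane given by a unit normal and a reference point (mm)."""

    normal: np.ndarray
    point: np.ndarray

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-6:
            self.normal = self.normal / n
        self.point = np.asarray(self.point, dtype=float)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal


@dataclass
class ReferenceFrame:
    """Orthonormal standard axes expressed in image space."""

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    handedness: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        for name in "XYZ":
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"axis {name} is not unit length")
            setattr(self, name, v)
        for a, b in (("X", "Y"), ("X", "Z"), ("Y", "Z")):
            if abs(np.dot(getattr(self, a), getattr(self, b))) > 1e-6:
                raise ValueError(f"axes {a} and {b} are not orthogonal")
        self.handedness = float(np.sign(np.linalg.det(
            np.stack([self.X, self.Y, self.Z]))))

    def to_json(self, path: str | Path) -> Path:
        payload = {"origin": self.origin.tolist(), "X": self.X.tolist(),
                   "Y": self.Y.tolist(), "Z": self.Z.tolist(),
                   "handedness": self.handedness}
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceFrame":
        raw = json.loads(Path(path).read_text())
        return cls(origin=raw["origin"], X=raw["X"], Y=raw["Y"], Z=raw["Z"])


def _plane_through(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> Plane3:
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1e-12)
    if norm < 1e-9 * scale**2:
        raise ValueError("defining points are collinear")
    n = n / norm
    if n[2] < 0 or (n[2] == 0 and n[1] < 0):
        n = -n  # superior-positive by convention
    return Plane3(normal=n, point=p1)


def _lowest_voxel(mask: BinaryMask, values: np.ndarray) -> np.ndarray:
    """Physical point of the voxel minimizing ``values``.

    Ties broken by smallest left-right coordinate, then most posterior.
    """
    pts = np.argwhere(mask.array) * np.asarray(mask.spacing)
    if len(pts) == 0:
        raise ValueError("empty eyeball mask")
    v = np.asarray(values, dtype=float)
    order = np.lexsort((pts[:, 1], pts[:, 0], v))
    return pts[order[0]]


def initial_lateral_plane(crus_left: np.ndarray, crus_right: np.ndarray,
                          eyeballs: BinaryMask) -> Plane3:
    """Plane through both crus tops and the globally lowest eyeball voxel."""
    pts = np.argwhere(eyeballs.array) * np.asarray(eyeballs.spacing)
    if len(pts) == 0:
        raise ValueError("empty eyeball mask")
    lowest = _lowest_voxel(eyeballs, pts[:, 2])
    return _plane_through(np.asarray(crus_left, float),
                          np.asarray(crus_right, float), lowest)


def refine_fundus_point(plane: Plane3, eyeballs: BinaryMask,
                        crus_left: np.ndarray, crus_right: np.ndarray,
                        max_iter: int = 20) -> tuple[np.ndarray, Plane3]:
    """Iterate to the supporting plane below the eyeballs.

    Each iteration selects the eyeball voxel farthest below the current
    plane and rebuilds the plane through it and the two crus tops; at
    convergence no eyeball voxel lies strictly below the plane (within
    1e-6 mm) and the selected voxel is the refined fundus point.
    """
    crus_left = np.asarray(crus_left, float)
    crus_right = np.asarray(crus_right, float)
    pts = np.argwhere(eyeballs.array) * np.asarray(eyeballs.spacing)
    if len(pts) == 0:
        raise ValueError("empty eyeball mask")
    current = None
    for _ in range(max_iter):
        sd = plane.signed_distance(pts)
        candidate = _lowest_voxel(eyeballs, sd)
        if current is not None and np.allclose(candidate, current):
            return current, plane
        if current is not None and sd.min() >= -1e-6:
            return current, plane
        current = candidate
        plane = _plane_through(crus_left, crus_right, current)
    sd = plane.signed_distance(pts)
    if sd.min() >= -1e-6:
        return current, plane
    raise RuntimeError("non-convergent fundus refinement")


def build_frame(crus_left: np.ndarray, crus_right: np.ndarray,
                fundus: np.ndarray) -> ReferenceFrame:
    """Standard frame from the two crus tops and the refined fundus point.

    X is the lateral-plane normal (superior), Z the crus-top line
    projected orthogonal to X (rightward), and Y completes the triad
    with its sign forced anterior.  The crus line is generally not
    exactly orthogonal to the plane normal, hence the projection.
    """
    crus_left = np.asarray(crus_left, float)
    crus_right = np.asarray(crus_right, float)
    fundus = np.asarray(fundus, float)
    X = _plane_through(crus_left, crus_right, fundus).normal
    if X[2] <= 0:
        raise ValueError("lateral-plane normal has no superior component")
    z_raw = crus_right - crus_left
    Z = z_raw - np.dot(z_raw, X) * X
    nz = np.linalg.norm(Z)
    if nz < 1e-9 * np.linalg.norm(z_raw):
        raise ValueError("crus line parallel to the plane normal")
    Z = Z / nz
    if Z[0] < 0:
        Z = -Z
    Y = np.cross(X, Z)
    if Y[1] < 0:
        Y = -Y
    origin = 0.5 * (crus_left + crus_right)
    return ReferenceFrame(origin=origin, X=X, Y=Y, Z=Z)


def to_standard(v: np.ndarray, frame: ReferenceFrame) -> np.ndarray:
    """Express a (translation-free) vector in standard coordinates."""
    v = np.asarray(v, dtype=float)
    return np.stack([v @ frame.X, v @ frame.Y, v @ frame.Z], axis=-1)


def from_standard(v: np.ndarray, frame: ReferenceFrame) -> np.ndarray:
    """Inverse of :func:`to_standard`."""
    v = np.asarray(v, dtype=float)
    basis = np.stack([frame.X, frame.Y, frame.Z])
    return v @ basis
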