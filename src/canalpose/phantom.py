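"""Synthetic bilateral labyrinth + eyeball phantom with known ground truth.

The phantom emulates the gross geometry of the inner ear: per side, three
semicircular canals modelled as planar circular arcs swept into tubes, an
ampulla bulge at the free end of each arc, a vertical common-crus tube
joining the anterior and posterior canal arcs at its top, and a spherical
eyeball.  Because every canal is a planar arc, the true plane normal of
each canal is known exactly, which makes the phantom a ground-truth
oracle for the whole measurement pipeline.

Geometry is expressed in physical millimetres with the package axis
convention (x left->right, y posterior->anterior, z inferior->superior).
The default dimensions are a modestly enlarged human labyrinth (canal
arc radius 7.5 mm, duct radius 1.5 mm) so that the rasterized tubes are
several voxels wide at the default 0.5 mm grid; the canal plane
orientations follow published adult mean orientations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .volume_io import DEFAULT_LABEL_MAP, BinaryMask, LabelVolume

CANALS = ("anterior", "posterior", "lateral")
SIDES = ("left", "right")


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a near-zero vector")
    return v / n


def _perp_component(v: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Component of v orthogonal to the unit vector n."""
    v = np.asarray(v, dtype=float)
    return v - np.dot(v, n) * n


@dataclass
class CanalArcSpec:
    """A planar circular canal arc swept into a tube.

    The arc starts at its junction point (angle 0, where the canal meets
    the common crus or vestibule) and spans ``span_deg`` degrees; the far
    end carries the ampulla bulge.  ``orientation`` selects the sweep
    direction around the plane normal.
    """

    canal: str
    normal: np.ndarray        # unit plane normal
    center: np.ndarray        # arc centre, mm
    radius: float             # arc (major) radius, mm
    tube_radius: float        # duct (minor) radius, mm
    span_deg: float
    e1: np.ndarray            # unit vector centre -> junction (angle 0)
    orientation: int          # +1 / -1 sweep direction
    ampulla_radius: float

    def __post_init__(self) -> None:
        self.normal = _unit(self.normal)
        self.center = np.asarray(self.center, dtype=float)
        self.e1 = _unit(self.e1)
        if not (180.0 < self.span_deg < 360.0):
            raise ValueError(f"{self.canal}: span must be in (180, 360) deg")
        if min(self.radius, self.tube_radius, self.ampulla_radius) <= 0:
            raise ValueError(f"{self.canal}: radii must be positive")
        if abs(np.dot(self.normal, self.e1)) > 1e-9:
            raise ValueError(f"{self.canal}: e1 must be orthogonal to the plane normal")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +-1")

    @property
    def e2(self) -> np.ndarray:
        return np.cross(self.normal, self.e1)

    def point_at(self, theta_deg: np.ndarray | float) -> np.ndarray:
        """Arc point(s) at angle theta (degrees from the junction end)."""
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        c, s = np.cos(th), np.sin(th)
        return (self.center
                + self.radius * (np.multiply.outer(c, self.e1)
                                 + self.orientation * np.multiply.outer(s, self.e2)))

    def sample(self, n: int = 361) -> np.ndarray:
        return self.point_at(np.linspace(0.0, self.span_deg, n))

    @classmethod
    def from_junction(cls, canal: str, normal: np.ndarray, junction: np.ndarray,
                      center_hint: np.ndarray, tangent_hint: np.ndarray,
                      radius: float, tube_radius: float, span_deg: float,
                      ampulla_radius: float) -> "CanalArcSpec":
        """Build an arc starting at ``junction`` (angle 0).

        ``center_hint`` places the arc centre (projected into the canal
        plane) relative to the junction; ``tangent_hint`` selects which
        of the two sweep directions the arc leaves the junction along.
        """
        n = _unit(normal)
        d = _unit(_perp_component(center_hint, n))
        center = np.asarray(junction, float) + radius * d
        e1 = -d
        e2 = np.cross(n, e1)
        orientation = 1 if np.dot(tangent_hint, e2) > 0 else -1
        return cls(canal=canal, normal=n, center=center, radius=radius,
                   tube_radius=tube_radius, span_deg=span_deg, e1=e1,
                   orientation=orientation, ampulla_radius=ampulla_radius)


@dataclass
class SideSpec:
    """One labyrinth side: three canal arcs plus the common-crus tube."""

    side: str
    canals: dict[str, CanalArcSpec]
    crus_top: np.ndarray        # anterior/posterior junction, mm
    vestibule: np.ndarray       # lateral-canal junction on the crus, mm
    crus_bottom: np.ndarray
    crus_radius: float

    def __post_init__(self) -> None:
        self.crus_top = np.asarray(self.crus_top, dtype=float)
        self.vestibule = np.asarray(self.vestibule, dtype=float)
        self.crus_bottom = np.asarray(self.crus_bottom, dtype=float)
        if set(self.canals) != set(CANALS):
            raise ValueError("side must define anterior, posterior and lateral canals")


@dataclass
class EyeSpec:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("eye radius must be positive")


@dataclass
class PhantomSpec:
    """Full bilateral phantom description (JSON-serializable)."""

    sides: dict[str, SideSpec]
    eyes: dict[str, EyeSpec]
    shape: tuple[int, int, int] = (201, 221, 141)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    noise_p: float = 0.0
    seed: int = 0
    mirror_x: float = 50.0    # mid-sagittal plane, mm

    def validate(self) -> None:
        if not (0.0 <= self.noise_p < 1.0):
            raise ValueError("noise_p must be in [0, 1)")
        for side in SIDES:
            s = self.sides[side]
            normals = [s.canals[c].normal for c in CANALS]
            for i in range(3):
                for j in range(i + 1, 3):
                    ang = np.rad2deg(np.arccos(np.clip(abs(np.dot(normals[i], normals[j])), 0, 1)))
                    # angle between the canal *planes* must exceed 60 deg
                    if ang < 60.0 and 180.0 - ang < 60.0:
                        raise ValueError(f"{side}: canal normals closer than 60 deg")
            # anterior and posterior arcs must reach the crus
            for c in ("anterior", "posterior"):
                arc = s.canals[c]
                d = np.linalg.norm(arc.point_at(0.0) - s.crus_top)
                if d > arc.tube_radius + s.crus_radius:
                    raise ValueError(f"{side} {c}: arc does not meet the common crus")

    def to_json(self, path: str | Path) -> Path:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return o
        payload = json.loads(json.dumps(asdict(self), default=enc))
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        raw = json.loads(Path(path).read_text())
        sides = {
            k: SideSpec(side=v["side"],
                        canals={c: CanalArcSpec(**a) for c, a in v["canals"].items()},
                        crus_top=v["crus_top"], vestibule=v["vestibule"],
                        crus_bottom=v["crus_bottom"], crus_radius=v["crus_radius"])
            for k, v in raw["sides"].items()
        }
        eyes = {k: EyeSpec(**v) for k, v in raw["eyes"].items()}
        return cls(sides=sides, eyes=eyes, shape=tuple(raw["shape"]),
                   spacing=tuple(raw["spacing"]), noise_p=raw["noise_p"],
                   seed=raw["seed"], mirror_x=raw["mirror_x"])


@dataclass
class PhantomTruth:
    """Exact ground truth for recovery tests."""

    normals: dict[str, dict[str, np.ndarray]]     # side -> canal -> unit normal
    centers: dict[str, dict[str, np.ndarray]]
    crus_tops: dict[str, np.ndarray]              # side -> mm point
    fundus_point: np.ndarray                      # lowest supporting eyeball point
    fundus_normal: np.ndarray                     # supporting plane normal (superior)


# ---------------------------------------------------------------------------
# default spec

# Adult mean canal-plane orientations (unit normals) in the standard
# canal-eyeball frame (X superior, Y anterior, Z rightward), used as the
# noise-free phantom defaults; small per-side jitter is added on top.
_BASE_NORMALS_STD = {
    "left": {
        "anterior": np.array([0.1704, -0.5637, 0.8082]),
        "lateral": np.array([-0.9844, -0.1743, -0.0230]),
        "posterior": np.array([0.1852, -0.6511, -0.7360]),
    },
    "right": {
        "anterior": np.array([0.1903, -0.5795, -0.7925]),
        "lateral": np.array([-0.9889, -0.1484, 0.0099]),
        "posterior": np.array([0.1716, -0.6746, 0.7180]),
    },
}

_LABYRINTH_LEFT = np.array([25.0, 45.0, 40.0])   # mm
_EYE_LEFT = EyeSpec(center=np.array([35.0, 85.0, 50.0]), radius=11.0)


def _small_rotation(rng: np.random.Generator, sigma_deg: float) -> np.ndarray:
    """Random rotation matrix with axis-angle magnitude ~ N(0, sigma)."""
    axis = _unit(rng.normal(size=3))
    ang = np.deg2rad(rng.normal(scale=sigma_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def _build_side(side: str, labyrinth: np.ndarray, normals: dict[str, np.ndarray],
                lat_sign: float) -> SideSpec:
    """Assemble one side from its canal normals and labyrinth centre.

    ``lat_sign`` is -1 for the left side (lateral = -x) and +1 for the right.
    """
    T = labyrinth + np.array([0.0, -1.0, 5.0])          # common-crus top
    V = T + np.array([0.0, 0.0, -6.0])                  # vestibule junction
    # the tube continues well below the lateral-canal junction (vestibule
    # side): thinning retracts blunt dead ends by several voxels, and a
    # skeleton branch must survive below V for the junction to exist.
    # The stub is kinked slightly off-vertical: a perfectly axis-aligned
    # tube of even voxel width can vanish entirely under parallel thinning
    crus_bottom = V + np.array([1.5 * lat_sign, 1.0, -10.0])
    up = np.array([0.0, 0.0, 1.0])
    lateral_dir = np.array([lat_sign, 0.0, 0.0])

    canals = {
        # anterior arc arches highest: centre anterior-superior of the crus
        # top, departing postero-superiorly so its ampulla returns low
        "anterior": CanalArcSpec.from_junction(
            "anterior", normals["anterior"], T,
            center_hint=np.array([0.0, 0.4, 1.0]),
            tangent_hint=np.array([0.0, -1.0, 0.4]),
            radius=7.5, tube_radius=1.5, span_deg=300.0, ampulla_radius=2.2),
        # posterior arc: centre postero-superior, most posterior extreme
        "posterior": CanalArcSpec.from_junction(
            "posterior", normals["posterior"], T,
            center_hint=np.array([0.0, -1.0, 0.45]),
            tangent_hint=np.array([0.0, 0.3, 1.0]),
            radius=7.5, tube_radius=1.5, span_deg=300.0, ampulla_radius=2.2),
        # lateral arc: near-horizontal plane, centre lateral of the vestibule
        "lateral": CanalArcSpec.from_junction(
            "lateral", normals["lateral"], V,
            center_hint=lateral_dir,
            tangent_hint=np.array([0.0, 1.0, 0.0]),
            radius=6.5, tube_radius=1.5, span_deg=300.0, ampulla_radius=2.2),
    }
    return SideSpec(side=side, canals=canals, crus_top=T, vestibule=V,
                    crus_bottom=crus_bottom, crus_radius=1.5)


def default_spec(seed: int = 0, noise_p: float = 0.0,
                 jitter_deg: float = 1.0, jitter_mm: float = 0.25) -> PhantomSpec:
    """Default bilateral phantom, approximately mirror-symmetric.

    The canal-plane normals default to published adult means; each side
    receives an independent small rotation (sigma ``jitter_deg``) and
    translation (sigma ``jitter_mm``) so left and right are realistically
    imperfect mirror images.  Deterministic given ``seed``.
    """
    from .reference_frame import build_frame, from_standard

    rng = np.random.default_rng(seed)
    mirror_x = 50.0

    # base (pre-jitter) landmarks and the standard frame they define; the
    # published mean normals live in that frame and are mapped to image space
    labyrinth_base = {"left": _LABYRINTH_LEFT.copy()}
    labyrinth_base["right"] = labyrinth_base["left"].copy()
    labyrinth_base["right"][0] = 2 * mirror_x - labyrinth_base["right"][0]
    eye_base = {"left": EyeSpec(center=_EYE_LEFT.center.copy(), radius=_EYE_LEFT.radius)}
    eye_base["right"] = EyeSpec(center=_EYE_LEFT.center.copy(), radius=_EYE_LEFT.radius)
    eye_base["right"].center[0] = 2 * mirror_x - eye_base["right"].center[0]
    crus_base = {s: labyrinth_base[s] + np.array([0.0, -1.0, 5.0]) for s in SIDES}
    fundus0, _ = _support_plane_truth(crus_base["left"], crus_base["right"], eye_base)
    frame0 = build_frame(crus_base["left"], crus_base["right"], fundus0)

    sides: dict[str, SideSpec] = {}
    eyes: dict[str, EyeSpec] = {}
    for side, lat_sign in (("left", -1.0), ("right", 1.0)):
        rot = _small_rotation(rng, jitter_deg)
        shift = rng.normal(scale=jitter_mm, size=3)
        normals = {c: _unit(rot @ from_standard(n, frame0))
                   for c, n in _BASE_NORMALS_STD[side].items()}
        sides[side] = _build_side(side, labyrinth_base[side] + shift, normals, lat_sign)
        eyes[side] = EyeSpec(
            center=eye_base[side].center + rng.normal(scale=jitter_mm, size=3),
            radius=eye_base[side].radius + rng.normal(scale=0.1))

    spec = PhantomSpec(sides=sides, eyes=eyes, noise_p=noise_p, seed=seed,
                       mirror_x=mirror_x)
    spec.validate()
    return spec


def mirror_spec(spec: PhantomSpec) -> PhantomSpec:
    """Reflect the phantom across the mid-sagittal plane, swapping sides."""
    mx = spec.mirror_x

    def rp(p: np.ndarray) -> np.ndarray:          # reflect point
        q = np.asarray(p, float).copy()
        q[0] = 2 * mx - q[0]
        return q

    def rv(v: np.ndarray) -> np.ndarray:          # reflect vector
        q = np.asarray(v, float).copy()
        q[0] = -q[0]
        return q

    other = {"left": "right", "right": "left"}
    sides = {}
    for side, s in spec.sides.items():
        canals = {
            c: CanalArcSpec(canal=a.canal, normal=rv(a.normal), center=rp(a.center),
                            radius=a.radius, tube_radius=a.tube_radius,
                            span_deg=a.span_deg, e1=rv(a.e1),
                            orientation=-a.orientation,
                            ampulla_radius=a.ampulla_radius)
            for c, a in s.canals.items()
        }
        sides[other[side]] = SideSpec(side=other[side], canals=canals,
                                      crus_top=rp(s.crus_top),
                                      vestibule=rp(s.vestibule),
                                      crus_bottom=rp(s.crus_bottom),
                                      crus_radius=s.crus_radius)
    eyes = {other[k]: EyeSpec(center=rp(e.center), radius=e.radius)
            for k, e in spec.eyes.items()}
    return PhantomSpec(sides=sides, eyes=eyes, shape=spec.shape,
                       spacing=spec.spacing, noise_p=spec.noise_p,
                       seed=spec.seed, mirror_x=spec.mirror_x)


# ---------------------------------------------------------------------------
# rasterization

def _grid_block(shape, spacing, lo_mm, hi_mm):
    """Index slices and physical coordinates of a bounding box, or None."""
    lo = np.maximum(np.floor(np.asarray(lo_mm) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil(np.asarray(hi_mm) / spacing).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return None
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    axes = [np.arange(a, b) * s for (a, b), s in zip(zip(lo, hi), spacing)]
    P = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return sl, P


def _check_inside(name: str, lo_mm, hi_mm, shape, spacing) -> None:
    extent = (np.asarray(shape) - 1) * np.asarray(spacing)
    if np.any(np.asarray(lo_mm) < 0) or np.any(np.asarray(hi_mm) > extent):
        raise ValueError(f"solid {name!r} exceeds the grid "
                         f"(bounds {lo_mm}..{hi_mm}, extent {extent})")


def rasterize_arc_tube(mask: np.ndarray, arc: CanalArcSpec,
                       spacing: np.ndarray, name: str = "arc") -> None:
    """OR a swept-arc tube (with rounded end caps) into ``mask`` in place."""
    pad = arc.radius + arc.tube_radius
    lo = arc.center - pad
    hi = arc.center + pad
    _check_inside(name, lo, hi, mask.shape, spacing)
    block = _grid_block(mask.shape, spacing, lo, hi)
    if block is None:
        return
    sl, P = block
    q = P - arc.center
    a = q @ arc.normal
    qp = q - np.multiply.outer(a, arc.normal)
    rho = np.linalg.norm(qp, axis=-1)
    d_circle = np.hypot(rho - arc.radius, a)
    with np.errstate(invalid="ignore"):
        theta = np.rad2deg(np.arctan2(arc.orientation * (qp @ arc.e2), qp @ arc.e1))
    theta = np.mod(theta, 360.0)
    in_span = theta <= arc.span_deg
    inside = (d_circle <= arc.tube_radius) & in_span
    for end in (0.0, arc.span_deg):
        p_end = arc.point_at(end)
        inside |= np.linalg.norm(P - p_end, axis=-1) <= arc.tube_radius
    mask[sl] |= inside


def _rasterize_sphere(mask, center, radius, spacing, name):
    center = np.asarray(center, float)
    _check_inside(name, center - radius, center + radius, mask.shape, spacing)
    block = _grid_block(mask.shape, spacing, center - radius, center + radius)
    if block is None:
        return
    sl, P = block
    mask[sl] |= np.linalg.norm(P - center, axis=-1) <= radius


def _rasterize_capsule(mask, p0, p1, radius, spacing, name):
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    _check_inside(name, lo, hi, mask.shape, spacing)
    block = _grid_block(mask.shape, spacing, lo, hi)
    if block is None:
        return
    sl, P = block
    d = p1 - p0
    L2 = float(d @ d)
    t = np.clip(((P - p0) @ d) / L2, 0.0, 1.0) if L2 > 0 else np.zeros(P.shape[:-1])
    closest = p0 + np.multiply.outer(t, d)
    mask[sl] |= np.linalg.norm(P - closest, axis=-1) <= radius


def _flip_boundary(mask: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Flip voxels within one voxel of the surface with probability p."""
    st = np.ones((3, 3, 3), dtype=bool)
    inner = mask & ~ndimage.binary_erosion(mask, structure=st)
    outer = ndimage.binary_dilation(mask, structure=st) & ~mask
    band = inner | outer
    flips = band & (rng.random(mask.shape) < p)
    return mask ^ flips


def _support_plane_truth(crus_l: np.ndarray, crus_r: np.ndarray,
                         eyes: dict[str, EyeSpec]) -> tuple[np.ndarray, np.ndarray]:
    """Analytic supporting plane through the crus-top line under both eyes.

    Returns (tangency point, superior unit normal): of the pencil of
    planes containing the crus line, the most horizontal plane with both
    eyeballs entirely on its superior side.
    """
    A = np.asarray(crus_l, float)
    d = _unit(np.asarray(crus_r, float) - A)
    w = _unit(_perp_component(np.array([0.0, 0.0, 1.0]), d))
    u = np.cross(d, w)

    centers = [e.center for e in eyes.values()]
    radii = [e.radius for e in eyes.values()]

    def n_of(phi):
        return np.cos(phi) * w + np.sin(phi) * u

    def g(phi):
        n = n_of(phi)
        return min(float(n @ (c - A)) - r for c, r in zip(centers, radii))

    phis = np.linspace(-1.2, 1.2, 4001)
    vals = np.array([g(p) for p in phis])
    roots = []
    for i in range(len(phis) - 1):
        if vals[i] == 0.0:
            roots.append(phis[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, phis[i], phis[i + 1], xtol=1e-12))
    if not roots:
        raise RuntimeError("no supporting plane found for the eye spheres")
    # the most horizontal supporting plane is the anatomical lateral plane
    phi = max(roots, key=lambda p: n_of(p)[2])
    n = n_of(phi)
    i = int(np.argmin([float(n @ (c - A)) - r for c, r in zip(centers, radii)]))
    point = centers[i] - radii[i] * n
    return point, n


def build_phantom(spec: PhantomSpec,
                  labels: dict[str, int] | None = None) -> tuple[LabelVolume, PhantomTruth]:
    """Rasterize the phantom into a label volume and return its ground truth."""
    spec.validate()
    labels = dict(labels or DEFAULT_LABEL_MAP)
    spacing = np.asarray(spec.spacing, dtype=float)
    shape = tuple(spec.shape)

    masks: dict[str, np.ndarray] = {}
    for side in SIDES:
        s = spec.sides[side]
        m = np.zeros(shape, dtype=bool)
        for c in CANALS:
            arc = s.canals[c]
            rasterize_arc_tube(m, arc, spacing, name=f"{side} {c} canal")
            _rasterize_sphere(m, arc.point_at(arc.span_deg), arc.ampulla_radius,
                              spacing, name=f"{side} {c} ampulla")
        _rasterize_capsule(m, s.vestibule, s.crus_top, s.crus_radius,
                           spacing, name=f"{side} common crus")
        _rasterize_capsule(m, s.crus_bottom, s.vestibule, s.crus_radius,
                           spacing, name=f"{side} vestibule stub")
        masks[f"canal_{side}"] = m
        e = spec.eyes[side]
        em = np.zeros(shape, dtype=bool)
        _rasterize_sphere(em, e.center, e.radius, spacing, name=f"{side} eyeball")
        masks[f"eye_{side}"] = em

    if masks["canal_left"].sum() and (masks["canal_left"] & masks["canal_right"]).any():
        raise ValueError("left and right canal solids overlap")

    if spec.noise_p > 0:
        rng = np.random.default_rng(spec.seed)
        for key in list(masks):
            masks[key] = _flip_boundary(masks[key], spec.noise_p, rng)

    array = np.zeros(shape, dtype=np.int16)
    for role in ("canal_left", "canal_right", "eye_left", "eye_right"):
        array[(array == 0) & masks[role]] = labels[role]

    volume = LabelVolume(array=array, spacing=tuple(spacing), labels=labels)
    fundus_point, fundus_normal = _support_plane_truth(
        spec.sides["left"].crus_top, spec.sides["right"].crus_top, spec.eyes)
    truth = PhantomTruth(
        normals={s: {c: spec.sides[s].canals[c].normal.copy() for c in CANALS}
                 for s in SIDES},
        centers={s: {c: spec.sides[s].canals[c].center.copy() for c in CANALS}
                 for s in SIDES},
        crus_tops={s: spec.sides[s].crus_top.copy() for s in SIDES},
        fundus_point=fundus_point,
        fundus_normal=fundus_normal,
    )
    return volume, truth


def eyeball_mask(volume: LabelVolume) -> BinaryMask:
    """Pooled mask of both eyeballs (used for the reference frame)."""
    arr = np.zeros(volume.array.shape, dtype=bool)
    for role in ("eye_left", "eye_right"):
        if role in volume.labels:
            arr |= volume.array == volume.labels[role]
    if not arr.any():
        raise ValueError("volume contains no eyeball voxels")
    return BinaryMask(array=arr, spacing=volume.spacing)
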