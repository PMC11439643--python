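"""B-spline centerline fitting, curvature/torsion, and ampulla trimming.

A smoothing B-spline is fitted to each ordered canal path; curvature

    kappa = ||r' x r''|| / ||r'||^3

and torsion

    tau = (r' x r'') . r''' / ||r' x r''||^2

are evaluated at uniform parameters.  Points whose curvature or torsion
z-score exceeds 2 SD are anomalous — in real canals these concentrate at
the ampulla and junction ends of the centerline — and are removed before
plane fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import splev, splprep

from .centerline_topology import CanalPath

#: guard for the torsion denominator ||r' x r''||^2 (mm^3 scale)
STRAIGHT_EPS = 1e-12


class OverTrimmedError(RuntimeError):
    """Raised when outlier removal would discard too much of a centerline."""


@dataclass
class SplineModel:
    """Parametric B-spline curve p(u) = sum_i P_i B_{i,k}(u), u in [0, 1]."""

    tck: tuple                    # (knots, coefficients, order) from splprep
    u: np.ndarray                 # parameter value of each input point
    k: int
    s: float

    @property
    def control_points(self) -> np.ndarray:
        return np.asarray(self.tck[1]).T

    def evaluate(self, t: np.ndarray | float, der: int = 0) -> np.ndarray:
        """Curve (or derivative) values at parameters t, shape (n, 3)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.stack(splev(t, self.tck, der=der), axis=-1)


@dataclass
class GeometryProfile:
    """Sampled differential geometry of a spline curve."""

    t: np.ndarray
    position: np.ndarray
    kappa: np.ndarray             # >= 0, 1/mm
    tau: np.ndarray               # 1/mm
    straight: np.ndarray          # bool: torsion undefined (near-zero cross)
    z_kappa: np.ndarray | None = None
    z_tau: np.ndarray | None = None
    keep: np.ndarray | None = None


def fit_bspline(path: CanalPath | np.ndarray, k: int = 3,
                s: float | None = None) -> SplineModel:
    """Fit an open B-spline to an ordered point sequence.

    Parameters
    ----------
    path:
        A :class:`CanalPath` or an (n, 3) array of ordered points (mm).
    k:
        Spline order (cubic by default).
    s:
        ``splprep`` smoothing factor in squared mm.  ``0`` interpolates
        every point exactly; ``None`` defaults to the number of points,
        a mild smoothing that suppresses voxel quantization noise in the
        derivatives.
    """
    pts = path.points if isinstance(path, CanalPath) else np.asarray(path, dtype=float)
    dup = np.all(np.isclose(np.diff(pts, axis=0), 0.0), axis=1)
    if dup.any():
        warnings.warn(f"removed {int(dup.sum())} duplicate consecutive points",
                      stacklevel=2)
        pts = pts[np.concatenate([[True], ~dup])]
    if len(pts) <= k:
        raise ValueError(f"need more than k={k} points, got {len(pts)}")
    if s is None:
        s = float(len(pts))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # splprep chatters about knot choice
        tck, u = splprep(list(pts.T), k=k, s=s)
    return SplineModel(tck=tck, u=np.asarray(u), k=k, s=float(s))


def geometry_profile(model: SplineModel, m: int = 200) -> GeometryProfile:
    """Curvature and torsion at ``m`` uniform parameters."""
    if m < 10:
        raise ValueError("need at least 10 samples")
    t = np.linspace(0.0, 1.0, m)
    r = model.evaluate(t, der=0)
    r1 = model.evaluate(t, der=1)
    r2 = model.evaluate(t, der=2)
    r3 = model.evaluate(t, der=3)
    cross = np.cross(r1, r2)
    ncross = np.linalg.norm(cross, axis=1)
    speed = np.linalg.norm(r1, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(speed > 0, ncross / speed**3, 0.0)
    straight = ncross**2 < STRAIGHT_EPS
    tau = np.zeros_like(kappa)
    good = ~straight
    tau[good] = np.einsum("ij,ij->i", cross[good], r3[good]) / ncross[good] ** 2
    return GeometryProfile(t=t, position=r, kappa=kappa, tau=tau, straight=straight)


def flag_outliers(profile: GeometryProfile, z_cut: float = 2.0,
                  edge_frac: float = 0.02,
                  sd_floor: float = 1e-3) -> GeometryProfile:
    """Z-score each series and flag samples beyond ``z_cut`` SD.

    The first and last ``edge_frac`` of the parameter range are excluded
    from the mean/SD estimates (spline end effects would dominate the
    statistics) but still receive z-scores and flags.  Each series is
    standardized separately.  A series whose spread falls below
    ``sd_floor`` (1/mm; well under the curvature/torsion variation of a
    real canal) carries no geometric information — e.g. the torsion of
    a planar centerline is numerical noise — and contributes no flags.
    """
    m = len(profile.t)
    if m < 10:
        raise ValueError("need at least 10 samples")
    edge = int(round(edge_frac * m))
    interior = slice(edge, m - edge) if edge else slice(None)

    def zscore(series: np.ndarray) -> np.ndarray:
        mu = series[interior].mean()
        sd = series[interior].std()  # population SD
        if sd <= sd_floor:
            return np.zeros_like(series)
        return (series - mu) / sd

    z_kappa = zscore(profile.kappa)
    z_tau = zscore(profile.tau)
    if not z_kappa.any() and not z_tau.any():
        warnings.warn("curvature and torsion are both constant; nothing flagged",
                      stacklevel=2)
    keep = ~((np.abs(z_kappa) > z_cut) | (np.abs(z_tau) > z_cut))
    return replace(profile, z_kappa=z_kappa, z_tau=z_tau, keep=keep)


def select_plane_points(path: CanalPath, profile: GeometryProfile,
                        model: SplineModel, min_keep_frac: float = 0.6) -> CanalPath:
    """Remove path points whose nearest curve sample is flagged.

    Plane fitting needs a contiguous arc, so of the surviving points the
    longest contiguous run is kept.  If fewer than ``min_keep_frac`` of
    the original points survive the path is considered over-trimmed:
    such canals need manual review rather than a silently bad fit.
    """
    if profile.keep is None:
        raise ValueError("profile has no keep flags; run flag_outliers first")
    m = len(profile.t)
    sample_of_point = np.clip(np.rint(model.u * (m - 1)).astype(int), 0, m - 1)
    point_keep = profile.keep[sample_of_point]
    if len(point_keep) != len(path.points):
        raise ValueError("profile/model not aligned with path")

    # longest contiguous kept run
    best_len, best_start = 0, 0
    run_start = None
    for i, k in enumerate(np.concatenate([point_keep, [False]])):
        if k and run_start is None:
            run_start = i
        elif not k and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len < max(5, min_keep_frac * len(path.points)):
        raise OverTrimmedError(
            f"{path.side} {path.canal}: only {best_len}/{len(path.points)} points "
            "survive outlier trimming; manual review needed")
    sel = slice(best_start, best_start + best_len)
    return CanalPath(side=path.side, canal=path.canal,
                     points=path.points[sel], indices=path.indices[sel],
                     end_classes=path.end_classes,
                     flags=path.flags + (["trimmed"] if best_len < len(path.points) else []))
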