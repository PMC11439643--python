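"""End-to-end orchestration: label volume -> subject attitude -> cohort."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import attitude as att
from . import centerline_topology as topo
from . import curve_geometry as geom
from . import reference_frame as rf
from .skeletonize import CenterlinePoints, skeletonize_mask
from .volume_io import DEFAULT_LABEL_MAP, BinaryMask, LabelVolume

log = logging.getLogger(__name__)

SIDES = ("left", "right")
CANALS = ("anterior", "posterior", "lateral")


@dataclass
class RunConfig:
    """Tunable pipeline parameters with their standard defaults."""

    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    adjacency_threshold: float = 2.0     # index units
    spline_order: int = 3
    smoothing: float | None = None       # None -> number of points
    sample_count: int = 200
    z_cut: float = 2.0                   # SD
    min_keep_frac: float = 0.6
    fit_mode: str = "global"             # or "windowed"
    window_frac: float = 1.0 / 3.0
    smooth_masks: bool = True            # 3x3x3 majority vote before thinning
    min_spur: int = 6                    # skeleton branches shorter than this
    min_component: int = 10              # skeleton components smaller than this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adjacency_threshold <= 0:
            raise ValueError("adjacency_threshold must be positive")
        if self.spline_order < 1:
            raise ValueError("spline_order must be >= 1")
        if self.sample_count < 10:
            raise ValueError("sample_count must be >= 10")
        if self.z_cut <= 0:
            raise ValueError("z_cut must be positive")
        if not (0.0 < self.min_keep_frac <= 1.0):
            raise ValueError("min_keep_frac must be in (0, 1]")
        if self.fit_mode not in ("windowed", "global"):
            raise ValueError("fit_mode must be 'windowed' or 'global'")
        if not (0.0 < self.window_frac <= 1.0):
            raise ValueError("window_frac must be in (0, 1]")


@dataclass
class SubjectResult:
    subject_id: str
    frame: rf.ReferenceFrame
    attitudes: dict[tuple[str, str], att.CanalAttitude]
    qc_flags: dict[str, list[str]]

    def clean(self, side: str, canal: str) -> bool:
        key = f"{side}_{canal}"
        return (side, canal) in self.attitudes and not self.qc_flags.get(key)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "subject_id": self.subject_id,
            "frame": {"origin": self.frame.origin.tolist(),
                      "X": self.frame.X.tolist(), "Y": self.frame.Y.tolist(),
                      "Z": self.frame.Z.tolist(),
                      "handedness": self.frame.handedness},
            "attitudes": {
                f"{s}_{c}": {
                    "normal_standard": a.normal.tolist(),
                    "normal_image": a.normal_image.tolist(),
                    "direction_angles_deg": list(a.direction_angles),
                    "n_points": a.n_points,
                    "rms_distance_mm": a.rms_distance,
                }
                for (s, c), a in sorted(self.attitudes.items())
            },
            "qc_flags": {k: v for k, v in sorted(self.qc_flags.items()) if v},
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _skeletonize_canonical(mask: BinaryMask, flip: bool) -> CenterlinePoints:
    """Thin a one-side mask, optionally in mirrored (left) chirality."""
    if not flip:
        return skeletonize_mask(mask)
    flipped = BinaryMask(array=mask.array[::-1].copy(), spacing=mask.spacing)
    sk = skeletonize_mask(flipped)
    idx = sk.indices.copy()
    idx[:, 0] = mask.array.shape[0] - 1 - idx[:, 0]
    return CenterlinePoints(indices=idx, spacing=mask.spacing)


def _majority_smooth(arr: np.ndarray) -> np.ndarray:
    """3x3x3 majority vote: removes salt-and-pepper segmentation noise."""
    from scipy import ndimage
    counts = ndimage.uniform_filter(arr.astype(np.float32), size=3)
    return counts > 0.5


def _combined_canal_mask(volume: LabelVolume, smooth: bool) -> BinaryMask:
    arr = np.zeros(volume.array.shape, dtype=bool)
    found = False
    for role in ("canal_left", "canal_right"):
        if role in volume.labels:
            m = volume.array == volume.labels[role]
            if m.any():
                arr |= m
                found = True
    if not found:
        raise ValueError("volume contains no canal voxels")
    if smooth:
        arr = _majority_smooth(arr)
    return BinaryMask(array=arr, spacing=volume.spacing)


def _pooled_eye_mask(volume: LabelVolume, qc: dict[str, list[str]],
                     smooth: bool = True) -> BinaryMask:
    arr = np.zeros(volume.array.shape, dtype=bool)
    for role in ("eye_left", "eye_right"):
        m = volume.array == volume.labels.get(role, -1)
        if m.any():
            arr |= m
        else:
            qc.setdefault("frame", []).append(f"missing {role}")
    if not arr.any():
        raise ValueError("volume contains no eyeball voxels")
    if smooth:
        arr = _majority_smooth(arr)
    return BinaryMask(array=arr, spacing=volume.spacing)


def _measure_canal(path: topo.CanalPath, frame: rf.ReferenceFrame,
                   config: RunConfig) -> att.CanalAttitude:
    """Trim one canal path and fit its oriented plane normal."""
    model = geom.fit_bspline(path, k=config.spline_order, s=config.smoothing)
    profile = geom.flag_outliers(geom.geometry_profile(model, m=config.sample_count),
                                 z_cut=config.z_cut)
    trimmed = geom.select_plane_points(path, profile, model,
                                       min_keep_frac=config.min_keep_frac)
    global_fit = att.fit_plane_svd(trimmed.points)
    if config.fit_mode == "windowed":
        window = max(5, int(round(config.window_frac * len(trimmed.points))))
        normals_img = att.local_plane_normals(trimmed.points, window=window)
    else:
        normals_img = [global_fit.normal]
    normals_std = [rf.to_standard(n, frame) for n in normals_img]
    normals_std[0] = att.orient_normal(normals_std[0], path.side, path.canal)
    for i in range(1, len(normals_std)):
        if np.dot(normals_std[i], normals_std[0]) < 0:
            normals_std[i] = -normals_std[i]
    v_avg = att.orient_normal(att.average_unit_normals(normals_std),
                              path.side, path.canal)
    return att.CanalAttitude(
        side=path.side, canal=path.canal, normal=v_avg,
        normal_image=rf.from_standard(v_avg, frame),
        direction_angles=att.direction_angles(v_avg),
        n_points=len(trimmed.points), rms_distance=global_fit.rms_distance)


def extract_canal_paths(volume: LabelVolume, config: RunConfig | None = None
                        ) -> tuple[dict[tuple[str, str], topo.CanalPath],
                                   dict[str, np.ndarray], dict[str, list[str]]]:
    """Skeletonize, split sides, trace the six canal paths and crus tops."""
    config = config or RunConfig()
    qc: dict[str, list[str]] = {}
    mask = _combined_canal_mask(volume, config.smooth_masks)
    # split at the center of mass along the left-right axis; each side is
    # thinned in left chirality (the right side mirrored in, and back out)
    # so the measurement is exactly equivariant under reflection -- 3D
    # parallel thinning itself is not mirror-symmetric
    xs = np.nonzero(mask.array.any(axis=(1, 2)))[0]
    cx = np.argwhere(mask.array)[:, 0].mean()
    if xs.min() >= cx or xs.max() < cx:
        raise ValueError("unilateral input: canal mask does not span both sides")
    paths: dict[tuple[str, str], topo.CanalPath] = {}
    crus_tops: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        arr = mask.array.copy()
        if side == "left":
            arr[int(np.ceil(cx)):] = False
        else:
            arr[:int(np.ceil(cx))] = False
        side_pts = _skeletonize_canonical(BinaryMask(array=arr, spacing=mask.spacing),
                                          flip=(side == "right"))
        pts, graph, classes = topo.prune_skeleton(
            side_pts, threshold=config.adjacency_threshold,
            min_spur=config.min_spur, min_component=config.min_component)
        crus_tops[side] = topo.identify_common_crus_top(pts, classes)
        poles = topo.find_canal_poles(pts, classes, side)
        for canal, pole in poles.items():
            key = f"{side}_{canal}"
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pole = topo.snap_to_ordinary(pole, graph, classes, pts)
                paths[(side, canal)] = topo.trace_from_pole(
                    pole, graph, classes, pts, side, canal)
            except (ValueError, RuntimeError) as exc:
                qc.setdefault(key, []).append(f"trace failed: {exc}")
    return paths, crus_tops, qc


def measure_subject(volume: LabelVolume, config: RunConfig | None = None,
                    subject_id: str = "subject") -> SubjectResult:
    """Full measurement of one subject's label volume.

    Stages: skeletonize -> classify/trace -> reference frame ->
    spline trimming -> SVD plane fit -> oriented attitude, for all six
    canals.  Deterministic given (volume, config).  Stage failures for
    individual canals are recorded as QC flags; only a failed reference
    frame aborts the subject.
    """
    config = config or RunConfig()
    paths, crus_tops, qc = extract_canal_paths(volume, config)

    eyes = _pooled_eye_mask(volume, qc, smooth=config.smooth_masks)
    plane = rf.initial_lateral_plane(crus_tops["left"], crus_tops["right"], eyes)
    fundus, _ = rf.refine_fundus_point(plane, eyes, crus_tops["left"],
                                       crus_tops["right"])
    frame = rf.build_frame(crus_tops["left"], crus_tops["right"], fundus)

    attitudes: dict[tuple[str, str], att.CanalAttitude] = {}
    for (side, canal), path in paths.items():
        key = f"{side}_{canal}"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                attitudes[(side, canal)] = _measure_canal(path, frame, config)
        except geom.OverTrimmedError as exc:
            qc.setdefault(key, []).append(f"over-trimmed: {exc}")
        except (ValueError, RuntimeError) as exc:
            qc.setdefault(key, []).append(f"attitude failed: {exc}")
    return SubjectResult(subject_id=subject_id, frame=frame,
                         attitudes=attitudes, qc_flags=qc)


def aggregate_subjects(results: list[SubjectResult]) -> att.CohortSummary:
    """Cohort aggregate: V_avg per canal, deviation stats, dihedral table.

    The dihedral table is reported twice: as the mean of per-subject
    dihedral angles and as the angle between the cohort mean normals
    (the two differ once normals vary across subjects).
    """
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for res in results:
        for (side, canal), a in res.attitudes.items():
            if res.clean(side, canal):
                groups.setdefault((side, canal), []).append(a.normal)

    mean_normals, deviation, n_subjects = {}, {}, {}
    for key, normals in groups.items():
        v = att.average_unit_normals(normals)
        mean_normals[key] = v
        deviation[key] = att.deviation_stats(normals, v)
        n_subjects[key] = len(normals)
    missing = [k for s in SIDES for c in CANALS if (k := (s, c)) not in mean_normals]
    for key in missing:
        warnings.warn(f"no usable subjects for {key[0]} {key[1]}; canal omitted",
                      stacklevel=2)

    pair_keys = list(combinations([(s, c) for s in SIDES for c in CANALS], 2))
    dihedral_subj: dict[tuple, float] = {}
    dihedral_mean: dict[tuple, float] = {}
    for ka, kb in pair_keys:
        per_subject = [
            att.dihedral_angle(r.attitudes[ka].normal, r.attitudes[kb].normal)
            for r in results
            if r.clean(*ka) and r.clean(*kb)
        ]
        if per_subject:
            dihedral_subj[(ka, kb)] = float(np.mean(per_subject))
        if ka in mean_normals and kb in mean_normals:
            dihedral_mean[(ka, kb)] = att.dihedral_angle(mean_normals[ka],
                                                         mean_normals[kb])
    return att.CohortSummary(mean_normals=mean_normals, deviation=deviation,
                             dihedral_mean_of_subjects=dihedral_subj,
                             dihedral_of_mean_normals=dihedral_mean,
                             n_subjects=n_subjects)


def write_cohort_tables(summary: att.CohortSummary, out_dir: str | Path) -> list[Path]:
    """CSV exports: mean normals, dihedral angles, deviation statistics."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    rows = [{"side": s, "canal": c, "X": v[0], "Y": v[1], "Z": v[2],
             "n_subjects": summary.n_subjects.get((s, c), 0)}
            for (s, c), v in sorted(summary.mean_normals.items())]
    p = out_dir / "cohort_normals.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)

    def tag(key):
        side, canal = key
        return f"{side.capitalize()}_{canal[0].upper()}"

    rows = [{"plane_1": tag(ka), "plane_2": tag(kb),
             "dihedral_deg_mean_of_subjects": round(v, 2),
             "dihedral_deg_of_mean_normals":
                 round(summary.dihedral_of_mean_normals.get((ka, kb), np.nan), 2)}
            for (ka, kb), v in summary.dihedral_mean_of_subjects.items()]
    p = out_dir / "cohort_dihedral.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)

    rows = [{"normal_vector": tag(k), "mean_deg": round(m, 2), "sd_deg": round(sd, 2)}
            for k, (m, sd) in sorted(summary.deviation.items())]
    p = out_dir / "cohort_deviation.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)
    return written
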