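"""Label-volume I/O, structure masks and segmentation overlap.

Volumes are kept in a fixed anatomical axis convention: array axis ``i``
runs left->right, axis ``j`` posterior->anterior and axis ``k``
inferior->superior (RAS+).  NIfTI files are re-oriented to this
convention on load using the affine in the header, so downstream
geometry never depends on scanner orientation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

#: Structure roles understood by the pipeline.
ROLES = ("canal_left", "canal_right", "eye_left", "eye_right")

#: Default label-value map; configurable because label conventions vary
#: between annotation projects.
DEFAULT_LABEL_MAP = {
    "canal_left": 1,
    "canal_right": 2,
    "eye_left": 3,
    "eye_right": 4,
}


class VolumeFormatError(ValueError):
    """Raised when a file is not a usable 3D integer label volume."""


@dataclass
class LabelVolume:
    """A 3D integer label grid with physical voxel spacing in mm.

    Attributes
    ----------
    array:
        Non-negative integer labels, index order (i, j, k) with the RAS+
        axis convention described in the module docstring.
    spacing:
        Physical step per axis in mm, strictly positive.
    labels:
        Map from structure role to the integer label value used for it.
    """

    array: np.ndarray
    spacing: tuple[float, float, float]
    labels: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise VolumeFormatError(f"expected a 3D array, got ndim={self.array.ndim}")
        if not np.issubdtype(self.array.dtype, np.integer):
            raise VolumeFormatError(f"label array must be integer, got {self.array.dtype}")
        if self.array.size and self.array.min() < 0:
            raise VolumeFormatError("label values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        values = list(self.labels.values())
        if len(set(values)) != len(values):
            raise ValueError("two roles share the same label value")

    def missing_roles(self) -> list[str]:
        """Roles whose declared label value does not occur in the array."""
        present = set(np.unique(self.array).tolist())
        return [r for r, v in self.labels.items() if v not in present]


@dataclass
class BinaryMask:
    """A boolean voxel grid with its physical spacing in mm."""

    array: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=bool)
        if self.array.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def count(self) -> int:
        return int(self.array.sum())


def read_label_volume(path: str | Path, labels: dict[str, int] | None = None) -> LabelVolume:
    """Read a NIfTI label volume and re-orient it to the RAS+ convention.

    Parameters
    ----------
    path:
        A ``.nii`` or ``.nii.gz`` file.
    labels:
        Role -> label-value map; defaults to :data:`DEFAULT_LABEL_MAP`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for corrupt files
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)  # RAS+ == our axis convention
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D data, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise VolumeFormatError(f"{path}: voxel values are not integers")
        data = rounded.astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(array=data, spacing=spacing, labels=dict(labels or DEFAULT_LABEL_MAP))


def write_label_volume(volume: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as NIfTI with the spacing encoded in the affine."""
    path = Path(path)
    if not np.any(volume.array):
        warnings.warn(f"writing an all-zero label volume to {path}", stacklevel=2)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.array, dtype=np.int16), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def extract_structure_mask(volume: LabelVolume, role: str) -> BinaryMask:
    """Binary mask of one structure role; errors if the role has no voxels."""
    if role not in volume.labels:
        raise KeyError(f"role {role!r} not in label map {sorted(volume.labels)}")
    value = volume.labels[role]
    arr = volume.array == value
    if not arr.any():
        raise ValueError(f"role {role!r} (label {value}) has no voxels in this volume")
    return BinaryMask(array=arr, spacing=volume.spacing)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient, 2|X∩Y| / (|X|+|Y|).

    Defined only when at least one mask is non-empty; two empty masks
    raise instead of silently reporting perfect overlap.
    """
    if a.array.shape != b.array.shape:
        raise ValueError(f"shape mismatch: {a.array.shape} vs {b.array.shape}")
    na, nb = a.count, b.count
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int(np.logical_and(a.array, b.array).sum())
    return 2.0 * inter / (na + nb)


def load_label_map(path: str | Path) -> dict[str, int]:
    """Load a role -> label-value map from a JSON config file."""
    with open(path) as fh:
        raw = json.load(fh)
    unknown = set(raw) - set(ROLES)
    if unknown:
        raise ValueError(f"unknown roles in label map: {sorted(unknown)}")
    return {k: int(v) for k, v in raw.items()}
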