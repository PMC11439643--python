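"""3D thinning of binary canal masks to one-voxel-wide centerlines."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize

from .volume_io import BinaryMask


@dataclass
class CenterlinePoints:
    """Skeleton voxels of a mask with their physical coordinates.

    ``indices`` are integer (i, j, k) voxel triples; ``physical`` is the
    same set scaled componentwise by the voxel spacing, in mm.  Geometry
    downstream of the thinning step always works in physical space so
    that anisotropic spacing is honoured.
    """

    indices: np.ndarray                  # (n, 3) int
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices)
        if self.indices.ndim != 2 or self.indices.shape[1] != 3:
            raise ValueError("indices must be an (n, 3) array")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def physical(self) -> np.ndarray:
        """Physical coordinates in mm, indices scaled by spacing."""
        return self.indices * np.asarray(self.spacing)

    def __len__(self) -> int:
        return len(self.indices)

    def subset(self, sel: np.ndarray) -> "CenterlinePoints":
        return CenterlinePoints(indices=self.indices[sel], spacing=self.spacing)


def skeletonize_mask(mask: BinaryMask) -> CenterlinePoints:
    """Thin a binary mask to its voxel centerline.

    Uses connectivity-preserving 3D thinning in index space (the
    adjacency threshold downstream is stated in index units); physical
    coordinates are attached afterwards.
    """
    if not mask.array.any():
        raise ValueError("cannot skeletonize an empty mask")
    sk = _skimage_skeletonize(mask.array)
    return CenterlinePoints(indices=np.argwhere(sk), spacing=mask.spacing)


def to_physical(points: CenterlinePoints) -> np.ndarray:
    """Physical mm coordinates of the skeleton points."""
    return points.physical


def to_indices(physical: np.ndarray, spacing) -> np.ndarray:
    """Invert :func:`to_physical` (exact for points produced by it)."""
    return np.rint(np.asarray(physical) / np.asarray(spacing)).astype(int)
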