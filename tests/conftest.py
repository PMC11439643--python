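"""Shared fixtures: the default phantom and its full-pipeline measurement.

The expensive artefacts (rasterized volumes, measured subjects) are
session-scoped; everything is generated programmatically at test time.
"""

from __future__ import annotations

import numpy as np
import pytest

from canalpose import phantom as ph
from canalpose.pipeline import measure_subject


@pytest.fixture(scope="session")
def default_phantom():
    """(spec, volume, truth) for the noise-free default phantom, seed 0."""
    spec = ph.default_spec(seed=0)
    volume, truth = ph.build_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def measured_default(default_phantom):
    """SubjectResult of the full pipeline on the default phantom."""
    _, volume, _ = default_phantom
    return measure_subject(volume, subject_id="phantom-seed0")


@pytest.fixture(scope="session")
def mirrored_pair(default_phantom):
    """Measurements of the default phantom and its mirror image."""
    spec, volume, truth = default_phantom
    mspec = ph.mirror_spec(spec)
    mvolume, mtruth = ph.build_phantom(mspec)
    return (measure_subject(volume, subject_id="orig"),
            measure_subject(mvolume, subject_id="mirrored"),
            truth, mtruth)


def angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Unsigned angle between two directions (sign-insensitive), degrees."""
    c = abs(float(np.dot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.degrees(np.arccos(min(c, 1.0))))
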