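"""Shared fixtures: small synthetic cohorts and hand-built frames."""

import numpy as np
import pytest

import facekin as fk
from facekin.landmarks import MeshFrame, detector_to_world
from facekin.synthdata import NEUTRAL_FACE


def neutral_mesh_frame(time_s: float = 0.0, scale: float = 1.0,
                       rotation: np.ndarray | None = None,
                       translation: np.ndarray | None = None) -> MeshFrame:
    """A mesh frame of the neutral synthetic face, optionally rigidly moved."""
    R = np.eye(3) if rotation is None else np.asarray(rotation)
    t = np.zeros(3) if translation is None else np.asarray(translation)
    pts = {
        mid: R @ (scale * np.asarray(p)) + t for mid, p in NEUTRAL_FACE.items()
    }
    return MeshFrame(time_s=time_s, points=pts)


@pytest.fixture(scope="session")
def neutral_frame():
    return neutral_mesh_frame()


@pytest.fixture(scope="session")
def neutral_clinical():
    return fk.to_canonical(neutral_mesh_frame())


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """4 participants x 20 words with default noise, written to disk."""
    cohort = fk.generate_cohort(4, seed=11)
    paths = cohort.write(tmp_path_factory.mktemp("cohort"))
    return cohort, paths


@pytest.fixture(scope="session")
def small_recordings(small_cohort):
    _, paths = small_cohort
    return fk.load_recordings(paths["landmarks"], paths["timings"])


@pytest.fixture(scope="session")
def small_store(small_recordings):
    return fk.extract_traces(small_recordings, refine=False)
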