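"""Shared fixtures: canned synthetic scenes and pipeline runs.

The expensive multi-temporal pipeline on the standard 120x120 scene is run
once per session and shared by every test that inspects its stages.
"""

from __future__ import annotations

import numpy as np
import pytest

import polsarseg as ps
from polsarseg.pipeline import combine_and_cut, per_date_stages
from polsarseg.synthetic import canned_params


@pytest.fixture(scope="session")
def canned_scene():
    """Standard 3-date, 120x120, 16-parcel, 4-look scene (seed 1)."""
    spec = ps.canned_scene(seed=1)
    images, truth = ps.generate_timeseries(spec)
    return spec, images, truth


@pytest.fixture(scope="session")
def canned_stages(canned_scene):
    """Per-date over-segmentations and thinned edge maps for the canned scene."""
    _, images, _ = canned_scene
    params = canned_params(k=16, seed=0)
    return [per_date_stages(img, params) for img in images], params


@pytest.fixture(scope="session")
def canned_result(canned_stages):
    """Full multi-temporal pipeline result on the canned scene."""
    stages, params = canned_stages
    return combine_and_cut([s[0] for s in stages], [s[1] for s in stages], params)


@pytest.fixture(scope="session")
def small_scene():
    """Cheap 48x48, 2x2-parcel, 2-date scene for end-to-end determinism tests."""
    spec = ps.canned_scene(seed=7, height=48, width=48, parcels=(2, 2),
                               n_dates=2)
    images, truth = ps.generate_timeseries(spec)
    return spec, images, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_pd_matrix(rng, scale=1.0):
    """Random 3x3 Hermitian positive-definite matrix."""
    a = rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))
    return scale * (a @ a.conj().T + 0.1 * np.eye(3))
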