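"""Shared fixtures: tiny device profile for fast unit tests and one
session-scoped synthetic cohort reused by the end-to-end analyses."""

import numpy as np
import pytest
from hypothesis import settings

from gaseg import DeviceProfile, SPECTRALIS_SMALL, SyntheticParams, generate_cohort
from gaseg.profiles import register_profile

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


#: miniature protocol for unit tests: everything runs in milliseconds
TINY = DeviceProfile(
    name="tiny",
    fov_mm=(6.0, 6.0),
    native_dims=(40, 16, 8),
    net_input_dims=(8, 16, 8),
    mask_dims=(16, 8),
    quality_min=25.0,
    has_nir=True,
)
register_profile(TINY)


@pytest.fixture(scope="session")
def tiny_profile():
    return TINY


@pytest.fixture(scope="session")
def study_cohort(tmp_path_factory):
    """The scaled-down longitudinal GA cohort used by the end-to-end tests:
    20 subjects x 1 eye x 3 visits, moderate speckle, 30 % nAMD."""
    out = tmp_path_factory.mktemp("cohort")
    params = SyntheticParams(
        device=SPECTRALIS_SMALL,
        n_subjects=20,
        eyes_per_subject=1,
        visits_per_eye=3,
        speckle_sigma=0.2,
        namd_fraction=0.3,
        seed=101,
    )
    records = generate_cohort(params, out)
    return {"records": records, "dir": out, "params": params,
            "profile": SPECTRALIS_SMALL}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
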