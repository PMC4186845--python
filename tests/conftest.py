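"""Shared fixtures: small synthetic cohorts and preprocessed series.

Simulation studies in the tests run on a desk-scale grid (20 x 20 x 16
voxels of 2 mm, one 100-frame run) so the whole suite stays fast; the
generator's study-scale defaults are exercised separately where cheap.
"""

from __future__ import annotations

import numpy as np
import pytest

from restvar import CohortConfig, generate_cohort
from restvar.pipeline import preprocess_record

SMALL_GRID = (20, 20, 16)
#: variability-effect parcel used throughout the tests (left putamen)
EFFECT_LABEL = 3
#: connectivity seed/target parcels (left caudate -> right fusiform)
SEED_LABEL, TARGET_LABEL = 1, 6
#: coupling slope (score percent^-1) for connectivity-effect cohorts
COUPLING_SLOPE = 0.03


def small_config(seed: int = 0, **kw) -> CohortConfig:
    defaults = dict(
        n_subjects=10,
        grid_shape=SMALL_GRID,
        voxel_size=2.0,
        n_runs=1,
        n_timepoints_per_run=100,
        seed=seed,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def effect_cohort():
    """Ten subjects with a variability effect (target r = 0.9) in one parcel."""
    return generate_cohort(small_config(seed=7, effect_rois=((EFFECT_LABEL, 0.9),)))


@pytest.fixture(scope="session")
def null_cohort():
    """Ten subjects with no injected effects."""
    return generate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def preprocessed_effect(effect_cohort):
    return [preprocess_record(sub) for sub in effect_cohort]


@pytest.fixture(scope="session")
def preprocessed_null(null_cohort):
    return [preprocess_record(sub) for sub in null_cohort]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
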