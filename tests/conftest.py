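import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("morphnet").setLevel(logging.ERROR)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 10-region, 6-subject, 2-session cohort shared across tests."""
    from morphnet import synthetic

    spec = synthetic.SyntheticCohortSpec(
        n_regions=10,
        n_subjects=6,
        n_sessions=2,
        image_shape=(48, 32, 32),
        parcel_edge=5,
        n_families=5,
        seed=7,
    )
    atlas = synthetic.generate_atlas(spec)
    cohort = synthetic.generate_cohort(spec, atlas)
    return spec, atlas, cohort


@pytest.fixture(scope="session")
def small_matrices(small_cohort):
    from morphnet import similarity

    spec, atlas, cohort = small_cohort
    return {
        key: similarity.build_similarity_matrix(gm, atlas) for key, gm in cohort.items()
    }
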