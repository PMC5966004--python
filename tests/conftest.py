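import numpy as np
import pytest

from voxdose import (
    RunConfig,
    SyntheticCohortConfig,
    generate_cohort,
    load_default_registry,
)


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: 2 patients, 32^3 grid, a handful of lesions."""
    return SyntheticCohortConfig(
        n_patients=2,
        grid_shape=(32, 32, 32),
        mean_lesions_per_patient=4.0,
        lesion_count_bounds=(2, 6),
        semi_axis_range_vox=(2.0, 3.5),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
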