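import numpy as np
import pytest

from hapticrec.behavioral_prep import assemble_features, impute_plegic_pso, \
    to_zscores
from hapticrec.config import CohortConfig
from hapticrec.synthetic_cohort import generate_behavioral_cohort, \
    generate_control_reference, toy_tract_atlas


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_behavioral_cohort(default_config)


@pytest.fixture(scope="session")
def default_reference(default_config):
    return generate_control_reference(default_config)


@pytest.fixture(scope="session")
def impaired_zmatrix(default_cohort, default_reference):
    """Z-matrix restricted to the 14 impaired patients (the PCA cohort),
    together with their nine-month outcome and subgroup labels."""
    imputed = impute_plegic_pso(default_cohort)
    z = to_zscores(imputed, default_reference)
    impaired = imputed[imputed.subgroup.isin(["PTI", "RTI"])]
    zi = assemble_features(z, z.measures)
    zi.data = zi.data.loc[impaired.patient_id]
    return (zi, impaired["tor9"].to_numpy(float),
            impaired["subgroup"].to_numpy())


@pytest.fixture(scope="session")
def small_grid_config() -> CohortConfig:
    """Coarse 24^3 grid for voxel-level tests."""
    return CohortConfig(seed=3, grid_shape=(24, 24, 24))


@pytest.fixture(scope="session")
def small_atlas(small_grid_config):
    return toy_tract_atlas(small_grid_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
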