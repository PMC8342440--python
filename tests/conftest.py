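import numpy as np
import pytest

from lifespan_cca import synthdata as sd


@pytest.fixture(scope="session")
def small_cohort():
    """140-subject cohort with 5 dead and 3 outlier-carrying variables."""
    spec = sd.CohortSpec(
        n_subjects=140, n_behavior_vars=40, n_nodes=40,
        n_dead_vars=5, n_outlier_cells=3, seed=1,
    )
    return spec, sd.generate_cohort(spec)


@pytest.fixture(scope="session")
def planted():
    """Two-view cohort with planted cross-view rho 0.6 and age association 0.65."""
    D1, D2, ages, truth = sd.planted_axis_cohort(n_subjects=600, seed=11)
    return D1, D2, ages, truth


@pytest.fixture(scope="session")
def module_cohort():
    """Cohort whose only cross-domain coupling is linear in age, restricted
    to two behavior domains and two network modules."""
    return sd.module_coupled_cohort(n_subjects=400, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
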