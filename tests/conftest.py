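import numpy as np
import pytest

from astropair.synthetic_data import CohortSpec, simulate_cohort


def small_spec(seed: int = 1, **overrides) -> CohortSpec:
    """Reduced cohort for fast tests: same structure, smaller scale."""
    defaults = dict(
        n_patients=6,
        n_genes=600,
        n_chromosomes=8,
        progression_groups={"A2->A3": 2, "A2->G4": 2, "A3->G4": 2},
        n_subgroup_genes=50,
        n_signature_genes=20,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-scale simulated cohort shared across read-only tests."""
    return simulate_cohort(CohortSpec(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
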