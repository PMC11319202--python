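import numpy as np
import pytest

from regle.synthgen import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort shared by read-only tests (never mutated)."""
    cfg = SimConfig(
        n_individuals=800,
        n_variants=100,
        causal_per_factor=10,
        heritability_per_factor=0.3,
        corrupt_fraction=0.0,
        seed=101,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
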