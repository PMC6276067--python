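import numpy as np
import pytest

from mortset import GroundTruth, simulate_population_set, simulate_surface


@pytest.fixture(scope="session")
def noiseless_surface():
    """Deterministic rank-1 surface: rates exactly exp(alpha + beta kappa)."""
    return simulate_surface(GroundTruth(seed=1), deterministic=True)


@pytest.fixture(scope="session")
def noisy_surface():
    """Poisson-observed surface at exposure 1e5 (the default conditions)."""
    return simulate_surface(GroundTruth(seed=2))


@pytest.fixture(scope="session")
def popset():
    """Two correlated populations with a male/female-style gap."""
    return simulate_population_set(
        GroundTruth(seed=3, sex_gap=0.35), n_pops=2, cross_corr=0.8
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
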