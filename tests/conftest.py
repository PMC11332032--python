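import numpy as np
import pytest

from holdoutcca import HoldoutConfig, SimulationConfig, simulate_two_view


@pytest.fixture(scope="session")
def small_cohort():
    """A small multi-site cohort with one strong planted component."""
    cfg = SimulationConfig(
        n_subjects=500,
        n_features=60,
        true_correlations=(0.6,),
        n_sites=5,
        noise_sd=0.5,
        seed=7,
    )
    return simulate_two_view(cfg)


@pytest.fixture(scope="session")
def fast_holdout_config():
    """A hold-out configuration small enough for unit tests."""
    return HoldoutConfig(
        n_reps=2,
        n_test_sites=1,
        k_pc=15,
        d=3,
        grid_brain=(0.6, 0.8, 1.0),
        grid_behavior=(0.6, 0.8, 1.0),
        n_inner=10,
        B_train=120,
        B_test=120,
        seed=5,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
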