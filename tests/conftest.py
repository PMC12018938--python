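import numpy as np
import pytest

from immunoprofile import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-participant cohort (40 PWOH / 20 PLWH) with the default 56-marker
    panel and a little missingness."""
    cfg = SimulationConfig(n_pwoh=40, n_plwh=20, missing_rate=0.02, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort_config():
    """No group effects, no covariate effects, equal coordination."""
    return dict(
        marker_effects={},
        covariate_effects={},
        within_block_rho={"PWOH": 0.3, "PLWH": 0.3},
        missing_rate=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
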