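import numpy as np
import pytest

from cfpromoter import SimulationConfig, simulate_coverage_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Default discovery-scale cohort with planted effects, full effect (ff=1)."""
    cfg = SimulationConfig(seed=7, fixed_fetal_fraction=1.0)
    return simulate_coverage_cohort(cfg) + (cfg,)


@pytest.fixture(scope="session")
def null_cohort():
    """Label-independent cohort: no planted genes."""
    cfg = SimulationConfig(seed=11, n_diff=0)
    return simulate_coverage_cohort(cfg) + (cfg,)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
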