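import numpy as np
import pytest

from contraction_bias import (
    ObserverParams,
    ParamDistribution,
    TaskConfig,
    UniformLogPrior,
    generate_cohort,
)


@pytest.fixture
def unit_prior() -> UniformLogPrior:
    return UniformLogPrior(0.0, 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)


@pytest.fixture
def biased_observer() -> ObserverParams:
    """Memory noise above probe noise: the contraction-bias regime."""
    return ObserverParams(sigma1=0.3, sigma2=0.2)


@pytest.fixture(scope="session")
def standard_cohort():
    """9 simulated subjects on the standard 150-600 px task, observer noise
    at the operating point (sigma1/sigma2 = 0.26/0.20 normalized)."""
    cfg = TaskConfig()
    trials, truth = generate_cohort(9, cfg, ParamDistribution(0.26, 0.20), seed=11)
    return cfg, trials, truth
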