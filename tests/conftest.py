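import numpy as np
import pytest

from cytonx import ModelConfig, simulate
from cytonx.config import MarkerParams, MarkerThresholds


def zero_noise_config(**overrides) -> ModelConfig:
    """All spreads zero: every draw collapses to its central value."""
    markers = MarkerParams(
        init_sd=0.0, cd62l_factor_sd=0.0, cd27_factor_sd=0.0, klrg1_factor_sd=0.0,
        thresholds=MarkerThresholds(),
    )
    defaults = dict(
        v_mp=0.0, v_p=0.0, v_e=0.0, sigma_md=0.0, sigma_d=0.0, v_a=0.0, v_div=0.0,
        markers=markers,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def basic_run():
    """One full-scale basic-model run (1000 naive cells, 8 days)."""
    return simulate(ModelConfig(variant="basic", seed=1))


@pytest.fixture(scope="session")
def hetero_run():
    """One full-scale heterogeneous-activation run."""
    return simulate(ModelConfig(variant="heterogeneous_activation", seed=1))
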