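import numpy as np
import pytest

from sesdebt import IntegrateOptions, ModelParams


@pytest.fixture
def params() -> ModelParams:
    """Default parameter set (the documented per-km^2 calibration)."""
    return ModelParams()


@pytest.fixture
def bistable() -> ModelParams:
    """A productivity/harvest combination with two interior equilibria."""
    return ModelParams(c0=0.0044, h=0.001)


@pytest.fixture
def fast_opts() -> IntegrateOptions:
    """Adaptive steps, natural-step reporting: for long-horizon checks."""
    return IntegrateOptions(max_step=None, dt=None)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
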