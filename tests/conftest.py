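import numpy as np
import pytest

from amyca.model import ModelConfig, simulate
from amyca.params import ModelParams


@pytest.fixture(scope="session")
def params():
    return ModelParams()


def make_config(**kw):
    return ModelConfig(**kw)


@pytest.fixture(scope="session")
def trace_p5(params):
    """Oscillatory constant-IP3 run (p=5, no amyloid), shared across tests."""
    cfg = ModelConfig(variant="constant_ip3", p_fixed=5.0, a=0.0,
                      t_end=400.0)
    return simulate(cfg, params)


@pytest.fixture(scope="session")
def trace_p10(params):
    cfg = ModelConfig(variant="constant_ip3", p_fixed=10.0, a=0.0,
                      t_end=400.0)
    return simulate(cfg, params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)
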