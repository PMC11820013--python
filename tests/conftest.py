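import numpy as np
import pytest

from camil.model import CamilConfig, CamilModel
from camil.synth_data import SynthConfig, make_bags


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model():
    """Small randomized model whose every gradient path is live."""
    model = CamilModel(CamilConfig(in_dim=6, model_dim=5, pool_hidden=4, seed=7))
    r = np.random.default_rng(99)
    for k in model.params:
        model.params[k] = r.normal(0.0, 0.5, size=model.params[k].shape)
    return model


@pytest.fixture
def small_bags():
    """Quick synthetic bag set for pipeline-level tests."""
    return make_bags(
        SynthConfig(n_bags=24, n_min=5, n_max=10, feature_dim=12, seed=3)
    )
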