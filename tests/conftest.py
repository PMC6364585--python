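import numpy as np
import pytest

from scemsort import make_model_params


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def base_params():
    """Default mechanical parameters at moderate tension and adhesion."""
    return make_model_params(beta=1.0, A_M=0.2, gamma_m=1.2)
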