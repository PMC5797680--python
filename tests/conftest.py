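import warnings

import numpy as np
import pytest

# arviz emits a refactor FutureWarning on import; irrelevant to these tests
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def reduced_sampler():
    from tlab.robust import SamplerConfig

    return SamplerConfig(steps=10_000, burn_in=2_000, seed=0)
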