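import numpy as np
import pytest
from hypothesis import settings

import renalperf as rp

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None, database=None
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_grid() -> rp.TimeGrid:
    """The study acquisition grid: 65 frames at 6.6 s."""
    return rp.TimeGrid(65, 6.6)


@pytest.fixture(scope="session")
def study_aif() -> rp.ArterialInputFunction:
    """Default population AIF on the study grid (unit peak)."""
    return rp.make_aif(rp.PhantomConfig())


@pytest.fixture(scope="session")
def noiseless_config() -> rp.PhantomConfig:
    return rp.PhantomConfig(noise_sigma=0.0, s0_jitter=0.0)
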