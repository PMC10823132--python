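import numpy as np
import pytest

from riverkill import RiverFrame, ScenarioConfig


@pytest.fixture
def odra_frame() -> RiverFrame:
    """Lower Odra geometry: 124 km main stem + 26 km side arm, 20-m strip."""
    return RiverFrame(
        km_start=617.6,
        km_end=741.6,
        extra_branches=(("Western Odra", 26.0),),
        strip_width_w=20.0,
        n_banks=2,
    )


@pytest.fixture
def scenario() -> ScenarioConfig:
    return ScenarioConfig(seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
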