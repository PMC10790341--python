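import pytest

from follisim import GrowthModelParams, PopulationConfig


@pytest.fixture
def params() -> GrowthModelParams:
    """Default growth-model constants."""
    return GrowthModelParams()


@pytest.fixture
def no_atresia_config() -> PopulationConfig:
    return PopulationConfig(atresia_hazard=None)
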