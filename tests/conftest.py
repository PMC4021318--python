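import numpy as np
import pytest

from soyco2.crop_model import CalibParams, PhysioConstants
from soyco2.synthetic import SynthConfig, default_cell_specs, gen_weather


@pytest.fixture(scope="session")
def pc():
    return PhysioConstants()


@pytest.fixture(scope="session")
def cp():
    return CalibParams(
        co2_sens=1.1,
        tech_intercept=0.2,
        tech_slope=0.02,
        drought_sens=0.8,
        cold_threshold=9.0,
        cold_sens=0.1,
        yield_scale=0.35,
    )


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(n_cells_per_country=1, seed=42)


@pytest.fixture(scope="session")
def cell_specs(synth_cfg):
    return default_cell_specs(synth_cfg)


@pytest.fixture(scope="session")
def usa_weather(synth_cfg, cell_specs):
    """27+1 years of daily weather for a northern-hemisphere cell."""
    return gen_weather(synth_cfg, cell_specs[0])


@pytest.fixture(scope="session")
def brazil_weather(synth_cfg, cell_specs):
    """Southern-hemisphere forcing (growing season spans the new year)."""
    return gen_weather(synth_cfg, cell_specs[1])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
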