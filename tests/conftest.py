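import numpy as np
import pytest

from mregaval.config import PipelineConfig
from mregaval.synthetic import SynthParams, generate_component_series


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_series(config):
    """One default synthetic component series with its ground truth."""
    return generate_component_series(config, seed=7)


@pytest.fixture(scope="session")
def short_params() -> SynthParams:
    """Reduced-length generator parameters for fast tests."""
    return SynthParams(n_samples=1200, n_events=4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
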