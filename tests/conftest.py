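import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from elsm import (
    LiquidSpec,
    SimulationConfig,
    TemplateDatasetSpec,
    build_liquid,
    make_template_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_dataset():
    """The default synthetic classification task (5 classes, 40 channels)."""
    return make_template_dataset(TemplateDatasetSpec(seed=11))


@pytest.fixture(scope="session")
def demo_liquid():
    """A 500-neuron liquid matched to the demo dataset's channel count."""
    return build_liquid(LiquidSpec(n_neurons=500, seed=0), n_channels=40, seed=0)


@pytest.fixture(scope="session")
def demo_simulation(demo_dataset, demo_liquid):
    """One simulated sample with recorded state traces."""
    from elsm import run

    cfg = SimulationConfig(duration=250.0, record_states=True, seed=42)
    raster, trace = run(demo_liquid, demo_dataset.train_rasters[0], cfg)
    return raster, trace
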