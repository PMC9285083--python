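import numpy as np
import pytest

from primecrop import phenology as phen
from primecrop import synthetic as synth


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured scenario configuration."""
    return synth.SimulationConfig(seed=7, n_counties=8, pixels_per_county=2)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return synth.make_scenario(small_config)


@pytest.fixture(scope="session")
def maize_model():
    cfg = synth.SimulationConfig(seed=0)
    return synth.reference_shape_model(cfg)


@pytest.fixture()
def clean_series(maize_model):
    """Noise-free daily WDRVI series equal to the maize reference curve."""
    return phen.WdrviSeries(pixel_id=0, year=2000,
                            grid=maize_model.grid.copy(),
                            values=maize_model.curve.copy())


def true_stage_frame(bundle):
    """Pixel-level truth table with float stage dates."""
    return bundle.truth.pixel_stages


def detected_vs_truth(pixel_stages, truth):
    merged = pixel_stages.merge(
        truth, on=["pixel_id", "county_id", "year"], suffixes=("_det", "_true")
    )
    return merged


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
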