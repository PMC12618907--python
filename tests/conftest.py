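import numpy as np
import pytest

import riskpipe as rp
from riskpipe import synthetic as syn


@pytest.fixture(scope="session")
def world_spec():
    return syn.WorldSpec(
        n_rows=40, n_cols=40, cell_size_deg=0.25,
        origin_lon=-60.0, origin_lat=0.0,
        n_predictors=4, collinear_pairs=((0, 1, 0.99),),
        smoothness=4.0, seed=1,
    )


@pytest.fixture(scope="session")
def stack(world_spec):
    return syn.generate_climate_stack(world_spec)


@pytest.fixture(scope="session")
def niche():
    return syn.NicheSpec(
        optimum=(0.5, 0.0, -0.3, 0.1),
        tolerance=(1.0, 1.5, 1.2, 2.0),
        max_prob=0.9,
    )


@pytest.fixture(scope="session")
def surface(stack, niche):
    return syn.generate_virtual_species(stack, niche)


@pytest.fixture(scope="session")
def occurrences(surface):
    return syn.sample_presences(surface, 60, seed=2)


@pytest.fixture(scope="session")
def zones(stack):
    return syn.generate_zone_raster(stack, 3, seed=3)


@pytest.fixture(scope="session")
def background(occurrences, zones, stack):
    return rp.select_background(occurrences, zones, stack, n_points=800, seed=4)


@pytest.fixture(scope="session")
def masked_stack(stack, background):
    return rp.crop_mask(stack, background)


@pytest.fixture(scope="session")
def tuning_report(occurrences, background, masked_stack):
    """Full 50-candidate tuning run, shared across test modules."""
    return rp.tune(occurrences, background, masked_stack, seed=5)


@pytest.fixture(scope="session")
def production_table():
    return syn.generate_production_table(
        n_municipalities=60, n_concentrated=3, concentration_share=0.9, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
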