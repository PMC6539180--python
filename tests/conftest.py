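"""Shared fixtures: small synthetic trials reused across test modules.

The simulated scenes are the expensive part of the suite, so full-size
trials are session-scoped and rendered once.
"""

from __future__ import annotations

import numpy as np
import pytest

from peafield.geo_io import BAND_NAMES, BandStack, ElevationGrid, GeoTransform
from peafield.pipeline import PipelineConfig, extract_features, simulate_trial
from peafield.synthetic_field import default_panel_region


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture()
def transform():
    return GeoTransform(origin_easting=100.0, origin_northing=200.0, pixel_size=0.5)


def random_stack(rng, shape=(16, 16), transform=None) -> BandStack:
    transform = transform or GeoTransform(0.0, shape[0] * 1.0, 1.0)
    bands = {b: rng.uniform(0.01, 0.9, shape) for b in BAND_NAMES}
    return BandStack(bands=bands, transform=transform)


def random_elevation(rng, shape=(16, 16), role="DSM", transform=None) -> ElevationGrid:
    transform = transform or GeoTransform(0.0, shape[0] * 1.0, 1.0)
    return ElevationGrid(values=rng.normal(100.0, 1.0, shape),
                         transform=transform, role=role)


@pytest.fixture(scope="session")
def winter_cfg():
    """Default winter-trial study conditions: 20 entries x 3 replicates,
    five imaging timepoints spanning emergence to maturity."""
    return PipelineConfig(seed=11, out_dir="unused")


@pytest.fixture(scope="session")
def winter_sim(winter_cfg):
    return simulate_trial(winter_cfg)


@pytest.fixture(scope="session")
def winter_features(winter_cfg, winter_sim):
    layout, truth, spec, scenes = winter_sim
    panel = default_panel_region(layout, spec)
    return extract_features(layout, scenes, winter_cfg, panel_polygon=panel)


@pytest.fixture(scope="session")
def spring_cfg():
    """Spring-trial conditions: three imaging timepoints around flowering,
    30% of plots lodging after the growth peak."""
    return PipelineConfig(seed=13, out_dir="unused",
                          timepoints=(1231.0, 1424.0, 1648.0),
                          lodging_fraction=0.3, model_add=1231.0)


@pytest.fixture(scope="session")
def spring_sim(spring_cfg):
    return simulate_trial(spring_cfg)


@pytest.fixture(scope="session")
def spring_features(spring_cfg, spring_sim):
    layout, truth, spec, scenes = spring_sim
    panel = default_panel_region(layout, spec)
    return extract_features(layout, scenes, spring_cfg, panel_polygon=panel)
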