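import dataclasses

import numpy as np
import pytest

from nanowell import (
    ArrayLayout,
    DustModel,
    Region,
    SyntheticScenario,
    demo_plex,
)


@pytest.fixture(scope="session")
def layout():
    """Full-size device layout (28x28 wells of 300 um at 50 um spacing)."""
    return ArrayLayout()


@pytest.fixture(scope="session")
def small_layout():
    """A 6x6-well array for fast rendering."""
    return ArrayLayout(n_well_rows=6, n_well_cols=6)


@pytest.fixture(scope="session")
def plex():
    return demo_plex()


def make_scenario(layout, plex, densities=None, **overrides):
    """A clean (noiseless, dust-free) scenario covering the array with one region."""
    w, h = layout.array_extent_um
    regions = ()
    if densities is not None:
        regions = (
            Region("tissue", ((0, 0), (w, 0), (w, h), (0, h)), densities),
        )
    params = dict(
        layout=layout,
        plex=plex,
        regions=regions,
        pixel_noise_sd_afu=0.0,
        dust=DustModel(count=0),
        missing_post_prob=0.0,
        seed=11,
    )
    params.update(overrides)
    return SyntheticScenario(**params)


@pytest.fixture
def clean_scenario(small_layout, plex):
    densities = {"miR-21": 10.0, "let-7a": 4.0, "miR-16": 6.0, "miR-19b": 2.0,
                 "miR-210": 1.0, "miR-20a": 1.5, "miR-15b": 2.5}
    return make_scenario(small_layout, plex, densities)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def scenario_with(scenario, **kwargs):
    return dataclasses.replace(scenario, **kwargs)
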