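"""Shared fixtures: one wild-type-like cardiomyocyte volume and one large
shape population are generated once per session (they are the expensive
inputs several recovery tests score against)."""

import numpy as np
import pytest

from mitomorph import morphometry as M
from mitomorph.synthetic import (
    VolumeParams,
    generate_cardiomyocyte_volume,
    generate_shape_population,
)


@pytest.fixture(scope="session")
def wt_volume():
    """Cardiomyocyte label volume at the wild-type study conditions."""
    params = VolumeParams(shape_zyx=(48, 640, 640), seed=1)
    volume, truth = generate_cardiomyocyte_volume(params)
    return params, volume, truth


@pytest.fixture(scope="session")
def ifm_population():
    """300 interfibrillar bodies drawn at the wild-type IFM oval fraction."""
    volume, truth = generate_shape_population(n=300, oval_fraction=0.69, seed=3)
    return volume, truth


@pytest.fixture(scope="session")
def ifm_population_classes(ifm_population):
    """Predicted shape class for every object of the 300-body population."""
    volume, truth = ifm_population
    return {
        lab: M.classify_shape(volume, lab) for lab in map(int, volume.label_ids())
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
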