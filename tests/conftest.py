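"""Shared fixtures: idealized stellate-cell models and quantal conductances."""

import numpy as np
import pytest

from stellate.cable import (
    ADULT_QUANTAL,
    IMMATURE_QUANTAL,
    PassiveProperties,
    compartmentalize,
)
from stellate.morphology import build_idealized_sc


@pytest.fixture(scope="session")
def immature_props():
    return PassiveProperties(Cm=0.9, Rm=20000.0, Ri=150.0, E_leak=-70.0)


@pytest.fixture(scope="session")
def idealized_morph():
    """Soma 8 µm with one unbranched 90 µm x 0.47 µm dendrite."""
    return build_idealized_sc(8.0, 1, 90.0, 0.47, 1, 1.0)


@pytest.fixture(scope="session")
def idealized_model(idealized_morph, immature_props):
    return compartmentalize(idealized_morph, immature_props, 1.0)


@pytest.fixture(scope="session")
def immature_synapse():
    return IMMATURE_QUANTAL


@pytest.fixture(scope="session")
def adult_synapse():
    return ADULT_QUANTAL


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
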