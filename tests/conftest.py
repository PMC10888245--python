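"""Shared fixtures: synthetic molecules, movies and structures.

Everything is generated at test time from fixed seeds; nothing is read
from disk except files the tests themselves write into tmp paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from lamhinge.core_io import TipModel
from lamhinge.synth_movie import HingedRodParams, generate_movie


@pytest.fixture(scope="session")
def default_params() -> HingedRodParams:
    return HingedRodParams()


@pytest.fixture(scope="session")
def stiff_straight_params() -> HingedRodParams:
    """Straight, effectively rigid rod (stiff limit of the generator)."""
    return HingedRodParams(mean_angle=180.0, angle_sd=0.0,
                           persistence_length=1e6)


@pytest.fixture(scope="session")
def bent_movie(default_params):
    """Short movie of one flexible molecule at the default conditions."""
    return generate_movie(default_params, 6, seed=11)


@pytest.fixture(scope="session")
def straight_movie(stiff_straight_params):
    return generate_movie(stiff_straight_params, 4, seed=5)


@pytest.fixture(scope="session")
def sharp_tip() -> TipModel:
    return TipModel(sphere_radius=1.0, cone_half_angle=5.0)


@pytest.fixture(scope="session")
def imaging_tip() -> TipModel:
    """2 nm apex used for the obscuration geometry."""
    return TipModel(sphere_radius=2.0, cone_half_angle=5.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240206)
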