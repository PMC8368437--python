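"""Shared small-scale geometry fixtures (session-scoped: lead fields are reused)."""

import numpy as np
import pytest

import ictalmeg as im


@pytest.fixture(scope="session")
def small_array():
    return im.make_sensor_array(30, 120.0, seed=0)


@pytest.fixture(scope="session")
def coarse_grid():
    return im.make_source_grid(spacing_mm=30.0, radius_mm=96.0)


@pytest.fixture(scope="session")
def atlas():
    return im.RegionAtlas.default()


@pytest.fixture(scope="session")
def coarse_leadfield(small_array, coarse_grid):
    return im.sphere_leadfield(small_array, coarse_grid)


@pytest.fixture(scope="session")
def mid_array():
    return im.make_sensor_array(60, 120.0, seed=1)


@pytest.fixture(scope="session")
def mid_grid():
    return im.make_source_grid(spacing_mm=12.0, radius_mm=96.0)


@pytest.fixture(scope="session")
def mid_leadfield(mid_array, mid_grid):
    return im.sphere_leadfield(mid_array, mid_grid)


def tangential(loc, rng):
    """Random unit vector tangential to the sphere radius at ``loc``."""
    loc = np.asarray(loc, dtype=float)
    rhat = loc / np.linalg.norm(loc)
    u = rng.standard_normal(3)
    u -= rhat * (u @ rhat)
    return u / np.linalg.norm(u)
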