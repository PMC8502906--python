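"""Shared fixtures: phantom series at several resolutions.

Session-scoped because phantom generation and series registration are the
expensive steps; every test reads them without mutating.
"""

from dataclasses import replace

import numpy as np
import pytest

from pelvimotion.phantom import PhantomConfig, generate_series
from pelvimotion.registration import register_series


@pytest.fixture(scope="session")
def coarse_config():
    """Coarse study grid used for the heavier pipeline tests."""
    return PhantomConfig(grid_shape=(64, 64, 32), spacing_mm=(1.5, 1.5, 3.0))


@pytest.fixture(scope="session")
def coarse_series(coarse_config):
    return generate_series(coarse_config)


@pytest.fixture(scope="session")
def coarse_fields(coarse_series):
    """Displacement fields of every frame relative to the first."""
    return register_series([f.image for f in coarse_series])


@pytest.fixture(scope="session")
def default_series():
    """Phantom series at the default (finest) resolution."""
    return generate_series(PhantomConfig())


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast phantom for structural/error-path tests."""
    return PhantomConfig(
        grid_shape=(48, 48, 24), spacing_mm=(2.0, 2.0, 4.0), n_frames=4
    )


@pytest.fixture(scope="session")
def tiny_series(tiny_config):
    return generate_series(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def still_config(config, **overrides):
    """A copy of a phantom config with all motion amplitudes zeroed."""
    return replace(
        config,
        bladder_growth_mm_per_frame=0.0,
        rectum_drift_mm_per_frame=0.0,
        prostate_relaxation_mm=0.0,
        **overrides,
    )
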