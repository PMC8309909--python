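"""Shared fixtures: geometries, forward-model runs, a small cohort."""

import numpy as np
import pytest

from torsoecg.geometry import (GeometryConfig, build_torso_geometry,
                               place_electrodes)
from torsoecg.cardiac_sim import run_simulation
from torsoecg.synthetic_ecg import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_geometry():
    return build_torso_geometry()


@pytest.fixture(scope="session")
def default_layout(default_geometry):
    return place_electrodes(default_geometry)


@pytest.fixture(scope="session")
def default_simulation(default_geometry, default_layout):
    """Forward run on the default grid, long enough for >= 2 full beats."""
    return run_simulation(default_geometry, duration=3.4,
                          layout=default_layout, store_surface=False)


#: Same physical torso at half the grid resolution; the heart subgrid is
#: refined twice as much so the active tissue is identical.
COARSE_CONFIG = GeometryConfig(shape=(27, 32, 16), spacing=1.5)


@pytest.fixture(scope="session")
def coarse_geometry():
    return build_torso_geometry(COARSE_CONFIG)


@pytest.fixture(scope="session")
def coarse_simulation(coarse_geometry):
    layout = place_electrodes(coarse_geometry)
    return run_simulation(coarse_geometry, duration=3.4, layout=layout,
                          store_surface=False, heart_refine=3)


@pytest.fixture(scope="session")
def small_cohort():
    """Four clean subjects with short records, for EA/pipeline tests."""
    cfg = CohortConfig(n_subjects=4, rest_duration=50.0,
                       walking_duration=50.0, seed=7)
    return cfg, generate_cohort(cfg)
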