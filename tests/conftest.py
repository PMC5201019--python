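"""Shared fixtures: coarse grids and simulators sized so the whole suite
runs in minutes on one CPU.  Heavy objects are session-scoped and shared.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fdapsim as fs

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

# Coarse-but-resolved discretization used for suite-level simulations; the
# mesh-refinement test quantifies its distance from the converged curve.
COARSE = dict(spacing=0.5, spacing_z=0.25)


@pytest.fixture(scope="session")
def round_geom():
    return fs.make_round_cell(20.0, 3.5, 0.3)


@pytest.fixture(scope="session")
def roi():
    return fs.ROISpec(center=(10.0, 0.0), radius=1.0)


@pytest.fixture(scope="session")
def coarse_grid(round_geom, roi):
    return fs.voxelize(round_geom, COARSE["spacing"], half_cell=True,
                       spacing_z=COARSE["spacing_z"], roi=roi)


@pytest.fixture(scope="session")
def coarse_sim(coarse_grid, roi):
    return fs.Simulator(coarse_grid, roi)


@pytest.fixture(scope="session")
def small_library(coarse_grid, roi, coarse_sim):
    """5 x 5 library centred on (F=100 uM, K_dep=0.06 1/s), coarse grid."""
    spec = fs.GridSpec(
        F_values=(80.0, 90.0, 100.0, 110.0, 120.0),
        K_values=(0.04, 0.05, 0.06, 0.07, 0.08),
        geometry_id="round_cell_20_3.5_0.3_coarse")
    return fs.generate_library(spec, coarse_grid, roi, simulator=coarse_sim)


@pytest.fixture(scope="session")
def donly_d3(coarse_sim):
    """Diffusion-only run, D = 3 um^2/s, full 25-s recording."""
    return fs.simulate_diffusion_only(3.0, simulator=coarse_sim)


@pytest.fixture(scope="session")
def tiny_axon():
    geom, roi_ax = fs.make_axon(10.0, 0.5, 0.5)
    grid = fs.voxelize(geom, 0.25, half_cell=True, spacing_z=0.125,
                       roi=roi_ax)
    return geom, roi_ax, grid
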