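"""Shared fixtures.

The transient scenario runs are deterministic and moderately expensive, so
they are session-scoped and shared between the unit suites and the
acceptance suite.
"""

import numpy as np
import pytest

import lobulefem as lf
from lobulefem.scenarios import ScenarioConfig

R = 5.0e-4  # default lobule circumradius [m]


@pytest.fixture(scope="session")
def params():
    return lf.MaterialParams()


@pytest.fixture(scope="session")
def kinetics():
    from lobulefem.cell import KineticParams
    return KineticParams()


@pytest.fixture(scope="session")
def solutes():
    return lf.default_solutes()


@pytest.fixture(scope="session")
def single_mesh():
    """Default-resolution single lobule (the reference geometry)."""
    return lf.build_single_lobule()


@pytest.fixture(scope="session")
def coarse_mesh():
    """Coarse single lobule for cheap FEM checks."""
    return lf.build_single_lobule(target_edge_length=R / 8)


@pytest.fixture(scope="session")
def pericentral_run():
    """Full single-lobule run at the high-fat-diet inflow (FFA 3 mmol/l)."""
    return lf.run_scenario(ScenarioConfig())


@pytest.fixture(scope="session")
def periportal_run():
    """Full single-lobule run at reduced FFA intake (0.2 mmol/l)."""
    return lf.run_scenario(
        ScenarioConfig(inflow_conc={"FFA": 0.2, "Ox": 0.091}))


@pytest.fixture(scope="session")
def obstructed_run():
    """7-lobule group with the left lobule's outflow obstructed."""
    return lf.run_scenario(
        ScenarioConfig(geometry="group7", bc_preset="outflow_obstruction",
                       target_edge_length=R / 8))


@pytest.fixture(scope="session")
def undisturbed_group_stationary():
    cfg = ScenarioConfig(geometry="group7", bc_preset="undisturbed",
                         target_edge_length=R / 8)
    return lf.stationary_perfusion(cfg)


@pytest.fixture(scope="session")
def obstructed_group_stationary():
    cfg = ScenarioConfig(geometry="group7", bc_preset="outflow_obstruction",
                         target_edge_length=R / 8)
    return lf.stationary_perfusion(cfg)


@pytest.fixture(scope="session")
def drainage_group_stationary():
    cfg = ScenarioConfig(geometry="group7",
                         bc_preset="obstruction_with_drainage",
                         target_edge_length=R / 8)
    return lf.stationary_perfusion(cfg)


def darcy_bc(mesh, p_in=133.0, p_out=0.0):
    """Dirichlet node/value arrays for the standard inflow/outflow data."""
    n_in = mesh.boundary_nodes(("inflow_portal", "inflow_venule"))
    n_out = mesh.boundary_nodes("outflow_central")
    nodes = np.concatenate([n_in, n_out])
    vals = np.concatenate([np.full(len(n_in), p_in),
                           np.full(len(n_out), p_out)])
    return nodes, vals
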