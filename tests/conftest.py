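"""Shared fixtures.

Expensive simulations are session-scoped so the whole suite pays for each
at most once: the 3x3 hematocrit/porosity sweep (with its trajectories),
the steady channel verification solves, and the steady-inflow control run.
"""

import dataclasses

import numpy as np
import pytest

from aneuflow.case import CaseConfig, coarse_case
from aneuflow.experiments import SweepSpec, run_sweep
from aneuflow.geometry import (GeometryParams, build_channel_mesh,
                               build_idealized_geometry, graded_wall_coords)
from aneuflow.rheology import CassonParams, newtonian_params
from aneuflow.solver import SolverConfig, run_transient, solve_steady


@pytest.fixture(scope="session")
def coarse_mesh():
    return build_idealized_geometry(GeometryParams(mesh_size=0.4e-3))


@pytest.fixture(scope="session")
def sweep_results():
    """Default 3 HCT x 3 porosity sweep on the coarse fixture, 3 cycles.

    Returns (dataframe, {(hct, porosity): trajectory}).
    """
    spec = SweepSpec(base_case=coarse_case())
    df, trajs = run_sweep(spec, keep_trajectories=True)
    return df, trajs


@pytest.fixture(scope="session")
def baseline_run(sweep_results):
    """Uncoiled normal-hematocrit trajectory from the sweep."""
    _, trajs = sweep_results
    return trajs[(0.40, 1.0)]


@pytest.fixture(scope="session")
def steady_control_run():
    """Constant-inflow control on the coarse fixture (1 cycle)."""
    case = coarse_case().with_(
        waveform_profile="steady",
        solver=dataclasses.replace(coarse_case().solver, cycles=1))
    return run_transient(case), case.rheology_params()


# ----------------------------------------------------------- channel oracles

CHANNEL_H = 3e-3
CHANNEL_L = 20e-3
POISEUILLE_MU = 0.0035
POISEUILLE_U = 0.05          # mean inlet speed, Re ~ 45


@pytest.fixture(scope="session")
def poiseuille_solution():
    """Steady Newtonian channel flow with a graded wall mesh."""
    y = graded_wall_coords(CHANNEL_H, 24, 2e-5)
    mesh = build_channel_mesh(CHANNEL_L, CHANNEL_H, nx=60, y_coords=y)
    cfg = SolverConfig(under_relaxation_u=0.8, under_relaxation_p=0.8,
                       outer_iterations_max=400)
    state = solve_steady(mesh, newtonian_params(POISEUILLE_MU),
                         inlet_speed=POISEUILLE_U, cfg=cfg)
    return mesh, state


CASSON_G = 10.0              # driving body force (pressure gradient), Pa/m
CASSON_PARAMS = CassonParams(tau_y=0.004, mu_inf=0.0035)


@pytest.fixture(scope="session")
def casson_channel_solution():
    """Casson channel driven by a body force with traction-free ends."""
    mesh = build_channel_mesh(CHANNEL_L, CHANNEL_H, nx=30, ny=48)
    cfg = SolverConfig(inlet_profile="traction_free",
                       body_force=(CASSON_G, 0.0),
                       under_relaxation_u=0.8, under_relaxation_p=0.8,
                       outer_iterations_max=600,
                       momentum_tolerance=1e-6, continuity_tolerance=1e-6)
    state = solve_steady(mesh, CASSON_PARAMS, cfg=cfg)
    return mesh, state


DARCY_MU = 0.00345
DARCY_U = 0.1
DARCY_K = 1e-10
DARCY_BAND = (8e-3, 12e-3)


@pytest.fixture(scope="session")
def darcy_slab_solution():
    """Plug flow through a porous band (slip walls, uniform inlet)."""
    mesh = build_channel_mesh(CHANNEL_L, CHANNEL_H, nx=100, ny=16,
                              porous_band=DARCY_BAND)
    cfg = SolverConfig(inlet_profile="uniform", wall_slip=True,
                       under_relaxation_u=0.8, under_relaxation_p=0.8,
                       outer_iterations_max=400)
    state = solve_steady(mesh, newtonian_params(DARCY_MU),
                         inlet_speed=DARCY_U, cfg=cfg,
                         porous_permeability=DARCY_K)
    return mesh, state


@pytest.fixture
def tiny_case():
    """Cheapest meaningful transient case (for equivalence/restart tests)."""
    return CaseConfig(
        geometry=GeometryParams(mesh_size=0.6e-3),
        solver=SolverConfig(dt=0.01, cycles=1, snapshot_stride=4),
        name="tiny")
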