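"""Flow solver: trivial/analytic solutions, conservation, equivalences, restart."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from aneuflow.case import CaseConfig
from aneuflow.fem import P1Discretization
from aneuflow.geometry import GeometryParams, build_channel_mesh
from aneuflow.rheology import CassonParams, newtonian_params
from aneuflow.solver import (CheckpointError, FlowState, SolverConfig,
                             SolverDivergenceError, advance, checkpoint_read,
                             checkpoint_write, run_transient, solve_steady)
from conftest import (CASSON_G, CASSON_PARAMS, CHANNEL_H, CHANNEL_L, DARCY_BAND,
                      DARCY_K, DARCY_MU, DARCY_U, POISEUILLE_MU, POISEUILLE_U)


def test_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(dt=0.0)
    with pytest.raises(ValueError):
        SolverConfig(cycles=0)
    with pytest.raises(ValueError):
        SolverConfig(under_relaxation_u=1.5)
    with pytest.raises(ValueError):
        SolverConfig(time_scheme="crank")


def test_zero_inflow_stays_exactly_at_rest(coarse_mesh):
    state = FlowState.rest(coarse_mesh.n_points)
    new = advance(state, 0.01, coarse_mesh, newtonian_params(0.0035),
                  inlet_speed=0.0)
    assert np.all(new.ux == 0.0) and np.all(new.uy == 0.0)
    assert np.all(new.p == 0.0)


class TestPoiseuille:
    def test_centerline_velocity(self, poiseuille_solution):
        mesh, state = poiseuille_solution
        sel = np.abs(mesh.points[:, 0] - 0.8 * CHANNEL_L) < 1e-9
        y, u = mesh.points[sel, 1], state.ux[sel]
        i = np.argsort(y)
        u_center = np.interp(CHANNEL_H / 2, y[i], u[i])
        assert u_center == pytest.approx(1.5 * POISEUILLE_U, rel=0.02)

    def test_no_slip_exact_on_walls(self, poiseuille_solution):
        mesh, state = poiseuille_solution
        wall = mesh.nodes_for("WALL_VESSEL")
        assert np.all(state.ux[wall] == 0.0)
        assert np.all(state.uy[wall] == 0.0)

    def test_global_mass_balance(self, poiseuille_solution):
        mesh, state = poiseuille_solution
        disc = P1Discretization(mesh)
        q_in = disc.boundary_flux(state.ux, state.uy, "INLET")
        q_out = disc.boundary_flux(state.ux, state.uy, "OUTLET")
        assert abs(q_in + q_out) < 1e-10 * abs(q_in)


def casson_channel_profile(y_from_wall, G, half_height, params, n=20001):
    """Quadrature oracle: closed-form Casson channel velocity profile.

    Shear stress grows linearly from the centerline, tau = G*yc; the plug
    extends to yc = tau_y/G and outside it the Casson law gives
    gamma_dot = (sqrt(G*yc) - sqrt(tau_y))^2 / mu_inf.
    """
    yc_grid = np.linspace(0.0, half_height, n)
    gd = np.where(
        yc_grid > params.tau_y / G,
        (np.sqrt(np.maximum(G * yc_grid, 0)) - np.sqrt(params.tau_y)) ** 2
        / params.mu_inf, 0.0)
    integ = cumulative_trapezoid(gd, yc_grid, initial=0.0)
    u_of_yc = integ[-1] - integ  # u(yc) = int_yc^a gamma_dot
    yc = np.abs(y_from_wall - half_height)
    return np.interp(yc, yc_grid, u_of_yc)


def test_casson_channel_matches_closed_form(casson_channel_solution):
    mesh, state = casson_channel_solution
    sel = np.abs(mesh.points[:, 0] - 0.5 * CHANNEL_L) < 1e-9
    y, u = mesh.points[sel, 1], state.ux[sel]
    u_exact = casson_channel_profile(y, CASSON_G, CHANNEL_H / 2, CASSON_PARAMS)
    l2 = np.sqrt(np.sum((u - u_exact) ** 2) / np.sum(u_exact ** 2))
    assert l2 < 0.02
    # plug core: velocity at the centerline and half a plug-width off agree
    a = CHANNEL_H / 2
    yp = CASSON_PARAMS.tau_y / CASSON_G
    u_c = np.interp(a, y[np.argsort(y)], u[np.argsort(y)])
    u_half_plug = np.interp(a - 0.5 * yp, y[np.argsort(y)], u[np.argsort(y)])
    assert u_half_plug == pytest.approx(u_c, rel=0.01)


def test_darcy_slab_pressure_drop(darcy_slab_solution):
    mesh, state = darcy_slab_solution
    sel = np.abs(mesh.points[:, 1] - CHANNEL_H / 2) < 1e-9
    x, p = mesh.points[sel, 0], state.p[sel]
    i = np.argsort(x)
    x, p = x[i], p[i]
    dp = np.interp(DARCY_BAND[0], x, p) - np.interp(DARCY_BAND[1], x, p)
    dp_exact = DARCY_MU * DARCY_U * (DARCY_BAND[1] - DARCY_BAND[0]) / DARCY_K
    assert dp == pytest.approx(dp_exact, rel=0.02)


def test_divergence_reports_residuals(coarse_mesh):
    cfg = SolverConfig(outer_iterations_max=1)
    state = FlowState.rest(coarse_mesh.n_points)
    with pytest.raises(SolverDivergenceError) as exc:
        advance(state, 0.005, coarse_mesh, newtonian_params(0.0035),
                inlet_speed=0.5, cfg=cfg)
    assert exc.value.momentum_residual > 0
    assert exc.value.continuity_residual >= 0


class TestTransient:
    def test_step_count_and_final_time(self, baseline_run):
        # 3 cycles of 0.8 s at dt = 5 ms -> 480 steps, final time 2.4 s
        traj = baseline_run
        assert len(traj.residual_log) == 480
        assert traj.residual_log[-1]["time"] == pytest.approx(2.4)
        assert traj.states[-1].time == pytest.approx(2.4)

    def test_snapshot_times_strictly_increasing(self, baseline_run):
        t = baseline_run.times
        assert np.all(np.diff(t) > 0)

    def test_mass_conserved_at_every_snapshot(self, baseline_run):
        traj = baseline_run
        disc = P1Discretization(traj.mesh)
        for st in traj.states[1:]:
            q_in = disc.boundary_flux(st.ux, st.uy, "INLET")
            q_out = disc.boundary_flux(st.ux, st.uy, "OUTLET")
            assert abs(q_in + q_out) <= 1e-5 * abs(q_in)

    def test_phase_snapshots_present_every_cycle(self, baseline_run):
        traj = baseline_run
        for c in range(3):
            for phase in (0.24, 0.54):
                traj.state_at(c * 0.8 + phase, tol=1e-9)


class TestEquivalences:
    def test_zero_yield_casson_equals_newtonian_bitwise(self, tiny_case):
        mu = 0.0035
        c1 = tiny_case.with_(hematocrit=None, tau_y=0.0, mu_inf=mu)
        t1 = run_transient(c1)
        t2 = run_transient(tiny_case.with_(hematocrit=None, tau_y=0.0, mu_inf=mu))
        # determinism first: identical configs give identical runs
        np.testing.assert_array_equal(t1.last_state.ux, t2.last_state.ux)
        # and the zero-yield path is the constant-viscosity path exactly
        mesh = t1.mesh
        state = FlowState.rest(mesh.n_points)
        a = advance(state, 0.01, mesh, CassonParams(tau_y=0.0, mu_inf=mu),
                    inlet_speed=0.3)
        b = advance(state, 0.01, mesh, newtonian_params(mu), inlet_speed=0.3)
        np.testing.assert_array_equal(a.ux, b.ux)
        np.testing.assert_array_equal(a.uy, b.uy)
        np.testing.assert_array_equal(a.p, b.p)

    def test_open_porosity_equals_no_coil_bitwise(self, tiny_case):
        t_open = run_transient(tiny_case.with_(porosity=1.0))
        t_none = run_transient(tiny_case)  # porous model never configured
        np.testing.assert_array_equal(t_open.last_state.ux, t_none.last_state.ux)
        np.testing.assert_array_equal(t_open.last_state.uy, t_none.last_state.uy)
        np.testing.assert_array_equal(t_open.last_state.p, t_none.last_state.p)


class TestCheckpoint:
    def test_roundtrip_bit_exact(self, tiny_case, tmp_path):
        traj = run_transient(tiny_case)
        path = tmp_path / "chk.npz"
        checkpoint_write(traj, path)
        back, last, prev, step = checkpoint_read(path)
        assert step == len(traj.residual_log)
        np.testing.assert_array_equal(last.ux, traj.last_state.ux)
        assert len(back.states) == len(traj.states)
        for a, b in zip(back.states, traj.states):
            np.testing.assert_array_equal(a.ux, b.ux)
            np.testing.assert_array_equal(a.p, b.p)

    def test_truncated_file_rejected(self, tiny_case, tmp_path):
        traj = run_transient(tiny_case)
        path = tmp_path / "chk.npz"
        checkpoint_write(traj, path)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 3])
        with pytest.raises(CheckpointError):
            checkpoint_read(path)

    def test_restart_matches_uninterrupted_run(self, tiny_case, tmp_path):
        full_case = tiny_case.with_(
            solver=dataclasses.replace(tiny_case.solver, cycles=2))
        full = run_transient(full_case)
        half = run_transient(tiny_case)  # 1 cycle
        path = tmp_path / "half.npz"
        checkpoint_write(half, path)
        resumed = run_transient(full_case, restart=path)
        assert resumed.last_state.time == pytest.approx(full.last_state.time)
        for name in ("ux", "uy", "p"):
            a = getattr(resumed.last_state, name)
            b = getattr(full.last_state, name)
            assert np.max(np.abs(a - b)) <= 1e-10
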