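"""Unsteady incompressible non-Newtonian flow solver.

Time stepping is implicit (backward Euler by default, BDF2 optional); each
step performs Picard outer iterations on the coupled stabilized system: the
apparent viscosity and advection field are frozen at the previous iterate,
the Darcy sink is treated implicitly, and the linearized saddle system is
solved directly (sparse LU).  The outer loop monitors normalized momentum
and continuity residuals of the nonlinear system and stops when both are
below their tolerances; exceeding the iteration budget raises
:class:`SolverDivergenceError` carrying the final residuals.

The run is fully deterministic: no randomness anywhere, and with unit
under-relaxation each accepted iterate is the exact LU solution, so restart
from a checkpoint reproduces an uninterrupted run bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from . import mesh as _mesh
from .fem import P1Discretization
from .mesh import Mesh
from .rheology import CassonParams, apparent_viscosity
from .waveform import Waveform

__all__ = ["SolverConfig", "FlowState", "FlowTrajectory",
           "SolverDivergenceError", "CheckpointError", "advance",
           "run_transient", "solve_steady", "checkpoint_write",
           "checkpoint_read", "BoundaryConditions"]

CHECKPOINT_VERSION = 1


class SolverDivergenceError(RuntimeError):
    """Outer iterations exhausted; carries the last residuals."""

    def __init__(self, msg, momentum_residual, continuity_residual, time=None):
        super().__init__(msg)
        self.momentum_residual = momentum_residual
        self.continuity_residual = continuity_residual
        self.time = time


class CheckpointError(RuntimeError):
    """Unreadable or incompatible checkpoint file."""


@dataclass(frozen=True)
class SolverConfig:
    dt: float = 0.002                   # s
    cycles: int = 3
    outer_iterations_max: int = 200
    continuity_tolerance: float = 1e-5
    momentum_tolerance: float = 1e-5
    under_relaxation_u: float = 1.0
    under_relaxation_p: float = 1.0
    time_scheme: str = "implicit_euler"  # "implicit_euler" | "bdf2"
    density: float = 1060.0              # kg/m^3
    snapshot_stride: int = 4
    body_force: tuple = (0.0, 0.0)       # N/m^3, mainly for verification runs
    inlet_profile: str = "parabolic"     # "parabolic" | "uniform" | "traction_free"
    wall_slip: bool = False              # verification channels only

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not (0 < self.under_relaxation_u <= 1 and 0 < self.under_relaxation_p <= 1):
            raise ValueError("relaxation factors must lie in (0, 1]")
        if self.continuity_tolerance <= 0 or self.momentum_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.time_scheme not in ("implicit_euler", "bdf2"):
            raise ValueError(f"unknown time scheme {self.time_scheme!r}")


@dataclass
class FlowState:
    """Nodal velocity/pressure fields at one instant."""

    time: float
    ux: np.ndarray
    uy: np.ndarray
    p: np.ndarray

    @classmethod
    def rest(cls, n: int, time: float = 0.0) -> "FlowState":
        return cls(time=time, ux=np.zeros(n), uy=np.zeros(n), p=np.zeros(n))

    def copy(self) -> "FlowState":
        return FlowState(self.time, self.ux.copy(), self.uy.copy(), self.p.copy())


@dataclass
class FlowTrajectory:
    """Snapshot record of a transient run."""

    mesh: Mesh
    waveform: Waveform | None
    period: float
    cycles: int
    dt: float
    states: list = field(default_factory=list)       # FlowState snapshots
    residual_log: list = field(default_factory=list)
    last_state: FlowState | None = None
    prev_state: FlowState | None = None              # for BDF2 restart

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    def state_at(self, t: float, tol: float | None = None) -> FlowState:
        times = self.times
        i = int(np.argmin(np.abs(times - t)))
        if tol is None:
            tol = 0.51 * self.dt
        if abs(times[i] - t) > tol:
            raise KeyError(f"no snapshot within {tol} of t={t}")
        return self.states[i]

    def final_cycle(self):
        """Snapshots spanning the last cycle, endpoints included."""
        t0 = (self.cycles - 1) * self.period
        eps = 1e-9 * self.period
        return [s for s in self.states if s.time >= t0 - eps]


# --------------------------------------------------------------------------
# boundary conditions
# --------------------------------------------------------------------------

class BoundaryConditions:
    """Precomputed Dirichlet machinery for a mesh + solver config."""

    def __init__(self, mesh: Mesh, cfg: SolverConfig):
        self.cfg = cfg
        n = mesh.n_points
        wall_nodes = np.unique(np.concatenate([
            mesh.nodes_for(_mesh.WALL_VESSEL), mesh.nodes_for(_mesh.WALL_SAC)]))
        inlet_nodes = mesh.nodes_for(_mesh.INLET)
        self.inlet_free = cfg.inlet_profile == "traction_free"
        # with no-slip walls the inlet/wall corner nodes belong to the wall
        # (the parabolic profile is zero there anyway); with slip walls only
        # u_y is wall-constrained, so u_x must still be prescribed at corners
        if not self.inlet_free and not cfg.wall_slip:
            inlet_nodes = np.setdiff1d(inlet_nodes, wall_nodes)
        inlet_uy = np.setdiff1d(inlet_nodes, wall_nodes) if cfg.wall_slip \
            else inlet_nodes
        self.wall_nodes = wall_nodes
        self.inlet_nodes = inlet_nodes
        self.inlet_uy = inlet_uy

        if not self.inlet_free and len(inlet_nodes):
            y = mesh.points[inlet_nodes, 1]
            # span of the full inlet boundary, walls included
            y_all = mesh.points[mesh.nodes_for(_mesh.INLET), 1]
            y0, y1 = y_all.min(), y_all.max()
            yc, hh = 0.5 * (y0 + y1), (y1 - y0)
            if cfg.inlet_profile == "parabolic":
                self.inlet_shape = 1.5 * (1.0 - (2.0 * (y - yc) / hh) ** 2)
            elif cfg.inlet_profile == "uniform":
                self.inlet_shape = np.ones(len(inlet_nodes))
            else:
                raise ValueError(f"unknown inlet profile {cfg.inlet_profile!r}")

        idx = []
        val_template = []
        if cfg.wall_slip:
            # verification channels: walls are y-normal, constrain u_y only
            idx.append(wall_nodes + n)
            val_template.append(np.zeros(len(wall_nodes)))
        else:
            idx.append(wall_nodes)
            idx.append(wall_nodes + n)
            val_template.append(np.zeros(len(wall_nodes)))
            val_template.append(np.zeros(len(wall_nodes)))
        if not self.inlet_free:
            self._in_slice = sum(len(i) for i in idx)
            idx.append(inlet_nodes)          # u_x = shape * U(t)
            idx.append(inlet_uy + n)         # u_y = 0
            val_template.append(np.zeros(len(inlet_nodes)))
            val_template.append(np.zeros(len(inlet_uy)))
        self.idx = np.concatenate(idx) if idx else np.empty(0, dtype=np.int64)
        self._val = np.concatenate(val_template) if val_template else np.empty(0)

    def dirichlet(self, inlet_speed: float):
        val = self._val.copy()
        if not self.inlet_free and len(self.inlet_nodes):
            k = self._in_slice
            val[k:k + len(self.inlet_nodes)] = self.inlet_shape * inlet_speed
        return self.idx, val


# --------------------------------------------------------------------------
# Picard iteration
# --------------------------------------------------------------------------

def _picard(disc: P1Discretization, cfg: SolverConfig, rheo: CassonParams,
            permeability: float, dt_coeff: float, hist_x, hist_y,
            dir_idx, dir_val, guess, time=None):
    """Solve one nonlinear (steady or time-step) problem.

    Returns (x, iterations, mom_res, cont_res); ``x`` is the stacked
    [ux, uy, p] vector.  Residuals are normalized by the per-row sum of
    absolute term magnitudes (|A||x| + |b|), a scale-free measure that works
    for both quiescent and pulsatile states.
    """
    n = disc.n
    rho = cfg.density
    x = guess.copy()
    x[dir_idx] = dir_val
    mom_res = cont_res = np.inf
    om_u, om_p = cfg.under_relaxation_u, cfg.under_relaxation_p
    prev_mom = np.inf
    for it in range(cfg.outer_iterations_max + 1):
        ax, ay = x[:n], x[n:2 * n]
        gdot = disc.shear_rates(ax, ay)
        mu_e = apparent_viscosity(gdot, rheo)
        sigma_e = disc.darcy_coeff(mu_e, permeability)
        A_coo, b = disc.assemble(ax, ay, mu_e, sigma_e, rho, dt_coeff,
                                 hist_x, hist_y, cfg.body_force)
        A, bb = disc.apply_dirichlet(A_coo, b, dir_idx, dir_val)

        r = A @ x - bb
        scale = abs(A) @ np.abs(x) + np.abs(bb)
        denom_m = np.linalg.norm(scale[:2 * n])
        denom_c = np.linalg.norm(scale[2 * n:])
        mom_res = np.linalg.norm(r[:2 * n]) / denom_m if denom_m > 0 else 0.0
        cont_res = np.linalg.norm(r[2 * n:]) / denom_c if denom_c > 0 else 0.0
        if mom_res < cfg.momentum_tolerance and cont_res < cfg.continuity_tolerance:
            return x, it, mom_res, cont_res
        if it == cfg.outer_iterations_max:
            break
        # Picard on convection can enter a two-cycle near the tolerance on
        # convection-dominated meshes; damp once progress stalls
        if it >= 2 and mom_res > 0.9 * prev_mom:
            om_u = min(om_u, 0.6)
            om_p = min(om_p, 0.6)
        prev_mom = mom_res

        x_new = spla.spsolve(A.tocsc(), bb)
        # first solve is taken in full: every later iterate is then a convex
        # blend of exact solutions of the linearized system, which keeps the
        # discrete global mass balance exact under under-relaxation
        if it == 0 or (om_u == 1.0 and om_p == 1.0):
            x = x_new
        else:
            w = np.empty(3 * n)
            w[:2 * n] = om_u
            w[2 * n:] = om_p
            x = x + w * (x_new - x)
            x[dir_idx] = dir_val

    raise SolverDivergenceError(
        f"outer iterations exhausted (mom={mom_res:.3e}, cont={cont_res:.3e}"
        + (f", t={time:.4f} s" if time is not None else "") + ")",
        momentum_residual=mom_res, continuity_residual=cont_res, time=time)


# --------------------------------------------------------------------------
# public stepping API
# --------------------------------------------------------------------------

def advance(state: FlowState, dt: float, mesh: Mesh, rheology: CassonParams,
            porous_permeability: float = np.inf,
            bc: BoundaryConditions | None = None,
            cfg: SolverConfig | None = None,
            inlet_speed: float | None = None,
            disc: P1Discretization | None = None,
            prev_state: FlowState | None = None) -> FlowState:
    """Advance one implicit time step; returns the state at t + dt.

    ``inlet_speed`` is the inlet mean velocity at the NEW time level (the
    boundary condition is applied implicitly).  ``prev_state`` enables BDF2.
    """
    cfg = cfg or SolverConfig(dt=dt)
    disc = disc or P1Discretization(mesh)
    bc = bc or BoundaryConditions(mesh, cfg)
    if inlet_speed is None:
        inlet_speed = 0.0

    if cfg.time_scheme == "bdf2" and prev_state is not None:
        dt_coeff = 1.5 / dt
        hist_x = (2.0 * state.ux - 0.5 * prev_state.ux) / dt
        hist_y = (2.0 * state.uy - 0.5 * prev_state.uy) / dt
    else:
        dt_coeff = 1.0 / dt
        hist_x = state.ux / dt
        hist_y = state.uy / dt

    dir_idx, dir_val = bc.dirichlet(inlet_speed)
    guess = np.concatenate([state.ux, state.uy, state.p])
    x, its, mres, cres = _picard(disc, cfg, rheology, porous_permeability,
                                 dt_coeff, hist_x, hist_y, dir_idx, dir_val,
                                 guess, time=state.time + dt)
    n = disc.n
    new = FlowState(time=state.time + dt, ux=x[:n], uy=x[n:2 * n], p=x[2 * n:])
    new._iterations = its          # type: ignore[attr-defined]
    new._residuals = (mres, cres)  # type: ignore[attr-defined]
    return new


def solve_steady(mesh: Mesh, rheology: CassonParams, inlet_speed: float = 0.0,
                 cfg: SolverConfig | None = None,
                 porous_permeability: float = np.inf) -> FlowState:
    """Steady solution (no time derivative) by Picard iteration."""
    cfg = cfg or SolverConfig(under_relaxation_u=0.7, under_relaxation_p=0.7,
                              outer_iterations_max=400)
    disc = P1Discretization(mesh)
    bc = BoundaryConditions(mesh, cfg)
    n = disc.n
    zeros = np.zeros(n)
    dir_idx, dir_val = bc.dirichlet(inlet_speed)
    x, its, mres, cres = _picard(disc, cfg, rheology, porous_permeability,
                                 0.0, zeros, zeros, dir_idx, dir_val,
                                 np.zeros(3 * n))
    st = FlowState(time=0.0, ux=x[:n], uy=x[n:2 * n], p=x[2 * n:])
    st._iterations = its  # type: ignore[attr-defined]
    return st


# --------------------------------------------------------------------------
# transient driver
# --------------------------------------------------------------------------

def run_transient(case, restart=None, progress=False) -> FlowTrajectory:
    """Integrate ``case`` over ``cycles`` cardiac cycles.

    ``case`` is a :class:`aneuflow.case.CaseConfig` (anything exposing
    ``build()``).  Snapshots are stored every ``snapshot_stride`` steps and
    always at the named cycle phases (peak systole, early diastole) of each
    cycle.  Only the final cycle feeds the wall indices downstream.
    """
    mesh, wave, rheo, porous, cfg = case.build()
    disc = P1Discretization(mesh)
    bc = BoundaryConditions(mesh, cfg)
    n = disc.n

    period = wave.period
    steps_per_cycle = max(1, int(round(period / cfg.dt)))
    dt = period / steps_per_cycle  # align the grid with the cycle exactly
    total_steps = cfg.cycles * steps_per_cycle
    phase_steps = {int(round(wave.t_peak_systole / dt)) % steps_per_cycle,
                   int(round(wave.t_early_diastole / dt)) % steps_per_cycle}

    if restart is not None:
        traj, state, prev, start_step = checkpoint_read(restart, expect_n=n)
        traj.mesh, traj.waveform = mesh, wave
        traj.cycles, traj.period, traj.dt = cfg.cycles, period, dt
    else:
        traj = FlowTrajectory(mesh=mesh, waveform=wave, period=period,
                              cycles=cfg.cycles, dt=dt)
        state = FlowState.rest(n)
        prev = None
        traj.states.append(state.copy())
        start_step = 0

    perm = porous.permeability
    for s in range(start_step + 1, total_steps + 1):
        t_new = s * dt
        new = advance(state, dt, mesh, rheo, porous_permeability=perm,
                      bc=bc, cfg=cfg, inlet_speed=float(wave.evaluate(t_new)),
                      disc=disc, prev_state=prev)
        new.time = t_new  # avoid accumulation drift
        traj.residual_log.append({
            "step": s, "time": t_new,
            "iterations": getattr(new, "_iterations", None),
            "momentum_residual": getattr(new, "_residuals", (None, None))[0],
            "continuity_residual": getattr(new, "_residuals", (None, None))[1]})
        prev, state = state, new
        if s % cfg.snapshot_stride == 0 or (s % steps_per_cycle) in phase_steps \
                or s == total_steps:
            traj.states.append(state.copy())
        if progress and s % steps_per_cycle == 0:
            print(f"  cycle {s // steps_per_cycle}/{cfg.cycles} done")

    traj.last_state = state
    traj.prev_state = prev
    return traj


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------

def checkpoint_write(traj: FlowTrajectory, path) -> None:
    """Serialize a trajectory (snapshots + exact restart state) to ``path``."""
    data = {
        "version": np.array([CHECKPOINT_VERSION]),
        "period": np.array([traj.period]),
        "cycles": np.array([traj.cycles]),
        "dt": np.array([traj.dt]),
        "snap_times": np.array([s.time for s in traj.states]),
        "snap_ux": np.array([s.ux for s in traj.states]),
        "snap_uy": np.array([s.uy for s in traj.states]),
        "snap_p": np.array([s.p for s in traj.states]),
    }
    if traj.last_state is not None:
        data["last_time"] = np.array([traj.last_state.time])
        data["last"] = np.stack([traj.last_state.ux, traj.last_state.uy,
                                 traj.last_state.p])
    if traj.prev_state is not None:
        data["prev_time"] = np.array([traj.prev_state.time])
        data["prev"] = np.stack([traj.prev_state.ux, traj.prev_state.uy,
                                 traj.prev_state.p])
    np.savez(path, **data)


def checkpoint_read(path, expect_n: int | None = None):
    """Load a checkpoint; returns (trajectory, last_state, prev_state, step)."""
    try:
        with np.load(path) as z:
            data = {k: z[k] for k in z.files}
    except Exception as exc:
        raise CheckpointError(f"unreadable checkpoint {path}: {exc}") from exc
    if "version" not in data or int(data["version"][0]) != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version mismatch (need {CHECKPOINT_VERSION})")
    dt = float(data["dt"][0])
    traj = FlowTrajectory(mesh=None, waveform=None,
                          period=float(data["period"][0]),
                          cycles=int(data["cycles"][0]), dt=dt)
    for t, ux, uy, p in zip(data["snap_times"], data["snap_ux"],
                            data["snap_uy"], data["snap_p"]):
        traj.states.append(FlowState(time=float(t), ux=ux, uy=uy, p=p))
    if "last" not in data:
        raise CheckpointError("checkpoint lacks a restart state")
    last = FlowState(time=float(data["last_time"][0]), ux=data["last"][0],
                     uy=data["last"][1], p=data["last"][2])
    prev = None
    if "prev" in data:
        prev = FlowState(time=float(data["prev_time"][0]), ux=data["prev"][0],
                         uy=data["prev"][1], p=data["prev"][2])
    if expect_n is not None and len(last.ux) != expect_n:
        raise CheckpointError("checkpoint mesh size does not match the case")
    step = int(round(last.time / dt))
    traj.last_state, traj.prev_state = last, prev
    return traj, last, prev, step
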