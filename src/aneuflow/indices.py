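"""Wall shear stress, TAWSS, OSI and wall-pressure statistics.

Wall shear is the tangential component of the full viscous traction
``mu_app * (grad u + grad u^T) . n`` on each wall facet (boundary edge),
evaluated from the adjacent element's P1 gradient.  Over the final cardiac
cycle the per-facet time series tau(t) yields

    TAWSS = (1/T) * int ||tau|| dt
    OSI   = 1/2 * (1 - ||int tau dt|| / int ||tau|| dt)   in [0, 1/2]

by trapezoidal quadrature on the stored snapshot times.  OSI of an
identically zero series (a stagnant facet) is defined as 0 and flagged.
Region aggregates (sac wall vs vessel wall) are the facet maximum and the
facet-length-weighted average, the 2D surrogate of an area-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mesh as _mesh
from .fem import P1Discretization
from .mesh import Mesh
from .rheology import CassonParams, apparent_viscosity
from .solver import FlowState, FlowTrajectory

__all__ = ["WallShearSeries", "IndicesReport", "wall_geometry", "wall_shear",
           "osi", "tawss", "aggregate", "report"]


@dataclass(frozen=True)
class WallGeometry:
    """Static facet data for the tagged walls of a mesh."""

    edge_index: np.ndarray   # indices into mesh.boundary_edges
    edges: np.ndarray        # (F, 2) node pairs
    cells: np.ndarray        # (F,) adjacent triangle
    normals: np.ndarray      # (F, 2) outward unit normals
    lengths: np.ndarray      # (F,)
    midpoints: np.ndarray    # (F, 2)
    region: np.ndarray       # (F,) WALL_VESSEL | WALL_SAC


def wall_geometry(mesh: Mesh) -> WallGeometry:
    if "wall_geometry" in mesh._cache:
        return mesh._cache["wall_geometry"]
    tags = mesh.boundary_tags
    mask = (tags == _mesh.WALL_VESSEL) | (tags == _mesh.WALL_SAC)
    idx = np.flatnonzero(mask)
    edges = mesh.boundary_edges[idx]
    wg = WallGeometry(
        edge_index=idx,
        edges=edges,
        cells=mesh.boundary_edge_cells()[idx],
        normals=mesh.boundary_edge_normals()[idx],
        lengths=mesh.edge_lengths(edges),
        midpoints=0.5 * (mesh.points[edges[:, 0]] + mesh.points[edges[:, 1]]),
        region=tags[idx].copy())
    mesh._cache["wall_geometry"] = wg
    return wg


def wall_shear(state: FlowState, mesh: Mesh, rheology: CassonParams,
               facets: np.ndarray | None = None) -> np.ndarray:
    """Tangential wall traction vectors, (F, 2) in Pa.

    ``facets`` selects boundary-edge indices; they must all carry a WALL_*
    tag (default: every wall facet).
    """
    wg = wall_geometry(mesh)
    if facets is None:
        sel = slice(None)
    else:
        facets = np.asarray(facets)
        pos = {e: i for i, e in enumerate(wg.edge_index)}
        missing = [int(f) for f in facets if f not in pos]
        if missing:
            raise ValueError(f"facets {missing} are not on a WALL_* boundary")
        sel = np.array([pos[f] for f in facets])
    cells = wg.cells[sel]
    n = wg.normals[sel]

    disc = mesh._cache.setdefault("p1disc", P1Discretization(mesh))
    dudx, dudy, dvdx, dvdy = disc.element_gradients(state.ux, state.uy)
    gdot = np.sqrt(2.0 * (dudx ** 2 + dvdy ** 2) + (dudy + dvdx) ** 2)
    mu = apparent_viscosity(gdot, rheology)
    # full stress 2*mu*D, traction on the facet normal
    sxx = 2.0 * mu * dudx
    syy = 2.0 * mu * dvdy
    sxy = mu * (dudy + dvdx)
    tx = sxx[cells] * n[:, 0] + sxy[cells] * n[:, 1]
    ty = sxy[cells] * n[:, 0] + syy[cells] * n[:, 1]
    t = np.column_stack([tx, ty])
    t -= (np.einsum("ij,ij->i", t, n))[:, None] * n  # remove normal part
    return t


@dataclass
class WallShearSeries:
    """Time series of wall shear vectors over one cycle for all wall facets."""

    times: np.ndarray        # (nt,) strictly increasing, spanning one period
    tau: np.ndarray          # (nt, F, 2) Pa
    geometry: WallGeometry | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.tau)):
            raise ValueError("non-finite wall shear values")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])


def tawss(series: WallShearSeries) -> np.ndarray:
    """Time-averaged magnitude of the wall shear vector, per facet (Pa)."""
    mag = np.linalg.norm(series.tau, axis=2)
    return np.trapezoid(mag, series.times, axis=0) / series.period


def osi(series: WallShearSeries, return_flags: bool = False):
    """Oscillatory shear index per facet; 0 for an identically zero series."""
    mag = np.linalg.norm(series.tau, axis=2)
    int_mag = np.trapezoid(mag, series.times, axis=0)
    int_vec = np.trapezoid(series.tau, series.times, axis=0)
    mean_mag = np.linalg.norm(int_vec, axis=1)
    degenerate = int_mag == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 0.5 * (1.0 - mean_mag / int_mag)
    val[degenerate] = 0.0
    val = np.maximum(val, 0.0)  # guard roundoff at perfectly steady facets
    if return_flags:
        return val, degenerate
    return val


def aggregate(per_facet_values, mesh: Mesh, region_tag: str):
    """(max, facet-length-weighted average) of a per-wall-facet field."""
    wg = wall_geometry(mesh)
    sel = wg.region == region_tag
    if not np.any(sel):
        raise ValueError(f"no wall facets tagged {region_tag}")
    v = np.asarray(per_facet_values)[sel]
    ln = wg.lengths[sel]
    return float(v.max()), float(np.sum(v * ln) / np.sum(ln))


def _wall_pressure_stats(state: FlowState, mesh: Mesh, region_tag: str):
    wg = wall_geometry(mesh)
    sel = wg.region == region_tag
    edges = wg.edges[sel]
    ln = wg.lengths[sel]
    pm = 0.5 * (state.p[edges[:, 0]] + state.p[edges[:, 1]])
    return float(state.p[np.unique(edges)].max()), float(np.sum(pm * ln) / np.sum(ln))


@dataclass
class IndicesReport:
    """Per-facet wall indices and per-region aggregates for one run."""

    facet_frame: pd.DataFrame          # facet_id,x,y,region,tawss,osi,mean_tau,stagnant
    region_stats: dict                 # region -> dict of aggregates
    phase_times: dict                  # name -> absolute snapshot time

    def region_frame(self) -> pd.DataFrame:
        rows = []
        for region, st in self.region_stats.items():
            rows.append({"region": region, **st})
        return pd.DataFrame(rows)

    def write_csv(self, facet_path, region_path) -> None:
        self.facet_frame.to_csv(facet_path, index=False)
        self.region_frame().to_csv(region_path, index=False)


def report(trajectory: FlowTrajectory, mesh: Mesh | None = None,
           rheology: CassonParams | None = None) -> IndicesReport:
    """Assemble TAWSS/OSI/pressure statistics from the final cardiac cycle.

    Requires the trajectory to contain snapshots spanning the final cycle
    and the two named phase instants (peak systole, early diastole).
    Deterministic: identical trajectories yield identical reports.
    """
    mesh = mesh if mesh is not None else trajectory.mesh
    if rheology is None:
        raise ValueError("rheology parameters are required")
    states = trajectory.final_cycle()
    if len(states) < 3:
        raise ValueError("trajectory does not contain a resolved final cycle")
    times = np.array([s.time for s in states])
    if times[-1] - times[0] < trajectory.period * (1 - 1e-9):
        raise ValueError("final-cycle snapshots do not span a full period")

    wg = wall_geometry(mesh)
    tau = np.empty((len(states), len(wg.edges), 2))
    for i, s in enumerate(states):
        tau[i] = wall_shear(s, mesh, rheology)
    series = WallShearSeries(times=times, tau=tau, geometry=wg)

    tw = tawss(series)
    os_, stagnant = osi(series, return_flags=True)
    mean_tau = np.linalg.norm(
        np.trapezoid(series.tau, times, axis=0), axis=1) / series.period

    facet_frame = pd.DataFrame({
        "facet_id": wg.edge_index,
        "x": wg.midpoints[:, 0], "y": wg.midpoints[:, 1],
        "length": wg.lengths, "region": wg.region,
        "tawss": tw, "osi": os_, "mean_tau": mean_tau,
        "stagnant": stagnant})

    t0 = times[0]
    wave = trajectory.waveform
    phases = {}
    if wave is not None:
        phases = {"peak_systole": t0 + wave.t_peak_systole,
                  "early_diastole": t0 + wave.t_early_diastole}
    phase_states = {}
    for name, t in phases.items():
        try:
            phase_states[name] = trajectory.state_at(t, tol=1e-9 * trajectory.period)
        except KeyError as exc:
            raise ValueError(f"missing {name} snapshot at t={t}") from exc

    region_stats = {}
    for region in (_mesh.WALL_SAC, _mesh.WALL_VESSEL):
        if not np.any(wg.region == region):
            continue
        max_tw, avg_tw = aggregate(tw, mesh, region)
        max_os, avg_os = aggregate(os_, mesh, region)
        st = {"max_tawss": max_tw, "avg_tawss": avg_tw,
              "max_osi": max_os, "avg_osi": avg_os,
              "n_stagnant": int(stagnant[wg.region == region].sum())}
        for name, ps in phase_states.items():
            pmax, pavg = _wall_pressure_stats(ps, mesh, region)
            st[f"max_pressure_{name}"] = pmax
            st[f"avg_pressure_{name}"] = pavg
        region_stats[region] = st

    return IndicesReport(facet_frame=facet_frame, region_stats=region_stats,
                         phase_times={k: float(v) for k, v in phases.items()})
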