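"""Case configuration: geometry + waveform + rheology + coil + solver.

A case can be built programmatically or loaded from YAML.  Lengths/times in
YAML may carry unit suffixes (``"3 mm"``, ``"30 cm"``, ``"0.8 s"``); bare
numbers are SI.  Example::

    geometry:
      vessel_diameter: 3 mm
      dome_diameter: 5 mm
      neck_width: 2.5 mm
      mesh_size: 0.2 mm
    waveform: {profile: default_mca, period: 0.8 s,
               mean_velocity: 0.25, peak_velocity: 0.5}
    rheology: {hematocrit: 0.40}
    coil: {porosity: from_coil,
           coil: {wire_diameter: 0.254 mm, length: 30 cm, sac_volume: 103.87 mm^3}}
    solver: {dt: 0.002 s, cycles: 3}
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .coil import CoilSpec, PorousProps, permeability_for_porosity, porosity_from_coil
from .geometry import GeometryParams, build_idealized_geometry
from .mesh import Mesh
from .mesh_io import read_mesh
from .rheology import CassonParams, newtonian_params, params_from_hematocrit
from .solver import SolverConfig
from .units import parse_quantity
from .waveform import Waveform, generate_waveform

__all__ = ["CaseConfig", "load_case", "default_case", "coarse_case"]


@dataclass
class CaseConfig:
    """Complete description of one simulation."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    mesh_path: str | None = None          # external mesh overrides geometry
    waveform_profile: str = "default_mca"
    period: float = 0.8
    mean_velocity: float = 0.25
    peak_velocity: float = 0.5
    hematocrit: float | None = 0.40
    tau_y: float | None = None            # explicit rheology override
    mu_inf: float | None = None
    gamma_dot_min: float = 1e-3
    porosity: float | str = 1.0           # float or "from_coil"
    coil: CoilSpec | None = None
    permeability: float | str = "table"   # "table" or explicit m^2
    solver: SolverConfig = field(default_factory=SolverConfig)
    name: str = "case"

    # ------------------------------------------------------------------
    def resolved_porosity(self) -> float:
        if self.porosity == "from_coil":
            if self.coil is None:
                raise ValueError("porosity: from_coil requires a coil block")
            return porosity_from_coil(self.coil)
        return float(self.porosity)

    def porous_props(self) -> PorousProps:
        eps = self.resolved_porosity()
        if self.permeability == "table":
            k = permeability_for_porosity(eps)
        else:
            k = float(self.permeability)
        return PorousProps(porosity=eps, permeability=k)

    def rheology_params(self) -> CassonParams:
        if self.tau_y is not None or self.mu_inf is not None:
            if self.tau_y is None or self.mu_inf is None:
                raise ValueError("explicit rheology needs both tau_y and mu_inf")
            return CassonParams(tau_y=self.tau_y, mu_inf=self.mu_inf,
                                gamma_dot_min=self.gamma_dot_min)
        if self.hematocrit is None:
            raise ValueError("give hematocrit or explicit {tau_y, mu_inf}")
        return params_from_hematocrit(self.hematocrit,
                                      gamma_dot_min=self.gamma_dot_min)

    def waveform(self) -> Waveform:
        return generate_waveform(self.waveform_profile, period=self.period,
                                 mean_velocity=self.mean_velocity,
                                 peak_velocity=self.peak_velocity)

    def build_mesh(self) -> Mesh:
        if self.mesh_path is not None:
            return read_mesh(self.mesh_path)
        return build_idealized_geometry(self.geometry)

    def build(self):
        """(mesh, waveform, rheology, porous, solver) tuple for the solver."""
        return (self.build_mesh(), self.waveform(), self.rheology_params(),
                self.porous_props(), self.solver)

    def with_(self, **kw) -> "CaseConfig":
        """Functional update (dataclasses.replace passthrough)."""
        return replace(self, **kw)


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def default_case() -> CaseConfig:
    """Production-resolution case (0.2 mm mesh, dt = 2 ms, 3 cycles)."""
    return CaseConfig()


def coarse_case() -> CaseConfig:
    """Coarse desk-scale fixture used by the test-suite and sweeps.

    0.4 mm mesh (~1.4k cells), dt = 5 ms (160 steps/cycle), 3 cycles; keeps
    a full 3x3 hematocrit x porosity sweep within a few CPU-minutes.
    """
    return CaseConfig(
        geometry=GeometryParams(mesh_size=0.4e-3),
        solver=SolverConfig(dt=0.005, cycles=3, snapshot_stride=4),
        name="coarse_fixture")


# --------------------------------------------------------------------------
# YAML loading
# --------------------------------------------------------------------------

def _geometry_from_dict(d: dict) -> GeometryParams:
    kw = {}
    lengths = {"vessel_diameter", "vessel_length", "dome_diameter",
               "neck_width", "sac_stand_off", "mesh_size"}
    for k, v in d.items():
        if k in lengths:
            kw[k] = parse_quantity(v, "length")
        elif k == "boundary_layer_layers":
            kw[k] = int(v)
        elif k == "boundary_layer_growth":
            kw[k] = float(v)
        else:
            raise ValueError(f"unknown geometry key {k!r}")
    return GeometryParams(**kw)


def _solver_from_dict(d: dict) -> SolverConfig:
    kw = dict(d)
    if "dt" in kw:
        kw["dt"] = parse_quantity(kw["dt"], "time")
    if "body_force" in kw:
        kw["body_force"] = tuple(float(v) for v in kw["body_force"])
    valid = {f.name for f in dataclasses.fields(SolverConfig)}
    unknown = set(kw) - valid
    if unknown:
        raise ValueError(f"unknown solver keys {sorted(unknown)}")
    return SolverConfig(**kw)


def load_case(path) -> CaseConfig:
    """Load a case configuration from a YAML file."""
    with open(path) as f:
        doc = yaml.safe_load(f) or {}
    kw: dict = {}
    if "geometry" in doc:
        kw["geometry"] = _geometry_from_dict(doc["geometry"])
    if "mesh" in doc:
        kw["mesh_path"] = str(doc["mesh"])
    wv = doc.get("waveform", {})
    if wv:
        kw["waveform_profile"] = wv.get("profile", "default_mca")
        if "period" in wv:
            kw["period"] = parse_quantity(wv["period"], "time")
        for key in ("mean_velocity", "peak_velocity"):
            if key in wv:
                kw[key] = float(wv[key])
    rh = doc.get("rheology", {})
    if rh:
        if "hematocrit" in rh:
            kw["hematocrit"] = float(rh["hematocrit"])
        for key in ("tau_y", "mu_inf"):
            if key in rh:
                kw[key] = float(rh[key])
                kw.setdefault("hematocrit", None)
        if "gamma_dot_min" in rh:
            kw["gamma_dot_min"] = float(rh["gamma_dot_min"])
    cl = doc.get("coil", {})
    if cl:
        kw["porosity"] = cl.get("porosity", 1.0)
        if kw["porosity"] != "from_coil":
            kw["porosity"] = float(kw["porosity"])
        if "coil" in cl:
            c = cl["coil"]
            kw["coil"] = CoilSpec(
                wire_diameter=parse_quantity(c["wire_diameter"], "length"),
                length=parse_quantity(c["length"], "length"),
                sac_volume=parse_quantity(c["sac_volume"], "volume"))
        kw["permeability"] = cl.get("permeability", "table")
        if kw["permeability"] != "table":
            kw["permeability"] = float(kw["permeability"])
    if "solver" in doc:
        kw["solver"] = _solver_from_dict(doc["solver"])
    if "name" in doc:
        kw["name"] = str(doc["name"])
    return CaseConfig(**kw)
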