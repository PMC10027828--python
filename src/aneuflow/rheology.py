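"""Casson blood rheology with hematocrit-dependent coefficients.

Blood is shear-thinning with a small yield stress; the Casson law

    sqrt(tau) = sqrt(tau_y) + sqrt(mu_inf * gamma_dot)

gives the apparent viscosity

    mu(gamma_dot) = (sqrt(tau_y / gamma_dot) + sqrt(mu_inf))**2

which diverges as gamma_dot -> 0.  A shear-rate floor ``gamma_dot_min``
regularizes the stagnant limit (simple, monotone, and adequate because wall
shear in stagnant zones is near zero anyway).

The hematocrit dependence uses a Merrill-type yield stress and an
Einstein-type suspension viscosity:

    tau_y(H)   = 0.1 * (0.625 * H)**3        [Pa]
    mu_inf(H)  = eta_p * (1 - H)**(-2.5)     [Pa s]

with plasma viscosity eta_p = 1.45 mPa s.  Both are strictly increasing in
H, so hematocrit sweeps raise both the yield stress and the asymptotic
viscosity, as physiology requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CassonParams", "params_from_hematocrit", "newtonian_params",
           "apparent_viscosity", "shear_rate"]

DEFAULT_PLASMA_VISCOSITY = 0.00145  # Pa s
DEFAULT_GAMMA_DOT_MIN = 1e-3  # 1/s


@dataclass(frozen=True)
class CassonParams:
    """Casson coefficients.  ``tau_y == 0`` degenerates to a Newtonian fluid."""

    tau_y: float          # yield stress, Pa
    mu_inf: float         # asymptotic (high-shear) viscosity, Pa s
    hematocrit: float | None = None
    eta_p: float = DEFAULT_PLASMA_VISCOSITY
    gamma_dot_min: float = DEFAULT_GAMMA_DOT_MIN

    def __post_init__(self):
        if self.hematocrit is not None and not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.tau_y < 0:
            raise ValueError("yield stress must be >= 0")
        if self.mu_inf <= 0:
            raise ValueError("asymptotic viscosity must be positive")
        if self.gamma_dot_min <= 0:
            raise ValueError("shear-rate floor must be positive")


def params_from_hematocrit(H: float, eta_p: float = DEFAULT_PLASMA_VISCOSITY,
                           gamma_dot_min: float = DEFAULT_GAMMA_DOT_MIN) -> CassonParams:
    """Casson coefficients for red-cell volume fraction ``H`` (0 < H < 1)."""
    if not 0.0 < H < 1.0:
        raise ValueError(f"hematocrit must lie in (0, 1), got {H}")
    tau_y = 0.1 * (0.625 * H) ** 3
    mu_inf = eta_p * (1.0 - H) ** -2.5
    return CassonParams(tau_y=tau_y, mu_inf=mu_inf, hematocrit=H,
                        eta_p=eta_p, gamma_dot_min=gamma_dot_min)


def newtonian_params(mu: float) -> CassonParams:
    """A constant-viscosity fluid expressed in the same parameter container."""
    return CassonParams(tau_y=0.0, mu_inf=mu)


def apparent_viscosity(gamma_dot, p: CassonParams):
    """Regularized Casson apparent viscosity, elementwise on arrays.

    Total on gamma_dot >= 0; the floor keeps the value finite at zero shear.
    For ``tau_y == 0`` the exact constant ``mu_inf`` is returned, so a
    zero-yield run is bit-identical to a constant-viscosity Newtonian run.
    """
    gamma_dot = np.asarray(gamma_dot, dtype=float)
    if p.tau_y == 0.0:
        out = np.full(gamma_dot.shape, p.mu_inf)
        return out if out.shape else float(p.mu_inf)
    g = np.maximum(gamma_dot, p.gamma_dot_min)
    mu = (np.sqrt(p.tau_y / g) + np.sqrt(p.mu_inf)) ** 2
    return mu if mu.shape else float(mu)


def shear_rate(grad_u):
    """Shear-rate magnitude sqrt(2 D:D) from velocity gradient(s).

    ``grad_u`` has shape (..., 2, 2) with entries d u_i / d x_j.
    """
    g = np.asarray(grad_u, dtype=float)
    d11 = g[..., 0, 0]
    d22 = g[..., 1, 1]
    d12 = 0.5 * (g[..., 0, 1] + g[..., 1, 0])
    val = np.sqrt(2.0 * (d11 ** 2 + d22 ** 2 + 2.0 * d12 ** 2))
    return val if val.shape else float(val)
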