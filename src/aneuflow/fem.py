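"""Stabilized P1-P1 finite-element discretization of incompressible flow.

Unknown ordering: [u_x (N), u_y (N), p (N)] on mesh nodes.  Momentum uses
the gradient (Laplacian) form of the viscous term, whose natural boundary
condition is the classical do-nothing outlet (mu*du/dn - p*n = 0); wall
shear stress is post-processed from the full stress tensor separately.

Equal-order velocity/pressure interpolation is stabilized with SUPG/PSPG:
element residual terms are weighted by

    tau_T = [ (2*rho*c_t)^2 + (2*rho*|a|/h)^2 + (12*mu/h^2)^2
              + (mu/k)^2 ]^(-1/2)

where c_t is the transient coefficient (alpha0/dt), a the advection field
of the current Picard iterate, and mu/k the Darcy sink coefficient in the
porous (coiled sac) cells.  With P1 elements the strong residual has no
second derivatives, so the stabilization terms are simple products of
per-element constants; everything is assembled vectorized over elements.

Sum over an element's basis functions of each gradient component is zero,
so the PSPG rows sum to zero against a constant test function and the
discrete global mass balance (inflow = outflow) is exact at solver
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import mesh as _mesh
from .mesh import Mesh

__all__ = ["P1Discretization"]


@dataclass
class _Geom:
    tri: np.ndarray      # (M, 3) node ids
    gx: np.ndarray       # (M, 3) d(phi_i)/dx
    gy: np.ndarray       # (M, 3) d(phi_i)/dy
    area: np.ndarray     # (M,)
    h: np.ndarray        # (M,) element size sqrt(2*area)


class P1Discretization:
    """Assembly engine bound to one mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.n = mesh.n_points
        self.geom = self._precompute(mesh)
        self.sac_cells = mesh.cell_region == _mesh.SAC
        # COO scatter pattern: for each element, 3x3 block row/col node ids
        tri = self.geom.tri
        self._rows33 = np.repeat(tri, 3, axis=1)          # (M, 9) test idx
        self._cols33 = np.tile(tri, (1, 3))               # (M, 9) trial idx

    @staticmethod
    def _precompute(mesh: Mesh) -> _Geom:
        tri = mesh.triangles
        p = mesh.points[tri]
        x, y = p[..., 0], p[..., 1]
        area2 = ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
                 - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
        area = 0.5 * area2
        if np.any(area <= 0):
            raise ValueError("mesh must be positively oriented")
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        gx = b / area2[:, None]
        gy = c / area2[:, None]
        return _Geom(tri=tri, gx=gx, gy=gy, area=area, h=np.sqrt(2.0 * area))

    # ------------------------------------------------------------------
    def element_gradients(self, ux, uy):
        """Per-element velocity gradient tensor entries (each (M,))."""
        g = self.geom
        t = g.tri
        dudx = np.einsum("mi,mi->m", g.gx, ux[t])
        dudy = np.einsum("mi,mi->m", g.gy, ux[t])
        dvdx = np.einsum("mi,mi->m", g.gx, uy[t])
        dvdy = np.einsum("mi,mi->m", g.gy, uy[t])
        return dudx, dudy, dvdx, dvdy

    def shear_rates(self, ux, uy):
        dudx, dudy, dvdx, dvdy = self.element_gradients(ux, uy)
        return np.sqrt(2.0 * (dudx ** 2 + dvdy ** 2) + (dudy + dvdx) ** 2)

    def darcy_coeff(self, mu_e, permeability: float):
        """Element Darcy coefficient mu/k on SAC cells, exactly 0 elsewhere."""
        sigma = np.zeros(len(mu_e))
        if np.isfinite(permeability):
            sigma[self.sac_cells] = mu_e[self.sac_cells] / permeability
        return sigma

    # ------------------------------------------------------------------
    def assemble(self, a_x, a_y, mu_e, sigma_e, rho, dt_coeff,
                 hist_x, hist_y, body_force=(0.0, 0.0)):
        """Assemble the linearized coupled system A x = b.

        Parameters
        ----------
        a_x, a_y : nodal advection field (previous Picard iterate)
        mu_e : per-element apparent viscosity
        sigma_e : per-element Darcy coefficient mu/k (0 outside the sac)
        rho : density
        dt_coeff : coefficient of the new velocity in the time derivative
            (1/dt for implicit Euler, 1.5/dt for BDF2, 0 for steady)
        hist_x, hist_y : nodal time-history field so the momentum RHS term
            is rho*hist (u_old/dt for implicit Euler, etc.)
        body_force : constant (f_x, f_y) in N/m^3
        """
        g = self.geom
        t = g.tri
        M_, n = len(t), self.n
        A = g.area
        fx, fy = body_force

        axm = a_x[t].mean(axis=1)
        aym = a_y[t].mean(axis=1)
        amag = np.hypot(axm, aym)
        tau = 1.0 / np.sqrt((2.0 * rho * dt_coeff) ** 2
                            + (2.0 * rho * amag / g.h) ** 2
                            + (12.0 * mu_e / g.h ** 2) ** 2
                            + sigma_e ** 2)

        # a . grad(phi_j), constant per element: (M, 3)
        adg = axm[:, None] * g.gx + aym[:, None] * g.gy

        # consistent mass block (M, 3, 3)
        eye_off = (np.ones((3, 3)) + np.eye(3)) / 12.0
        Mloc = A[:, None, None] * eye_off[None]

        # diffusion
        Kloc = (mu_e * A)[:, None, None] * (
            g.gx[:, :, None] * g.gx[:, None, :] + g.gy[:, :, None] * g.gy[:, None, :])

        # Galerkin advection: int phi_i (a.grad phi_j) = A/3 * adg_j
        Cloc = (rho * A / 3.0)[:, None, None] * np.broadcast_to(
            adg[:, None, :], (M_, 3, 3))

        # momentum block shared by both components
        mom = (rho * dt_coeff + sigma_e)[:, None, None] * Mloc + Kloc + Cloc

        # SUPG weight per test function: tau * rho * (a.grad phi_i)
        w = (tau * rho)[:, None] * adg                      # (M, 3)
        supg_uu = w[:, :, None] * A[:, None, None] * (
            (rho * dt_coeff / 3.0 + sigma_e / 3.0)[:, None, None]
            + rho * adg[:, None, :])
        mom = mom + supg_uu

        # pressure gradient coupling: Galerkin -A/3 * g_i  (indep of j)
        gpx = -(A / 3.0)[:, None, None] * np.broadcast_to(
            g.gx[:, :, None], (M_, 3, 3))
        gpy = -(A / 3.0)[:, None, None] * np.broadcast_to(
            g.gy[:, :, None], (M_, 3, 3))
        # SUPG pressure coupling: w_i * A * g_j
        gpx = gpx + w[:, :, None] * A[:, None, None] * g.gx[:, None, :]
        gpy = gpy + w[:, :, None] * A[:, None, None] * g.gy[:, None, :]

        # continuity: Galerkin  A/3 * g_j  (indep of i)
        dux = (A / 3.0)[:, None, None] * np.broadcast_to(
            g.gx[:, None, :], (M_, 3, 3))
        duy = (A / 3.0)[:, None, None] * np.broadcast_to(
            g.gy[:, None, :], (M_, 3, 3))
        # PSPG velocity coupling
        coef = (rho * dt_coeff / 3.0 + sigma_e / 3.0)[:, None, None] + rho * adg[:, None, :]
        dux = dux + (tau * A)[:, None, None] * g.gx[:, :, None] * coef
        duy = duy + (tau * A)[:, None, None] * g.gy[:, :, None] * coef
        # PSPG pressure Laplacian
        ppp = (tau * A)[:, None, None] * (
            g.gx[:, :, None] * g.gx[:, None, :] + g.gy[:, :, None] * g.gy[:, None, :])

        rows, cols, vals = [], [], []
        r33 = self._rows33.reshape(M_, 3, 3)
        c33 = self._cols33.reshape(M_, 3, 3)
        # note: rows33 repeats tri entries rowwise -> r33[m,i,j] = tri[m,i]
        # cols33 tiles -> c33[m,i,j] = tri[m,j]

        def scatter(block, roff, coff):
            rows.append((r33 + roff).ravel())
            cols.append((c33 + coff).ravel())
            vals.append(block.ravel())

        scatter(mom, 0, 0)
        scatter(mom, n, n)
        scatter(gpx, 0, 2 * n)
        scatter(gpy, n, 2 * n)
        scatter(dux, 2 * n, 0)
        scatter(duy, 2 * n, n)
        scatter(ppp, 2 * n, 2 * n)

        A_coo = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(3 * n, 3 * n))

        # ------------------------------------------------------------ RHS
        b = np.zeros(3 * n)
        hxl = hist_x[t]                      # (M, 3)
        hyl = hist_y[t]
        hxm = hxl.mean(axis=1)
        hym = hyl.mean(axis=1)
        # Galerkin momentum RHS: rho * M * hist + f * A/3
        mx = rho * np.einsum("mij,mj->mi", Mloc, hxl) + fx * (A / 3.0)[:, None]
        my = rho * np.einsum("mij,mj->mi", Mloc, hyl) + fy * (A / 3.0)[:, None]
        # SUPG momentum RHS
        mx = mx + w * (A * (rho * hxm + fx))[:, None]
        my = my + w * (A * (rho * hym + fy))[:, None]
        np.add.at(b, t.ravel(), mx.ravel())
        np.add.at(b, (t + n).ravel(), my.ravel())
        # PSPG continuity RHS
        pr = (tau * A)[:, None] * (g.gx * (rho * hxm + fx)[:, None]
                                   + g.gy * (rho * hym + fy)[:, None])
        np.add.at(b, (t + 2 * n).ravel(), pr.ravel())

        return A_coo, b

    # ------------------------------------------------------------------
    def apply_dirichlet(self, A_coo: sp.coo_matrix, b, dir_idx, dir_val):
        """Replace Dirichlet rows by identity (columns kept)."""
        is_dir = np.zeros(3 * self.n, dtype=bool)
        is_dir[dir_idx] = True
        keep = ~is_dir[A_coo.row]
        A = sp.coo_matrix((np.concatenate([A_coo.data[keep], np.ones(len(dir_idx))]),
                           (np.concatenate([A_coo.row[keep], dir_idx]),
                            np.concatenate([A_coo.col[keep], dir_idx]))),
                          shape=A_coo.shape).tocsr()
        b = b.copy()
        b[dir_idx] = dir_val
        return A, b

    # ------------------------------------------------------------------
    def boundary_flux(self, ux, uy, tag: str) -> float:
        """Outward volume flux through the edges tagged ``tag`` (m^2/s in 2D)."""
        mesh = self.mesh
        edges = mesh.edges_for(tag)
        if not len(edges):
            return 0.0
        normals = mesh.boundary_edge_normals()[mesh.boundary_tags == tag]
        lengths = mesh.edge_lengths(edges)
        um = 0.5 * (np.column_stack([ux[edges[:, 0]], uy[edges[:, 0]]])
                    + np.column_stack([ux[edges[:, 1]], uy[edges[:, 1]]]))
        return float(np.sum(lengths * np.einsum("ij,ij->i", um, normals)))
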