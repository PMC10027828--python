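"""Idealized side-wall aneurysm geometry and meshing.

The synthetic case is a straight 2D parent vessel (a channel of height
``vessel_diameter``) carrying, on its upper wall, a circular saccular bulge
of diameter ``dome_diameter`` connected through a neck of width
``neck_width``.  The dome circle is positioned so its chord on the wall line
equals the neck width; everything above the wall line is the sac.  A planar
idealization is used deliberately: the solver physics (rheology, porous
sink, wall indices) are dimension-agnostic and the 2D case keeps the whole
pipeline runnable on a desktop, at the cost of the patient-specific 3D flow
structures.

Meshing strategy: boundary polylines are sampled at ``mesh_size``; graded
boundary-layer point rows are offset from the vessel and sac walls; a
hex-packed interior cloud fills the rest; scipy's Delaunay triangulates the
cloud and triangles whose centroid falls outside the domain are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from . import mesh as _mesh
from .mesh import Mesh

__all__ = ["GeometryParams", "MeshingError", "build_idealized_geometry",
           "build_channel_mesh", "sac_segment_area"]


class MeshingError(RuntimeError):
    """Meshing failed; the message names the violated constraint."""


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the idealized vessel + sac, SI units (meters)."""

    vessel_diameter: float = 3.0e-3
    vessel_length: float = 16.0e-3
    dome_diameter: float = 5.0e-3
    neck_width: float = 2.5e-3
    sac_stand_off: float | None = None   # neck-center x; default mid-vessel
    mesh_size: float = 0.2e-3
    boundary_layer_layers: int = 3
    boundary_layer_growth: float = 1.3

    def __post_init__(self):
        for name in ("vessel_diameter", "vessel_length", "dome_diameter",
                     "neck_width", "mesh_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.neck_width >= self.dome_diameter:
            raise ValueError("neck_width must be smaller than dome_diameter")
        if self.neck_width >= self.vessel_length:
            raise ValueError("neck_width must be smaller than vessel_length")
        if self.boundary_layer_layers < 0:
            raise ValueError("boundary_layer_layers must be >= 0")
        if self.boundary_layer_growth < 1.0:
            raise ValueError("boundary_layer_growth must be >= 1")

    @property
    def neck_center(self) -> float:
        return self.vessel_length / 2.0 if self.sac_stand_off is None else self.sac_stand_off


def sac_segment_area(params: GeometryParams) -> float:
    """Analytic area of the circular sac segment above the wall line."""
    R = params.dome_diameter / 2.0
    half_w = params.neck_width / 2.0
    hc = math.sqrt(R * R - half_w * half_w)
    return math.pi * R * R - (R * R * math.acos(hc / R) - hc * half_w)


# --------------------------------------------------------------------------
# point placement helpers
# --------------------------------------------------------------------------

def _polyline(p0, p1, h):
    """Points from p0 to p1 (inclusive) at spacing ~h."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n = max(1, int(round(np.linalg.norm(p1 - p0) / h)))
    t = np.linspace(0.0, 1.0, n + 1)
    return p0 + t[:, None] * (p1 - p0)


def _march(total, spacing):
    """Arclength positions 0..total with local step ``spacing(s)``."""
    xs = [0.0]
    while xs[-1] < total:
        xs.append(xs[-1] + max(spacing(xs[-1]), 1e-3 * total))
    xs = np.asarray(xs)
    return xs * (total / xs[-1])


def _corner_spacing(h, h_fine, *corner_dists):
    """Spacing field: ``h_fine`` at tagged corners, growing ~0.8/dist to h."""
    def fn(s):
        d = min(abs(s - c) for c in corner_dists)
        return float(np.clip(h_fine + 0.8 * d, h_fine, h))
    return fn


def _bl_offsets(params: GeometryParams):
    """Cumulative wall-normal offsets of the boundary-layer rows."""
    n = params.boundary_layer_layers
    if n == 0:
        return np.empty(0)
    g = params.boundary_layer_growth
    total = 0.6 * params.mesh_size
    if g == 1.0:
        t0 = total / n
    else:
        t0 = total * (g - 1.0) / (g ** n - 1.0)
    return np.array([t0 * (g ** (j + 1) - 1.0) / (g - 1.0) if g != 1.0
                     else t0 * (j + 1) for j in range(n)])


def _graded_span(a, b, h, offsets):
    """1D coordinates from a to b: graded rows near both ends, ~h inside."""
    offs = offsets[offsets < 0.45 * (b - a)]
    lo = a + offs
    hi = b - offs[::-1]
    inner_lo = a + (offs[-1] if len(offs) else 0.0)
    inner_hi = b - (offs[-1] if len(offs) else 0.0)
    n = max(2, int(round((inner_hi - inner_lo) / h)))
    mid = np.linspace(inner_lo, inner_hi, n + 1)[1:-1]
    return np.concatenate([[a], lo, mid, hi, [b]])


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

def build_idealized_geometry(params: GeometryParams) -> Mesh:
    """Mesh the idealized vessel + sac; returns a validated :class:`Mesh`."""
    D = params.vessel_diameter
    L = params.vessel_length
    R = params.dome_diameter / 2.0
    half_w = params.neck_width / 2.0
    h = params.mesh_size
    x0 = params.neck_center
    hc = math.sqrt(R * R - half_w * half_w)
    cx, cy = x0, D + hc

    if x0 - half_w <= h or x0 + half_w >= L - h:
        raise MeshingError("neck does not fit inside the vessel length "
                           "(sac_stand_off/neck_width vs vessel_length)")
    if h > 0.5 * min(D, params.neck_width):
        raise MeshingError("mesh_size too coarse for the vessel/neck width")

    offs = _bl_offsets(params)
    bl_total = offs[-1] if len(offs) else 0.0

    pts = []            # accumulated point groups
    h_fine = 0.3 * h    # local spacing at the reentrant neck corners
    # --- boundary points -------------------------------------------------
    bottom = _polyline((0.0, 0.0), (L, 0.0), h)
    xl = x0 - half_w
    s_l = _march(xl, _corner_spacing(h, h_fine, xl))
    top_left = np.column_stack([s_l, np.full_like(s_l, D)])
    s_r = _march(L - (x0 + half_w), _corner_spacing(h, h_fine, 0.0))
    top_right = np.column_stack([x0 + half_w + s_r, np.full_like(s_r, D)])
    y_io = _graded_span(0.0, D, h, offs)
    inlet = np.column_stack([np.zeros_like(y_io), y_io])
    outlet = np.column_stack([np.full_like(y_io, L), y_io])

    th_r = math.atan2(D - cy, half_w)            # right neck corner angle
    th_l = math.atan2(D - cy, -half_w) + 2 * math.pi  # left corner, CCW past top
    arc_len = (th_l - th_r) * R
    s_arc = _march(arc_len, _corner_spacing(h, h_fine, 0.0, arc_len))
    th = th_r + s_arc / R
    arc = np.column_stack([cx + R * np.cos(th), cy + R * np.sin(th)])

    pts += [bottom, top_left, top_right, inlet, outlet, arc]

    # --- boundary-layer rows (extruded from the wall samplings) ----------
    for d in offs:
        xs = bottom[1:-1, 0]
        pts.append(np.column_stack([xs, np.full_like(xs, d)]))           # bottom wall
        xs_l = top_left[1:, 0]        # keep corner, drop inlet end
        xs_r = top_right[:-1, 0]      # keep corner, drop outlet end
        pts.append(np.column_stack([xs_l, np.full_like(xs_l, D - d)]))   # top wall L
        pts.append(np.column_stack([xs_r, np.full_like(xs_r, D - d)]))   # top wall R
        r = R - d
        thi = th[1:-1]
        ring = np.column_stack([cx + r * np.cos(thi), cy + r * np.sin(thi)])
        # keep clear of the reentrant neck corners: Delaunay would otherwise
        # bridge the wall line through points hugging the corner
        for corner in ((x0 - half_w, D), (x0 + half_w, D)):
            ring = ring[np.hypot(ring[:, 0] - corner[0],
                                 ring[:, 1] - corner[1]) > 2.0 * d + 0.5 * h_fine]
        pts.append(ring)

    boundary_pts = np.vstack([bottom, top_left, top_right, inlet, outlet, arc])

    # --- interior cloud (hex packing) ------------------------------------
    dx, dy = h, h * math.sqrt(3.0) / 2.0
    xs = np.arange(0.5 * h, L, dx)
    ys = np.arange(0.5 * h, cy + R, dy)
    gx, gy = np.meshgrid(xs, ys)
    gx[1::2] += 0.5 * dx
    cloud = np.column_stack([gx.ravel(), gy.ravel()])
    inside = _inside(cloud, L, D, cx, cy, R)
    cloud = cloud[inside]
    # keep clear of the boundary and the BL band
    tree = cKDTree(boundary_pts)
    dist, _ = tree.query(cloud, k=1)
    cloud = cloud[dist > max(bl_total + 0.55 * h, 0.75 * h)]
    pts.append(cloud)

    # --- dedupe (boundary first, then BL rows, then cloud) ---------------
    allpts = np.vstack(pts)
    n_bnd = len(boundary_pts)
    tol = 0.3 * (offs[0] if len(offs) else h)
    keep = _dedupe(allpts, n_protected=n_bnd, radius=tol)
    allpts = allpts[keep]

    # --- triangulate and trim --------------------------------------------
    tri = Delaunay(allpts)
    cells_all = tri.simplices
    cen = allpts[cells_all].mean(axis=1)
    keep_tri = _inside(cen, L, D, cx, cy, R, tol=-1e-12 * L)
    # drop slivers (can appear along curved/graded boundaries)
    p = allpts[cells_all]
    area2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    degenerate = np.abs(area2) <= 1e-6 * h * h
    keep_tri &= ~degenerate
    if not keep_tri.any():
        raise MeshingError("triangulation empty after trimming")

    # Conformity repair: an unconstrained Delaunay may route thin triangles
    # across the wall line at the reentrant neck corners; trimming them
    # leaves notches.  Re-admit the trimmed neighbor of any boundary edge
    # that does not lie on a geometric curve, as long as it sits near a
    # corner (cap prevents creeping into the exterior wedge under the dome).
    corners = np.array([[x0 - half_w, D], [x0 + half_w, D]])
    geom = (L, D, cx, cy, R, h)
    for _ in range(12):
        bad_edges = _offcurve_edges(allpts, cells_all[keep_tri], geom)
        if not len(bad_edges):
            break
        owners = tri.neighbors  # not edge-indexed; rebuild edge map instead
        edge_map: dict = {}
        for ci, t in enumerate(cells_all):
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                edge_map.setdefault((min(a, b), max(a, b)), []).append(ci)
        added = False
        for a, b in bad_edges:
            for ci in edge_map.get((min(a, b), max(a, b)), []):
                if keep_tri[ci] or degenerate[ci]:
                    continue
                c = allpts[cells_all[ci]].mean(axis=0)
                if np.min(np.hypot(c[0] - corners[:, 0], c[1] - corners[:, 1])) < 2.5 * h:
                    keep_tri[ci] = True
                    added = True
        if not added:
            break
    cells = cells_all[keep_tri]

    # reindex to used points
    used, inv = np.unique(cells, return_inverse=True)
    cells = inv.reshape(cells.shape)
    points = allpts[used]

    mesh = _finalize(points, cells, L, D, cx, cy, R, h, h_fine, corners)
    try:
        mesh.validate()
    except _mesh.MeshValidationError as exc:  # pragma: no cover - defensive
        raise MeshingError(f"generated mesh failed validation: {exc}") from exc
    return mesh


def _inside(p, L, D, cx, cy, R, tol=0.0):
    """Point-in-domain test (channel rectangle union sac segment)."""
    x, y = p[:, 0], p[:, 1]
    in_rect = (x >= -tol) & (x <= L + tol) & (y >= -tol) & (y <= D + tol)
    in_sac = (y > D) & ((x - cx) ** 2 + (y - cy) ** 2 <= (R + tol) ** 2)
    return in_rect | in_sac


def _dedupe(pts, n_protected, radius):
    """Greedy removal of points within ``radius`` of an earlier point."""
    keep = np.ones(len(pts), dtype=bool)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    for a, b in pairs[np.argsort(pairs[:, 0])]:
        lo, hi = (a, b) if a < b else (b, a)
        if hi < n_protected:
            continue  # never drop boundary points against each other
        if keep[lo]:
            keep[hi] = False
    return keep


def _boundary_edges_of(cells) -> np.ndarray:
    edge_count: dict = {}
    for t in cells:
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            k = (min(a, b), max(a, b))
            edge_count[k] = edge_count.get(k, 0) + 1
    return np.array([k for k, c in edge_count.items() if c == 1], dtype=np.int64)


def _curve_flags(points, bedges, geom):
    """Which boundary edges lie on each geometric curve, by midpoint."""
    L, D, cx, cy, R, h = geom
    mid = 0.5 * (points[bedges[:, 0]] + points[bedges[:, 1]])
    tol = 1e-9 * L
    r = np.hypot(mid[:, 0] - cx, mid[:, 1] - cy)
    flags = {
        "inlet": mid[:, 0] < tol,
        "outlet": mid[:, 0] > L - tol,
        "bottom": np.abs(mid[:, 1]) < tol,
        "top": np.abs(mid[:, 1] - D) < tol,
        "arc": (np.abs(r - R) < 0.2 * h) & (mid[:, 1] > D - 0.2 * h),
    }
    return mid, flags


def _offcurve_edges(points, cells, geom):
    bedges = _boundary_edges_of(cells)
    if not len(bedges):
        return bedges
    _, flags = _curve_flags(points, bedges, geom)
    on = np.zeros(len(bedges), dtype=bool)
    for f in flags.values():
        on |= f
    return bedges[~on]


def _finalize(points, cells, L, D, cx, cy, R, h, h_fine, corners) -> Mesh:
    """Tag boundary edges and cell regions; assemble the Mesh."""
    bedges = _boundary_edges_of(cells)
    if not len(bedges):
        raise MeshingError("no boundary edges found")
    geom = (L, D, cx, cy, R, h)
    mid, flags = _curve_flags(points, bedges, geom)

    tol = 1e-9 * L
    on_curve = np.zeros(len(bedges), dtype=bool)
    for f in flags.values():
        on_curve |= f
    # corner-repair triangles may expose short edges that round the corner
    near_corner = np.min(
        np.hypot(mid[:, 0, None] - corners[None, :, 0],
                 mid[:, 1, None] - corners[None, :, 1]), axis=1) < 3.0 * h
    if not np.all(on_curve | near_corner):
        raise MeshingError(
            f"{int((~(on_curve | near_corner)).sum())} boundary edges off the "
            "geometry (interior hole or over-trimmed region); adjust mesh_size")

    tags = np.empty(len(bedges), dtype=object)
    tags[:] = _mesh.WALL_VESSEL
    tags[mid[:, 1] > D + tol] = _mesh.WALL_SAC
    tags[flags["inlet"]] = _mesh.INLET
    tags[flags["outlet"]] = _mesh.OUTLET

    cen = points[cells].mean(axis=1)
    in_dome = np.hypot(cen[:, 0] - cx, cen[:, 1] - cy) <= R
    region = np.where((cen[:, 1] > D) & in_dome, _mesh.SAC, _mesh.LUMEN).astype(object)
    return Mesh(points=points, triangles=cells, boundary_edges=bedges,
                boundary_tags=tags, cell_region=region)


# --------------------------------------------------------------------------
# structured channel meshes (verification cases)
# --------------------------------------------------------------------------

def build_channel_mesh(length: float, height: float, nx: int, ny: int = None,
                       y_coords: np.ndarray | None = None,
                       porous_band: tuple | None = None) -> Mesh:
    """Structured triangulated channel [0,L] x [0,H] for verification runs.

    ``y_coords`` overrides the uniform cross-stream node distribution (use a
    graded spacing to resolve wall shear).  ``porous_band=(x1, x2)`` tags
    cells with centroid x in that band as SAC so the Darcy sink applies
    there; both walls are tagged WALL_VESSEL, the ends INLET/OUTLET.
    """
    if y_coords is None:
        if ny is None:
            raise ValueError("give ny or y_coords")
        y = np.linspace(0.0, height, ny + 1)
    else:
        y = np.asarray(y_coords, float)
        if y[0] != 0.0 or abs(y[-1] - height) > 1e-12 * height:
            raise ValueError("y_coords must span [0, height]")
    x = np.linspace(0.0, length, nx + 1)
    X, Y = np.meshgrid(x, y, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel()])
    nyp = len(y)

    def nid(i, j):
        return i * nyp + j

    tris = []
    for i in range(nx):
        for j in range(nyp - 1):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]
    tris = np.array(tris, dtype=np.int64)

    bedges, tags = [], []
    for j in range(nyp - 1):
        bedges.append([nid(0, j), nid(0, j + 1)]); tags.append(_mesh.INLET)
        bedges.append([nid(nx, j), nid(nx, j + 1)]); tags.append(_mesh.OUTLET)
    for i in range(nx):
        bedges.append([nid(i, 0), nid(i + 1, 0)]); tags.append(_mesh.WALL_VESSEL)
        bedges.append([nid(i, nyp - 1), nid(i + 1, nyp - 1)]); tags.append(_mesh.WALL_VESSEL)

    cen = points[tris].mean(axis=1)
    region = np.full(len(tris), _mesh.LUMEN, dtype=object)
    if porous_band is not None:
        x1, x2 = porous_band
        region[(cen[:, 0] > x1) & (cen[:, 0] < x2)] = _mesh.SAC
    return Mesh(points=points, triangles=tris,
                boundary_edges=np.array(bedges, dtype=np.int64),
                boundary_tags=np.array(tags, dtype=object),
                cell_region=region)


def graded_wall_coords(height: float, n: int, first: float) -> np.ndarray:
    """Cross-stream coordinates graded geometrically toward both walls."""
    if not 0 < first < height / (2 * n):
        # fall back to uniform if the grading is unreasonable
        return np.linspace(0.0, height, n + 1)
    half = height / 2.0
    # solve growth g with first*(g^m - 1)/(g - 1) = half, m = n//2 cells per side
    m = max(2, n // 2)
    g_lo, g_hi = 1.0001, 3.0
    for _ in range(80):
        g = 0.5 * (g_lo + g_hi)
        tot = first * (g ** m - 1.0) / (g - 1.0)
        if tot > half:
            g_hi = g
        else:
            g_lo = g
    g = 0.5 * (g_lo + g_hi)
    d = first * g ** np.arange(m)
    yy = np.concatenate([[0.0], np.cumsum(d)])
    yy[-1] = half
    return np.concatenate([yy, (height - yy[:-1])[::-1]])
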