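"""Triangle mesh container with tagged boundaries and cell regions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Mesh", "BOUNDARY_TAGS", "REGION_TAGS", "MeshValidationError"]

# boundary tags
INLET = "INLET"
OUTLET = "OUTLET"
WALL_VESSEL = "WALL_VESSEL"
WALL_SAC = "WALL_SAC"
BOUNDARY_TAGS = (INLET, OUTLET, WALL_VESSEL, WALL_SAC)
WALL_TAGS = (WALL_VESSEL, WALL_SAC)

# cell regions
LUMEN = "LUMEN"
SAC = "SAC"
REGION_TAGS = (LUMEN, SAC)


class MeshValidationError(ValueError):
    """A structural invariant of the mesh is violated."""


@dataclass
class Mesh:
    """Conforming 2D triangulation of the lumen + sac domain.

    Attributes
    ----------
    points : (N, 2) float array, meters
    triangles : (M, 3) int array, positively oriented
    boundary_edges : (B, 2) int array of node pairs on the domain boundary
    boundary_tags : (B,) array of strings from ``BOUNDARY_TAGS``
    cell_region : (M,) array of strings from ``REGION_TAGS``
    """

    points: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray
    boundary_tags: np.ndarray
    cell_region: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        self.boundary_edges = np.ascontiguousarray(self.boundary_edges, dtype=np.int64)
        self.boundary_tags = np.asarray(self.boundary_tags, dtype=object)
        self.cell_region = np.asarray(self.cell_region, dtype=object)
        self._orient()

    # ------------------------------------------------------------------ basics
    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.triangles)

    def _orient(self) -> None:
        """Flip triangles so all signed areas are positive."""
        a = self.signed_areas()
        neg = a < 0
        if np.any(neg):
            tri = self.triangles[neg]
            self.triangles[neg] = tri[:, [0, 2, 1]]
            self._cache.clear()

    def signed_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def cell_areas(self) -> np.ndarray:
        return np.abs(self.signed_areas())

    def cell_centroids(self) -> np.ndarray:
        return self.points[self.triangles].mean(axis=1)

    def region_cells(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.cell_region == region)

    def region_area(self, region: str) -> float:
        return float(self.cell_areas()[self.region_cells(region)].sum())

    def edges_for(self, tag: str) -> np.ndarray:
        return self.boundary_edges[self.boundary_tags == tag]

    def edge_lengths(self, edges: np.ndarray) -> np.ndarray:
        d = self.points[edges[:, 1]] - self.points[edges[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def nodes_for(self, tag: str) -> np.ndarray:
        return np.unique(self.edges_for(tag))

    # ------------------------------------------------------------- adjacency
    def _edge_to_cells(self) -> dict:
        if "edge_to_cells" not in self._cache:
            m: dict = {}
            for c, tri in enumerate(self.triangles):
                for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                    key = (min(a, b), max(a, b))
                    m.setdefault(key, []).append(c)
            self._cache["edge_to_cells"] = m
        return self._cache["edge_to_cells"]

    def boundary_edge_cells(self) -> np.ndarray:
        """Index of the unique triangle owning each boundary edge."""
        m = self._edge_to_cells()
        cells = np.empty(len(self.boundary_edges), dtype=np.int64)
        for i, (a, b) in enumerate(self.boundary_edges):
            owners = m.get((min(a, b), max(a, b)), [])
            if len(owners) != 1:
                raise MeshValidationError(
                    f"boundary edge ({a},{b}) belongs to {len(owners)} triangles")
            cells[i] = owners[0]
        return cells

    def boundary_edge_normals(self) -> np.ndarray:
        """Outward unit normals of the boundary edges."""
        cells = self.boundary_edge_cells()
        p0 = self.points[self.boundary_edges[:, 0]]
        p1 = self.points[self.boundary_edges[:, 1]]
        t = p1 - p0
        n = np.column_stack([t[:, 1], -t[:, 0]])
        n /= np.linalg.norm(n, axis=1)[:, None]
        # orient away from the owning triangle's centroid
        cen = self.cell_centroids()[cells]
        mid = 0.5 * (p0 + p1)
        flip = np.einsum("ij,ij->i", n, mid - cen) < 0
        n[flip] *= -1.0
        return n

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        """Raise MeshValidationError on any broken structural invariant."""
        if np.any(self.signed_areas() <= 0):
            raise MeshValidationError("degenerate or mis-oriented triangle present")
        if len(self.boundary_edges) != len(self.boundary_tags):
            raise MeshValidationError("boundary edge/tag length mismatch")
        bad = set(self.boundary_tags) - set(BOUNDARY_TAGS)
        if bad:
            raise MeshValidationError(f"unknown boundary tags: {sorted(bad)}")
        bad = set(self.cell_region) - set(REGION_TAGS)
        if bad:
            raise MeshValidationError(f"unknown region tags: {sorted(bad)}")

        # every topological boundary edge appears exactly once and is tagged
        m = self._edge_to_cells()
        topo = {k for k, v in m.items() if len(v) == 1}
        tagged = {(min(a, b), max(a, b)) for a, b in self.boundary_edges}
        if topo != tagged:
            missing = topo - tagged
            extra = tagged - topo
            raise MeshValidationError(
                f"boundary tagging does not partition the boundary "
                f"({len(missing)} untagged, {len(extra)} spurious edges)")
        if len(tagged) != len(self.boundary_edges):
            raise MeshValidationError("duplicate boundary edges")
        self.boundary_edge_cells()  # each edge belongs to exactly one triangle

        # sac cells: one connected component, adjacent to the sac wall
        sac = self.region_cells(SAC)
        if len(sac):
            if not len(self.edges_for(WALL_SAC)):
                raise MeshValidationError("SAC region present but no WALL_SAC edges")
            comp = self._connected(sac)
            if comp != 1:
                raise MeshValidationError(f"SAC region has {comp} components")
            sac_wall_cells = set(self.boundary_edge_cells()[
                self.boundary_tags == WALL_SAC])
            if not sac_wall_cells & set(sac.tolist()):
                raise MeshValidationError("SAC region not adjacent to WALL_SAC")

    def _connected(self, cells: np.ndarray) -> int:
        cellset = set(cells.tolist())
        m = self._edge_to_cells()
        adj: dict = {c: [] for c in cellset}
        for owners in m.values():
            if len(owners) == 2:
                a, b = owners
                if a in cellset and b in cellset:
                    adj[a].append(b)
                    adj[b].append(a)
        seen: set = set()
        comps = 0
        for c in cellset:
            if c in seen:
                continue
            comps += 1
            stack = [c]
            while stack:
                x = stack.pop()
                if x in seen:
                    continue
                seen.add(x)
                stack.extend(adj[x])
        return comps
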