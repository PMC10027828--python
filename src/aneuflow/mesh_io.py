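"""Mesh and field file I/O.

Two on-disk formats are supported for meshes:

* Gmsh MSH 4.1 ASCII (`.msh`) — read and write.  Boundary tags and cell
  regions travel as physical groups named ``INLET``, ``OUTLET``,
  ``WALL_VESSEL``, ``WALL_SAC`` (dim 1) and ``LUMEN``, ``SAC`` (dim 2),
  so externally produced meshes with those groups load directly.
* Legacy VTK ASCII (`.vtk`) unstructured grid — write only, for
  visualization; accepts optional point and cell data arrays.
"""

from __future__ import annotations

import numpy as np

from . import mesh as _mesh
from .mesh import Mesh

__all__ = ["write_mesh", "read_mesh", "write_vtk", "MeshFileError"]

_BOUNDARY_IDS = {name: i + 1 for i, name in enumerate(_mesh.BOUNDARY_TAGS)}
_REGION_IDS = {name: i + 11 for i, name in enumerate(_mesh.REGION_TAGS)}


class MeshFileError(ValueError):
    """Malformed or incompatible mesh file."""


# ----------------------------------------------------------------- MSH write

def write_mesh(mesh: Mesh, path) -> None:
    """Write ``mesh`` as Gmsh MSH 4.1 ASCII with named physical groups."""
    pts = mesh.points
    lines = []
    w = lines.append
    w("$MeshFormat")
    w("4.1 0 8")
    w("$EndMeshFormat")

    w("$PhysicalNames")
    w(str(len(_BOUNDARY_IDS) + len(_REGION_IDS)))
    for name, pid in _BOUNDARY_IDS.items():
        w(f'1 {pid} "{name}"')
    for name, pid in _REGION_IDS.items():
        w(f'2 {pid} "{name}"')
    w("$EndPhysicalNames")

    # one curve entity per boundary tag, one surface entity per region
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    box = f"{lo[0]:.17g} {lo[1]:.17g} 0 {hi[0]:.17g} {hi[1]:.17g} 0"
    w("$Entities")
    w(f"0 {len(_BOUNDARY_IDS)} {len(_REGION_IDS)} 0")
    for name, pid in _BOUNDARY_IDS.items():
        w(f"{pid} {box} 1 {pid} 0")
    for name, pid in _REGION_IDS.items():
        w(f"{pid} {box} 1 {pid} 0")
    w("$EndEntities")

    # all nodes on the LUMEN surface entity
    n = len(pts)
    w("$Nodes")
    w(f"1 {n} 1 {n}")
    w(f"2 {_REGION_IDS[_mesh.LUMEN]} 0 {n}")
    for i in range(n):
        w(str(i + 1))
    for p in pts:
        w(f"{p[0]:.17g} {p[1]:.17g} 0")
    w("$EndNodes")

    blocks = []  # (entity_dim, entity_tag, elem_type, element rows)
    for name, pid in _BOUNDARY_IDS.items():
        e = mesh.edges_for(name)
        if len(e):
            blocks.append((1, pid, 1, e + 1))
    for name, pid in _REGION_IDS.items():
        t = mesh.triangles[mesh.cell_region == name]
        if len(t):
            blocks.append((2, pid, 2, t + 1))
    n_elem = sum(len(b[3]) for b in blocks)
    w("$Elements")
    w(f"{len(blocks)} {n_elem} 1 {n_elem}")
    eid = 1
    for dim, tag, etype, rows in blocks:
        w(f"{dim} {tag} {etype} {len(rows)}")
        for r in rows:
            w(f"{eid} " + " ".join(str(v) for v in r))
            eid += 1
    w("$EndElements")

    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


# ------------------------------------------------------------------ MSH read

def _sections(text: str) -> dict:
    out: dict = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("$") and not ln.startswith("$End"):
            name = ln[1:]
            j = i + 1
            body = []
            while j < len(lines) and lines[j].strip() != f"$End{name}":
                body.append(lines[j])
                j += 1
            if j == len(lines):
                raise MeshFileError(f"unterminated section ${name}")
            out[name] = body
            i = j + 1
        else:
            i += 1
    return out


def read_mesh(path) -> Mesh:
    """Read a Gmsh MSH 4.1 ASCII file carrying the expected physical groups."""
    with open(path) as f:
        text = f.read()
    sec = _sections(text)
    for required in ("MeshFormat", "PhysicalNames", "Entities", "Nodes", "Elements"):
        if required not in sec:
            raise MeshFileError(f"missing ${required} section")
    version = sec["MeshFormat"][0].split()[0]
    if not version.startswith("4"):
        raise MeshFileError(f"unsupported MSH version {version} (need 4.x)")

    # physical names
    phys: dict = {}
    rows = sec["PhysicalNames"]
    for ln in rows[1: 1 + int(rows[0])]:
        parts = ln.split(None, 2)
        dim, tag = int(parts[0]), int(parts[1])
        name = parts[2].strip().strip('"')
        phys[(dim, tag)] = name
    known = set(_mesh.BOUNDARY_TAGS) | set(_mesh.REGION_TAGS)
    offenders = sorted(set(phys.values()) - known)
    if offenders:
        raise MeshFileError(f"unknown physical group names: {offenders}")

    # entity -> physical name
    ent_phys: dict = {}
    it = iter(sec["Entities"])
    counts = [int(v) for v in next(it).split()]
    n_pt, n_curve, n_surf = counts[0], counts[1], counts[2]
    for _ in range(n_pt):
        next(it)
    for dim, n_ent in ((1, n_curve), (2, n_surf)):
        for _ in range(n_ent):
            vals = next(it).split()
            tag = int(vals[0])
            n_phys = int(vals[7])
            if n_phys >= 1:
                ent_phys[(dim, tag)] = phys.get((dim, int(vals[8])))

    # nodes
    it = iter(sec["Nodes"])
    n_blocks, n_nodes = [int(v) for v in next(it).split()[:2]]
    ids = np.empty(n_nodes, dtype=np.int64)
    coords = np.empty((n_nodes, 2), dtype=float)
    k = 0
    for _ in range(n_blocks):
        blk = next(it).split()
        nb = int(blk[3])
        for j in range(nb):
            ids[k + j] = int(next(it))
        for j in range(nb):
            xyz = next(it).split()
            coords[k + j] = (float(xyz[0]), float(xyz[1]))
        k += nb
    order = np.argsort(ids)
    ids, coords = ids[order], coords[order]
    id_to_idx = {int(v): i for i, v in enumerate(ids)}

    # elements
    edges, etags, tris, regions = [], [], [], []
    it = iter(sec["Elements"])
    n_blocks = int(next(it).split()[0])
    for _ in range(n_blocks):
        dim, ent, etype, nb = [int(v) for v in next(it).split()]
        name = ent_phys.get((dim, ent))
        for _ in range(nb):
            vals = [int(v) for v in next(it).split()]
            conn = [id_to_idx[v] for v in vals[1:]]
            if etype == 1:
                if name not in _mesh.BOUNDARY_TAGS:
                    raise MeshFileError(
                        f"line element on entity {ent} lacks a boundary group")
                edges.append(conn)
                etags.append(name)
            elif etype == 2:
                if name not in _mesh.REGION_TAGS:
                    raise MeshFileError(
                        f"triangle on entity {ent} lacks a region group")
                tris.append(conn)
                regions.append(name)
            else:
                raise MeshFileError(f"unsupported element type {etype}")
    if not tris:
        raise MeshFileError("no triangles in file")
    if _mesh.SAC not in regions:
        raise MeshFileError("file has no SAC region")
    mesh = Mesh(points=coords,
                triangles=np.array(tris, dtype=np.int64),
                boundary_edges=np.array(edges, dtype=np.int64),
                boundary_tags=np.array(etags, dtype=object),
                cell_region=np.array(regions, dtype=object))
    mesh.validate()
    return mesh


# ------------------------------------------------------------------ VTK

def write_vtk(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None, title: str = "aneuflow") -> None:
    """Write mesh (+ optional fields) as legacy VTK ASCII unstructured grid.

    Vector point data may be given as (N, 2) arrays; a zero z-component is
    appended.  Cell region is always emitted as an integer cell array.
    """
    pts = mesh.points
    tris = mesh.triangles
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(pts)} double"]
    lines += [f"{p[0]:.17g} {p[1]:.17g} 0" for p in pts]
    lines.append(f"CELLS {len(tris)} {4 * len(tris)}")
    lines += [f"3 {t[0]} {t[1]} {t[2]}" for t in tris]
    lines.append(f"CELL_TYPES {len(tris)}")
    lines += ["5"] * len(tris)

    lines.append(f"POINT_DATA {len(pts)}")
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            lines.append(f"VECTORS {name} double")
            lines += [f"{v[0]:.17g} {v[1]:.17g} 0" for v in arr]
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.17g}" for v in arr]

    lines.append(f"CELL_DATA {len(tris)}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(1 if r == _mesh.SAC else 0) for r in mesh.cell_region]
    for name, arr in (cell_data or {}).items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.17g}" for v in np.asarray(arr)]

    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")
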