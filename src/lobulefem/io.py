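"""File I/O: VTU/PVD snapshot series, Gmsh MSH meshes, YAML configs.

All writers emit plain ASCII with full double precision (repr round-trip),
so a written file reloads bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import yaml

from .mesh import ALL_TAGS, LobuleMesh

_TAG_IDS = {t: i + 1 for i, t in enumerate(ALL_TAGS)}
_ID_TAGS = {v: k for k, v in _TAG_IDS.items()}


def _fmt(arr: np.ndarray) -> str:
    a = np.asarray(arr)
    if np.issubdtype(a.dtype, np.integer):
        return " ".join(str(int(v)) for v in a.ravel())
    return " ".join(repr(float(v)) for v in a.ravel())


# ---------------------------------------------------------------------------
# VTU / PVD
# ---------------------------------------------------------------------------

def write_vtu(path, mesh: LobuleMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> Path:
    """Write an ASCII VTU unstructured-grid file with the mesh and fields.

    2-vector fields are padded to 3 components as VTK expects.
    """
    path = Path(path)
    n, m = len(mesh.vertices), len(mesh.cells)
    pts3 = np.zeros((n, 3))
    pts3[:, :2] = mesh.vertices

    def data_arrays(data: dict, n_items: int) -> str:
        chunks = []
        for name, arr in (data or {}).items():
            a = np.asarray(arr)
            if a.ndim == 1:
                comp = 1
            else:
                if a.shape[1] == 2:
                    a = np.hstack([a, np.zeros((len(a), 1))])
                comp = a.shape[1]
            if len(a) != n_items:
                raise ValueError(f"field {name!r} has wrong length")
            typ = "Int64" if np.issubdtype(a.dtype, np.integer) else "Float64"
            chunks.append(
                f'<DataArray type="{typ}" Name="{name}" '
                f'NumberOfComponents="{comp}" format="ascii">{_fmt(a)}'
                "</DataArray>")
        return "".join(chunks)

    body = (
        '<?xml version="1.0"?>'
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">'
        "<UnstructuredGrid>"
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">'
        "<Points>"
        f'<DataArray type="Float64" NumberOfComponents="3" format="ascii">'
        f"{_fmt(pts3)}</DataArray>"
        "</Points>"
        "<Cells>"
        f'<DataArray type="Int64" Name="connectivity" format="ascii">'
        f"{_fmt(mesh.cells)}</DataArray>"
        f'<DataArray type="Int64" Name="offsets" format="ascii">'
        f"{_fmt(3 * np.arange(1, m + 1))}</DataArray>"
        f'<DataArray type="UInt8" Name="types" format="ascii">'
        f"{' '.join(['5'] * m)}</DataArray>"
        "</Cells>"
        f"<PointData>{data_arrays(point_data, n)}</PointData>"
        f"<CellData>{data_arrays(cell_data, m)}</CellData>"
        "</Piece></UnstructuredGrid></VTKFile>"
    )
    path.write_text(body)
    return path


def read_vtu(path):
    """Read back an ASCII VTU file -> (vertices, cells, point_data, cell_data)."""
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")

    def parse(da):
        typ = da.get("type", "Float64")
        vals = da.text.split()
        comp = int(da.get("NumberOfComponents", "1"))
        arr = (np.array(vals, dtype=np.int64) if typ.startswith(("Int", "UInt"))
               else np.array(vals, dtype=float))
        return arr.reshape(-1, comp) if comp > 1 else arr

    pts = parse(piece.find("Points/DataArray"))[:, :2]
    conn = None
    for da in piece.findall("Cells/DataArray"):
        if da.get("Name") == "connectivity":
            conn = parse(da).reshape(-1, 3)
    pdata = {da.get("Name"): parse(da)
             for da in piece.findall("PointData/DataArray")}
    cdata = {da.get("Name"): parse(da)
             for da in piece.findall("CellData/DataArray")}
    return pts, conn, pdata, cdata


def write_pvd(path, series) -> Path:
    """Write a PVD collection for a [(time, vtu_filename), ...] series."""
    path = Path(path)
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="Collection" version="0.1">', "<Collection>"]
    for t, fname in series:
        lines.append(f'<DataSet timestep="{repr(float(t))}" part="0" '
                     f'file="{fname}"/>')
    lines += ["</Collection>", "</VTKFile>"]
    path.write_text("\n".join(lines))
    return path


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2
# ---------------------------------------------------------------------------

def write_msh(path, mesh: LobuleMesh) -> Path:
    """Write the mesh in Gmsh MSH 2.2 ASCII; boundary edges carry their tag
    id as physical group, triangles carry lobule_id + 100."""
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(_TAG_IDS))]
    for t, i in _TAG_IDS.items():
        lines.append(f'1 {i} "{t}"')
    lines += ["$EndPhysicalNames", "$Nodes", str(len(mesh.vertices))]
    for i, (x, y) in enumerate(mesh.vertices, start=1):
        lines.append(f"{i} {repr(float(x))} {repr(float(y))} 0.0")
    lines += ["$EndNodes", "$Elements",
              str(len(mesh.boundary_edges) + len(mesh.cells))]
    eid = 1
    for (a, b), tag in zip(mesh.boundary_edges, mesh.boundary_tags):
        pid = _TAG_IDS[tag]
        lines.append(f"{eid} 1 2 {pid} {pid} {a + 1} {b + 1}")
        eid += 1
    for tri, li in zip(mesh.cells, mesh.lobule_id):
        pid = int(li) + 100
        lines.append(f"{eid} 2 2 {pid} {pid} {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines))
    return path


def read_msh(path) -> LobuleMesh:
    """Read a MSH 2.2 file written by :func:`write_msh` (or compatible)."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    verts, edges, tags, cells, lids = [], [], [], [], []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                verts.append((float(parts[1]), float(parts[2])))
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                pid = int(parts[3]) if ntags else 0
                conn = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype == 1:
                    edges.append(conn)
                    tags.append(_ID_TAGS.get(pid, "wall"))
                elif etype == 2:
                    cells.append(conn)
                    lids.append(max(pid - 100, 0))
    verts = np.asarray(verts, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    lid = np.asarray(lids, dtype=np.int64)
    centers = np.array([verts[cells[lid == li]].mean(axis=(0, 1))
                        for li in np.unique(lid)])
    mesh = LobuleMesh(
        vertices=verts, cells=cells,
        boundary_edges=np.asarray(edges, dtype=np.int64),
        boundary_tags=np.asarray(tags, dtype=object),
        lobule_id=lid, lobule_centers=centers,
        circumradius=float(np.max(np.linalg.norm(verts - verts.mean(axis=0), axis=1))),
        meta={"source": str(path)},
    )
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# configs and manifests
# ---------------------------------------------------------------------------

def canonical_yaml(d: dict) -> str:
    return yaml.safe_dump(d, sort_keys=True, default_flow_style=False)


def config_hash(d: dict) -> str:
    return hashlib.sha256(canonical_yaml(d).encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(d: dict, path) -> Path:
    path = Path(path)
    path.write_text(canonical_yaml(d))
    return path


def write_manifest(path, cfg_dict: dict, wall_time_s: float,
                   extra: dict | None = None) -> Path:
    import scipy
    payload = {
        "config_hash": config_hash(cfg_dict),
        "config": cfg_dict,
        "wall_time_s": wall_time_s,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
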