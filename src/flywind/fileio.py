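"""Plain-text file I/O: ASCII STL/OBJ meshes, CSV polylines and series,
legacy-ASCII VTK fields and point clouds, optional HDF5 snapshots, and a
checksum manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .geometry import SurfaceMesh
from .grid import CartesianGrid

__all__ = [
    "write_stl",
    "read_stl",
    "write_obj",
    "write_polyline_csv",
    "read_polyline_csv",
    "write_series_csv",
    "write_vtk_rectilinear",
    "write_vtk_points",
    "write_hdf5_fields",
    "write_manifest",
]


def write_stl(path, mesh: SurfaceMesh) -> None:
    path = Path(path)
    v, f = mesh.vertices, mesh.faces
    if f.shape[1] != 3:
        raise ValueError("STL export needs a triangle mesh")
    a = v[f[:, 1]] - v[f[:, 0]]
    b = v[f[:, 2]] - v[f[:, 0]]
    n = np.cross(a, b)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / np.where(norm > 0, norm, 1.0)
    with path.open("w") as fh:
        fh.write(f"solid {mesh.role}\n")
        for tri, nrm in zip(f, n):
            fh.write(f"  facet normal {nrm[0]:.9e} {nrm[1]:.9e} {nrm[2]:.9e}\n")
            fh.write("    outer loop\n")
            for idx in tri:
                p = v[idx]
                fh.write(f"      vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write(f"endsolid {mesh.role}\n")


def read_stl(path, role: str = "body") -> SurfaceMesh:
    """Read an ASCII STL (vertices are de-duplicated exactly)."""
    verts: list[tuple[float, float, float]] = []
    index: dict[tuple[float, float, float], int] = {}
    faces: list[list[int]] = []
    tri: list[int] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if parts[:1] == ["vertex"]:
            key = (float(parts[1]), float(parts[2]), float(parts[3]))
            if key not in index:
                index[key] = len(verts)
                verts.append(key)
            tri.append(index[key])
            if len(tri) == 3:
                faces.append(tri)
                tri = []
    return SurfaceMesh(vertices=np.asarray(verts), faces=np.asarray(faces), role=role)


def write_obj(path, mesh: SurfaceMesh) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"o {mesh.role}\n")
        for p in mesh.vertices:
            fh.write(f"v {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        for f in mesh.faces:
            if f.size == 3:
                fh.write(f"f {f[0]+1} {f[1]+1} {f[2]+1}\n")
            else:
                fh.write(f"l {f[0]+1} {f[1]+1}\n")


def write_polyline_csv(path, points: np.ndarray, header: str = "x,y") -> None:
    np.savetxt(path, np.asarray(points), delimiter=",", header=header, comments="")


def read_polyline_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1)


def write_series_csv(path, columns: dict[str, np.ndarray]) -> None:
    names = list(columns)
    data = np.column_stack([np.asarray(columns[k]) for k in names])
    np.savetxt(path, data, delimiter=",", header=",".join(names), comments="")


def write_vtk_rectilinear(path, grid: CartesianGrid, fields: dict[str, np.ndarray]) -> None:
    """Legacy-ASCII VTK rectilinear grid with cell-centered fields written
    as point data on the cell-center lattice."""
    coords = grid.centers + tuple(np.zeros(1) for _ in range(3 - grid.ndim))
    shape = tuple(len(c) for c in coords)
    with Path(path).open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nflywind field\nASCII\n")
        fh.write("DATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {shape[0]} {shape[1]} {shape[2]}\n")
        for name, c in zip(("X", "Y", "Z"), coords):
            fh.write(f"{name}_COORDINATES {len(c)} double\n")
            fh.write(" ".join(f"{v:.9e}" for v in c) + "\n")
        fh.write(f"POINT_DATA {int(np.prod(shape))}\n")
        for name, arr in fields.items():
            flat = np.asarray(arr).reshape(-1, order="F")
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.9e}" for v in flat) + "\n")


def write_vtk_points(path, points: np.ndarray, scalars: dict[str, np.ndarray] | None = None) -> None:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    with Path(path).open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nflywind particles\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        if scalars:
            fh.write(f"POINT_DATA {len(pts)}\n")
            for name, arr in scalars.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{float(v):.9e}" for v in np.asarray(arr)) + "\n")


def write_hdf5_fields(path, grid: CartesianGrid, fields: dict[str, np.ndarray], t: float = 0.0) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["t"] = t
        for i, c in enumerate(grid.centers):
            fh.create_dataset(f"grid/axis{i}", data=c)
        for name, arr in fields.items():
            fh.create_dataset(f"fields/{name}", data=np.asarray(arr))


def write_manifest(run_dir, extra: dict | None = None) -> Path:
    """SHA-256 checksums of every file in a run directory."""
    run_dir = Path(run_dir)
    entries = {}
    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(run_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"files": entries}
    if extra:
        manifest.update(extra)
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
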