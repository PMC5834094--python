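"""Simplicial meshes (triangle surfaces, tetrahedral volumes) with scalar fields.

Coordinates are millimetres in a right-handed frame; vertex and element
indices are 0-based.  Scalar data live either on vertices ("point" data)
or on elements ("cell" data); per-element fields are what the dot sampler
consumes, and :func:`vertex_to_element_field` converts between the two by
averaging each element's vertex values.

File I/O covers three ASCII formats: VTK legacy (POLYDATA for surfaces,
UNSTRUCTURED_GRID with cell type 10 for tetrahedra), PLY 1.0 and OFF
(surfaces only).  Sidecar CSVs with header ``element_id,value`` attach
additional per-element scalars.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

__all__ = [
    "SurfaceMesh",
    "VolumeMesh",
    "ElementField",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "read_field_csv",
    "write_field_csv",
    "element_measure",
    "vertex_to_element_field",
    "normalize_field",
]


class MeshFormatError(ValueError):
    """Raised when a mesh file or field array violates the format contract."""


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class ElementField:
    """One scalar value per mesh element plus its normalization window."""

    values: np.ndarray
    window: tuple[float, float] | None = None
    name: str = "S"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise MeshFormatError(f"field {self.name!r} must be 1-D")


@dataclass
class _BaseMesh:
    vertices: np.ndarray
    point_data: dict[str, np.ndarray] = dc_field(default_factory=dict)
    cell_data: dict[str, np.ndarray] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.point_data = {k: np.asarray(v, dtype=float) for k, v in self.point_data.items()}
        self.cell_data = {k: np.asarray(v, dtype=float) for k, v in self.cell_data.items()}

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def _check_fields(self) -> None:
        for name, arr in self.point_data.items():
            if name == "normals":
                continue
            if len(arr) != self.n_vertices:
                raise MeshFormatError(
                    f"point field {name!r} has length {len(arr)}, expected {self.n_vertices}"
                )
        for name, arr in self.cell_data.items():
            if len(arr) != self.n_elements:
                raise MeshFormatError(
                    f"cell field {name!r} has length {len(arr)}, expected {self.n_elements}"
                )

    def field(self, name: str) -> ElementField:
        """Return the named scalar as per-element data, converting if needed."""
        if name in self.cell_data:
            return ElementField(self.cell_data[name], name=name)
        if name in self.point_data:
            return vertex_to_element_field(self, self.point_data[name], name=name)
        raise KeyError(f"mesh has no field {name!r}")


@dataclass
class SurfaceMesh(_BaseMesh):
    """Triangulated surface with optional outward unit vertex normals."""

    triangles: np.ndarray = dc_field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    vertex_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.vertex_normals is not None:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> np.ndarray:
        return self.triangles

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def validate(self) -> None:
        if self.n_elements and (
            self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= self.n_vertices
        ):
            raise MeshFormatError("triangle index out of range")
        for tri in self.triangles:
            if len(set(tri.tolist())) != 3:
                raise MeshFormatError(f"triangle {tri.tolist()} repeats a vertex")
        if self.vertex_normals is not None:
            if len(self.vertex_normals) != self.n_vertices:
                raise MeshFormatError("vertex_normals length mismatch")
            norms = np.linalg.norm(self.vertex_normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise MeshFormatError("vertex normals are not unit length")
        self._check_fields()


@dataclass
class VolumeMesh(_BaseMesh):
    """Tetrahedral volume mesh."""

    tetrahedra: np.ndarray = dc_field(default_factory=lambda: np.empty((0, 4), dtype=np.int64))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.tetrahedra = np.asarray(self.tetrahedra, dtype=np.int64).reshape(-1, 4)

    @property
    def elements(self) -> np.ndarray:
        return self.tetrahedra

    @property
    def n_elements(self) -> int:
        return len(self.tetrahedra)

    def validate(self) -> None:
        if self.n_elements and (
            self.tetrahedra.min(initial=0) < 0
            or self.tetrahedra.max(initial=-1) >= self.n_vertices
        ):
            raise MeshFormatError("tetrahedron index out of range")
        for tet in self.tetrahedra:
            if len(set(tet.tolist())) != 4:
                raise MeshFormatError(f"tetrahedron {tet.tolist()} repeats a vertex")
        self._check_fields()


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def element_measure(mesh: SurfaceMesh | VolumeMesh) -> np.ndarray:
    """Per-element area (mm^2) for surfaces or volume (mm^3) for volumes.

    Triangle area is half the magnitude of the edge cross product;
    tetrahedron volume is |det| / 6.  Degenerate elements yield 0.
    """
    v = mesh.vertices
    if isinstance(mesh, SurfaceMesh):
        a, b, c = v[mesh.triangles[:, 0]], v[mesh.triangles[:, 1]], v[mesh.triangles[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    a, b, c, d = (v[mesh.tetrahedra[:, i]] for i in range(4))
    det = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)
    return np.abs(det) / 6.0


def signed_tet_volume(mesh: VolumeMesh) -> np.ndarray:
    v = mesh.vertices
    a, b, c, d = (v[mesh.tetrahedra[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def vertex_to_element_field(
    mesh: SurfaceMesh | VolumeMesh, vertex_field: np.ndarray, name: str = "S"
) -> ElementField:
    """Convert point data to element data: mean of each element's vertex values."""
    vertex_field = np.asarray(vertex_field, dtype=float)
    if len(vertex_field) != mesh.n_vertices:
        raise MeshFormatError(
            f"vertex field length {len(vertex_field)} != vertex count {mesh.n_vertices}"
        )
    return ElementField(vertex_field[mesh.elements].mean(axis=1), name=name)


def normalize_field(
    field: ElementField | np.ndarray, window: tuple[float, float] | None = None
) -> ElementField:
    """Clip to ``window`` then map linearly onto [0, 1].

    Poisson means must be non-negative, so every scalar passes through this
    before weighting.  ``window`` defaults to the field's declared window,
    falling back to the data range.
    """
    if not isinstance(field, ElementField):
        field = ElementField(field)
    if window is None:
        window = field.window
    if window is None:
        lo, hi = float(field.values.min()), float(field.values.max())
        if lo == hi:
            hi = lo + 1.0  # constant field maps to 0
        window = (lo, hi)
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError(f"degenerate window {window}")
    vals = (np.clip(field.values, lo, hi) - lo) / (hi - lo)
    return ElementField(vals, window=(0.0, 1.0), name=field.name)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FMT = "%.17g"  # lossless float64 round trip


def _fmt_row(row) -> str:
    return " ".join(_FMT % x for x in row)


def _infer_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        return format.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("vtk", "ply", "off"):
        return suffix
    raise MeshFormatError(f"cannot infer mesh format from {path!r}; pass format=")


def read_mesh(path: str | Path, format: str | None = None) -> SurfaceMesh | VolumeMesh:
    """Read a mesh file (VTK legacy ASCII, PLY ascii or OFF).

    The cell type found in the file selects the returned kind; files mixing
    triangles and tetrahedra are rejected.
    """
    fmt = _infer_format(path, format)
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise MeshFormatError(f"cannot read {path}: {exc}") from exc
    if fmt == "vtk":
        mesh = _read_vtk(text)
    elif fmt == "ply":
        mesh = _read_ply(text)
    elif fmt == "off":
        mesh = _read_off(text)
    else:
        raise MeshFormatError(f"unsupported format {fmt!r}")
    mesh.validate()
    return mesh


def write_mesh(mesh: SurfaceMesh | VolumeMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh re-readably; round trips are lossless for float64."""
    mesh.validate()
    fmt = _infer_format(path, format)
    if fmt == "vtk":
        text = _write_vtk(mesh)
    elif fmt == "ply":
        text = _write_ply(mesh)
    elif fmt == "off":
        if isinstance(mesh, VolumeMesh):
            raise MeshFormatError("OFF supports surface meshes only")
        text = _write_off(mesh)
    else:
        raise MeshFormatError(f"unsupported format {fmt!r}")
    Path(path).write_text(text)


def read_field_csv(path: str | Path, name: str | None = None) -> ElementField:
    """Read a sidecar per-element scalar CSV with header ``element_id,value``."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header[:2]] != ["element_id", "value"]:
            raise MeshFormatError(f"bad CSV header {header!r}; expected element_id,value")
        rows = [(int(r[0]), float(r[1])) for r in reader if r]
    rows.sort()
    ids = [r[0] for r in rows]
    if ids != list(range(len(ids))):
        raise MeshFormatError("element_id column must cover 0..n-1 exactly once")
    return ElementField(np.array([r[1] for r in rows]), name=name or Path(path).stem)


def write_field_csv(field: ElementField, path: str | Path) -> None:
    lines = ["element_id,value"]
    lines += [f"{i},{_FMT % v}" for i, v in enumerate(field.values)]
    Path(path).write_text("\n".join(lines) + "\n")


# -- VTK legacy ASCII -------------------------------------------------------


def _read_vtk(text: str) -> SurfaceMesh | VolumeMesh:
    tokens = text.split()
    lines = text.splitlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise MeshFormatError("not a VTK legacy file")
    if not any(ln.strip().upper() == "ASCII" for ln in lines[1:5]):
        raise MeshFormatError("only ASCII VTK supported")
    it = iter(range(len(tokens)))
    pos = 0

    def take(n: int) -> list[str]:
        nonlocal pos
        out = tokens[pos : pos + n]
        if len(out) < n:
            raise MeshFormatError("truncated VTK file")
        pos += n
        return out

    def seek(word: str) -> bool:
        nonlocal pos
        for i in range(pos, len(tokens)):
            if tokens[i].upper() == word:
                pos = i + 1
                return True
        return False

    if not seek("DATASET"):
        raise MeshFormatError("VTK file has no DATASET")
    dataset = take(1)[0].upper()
    if not seek("POINTS"):
        raise MeshFormatError("VTK file has no POINTS")
    n_pts = int(take(1)[0])
    take(1)  # dtype
    verts = np.array(take(3 * n_pts), dtype=float).reshape(n_pts, 3)

    tris: list[list[int]] = []
    tets: list[list[int]] = []
    if dataset == "POLYDATA":
        if seek("POLYGONS"):
            n_cells = int(take(1)[0])
            take(1)  # total size
            for _ in range(n_cells):
                k = int(take(1)[0])
                ids = [int(t) for t in take(k)]
                if k != 3:
                    raise MeshFormatError("only triangle polygons supported")
                tris.append(ids)
    elif dataset == "UNSTRUCTURED_GRID":
        if not seek("CELLS"):
            raise MeshFormatError("UNSTRUCTURED_GRID without CELLS")
        n_cells = int(take(1)[0])
        take(1)
        cells = []
        for _ in range(n_cells):
            k = int(take(1)[0])
            cells.append([int(t) for t in take(k)])
        if not seek("CELL_TYPES"):
            raise MeshFormatError("missing CELL_TYPES")
        take(1)
        types = [int(t) for t in take(n_cells)]
        for ids, ct in zip(cells, types):
            if ct == 5:
                tris.append(ids)
            elif ct == 10:
                tets.append(ids)
            else:
                raise MeshFormatError(f"unsupported VTK cell type {ct}")
    else:
        raise MeshFormatError(f"unsupported VTK dataset {dataset}")

    if tris and tets:
        raise MeshFormatError("mixed triangle/tetrahedron mesh rejected")

    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    normals = None
    # parse POINT_DATA / CELL_DATA sections
    section = None
    n_sec = 0
    i = pos
    while i < len(tokens):
        tok = tokens[i].upper()
        if tok in ("POINT_DATA", "CELL_DATA"):
            section = tok
            n_sec = int(tokens[i + 1])
            i += 2
        elif tok == "SCALARS" and section is not None:
            name = tokens[i + 1]
            i += 3  # SCALARS name dtype [numComp]
            if i < len(tokens) and tokens[i].isdigit():
                i += 1
            if i < len(tokens) and tokens[i].upper() == "LOOKUP_TABLE":
                i += 2
            vals = np.array(tokens[i : i + n_sec], dtype=float)
            if len(vals) != n_sec:
                raise MeshFormatError(f"scalar array {name!r} truncated")
            i += n_sec
            (point_data if section == "POINT_DATA" else cell_data)[name] = vals
        elif tok == "NORMALS" and section == "POINT_DATA":
            i += 3  # NORMALS name dtype
            normals = np.array(tokens[i : i + 3 * n_sec], dtype=float).reshape(n_sec, 3)
            i += 3 * n_sec
        else:
            i += 1

    expected = n_pts
    for name, vals in point_data.items():
        if len(vals) != expected:
            raise MeshFormatError(f"point array {name!r} has wrong length")
    n_el = len(tets) if tets else len(tris)
    for name, vals in cell_data.items():
        if len(vals) != n_el:
            raise MeshFormatError(f"cell array {name!r} has wrong length")

    if tets:
        return VolumeMesh(verts, point_data, cell_data, tetrahedra=np.array(tets))
    return SurfaceMesh(
        verts,
        point_data,
        cell_data,
        triangles=np.array(tris, dtype=np.int64).reshape(-1, 3),
        vertex_normals=normals,
    )


def _write_vtk(mesh: SurfaceMesh | VolumeMesh) -> str:
    out = ["# vtk DataFile Version 3.0", "dotmap mesh", "ASCII"]
    is_vol = isinstance(mesh, VolumeMesh)
    out.append("DATASET UNSTRUCTURED_GRID" if is_vol else "DATASET POLYDATA")
    out.append(f"POINTS {mesh.n_vertices} double")
    out += [_fmt_row(v) for v in mesh.vertices]
    if is_vol:
        n = mesh.n_elements
        out.append(f"CELLS {n} {5 * n}")
        out += ["4 " + " ".join(str(i) for i in tet) for tet in mesh.tetrahedra]
        out.append(f"CELL_TYPES {n}")
        out += ["10"] * n
    else:
        n = mesh.n_elements
        out.append(f"POLYGONS {n} {4 * n}")
        out += ["3 " + " ".join(str(i) for i in tri) for tri in mesh.triangles]
    if mesh.point_data or (not is_vol and mesh.vertex_normals is not None):
        out.append(f"POINT_DATA {mesh.n_vertices}")
        if not is_vol and mesh.vertex_normals is not None:
            out.append("NORMALS normals double")
            out += [_fmt_row(v) for v in mesh.vertex_normals]
        for name in sorted(mesh.point_data):
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out += [_FMT % v for v in mesh.point_data[name]]
    if mesh.cell_data:
        out.append(f"CELL_DATA {mesh.n_elements}")
        for name in sorted(mesh.cell_data):
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out += [_FMT % v for v in mesh.cell_data[name]]
    return "\n".join(out) + "\n"


# -- PLY ascii --------------------------------------------------------------
# Tetrahedra are stored in a custom "tetrahedron" element with a
# vertex_indices list property; standard PLY readers will still see the
# vertex block.


def _read_ply(text: str) -> SurfaceMesh | VolumeMesh:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError("not a PLY file")
    elements: list[tuple[str, int, list[str]]] = []
    i = 1
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "format":
            if parts[1] != "ascii":
                raise MeshFormatError("only ascii PLY supported")
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property":
            if not elements:
                raise MeshFormatError("property before element")
            elements[-1][2].append(lines[i - 1].strip())
        elif parts[0] == "end_header":
            break
    body = lines[i:]
    row = 0
    verts = None
    normals = None
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    tris: list[list[int]] = []
    tets: list[list[int]] = []
    for name, count, props in elements:
        if name == "vertex":
            scalar_names = []
            for p in props:
                toks = p.split()
                if toks[1] == "list":
                    raise MeshFormatError("list property on vertex element")
                scalar_names.append(toks[-1])
            data = np.array(
                [body[row + k].split() for k in range(count)], dtype=float
            ).reshape(count, len(scalar_names))
            row += count
            cols = dict(zip(scalar_names, data.T))
            try:
                verts = np.column_stack([cols.pop("x"), cols.pop("y"), cols.pop("z")])
            except KeyError as exc:
                raise MeshFormatError("PLY vertex element lacks x/y/z") from exc
            if {"nx", "ny", "nz"} <= set(cols):
                normals = np.column_stack([cols.pop("nx"), cols.pop("ny"), cols.pop("nz")])
            point_data.update({k: v for k, v in cols.items()})
        elif name in ("face", "tetrahedron"):
            scalar_names = [p.split()[-1] for p in props if p.split()[1] != "list"]
            scalar_cols: dict[str, list[float]] = {s: [] for s in scalar_names}
            for k in range(count):
                toks = body[row + k].split()
                nv = int(toks[0])
                ids = [int(t) for t in toks[1 : 1 + nv]]
                if name == "face":
                    if nv != 3:
                        raise MeshFormatError("only triangular PLY faces supported")
                    tris.append(ids)
                else:
                    if nv != 4:
                        raise MeshFormatError("tetrahedron element must list 4 vertices")
                    tets.append(ids)
                for s, tok in zip(scalar_names, toks[1 + nv :]):
                    scalar_cols[s].append(float(tok))
            row += count
            for s, vals in scalar_cols.items():
                cell_data[s] = np.array(vals)
        else:
            row += count  # skip unknown elements
    if verts is None:
        raise MeshFormatError("PLY file has no vertex element")
    if tris and tets:
        raise MeshFormatError("mixed triangle/tetrahedron mesh rejected")
    if tets:
        return VolumeMesh(verts, point_data, cell_data, tetrahedra=np.array(tets))
    return SurfaceMesh(
        verts,
        point_data,
        cell_data,
        triangles=np.array(tris, dtype=np.int64).reshape(-1, 3),
        vertex_normals=normals,
    )


def _write_ply(mesh: SurfaceMesh | VolumeMesh) -> str:
    is_vol = isinstance(mesh, VolumeMesh)
    has_normals = not is_vol and mesh.vertex_normals is not None
    pnames = sorted(mesh.point_data)
    cnames = sorted(mesh.cell_data)
    head = ["ply", "format ascii 1.0", f"element vertex {mesh.n_vertices}"]
    head += ["property double x", "property double y", "property double z"]
    if has_normals:
        head += ["property double nx", "property double ny", "property double nz"]
    head += [f"property double {n}" for n in pnames]
    cell_el = "tetrahedron" if is_vol else "face"
    head.append(f"element {cell_el} {mesh.n_elements}")
    head.append("property list uchar int vertex_indices")
    head += [f"property double {n}" for n in cnames]
    head.append("end_header")
    body = []
    for i, v in enumerate(mesh.vertices):
        row = list(v)
        if has_normals:
            row += list(mesh.vertex_normals[i])
        row += [mesh.point_data[n][i] for n in pnames]
        body.append(_fmt_row(row))
    nv = 4 if is_vol else 3
    for i, el in enumerate(mesh.elements):
        parts = [str(nv)] + [str(j) for j in el]
        parts += [_FMT % mesh.cell_data[n][i] for n in cnames]
        body.append(" ".join(parts))
    return "\n".join(head + body) + "\n"


# -- OFF --------------------------------------------------------------------


def _read_off(text: str) -> SurfaceMesh:
    tokens = [
        t
        for line in text.splitlines()
        if not line.strip().startswith("#")
        for t in line.split()
    ]
    if not tokens or tokens[0] != "OFF":
        raise MeshFormatError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4  # skip edge count
    verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    tris = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise MeshFormatError("only triangular OFF faces supported")
        tris.append([int(t) for t in tokens[pos + 1 : pos + 4]])
        pos += 1 + k
    return SurfaceMesh(verts, triangles=np.array(tris, dtype=np.int64).reshape(-1, 3))


def _write_off(mesh: SurfaceMesh) -> str:
    out = ["OFF", f"{mesh.n_vertices} {mesh.n_elements} 0"]
    out += [_fmt_row(v) for v in mesh.vertices]
    out += ["3 " + " ".join(str(i) for i in tri) for tri in mesh.triangles]
    return "\n".join(out) + "\n"
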