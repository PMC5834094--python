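"""Synthetic test geometries and clinically-shaped scalar fields.

Everything here is deterministic given (parameters, seed) so the rest of
the package is testable without any external data:

* ``make_disc_gradient`` — planar 2 cm disc with a linear scalar gradient
  at a chosen axis angle (gradient-perception task geometry).
* ``make_square_scar`` — planar 2 cm square with a smooth radial bump
  (focal-source localization task geometry).
* ``make_sphere`` / ``make_shell_pair`` — icosphere shells with bimodal
  voltage-like fields (healthy plateau + low-voltage patch), nested for
  endo/epi co-display.
* ``make_lv_wedge`` — tetrahedralized curved slab with a partial-thickness
  "scar" intensity patch.
* ``make_activation_voltage_pair`` — geodesic activation-time field plus an
  independent voltage field on a closed surface.

Lengths are in the caller's units; the planar task fixtures default to cm
as in the perception experiments (diameter/edge 2 cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import Delaunay

from .mesh_core import (
    ElementField,
    SurfaceMesh,
    VolumeMesh,
    vertex_to_element_field,
)

__all__ = [
    "FixtureSpec",
    "make_disc_gradient",
    "make_square_scar",
    "make_sphere",
    "make_shell_pair",
    "make_lv_wedge",
    "make_activation_voltage_pair",
    "make_fixture",
]


@dataclass
class FixtureSpec:
    """Parameter bundle for :func:`make_fixture` (CLI entry point)."""

    kind: str  # disc_gradient | square_scar | sphere_pair | shell_pair | lv_wedge
    params: dict = dc_field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# planar task geometries
# ---------------------------------------------------------------------------


def make_disc_gradient(
    diameter: float = 2.0,
    theta: float = 0.0,
    resolution: int = 24,
    seed: int = 0,
    with_activation: bool = False,
) -> SurfaceMesh:
    """Planar triangulated disc with a linear gradient along axis ``theta``.

    The scalar rises linearly from 0 at the rim point opposite the axis to 1
    at the rim point along it (theta=0 means increasing along +x, measured in
    degrees counter-clockwise).  ``resolution`` is the number of radial rings.
    An optional second, isochron-style field ("activation") sweeps linearly
    along the perpendicular axis for combined-display tests.
    """
    if not 0 <= theta < 360:
        raise ValueError("theta must lie in [0, 360)")
    radius = diameter / 2.0
    verts = [(0.0, 0.0)]
    for ring in range(1, resolution + 1):
        r = radius * ring / resolution
        n = 6 * ring
        for k in range(n):
            a = 2 * np.pi * k / n
            verts.append((r * np.cos(a), r * np.sin(a)))
    xy = np.asarray(verts)
    tris = Delaunay(xy).simplices
    vertices = np.column_stack([xy, np.zeros(len(xy))])
    ax = np.deg2rad(theta)
    along = xy[:, 0] * np.cos(ax) + xy[:, 1] * np.sin(ax)
    grad = 0.5 + along / diameter  # 0 at -radius, 1 at +radius
    point_data = {"S": grad}
    if with_activation:
        perp = -xy[:, 0] * np.sin(ax) + xy[:, 1] * np.cos(ax)
        point_data["activation"] = 0.5 + perp / diameter
    normals = np.tile([0.0, 0.0, 1.0], (len(vertices), 1))
    mesh = SurfaceMesh(
        vertices,
        point_data=point_data,
        triangles=np.asarray(tris, dtype=np.int64),
        vertex_normals=normals,
    )
    mesh.cell_data["S"] = vertex_to_element_field(mesh, grad).values
    mesh.validate()
    return mesh


def make_square_scar(
    edge: float = 2.0,
    center: tuple[float, float] = (0.0, 0.0),
    radius: float = 0.4,
    resolution: int = 40,
    seed: int = 0,
) -> SurfaceMesh:
    """Planar triangulated square with a smooth radial bump field.

    Field peaks at 1 at ``center`` and decays smoothly to 0 at ``radius``
    (quartic bump), baseline 0 beyond.  The square spans
    [-edge/2, edge/2]^2; the bump disc must intersect it.
    """
    half = edge / 2.0
    cx, cy = center
    if abs(cx) - radius > half or abs(cy) - radius > half:
        raise ValueError("scar disc lies fully outside the square")
    n = resolution
    g = np.linspace(-half, half, n + 1)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), np.zeros((n + 1) ** 2)])
    idx = np.arange((n + 1) ** 2).reshape(n + 1, n + 1)
    tris = []
    for i in range(n):
        for j in range(n):
            v00, v10, v01, v11 = idx[i, j], idx[i + 1, j], idx[i, j + 1], idx[i + 1, j + 1]
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    r2 = ((vertices[:, 0] - cx) ** 2 + (vertices[:, 1] - cy) ** 2) / radius**2
    bump = np.where(r2 < 1.0, (1.0 - r2) ** 2, 0.0)
    normals = np.tile([0.0, 0.0, 1.0], (len(vertices), 1))
    mesh = SurfaceMesh(
        vertices,
        point_data={"S": bump},
        triangles=np.asarray(tris, dtype=np.int64),
        vertex_normals=normals,
    )
    mesh.cell_data["S"] = vertex_to_element_field(mesh, bump).values
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# spheres and shells
# ---------------------------------------------------------------------------


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1)[:, None]
    f = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.int64,
    )
    return v, f


def make_sphere(radius: float = 30.0, subdivisions: int = 3) -> SurfaceMesh:
    """Watertight icosphere with outward unit vertex normals."""
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = vlist[i] + vlist[j]
                m = m / np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts = np.asarray(vlist)
        faces = np.asarray(new_faces, dtype=np.int64)
    mesh = SurfaceMesh(verts * radius, triangles=faces, vertex_normals=verts.copy())
    mesh.validate()
    return mesh


def _patch_field(
    mesh: SurfaceMesh,
    axis: np.ndarray,
    patch_deg: float,
    plateau: float,
    floor: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Voltage-like field: plateau with a smooth low patch around ``axis``."""
    u = mesh.vertices - mesh.centroid
    u /= np.linalg.norm(u, axis=1)[:, None]
    ang = np.degrees(np.arccos(np.clip(u @ axis, -1.0, 1.0)))
    t = np.clip(ang / patch_deg, 0.0, 1.0)  # 0 at patch centre, 1 outside
    smooth = t * t * (3 - 2 * t)
    field = floor + (plateau - floor) * smooth
    if noise_sd > 0:
        field = field + rng.normal(0.0, noise_sd, len(field))
    return np.clip(field, 0.0, None)


def make_shell_pair(
    inner_radius: float = 25.0,
    outer_radius: float = 30.0,
    resolution: int = 3,
    scar_params: dict | None = None,
    seed: int = 0,
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Nested endo/epi icosphere shells with bimodal voltage-like fields.

    ``scar_params`` keys: ``patch_deg`` (angular radius, 0 disables the
    patch), ``plateau`` / ``floor`` (healthy and scar voltages, mV),
    ``noise_sd`` and ``overlap`` in [0, 1] — 1 puts the epicardial patch on
    the same axis as the endocardial one, 0 antipodal.
    """
    if not inner_radius < outer_radius:
        raise ValueError("inner_radius must be < outer_radius")
    p = {
        "patch_deg": 40.0,
        "plateau": 3.0,
        "floor": 0.2,
        "noise_sd": 0.1,
        "overlap": 1.0,
    }
    p.update(scar_params or {})
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    # rotate the epi axis away from the endo axis by (1 - overlap) * 180 deg
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    ang = np.pi * (1.0 - float(p["overlap"]))
    axis_epi = axis * np.cos(ang) + perp * np.sin(ang)

    shells = []
    for radius, ax in ((inner_radius, axis), (outer_radius, axis_epi)):
        mesh = make_sphere(radius, subdivisions=resolution)
        if p["patch_deg"] > 0:
            volt = _patch_field(
                mesh, ax, p["patch_deg"], p["plateau"], p["floor"], p["noise_sd"], rng
            )
        else:
            volt = np.full(mesh.n_vertices, p["plateau"])
        mesh.point_data["voltage"] = volt
        mesh.cell_data["voltage"] = vertex_to_element_field(mesh, volt).values
        mesh.validate()
        shells.append(mesh)
    return shells[0], shells[1]


# ---------------------------------------------------------------------------
# volumetric wedge
# ---------------------------------------------------------------------------


def make_lv_wedge(
    dimensions: dict | None = None,
    scar_transmurality: float = 0.75,
    resolution: int = 8,
    seed: int = 0,
) -> VolumeMesh:
    """Curved tetrahedralized slab with a partial-thickness scar patch.

    The wedge is a cylindrical-shell sector (inner radius to outer radius,
    angular span, axial height).  The "intensity" field is high inside the
    subendocardial fraction ``scar_transmurality`` of the wall thickness
    over a central angular/axial patch, baseline elsewhere, plus Gaussian
    noise.  Each hexahedral grid cell is split into six tetrahedra.
    """
    if not 0 < scar_transmurality <= 1:
        raise ValueError("scar_transmurality must lie in (0, 1]")
    dims = {"r_inner": 25.0, "r_outer": 35.0, "span_deg": 90.0, "height": 40.0}
    dims.update(dimensions or {})
    rng = np.random.default_rng(seed)
    n = resolution
    nr = max(2, n // 2)
    rr = np.linspace(dims["r_inner"], dims["r_outer"], nr + 1)
    aa = np.deg2rad(np.linspace(-dims["span_deg"] / 2, dims["span_deg"] / 2, n + 1))
    zz = np.linspace(0.0, dims["height"], n + 1)
    shape = (nr + 1, n + 1, n + 1)
    verts = np.empty(shape + (3,))
    for i, r in enumerate(rr):
        for j, a in enumerate(aa):
            verts[i, j, :, 0] = r * np.cos(a)
            verts[i, j, :, 1] = r * np.sin(a)
            verts[i, j, :, 2] = zz
    vertices = verts.reshape(-1, 3)
    vid = np.arange(len(vertices)).reshape(shape)

    # six-tet subdivision of each hex cell, consistent across the grid
    tets = []
    corner_order = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
    six = [(0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6), (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6)]
    for i in range(nr):
        for j in range(n):
            for k in range(n):
                c = [vid[i + di, j + dj, k + dk] for (di, dj, dk) in corner_order]
                for t in six:
                    tets.append([c[x] for x in t])
    tetrahedra = np.asarray(tets, dtype=np.int64)

    cent = vertices[tetrahedra].mean(axis=1)
    rad = np.hypot(cent[:, 0], cent[:, 1])
    depth = (rad - dims["r_inner"]) / (dims["r_outer"] - dims["r_inner"])  # 0 = endo
    ang = np.degrees(np.arctan2(cent[:, 1], cent[:, 0]))
    in_patch = (
        (np.abs(ang) < dims["span_deg"] / 4)
        & (np.abs(cent[:, 2] - dims["height"] / 2) < dims["height"] / 4)
    )
    scar = in_patch & (depth <= scar_transmurality)
    noise_sd = 0.02
    intensity = np.where(scar, 1.0, 0.05) + rng.normal(0.0, noise_sd, len(cent))
    mesh = VolumeMesh(
        vertices,
        cell_data={"intensity": np.clip(intensity, 0.0, None), "scar": scar.astype(float)},
        tetrahedra=tetrahedra,
    )
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# paired activation/voltage fields on a closed surface
# ---------------------------------------------------------------------------


def _edge_graph(mesh: SurfaceMesh) -> coo_matrix:
    e = np.vstack([
        mesh.triangles[:, [0, 1]],
        mesh.triangles[:, [1, 2]],
        mesh.triangles[:, [2, 0]],
    ])
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    return coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])), (n, n))


def is_closed_surface(mesh: SurfaceMesh) -> bool:
    """True when every undirected edge is shared by exactly two triangles."""
    e = np.vstack([
        mesh.triangles[:, [0, 1]],
        mesh.triangles[:, [1, 2]],
        mesh.triangles[:, [2, 0]],
    ])
    e = np.sort(e, axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    return bool(len(e) > 0 and (counts == 2).all())


def make_activation_voltage_pair(
    mesh: SurfaceMesh,
    circuit_params: dict | None = None,
    scar_params: dict | None = None,
    seed: int = 0,
) -> tuple[ElementField, ElementField]:
    """Geodesic activation-time field plus independent voltage field.

    Activation spreads at constant ``speed`` (mm/ms) from a random source
    vertex, wrapped modulo the ``cycle_length`` (ms) so values lie in
    [0, cycle_length).  Voltage is a healthy plateau with one low-voltage
    patch, independent of the activation source.  Requires a closed surface.
    """
    if not is_closed_surface(mesh):
        raise ValueError("activation fixture requires a closed surface mesh")
    cp = {"cycle_length": 250.0, "speed": 0.8}
    cp.update(circuit_params or {})
    sp = {"patch_deg": 40.0, "plateau": 3.0, "floor": 0.2, "noise_sd": 0.1}
    sp.update(scar_params or {})
    rng = np.random.default_rng(seed)
    source = int(rng.integers(mesh.n_vertices))
    dist = dijkstra(_edge_graph(mesh).tocsr(), indices=source)
    lat_v = (dist / cp["speed"]) % cp["cycle_length"]
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    volt_v = _patch_field(
        mesh, axis, sp["patch_deg"], sp["plateau"], sp["floor"], sp["noise_sd"], rng
    )
    lat = vertex_to_element_field(mesh, lat_v, name="activation")
    lat.window = (0.0, cp["cycle_length"])
    volt = vertex_to_element_field(mesh, volt_v, name="voltage")
    volt.window = (0.0, sp["plateau"])
    return lat, volt


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def make_fixture(spec: FixtureSpec):
    """Build the fixture named by ``spec.kind``; returns mesh(es)."""
    kind, p, seed = spec.kind, dict(spec.params), spec.seed
    if kind == "disc_gradient":
        return make_disc_gradient(seed=seed, **p)
    if kind == "square_scar":
        return make_square_scar(seed=seed, **p)
    if kind == "shell_pair":
        return make_shell_pair(seed=seed, **p)
    if kind == "sphere_pair":
        mesh = make_sphere(p.pop("radius", 30.0), p.pop("subdivisions", 3))
        lat, volt = make_activation_voltage_pair(mesh, seed=seed, **p)
        mesh.cell_data["activation"] = lat.values
        mesh.cell_data["voltage"] = volt.values
        return mesh
    if kind == "lv_wedge":
        return make_lv_wedge(seed=seed, **p)
    raise ValueError(f"unknown fixture kind {kind!r}")
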