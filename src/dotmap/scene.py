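"""Scene assembly: view state, dot elevation, two-layer rendering, density sweep.

Rendering is a deliberately simple software rasterizer (numpy z-buffer +
PIL PNG writer) under a scaled orthographic projection: pixels-per-mm
scales with D/D', so halving the camera distance doubles the on-screen
magnification.  Together with the D^2/D'^2 weight correction this makes
expected screen dot density exactly zoom-invariant.  Software rendering
also guarantees byte-identical output for identical inputs and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from PIL import Image

from .dot_sampler import (
    DotCloud,
    DotMapConfig,
    ViewState,
    barycentric_triangle,
    generate_dot_map,
)
from .mesh_core import ElementField, SurfaceMesh, VolumeMesh, normalize_field

__all__ = [
    "Camera",
    "SceneSpec",
    "view_from_camera",
    "offset_dots",
    "render_scene",
    "density_sweep",
    "extract_boundary",
]


@dataclass(frozen=True)
class Camera:
    """Orthographic camera: position/target/up plus field-of-view width.

    ``fov_mm`` is the world width (mm) mapped onto the image width at the
    reference distance; zooming the camera in (smaller distance to target)
    magnifies by D/D'.
    """

    position: tuple[float, float, float] = (0.0, 0.0, 100.0)
    target: tuple[float, float, float] = (0.0, 0.0, 0.0)
    up: tuple[float, float, float] = (0.0, 1.0, 0.0)
    fov_mm: float = 60.0

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pos = np.asarray(self.position, dtype=float)
        tgt = np.asarray(self.target, dtype=float)
        fwd = tgt - pos
        dist = np.linalg.norm(fwd)
        if dist == 0:
            raise ValueError("camera position coincides with target")
        fwd = fwd / dist
        right = np.cross(fwd, np.asarray(self.up, dtype=float))
        nr = np.linalg.norm(right)
        if nr == 0:
            raise ValueError("camera up vector parallel to view direction")
        right /= nr
        up = np.cross(right, fwd)
        return right, up, fwd

    def distance_to(self, point: np.ndarray) -> float:
        return float(np.linalg.norm(np.asarray(self.position, dtype=float) - point))

    def at_zoom(self, multiplier: float) -> "Camera":
        """Camera moved to ``multiplier`` times its current target distance."""
        pos = np.asarray(self.position, dtype=float)
        tgt = np.asarray(self.target, dtype=float)
        return replace(self, position=tuple(tgt + (pos - tgt) * multiplier))


@dataclass
class SceneSpec:
    """Everything needed to render one frame."""

    color_field: str | None = None
    dot_field: str | None = None
    colormap: str = "viridis"
    window: tuple[float, float] | None = None
    camera: Camera = dc_field(default_factory=Camera)
    config: DotMapConfig = dc_field(default_factory=DotMapConfig)
    show_color: bool = True
    show_dots: bool = True
    shading: str = "flat"  # flat | gouraud
    width: int = 480
    height: int = 480
    background: tuple[int, int, int] = (255, 255, 255)

    @classmethod
    def from_json(cls, path_or_dict) -> "SceneSpec":
        if isinstance(path_or_dict, dict):
            d = dict(path_or_dict)
        else:
            with open(path_or_dict) as fh:
                d = json.load(fh)
        if "camera" in d:
            cam = d["camera"]
            d["camera"] = Camera(**{k: tuple(v) if isinstance(v, list) else v for k, v in cam.items()})
        if "config" in d:
            d["config"] = DotMapConfig(**d["config"])
        if "window" in d and d["window"] is not None:
            d["window"] = tuple(d["window"])
        return cls(**d)


def view_from_camera(
    camera: Camera,
    mesh: SurfaceMesh | VolumeMesh,
    reference: float | None = None,
) -> ViewState:
    """ViewState with D' = current camera-to-centroid distance.

    ``reference`` is the scene-start distance D; when omitted the current
    distance is taken as the reference (first call of a scene).
    """
    d_prime = camera.distance_to(mesh.centroid)
    scale = float(np.abs(mesh.vertices).max(initial=1.0))
    if d_prime <= 1e-9 * scale:
        raise ValueError("camera coincides with mesh centroid")
    return ViewState(D=reference if reference is not None else d_prime, D_prime=d_prime)


# ---------------------------------------------------------------------------
# dot elevation
# ---------------------------------------------------------------------------


def offset_dots(cloud: DotCloud, mesh: SurfaceMesh, offset: float) -> DotCloud:
    """Displace each dot along its element's interpolated outward normal.

    Surface clouds only; the mesh must carry unit vertex normals.  Element
    indices and counts are preserved so repeated offsets compose additively.
    """
    if not isinstance(mesh, SurfaceMesh):
        raise TypeError("offset_dots applies to surface meshes only")
    if mesh.vertex_normals is None:
        raise ValueError("mesh has no vertex normals")
    if offset == 0 or cloud.n_dots == 0:
        return DotCloud(cloud.points.copy(), cloud.element_index, cloud.counts, cloud.caps)
    tri = mesh.triangles[cloud.element_index]
    a = mesh.vertices[tri[:, 0]]
    normals = np.empty_like(cloud.points)
    # per-element batches keep the least-squares barycentric solve vectorized
    for el in np.unique(cloud.element_index):
        sel = cloud.element_index == el
        va, vb, vc = mesh.triangles[el]
        wbc = barycentric_triangle(
            cloud.points[sel], mesh.vertices[va], mesh.vertices[vb], mesh.vertices[vc]
        )
        wa = 1.0 - wbc.sum(axis=1)
        n = (
            wa[:, None] * mesh.vertex_normals[va]
            + wbc[:, 0:1] * mesh.vertex_normals[vb]
            + wbc[:, 1:2] * mesh.vertex_normals[vc]
        )
        normals[sel] = n / np.linalg.norm(n, axis=1)[:, None]
    return DotCloud(
        cloud.points + offset * normals, cloud.element_index, cloud.counts, cloud.caps
    )


# ---------------------------------------------------------------------------
# rasterizer
# ---------------------------------------------------------------------------


def extract_boundary(mesh: VolumeMesh) -> SurfaceMesh:
    """Boundary triangles of a tetrahedral mesh (faces used exactly once)."""
    faces = np.vstack([
        mesh.tetrahedra[:, [0, 1, 2]],
        mesh.tetrahedra[:, [0, 1, 3]],
        mesh.tetrahedra[:, [0, 2, 3]],
        mesh.tetrahedra[:, [1, 2, 3]],
    ])
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = faces[counts[inv] == 1]
    return SurfaceMesh(mesh.vertices, triangles=boundary)


def _project(points: np.ndarray, camera: Camera, view: ViewState, width: int, height: int):
    """World -> (px, py, depth). Orthographic, px/mm = width/fov * D/D'."""
    right, up, fwd = camera.basis()
    tgt = np.asarray(camera.target, dtype=float)
    rel = points - tgt
    ppm = (width / camera.fov_mm) * (view.D / view.D_prime)
    px = width / 2.0 + (rel @ right) * ppm
    py = height / 2.0 - (rel @ up) * ppm
    depth = rel @ fwd
    return px, py, depth, ppm


def _colormap_lut(name: str) -> np.ndarray:
    import matplotlib

    cmap = matplotlib.colormaps[name]
    return (np.asarray(cmap(np.linspace(0, 1, 256)))[:, :3] * 255).astype(np.uint8)


def _raster_triangles(
    px, py, depth, tris, values, lut, img, zbuf, shading: str
) -> None:
    """Scanline-free per-triangle rasterization with a z-buffer.

    ``values`` is per-element (flat) or per-vertex (gouraud), already
    normalized to [0, 1].
    """
    h, w, _ = img.shape
    for t, tri in enumerate(tris):
        xs, ys, zs = px[tri], py[tri], depth[tri]
        x0, x1 = int(np.floor(xs.min())), int(np.ceil(xs.max()))
        y0, y1 = int(np.floor(ys.min())), int(np.ceil(ys.max()))
        x0, x1 = max(x0, 0), min(x1, w - 1)
        y0, y1 = max(y0, 0), min(y1, h - 1)
        if x0 > x1 or y0 > y1:
            continue
        d = (xs[1] - xs[0]) * (ys[2] - ys[0]) - (xs[2] - xs[0]) * (ys[1] - ys[0])
        if d == 0:
            continue
        gx, gy = np.meshgrid(
            np.arange(x0, x1 + 1) + 0.5, np.arange(y0, y1 + 1) + 0.5
        )
        w1 = ((gx - xs[0]) * (ys[2] - ys[0]) - (gy - ys[0]) * (xs[2] - xs[0])) / d
        w2 = ((gy - ys[0]) * (xs[1] - xs[0]) - (gx - xs[0]) * (ys[1] - ys[0])) / d
        w0 = 1.0 - w1 - w2
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        zpix = w0 * zs[0] + w1 * zs[1] + w2 * zs[2]
        sub_z = zbuf[y0 : y1 + 1, x0 : x1 + 1]
        upd = inside & (zpix < sub_z)
        if not upd.any():
            continue
        if shading == "gouraud":
            vpix = w0 * values[tri[0]] + w1 * values[tri[1]] + w2 * values[tri[2]]
            idx = np.clip((vpix * 255), 0, 255).astype(np.uint8)
            colors = lut[idx]
        else:
            idx = int(np.clip(values[t] * 255, 0, 255))
            colors = np.broadcast_to(lut[idx], upd.shape + (3,))
        sub_img = img[y0 : y1 + 1, x0 : x1 + 1]
        sub_z[upd] = zpix[upd]
        sub_img[upd] = colors[upd]


def render_scene(
    spec: SceneSpec,
    mesh: SurfaceMesh | VolumeMesh,
    cloud: DotCloud | None = None,
    view: ViewState | None = None,
    out: str | None = None,
) -> np.ndarray:
    """Render colour layer + dot layer to an RGB array (and optional PNG).

    The surface is painted via the colormap over ``spec.color_field``
    (normalized by ``spec.window``); dots are depth-tested against the
    surface with a bias equal to the configured offset plus one pixel's
    worth of depth, so elevated dots are never swallowed by their own
    surface.  Identical inputs produce byte-identical PNGs.
    """
    if view is None:
        view = view_from_camera(spec.camera, mesh)
    img = np.empty((spec.height, spec.width, 3), dtype=np.uint8)
    img[:, :] = spec.background
    zbuf = np.full((spec.height, spec.width), np.inf)

    surf = extract_boundary(mesh) if isinstance(mesh, VolumeMesh) else mesh
    px, py, depth, ppm = _project(surf.vertices, spec.camera, view, spec.width, spec.height)

    if spec.show_color and spec.color_field is not None and surf.n_elements:
        if spec.shading == "gouraud" and spec.color_field in mesh.point_data:
            vals = normalize_field(
                ElementField(mesh.point_data[spec.color_field]), spec.window
            ).values
        else:
            vals = normalize_field(mesh.field(spec.color_field), spec.window).values
        lut = _colormap_lut(spec.colormap)
        shading = "gouraud" if (
            spec.shading == "gouraud" and spec.color_field in mesh.point_data
        ) else "flat"
        _raster_triangles(px, py, depth, surf.triangles, vals, lut, img, zbuf, shading)
    elif surf.n_elements:
        # no colour layer: still occlude dots behind the model with a
        # background-coloured depth pass
        lut = np.tile(np.asarray(spec.background, dtype=np.uint8), (256, 1))
        vals = np.zeros(surf.n_elements)
        _raster_triangles(px, py, depth, surf.triangles, vals, lut, img, zbuf, "flat")

    if spec.show_dots and cloud is not None and cloud.n_dots:
        dx, dy, dz, _ = _project(cloud.points, spec.camera, view, spec.width, spec.height)
        bias = spec.config.offset + spec.camera.fov_mm / spec.width
        order = np.arange(cloud.n_dots)
        half = spec.config.dot_px // 2
        color = np.asarray(spec.config.dot_color, dtype=np.uint8)
        xi = np.round(dx).astype(int)
        yi = np.round(dy).astype(int)
        for i in order:
            x, y = xi[i], yi[i]
            if not (0 <= x < spec.width and 0 <= y < spec.height):
                continue
            if dz[i] > zbuf[y, x] + bias:
                continue
            x0, x1 = max(x - half, 0), min(x + half + (spec.config.dot_px % 2), spec.width)
            y0, y1 = max(y - half, 0), min(y + half + (spec.config.dot_px % 2), spec.height)
            img[y0:y1, x0:x1] = color

    if out is not None:
        Image.fromarray(img, "RGB").save(out, format="PNG")
    return img


# ---------------------------------------------------------------------------
# density sweep
# ---------------------------------------------------------------------------


def density_sweep(
    mesh: SurfaceMesh | VolumeMesh,
    field: ElementField,
    spec: SceneSpec,
    zoom_levels,
    region: tuple[float, float, float, float],
    reps: int = 1,
    seed: int = 0,
) -> list[dict]:
    """Projected dot density (dots per px^2) inside ``region`` per zoom level.

    ``zoom_levels`` are distance multipliers relative to the reference
    camera; the DotCloud is regenerated at every zoom and repetition with a
    fresh seeded stream.  ``region`` is (x0, y0, x1, y1) in pixels and must
    lie within the projected model at every zoom.  Returns one row per
    (zoom, rep) with keys zoom, D_prime, rep, n_dots, density.
    """
    x0, y0, x1, y1 = region
    area = (x1 - x0) * (y1 - y0)
    if area <= 0:
        raise ValueError("empty region")
    ref_view = view_from_camera(spec.camera, mesh)
    rows = []
    for zi, zoom in enumerate(zoom_levels):
        cam = spec.camera.at_zoom(zoom)
        view = view_from_camera(cam, mesh, reference=ref_view.D)
        for rep in range(reps):
            rng = np.random.default_rng((seed, zi, rep))
            cloud = generate_dot_map(mesh, field, view, spec.config, rng=rng)
            if cloud.n_dots:
                px, py, _, _ = _project(cloud.points, cam, view, spec.width, spec.height)
                n_in = int(((px >= x0) & (px < x1) & (py >= y0) & (py < y1)).sum())
            else:
                n_in = 0
            rows.append(
                {
                    "zoom": float(zoom),
                    "D_prime": view.D_prime,
                    "rep": rep,
                    "n_dots": n_in,
                    "density": n_in / area,
                }
            )
    return rows
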