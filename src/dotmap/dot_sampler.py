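"""Dot-map generation: distance-corrected element weights, capped Poisson
dot counts, and uniform random placement inside triangles and tetrahedra.

The pipeline is: per-element weight ``lam = V * S * D^2 / D'^2`` (measure x
normalized scalar x squared zoom ratio), brightness/contrast adjustment
``lam_adj = b * lam**c``, a Poisson(lam_adj) count per element truncated at
the cap ``N = ceil(q * V)``, then one uniform point per dot drawn inside the
source simplex.  The squared distance ratio makes the expected projected
screen dot density invariant under zoom for an orthographic camera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np

from .mesh_core import ElementField, SurfaceMesh, VolumeMesh, element_measure

__all__ = [
    "ViewState",
    "DotMapConfig",
    "WeightVector",
    "DotCloud",
    "compute_weight",
    "adjust_weight",
    "dot_cap",
    "draw_dot_counts",
    "sample_point_triangle",
    "sample_point_tetrahedron",
    "fold_triple",
    "generate_dot_map",
    "barycentric_triangle",
    "barycentric_tetrahedron",
]


@dataclass(frozen=True)
class ViewState:
    """Reference and current viewpoint-to-model distances (mm)."""

    D: float
    D_prime: float

    def __post_init__(self) -> None:
        if not (self.D > 0 and self.D_prime > 0):
            raise ValueError("viewpoint distances must be positive")

    @property
    def zoom_ratio(self) -> float:
        """D^2 / D'^2 — the density-correcting factor."""
        return self.D**2 / self.D_prime**2

    def at_distance(self, d_prime: float) -> "ViewState":
        return replace(self, D_prime=d_prime)


@dataclass(frozen=True)
class DotMapConfig:
    """User-facing dot-map controls.

    b scales and c exponentiates every element weight (brightness and
    contrast); q caps dot count per unit measure (``math.inf`` disables the
    cap); offset elevates surface dots along vertex normals.
    """

    b: float = 1.0
    c: float = 1.0
    q: float = math.inf
    seed: int = 0
    offset: float = 0.0
    dot_color: tuple[int, int, int] = (0, 0, 0)
    dot_px: int = 1

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.c > 0):
            raise ValueError("b and c must be positive")
        if not self.q > 0:
            raise ValueError("q must be positive (use math.inf for no cap)")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")


@dataclass
class WeightVector:
    lam: np.ndarray
    lam_adj: np.ndarray


@dataclass
class DotCloud:
    """Sampled dots with provenance back to their source elements."""

    points: np.ndarray  # (n, 3) mm
    element_index: np.ndarray  # (n,)
    counts: np.ndarray  # (n_elements,)
    caps: np.ndarray  # (n_elements,) may contain inf

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.element_index = np.asarray(self.element_index, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.caps = np.asarray(self.caps, dtype=float)

    @property
    def n_dots(self) -> int:
        return len(self.points)

    def to_csv(self, path: str | Path) -> None:
        lines = ["x,y,z,element_id"]
        lines += [
            "%.17g,%.17g,%.17g,%d" % (p[0], p[1], p[2], e)
            for p, e in zip(self.points, self.element_index)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_ply(self, path: str | Path) -> None:
        head = [
            "ply",
            "format ascii 1.0",
            f"element vertex {self.n_dots}",
            "property double x",
            "property double y",
            "property double z",
            "property int element_id",
            "end_header",
        ]
        body = [
            "%.17g %.17g %.17g %d" % (p[0], p[1], p[2], e)
            for p, e in zip(self.points, self.element_index)
        ]
        Path(path).write_text("\n".join(head + body) + "\n")


# ---------------------------------------------------------------------------
# weights and counts
# ---------------------------------------------------------------------------


def compute_weight(V, S, D, D_prime) -> np.ndarray:
    """Raw element weight ``lam = V * S * D^2 / D'^2`` (vectorized)."""
    D = np.asarray(D, dtype=float)
    D_prime = np.asarray(D_prime, dtype=float)
    if not (np.all(D > 0) and np.all(D_prime > 0)):
        raise ValueError("viewpoint distances must be positive")
    V = np.asarray(V, dtype=float)
    S = np.asarray(S, dtype=float)
    return V * S * (D * D) / (D_prime * D_prime)


def adjust_weight(lam, b: float, c: float) -> np.ndarray:
    """Brightness/contrast-adjusted weight ``b * lam**c`` with 0**c := 0."""
    if not (b > 0 and c > 0):
        raise ValueError("b and c must be positive")
    lam = np.asarray(lam, dtype=float)
    out = np.zeros_like(lam)
    pos = lam > 0
    out[pos] = b * np.power(lam[pos], c)
    return out


def dot_cap(measure, q: float) -> np.ndarray:
    """Per-element dot cap ``N = ceil(q * measure)``; q=inf means no cap.

    Ceiling (rather than floor) keeps every positive-measure element
    eligible for at least one dot.
    """
    measure = np.asarray(measure, dtype=float)
    if math.isinf(q):
        return np.full(measure.shape, np.inf)
    return np.ceil(q * measure)


def draw_dot_counts(lam_adj, caps, rng: np.random.Generator) -> np.ndarray:
    """Poisson(lam_adj) draw per element, truncated from above at caps."""
    lam_adj = np.asarray(lam_adj, dtype=float)
    caps = np.asarray(caps, dtype=float)
    x = rng.poisson(lam_adj)
    # float caps so inf passes through untouched
    return np.minimum(x, caps).astype(np.int64)


# ---------------------------------------------------------------------------
# uniform placement inside simplices
# ---------------------------------------------------------------------------


def sample_point_triangle(A, B, C, r1, r2) -> np.ndarray:
    """``P = (1 - sqrt(r1)) A + sqrt(r1) (1 - r2) B + sqrt(r1) r2 C``.

    Vectorized; for r1, r2 ~ U[0,1] the points are uniform over triangle
    ABC (the square root makes the area element Jacobian constant — without
    it density would pile up near vertex A and the sample mean would sit at
    A/2 + B/4 + C/4 instead of the centroid).
    """
    A, B, C = (np.asarray(x, dtype=float) for x in (A, B, C))
    s1 = np.sqrt(np.asarray(r1, dtype=float))[..., None]
    r2 = np.asarray(r2, dtype=float)[..., None]
    return (1.0 - s1) * A + s1 * (1.0 - r2) * B + s1 * r2 * C


def fold_triple(r1, r2, r3) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-stage fold of a uniform cube sample onto the unit simplex.

    Stage one reflects (r1, r2) into the triangle r1 + r2 <= 1; stage two
    folds the resulting prism into the tetrahedron r1 + r2 + r3 <= 1.
    Branch boundaries use <= exactly.  Returns (r1'', r2'', r3'').
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    r3 = np.asarray(r3, dtype=float)
    # stage 1: R' = R if r1 + r2 <= 1 else (1 - r1, 1 - r2, r3)
    flip = r1 + r2 > 1.0
    r1p = np.where(flip, 1.0 - r1, r1)
    r2p = np.where(flip, 1.0 - r2, r2)
    r3p = r3
    # stage 2
    s = r1p + r2p + r3p
    case2 = (s > 1.0) & (r2p + r3p > 1.0)  # -> (r1', 1 - r3', 1 - r1' - r2')
    case3 = (s > 1.0) & (r2p + r3p <= 1.0)  # -> (1 - r2' - r3', r2', s - 1)
    r1pp = np.where(case2, r1p, np.where(case3, 1.0 - r2p - r3p, r1p))
    r2pp = np.where(case2, 1.0 - r3p, r2p)
    r3pp = np.where(case2, 1.0 - r1p - r2p, np.where(case3, s - 1.0, r3p))
    return r1pp, r2pp, r3pp


def sample_point_tetrahedron(A, B, C, D, r1, r2, r3) -> np.ndarray:
    """Fold (r1, r2, r3) onto the unit simplex, then map into tet ABCD.

    ``P = (1 - sum(R'')) A + r1'' B + r2'' C + r3'' D``; uniform over the
    tetrahedron for uniform input variates.
    """
    A, B, C, D = (np.asarray(x, dtype=float) for x in (A, B, C, D))
    r1pp, r2pp, r3pp = fold_triple(r1, r2, r3)
    w0 = (1.0 - r1pp - r2pp - r3pp)[..., None]
    return w0 * A + r1pp[..., None] * B + r2pp[..., None] * C + r3pp[..., None] * D


# ---------------------------------------------------------------------------
# barycentric helpers (containment checks, normal interpolation)
# ---------------------------------------------------------------------------


def barycentric_triangle(points, A, B, C) -> np.ndarray:
    """Barycentric (w_B, w_C) of 3D points wrt triangle ABC via least squares.

    Points are assumed (near) the triangle plane.  Returns shape (n, 2);
    w_A = 1 - w_B - w_C.
    """
    P = np.asarray(points, dtype=float) - np.asarray(A, dtype=float)
    e1 = np.asarray(B, dtype=float) - A
    e2 = np.asarray(C, dtype=float) - A
    g11, g12, g22 = e1 @ e1, e1 @ e2, e2 @ e2
    p1, p2 = P @ e1, P @ e2
    det = g11 * g22 - g12 * g12
    if det == 0:
        return np.full((len(P), 2), np.nan)
    wb = (g22 * p1 - g12 * p2) / det
    wc = (g11 * p2 - g12 * p1) / det
    return np.column_stack([wb, wc])


def barycentric_tetrahedron(points, A, B, C, D) -> np.ndarray:
    """Barycentric (w_B, w_C, w_D) of points wrt tetrahedron ABCD."""
    A = np.asarray(A, dtype=float)
    M = np.column_stack([np.asarray(B) - A, np.asarray(C) - A, np.asarray(D) - A])
    P = np.asarray(points, dtype=float).reshape(-1, 3) - A
    return P @ np.linalg.inv(M).T


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def generate_dot_map(
    mesh: SurfaceMesh | VolumeMesh,
    field: ElementField,
    view: ViewState,
    config: DotMapConfig,
    rng: np.random.Generator | None = None,
) -> DotCloud:
    """Run the full dot-map pipeline for one mesh + scalar field + view.

    ``field`` must hold one normalized value in [0, 1] per element.  Counts
    are drawn first (element order), then two uniform variates per surface
    dot or three per volumetric dot place the points.  Identical inputs and
    seed give a bit-identical :class:`DotCloud`.
    """
    vals = field.values
    if len(vals) != mesh.n_elements:
        raise ValueError(
            f"field length {len(vals)} != element count {mesh.n_elements}"
        )
    if vals.min(initial=0.0) < 0 or vals.max(initial=0.0) > 1:
        raise ValueError("field must be normalized to [0, 1] (see normalize_field)")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    V = element_measure(mesh)
    lam = compute_weight(V, vals, view.D, view.D_prime)
    lam_adj = adjust_weight(lam, config.b, config.c)
    caps = dot_cap(V, config.q)
    counts = draw_dot_counts(lam_adj, caps, rng)

    total = int(counts.sum())
    element_index = np.repeat(np.arange(mesh.n_elements), counts)
    if total == 0:
        return DotCloud(np.empty((0, 3)), element_index, counts, caps)

    verts = mesh.vertices
    if isinstance(mesh, SurfaceMesh):
        tri = mesh.triangles[element_index]
        r = rng.random((total, 2))
        points = sample_point_triangle(
            verts[tri[:, 0]], verts[tri[:, 1]], verts[tri[:, 2]], r[:, 0], r[:, 1]
        )
    else:
        tet = mesh.tetrahedra[element_index]
        r = rng.random((total, 3))
        points = sample_point_tetrahedron(
            verts[tet[:, 0]],
            verts[tet[:, 1]],
            verts[tet[:, 2]],
            verts[tet[:, 3]],
            r[:, 0],
            r[:, 1],
            r[:, 2],
        )
    return DotCloud(points, element_index, counts, caps)
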