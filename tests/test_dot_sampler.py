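import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from dotmap.dot_sampler import (
    DotCloud,
    DotMapConfig,
    ViewState,
    adjust_weight,
    barycentric_tetrahedron,
    barycentric_triangle,
    compute_weight,
    dot_cap,
    draw_dot_counts,
    fold_triple,
    generate_dot_map,
    sample_point_tetrahedron,
    sample_point_triangle,
)
from dotmap.mesh_core import ElementField, SurfaceMesh, element_measure


class TestComputeWeight:
    def test_identity_case(self):
        assert compute_weight(1.0, 1.0, 10.0, 10.0) == 1.0

    def test_hand_substitution(self):
        assert compute_weight(2.0, 0.5, 10.0, 5.0) == pytest.approx(4.0)

    def test_zero_scalar_annihilates(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(0, 100, 50)
        assert (compute_weight(V, 0.0, 3.0, 7.0) == 0.0).all()

    @given(
        V=st.floats(0, 1e6, allow_nan=False),
        S=st.floats(0, 1, allow_nan=False),
        D=st.floats(1e-3, 1e3, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_halving_distance_exactly_quadruples(self, V, S, D):
        near = compute_weight(V, S, D, D / 2)
        far = compute_weight(V, S, D, D)
        assert near == 4.0 * far

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            compute_weight(1.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            compute_weight(1.0, 1.0, 1.0, -2.0)


class TestAdjustWeight:
    def test_identity_at_b1_c1(self):
        lam = np.array([0.0, 0.5, 2.0, 100.0])
        np.testing.assert_array_equal(adjust_weight(lam, 1.0, 1.0), lam)

    def test_hand_evaluation(self):
        assert adjust_weight(np.array([4.0]), 2.0, 0.5)[0] == pytest.approx(4.0)

    def test_zero_weight_stays_zero(self):
        assert adjust_weight(np.array([0.0]), 5.0, 0.3)[0] == 0.0

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            adjust_weight(np.array([1.0]), 0.0, 1.0)
        with pytest.raises(ValueError):
            adjust_weight(np.array([1.0]), 1.0, -1.0)


class TestDotCap:
    def test_unbounded(self):
        caps = dot_cap(np.array([0.1, 1e6]), math.inf)
        assert np.isinf(caps).all()

    def test_ceiling(self):
        assert dot_cap(np.array([0.35]), 10.0)[0] == 4

    def test_zero_measure(self):
        assert dot_cap(np.array([0.0]), 10.0)[0] == 0


class TestDrawDotCounts:
    def test_zero_mean_draws_zero(self):
        rng = np.random.default_rng(0)
        x = draw_dot_counts(np.zeros(1000), np.full(1000, np.inf), rng)
        assert (x == 0).all()

    def test_cap_is_hard(self):
        rng = np.random.default_rng(1)
        x = draw_dot_counts(np.full(10_000, 10.0), np.full(10_000, 3.0), rng)
        assert x.max() <= 3

    def test_poisson_moments(self):
        rng = np.random.default_rng(2)
        lam = 2.0
        n = 100_000
        x = draw_dot_counts(np.full(n, lam), np.full(n, np.inf), rng)
        se_mean = math.sqrt(lam / n)
        assert abs(x.mean() - lam) < 3 * se_mean
        # Var[(X - lam)^2] = lam + 2 lam^2 for Poisson
        se_var = math.sqrt((lam + 2 * lam**2) / n)
        assert abs(x.var() - lam) < 3 * se_var


class TestTriangleSampler:
    def test_collapses_to_vertices(self, ref_triangle):
        A, B, C = ref_triangle
        np.testing.assert_array_equal(sample_point_triangle(A, B, C, 0.0, 0.7), A)
        np.testing.assert_array_equal(sample_point_triangle(A, B, C, 1.0, 0.0), B)
        np.testing.assert_array_equal(sample_point_triangle(A, B, C, 1.0, 1.0), C)

    def test_mean_is_centroid(self, ref_triangle):
        A, B, C = ref_triangle
        rng = np.random.default_rng(3)
        r = rng.random((100_000, 2))
        P = sample_point_triangle(A, B, C, r[:, 0], r[:, 1])
        centroid = (A + B + C) / 3
        # per-coordinate sd of a uniform point in this triangle is < 0.24
        se = 0.24 / math.sqrt(len(P))
        assert (np.abs(P.mean(axis=0)[:2] - centroid[:2]) < 3 * se).all()

    def test_containment(self, ref_triangle):
        A, B, C = ref_triangle
        rng = np.random.default_rng(4)
        r = rng.random((100_000, 2))
        P = sample_point_triangle(A, B, C, r[:, 0], r[:, 1])
        w = barycentric_triangle(P, A, B, C)
        assert (w >= -1e-9).all() and (w.sum(axis=1) <= 1 + 1e-9).all()


class TestTetrahedronSampler:
    def test_origin_variates_give_vertex_a(self, ref_tetrahedron):
        A, B, C, D = ref_tetrahedron
        np.testing.assert_array_equal(sample_point_tetrahedron(A, B, C, D, 0, 0, 0), A)

    def test_hand_trace_to_vertex_b(self, ref_tetrahedron):
        A, B, C, D = ref_tetrahedron
        # r1 + r2 = 1 passes fold 1; sum = 1 passes fold 2 -> P = B
        np.testing.assert_array_equal(sample_point_tetrahedron(A, B, C, D, 1, 0, 0), B)

    def test_hand_trace_third_branch(self, ref_tetrahedron):
        A, B, C, D = ref_tetrahedron
        # (.5,.5,.5): fold 1 passes; sum 1.5 > 1, r2'+r3' = 1 <= 1 ->
        # R'' = (0, .5, .5) -> midpoint of C and D
        P = sample_point_tetrahedron(A, B, C, D, 0.5, 0.5, 0.5)
        np.testing.assert_allclose(P, (C + D) / 2)

    def test_fold_triple_lands_in_simplex(self):
        rng = np.random.default_rng(5)
        r = rng.random((50_000, 3))
        r1, r2, r3 = fold_triple(r[:, 0], r[:, 1], r[:, 2])
        assert (r1 >= 0).all() and (r2 >= 0).all() and (r3 >= 0).all()
        assert (r1 + r2 + r3 <= 1 + 1e-12).all()

    @given(
        r1=st.floats(0, 1, allow_nan=False),
        r2=st.floats(0, 1, allow_nan=False),
        r3=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_fold_triple_property(self, r1, r2, r3):
        f1, f2, f3 = fold_triple(r1, r2, r3)
        assert f1 >= -1e-12 and f2 >= -1e-12 and f3 >= -1e-12
        assert f1 + f2 + f3 <= 1 + 1e-12

    def test_mean_is_centroid(self, ref_tetrahedron):
        A, B, C, D = ref_tetrahedron
        rng = np.random.default_rng(6)
        r = rng.random((100_000, 3))
        P = sample_point_tetrahedron(A, B, C, D, r[:, 0], r[:, 1], r[:, 2])
        se = 0.2 / math.sqrt(len(P))
        np.testing.assert_allclose(P.mean(axis=0), (A + B + C + D) / 4, atol=3 * se)

    def test_containment(self, ref_tetrahedron):
        A, B, C, D = ref_tetrahedron
        rng = np.random.default_rng(7)
        r = rng.random((100_000, 3))
        P = sample_point_tetrahedron(A, B, C, D, r[:, 0], r[:, 1], r[:, 2])
        w = barycentric_tetrahedron(P, A, B, C, D)
        assert (w >= -1e-9).all() and (w.sum(axis=1) <= 1 + 1e-9).all()


class TestGenerateDotMap:
    def _unit_triangle_mesh(self):
        return SurfaceMesh(
            vertices=[[0, 0, 0], [2, 0, 0], [0, 1, 0]], triangles=[[0, 1, 2]]
        )

    def test_zero_field_gives_empty_cloud(self, disc16):
        field = ElementField(np.zeros(disc16.n_elements))
        cloud = generate_dot_map(disc16, field, ViewState(10, 10), DotMapConfig(seed=0))
        assert cloud.n_dots == 0
        assert (cloud.counts == 0).all()

    def test_poisson_mean_through_pipeline(self):
        # unit-area triangle, S=1, D=D', b=5 -> counts ~ Poisson(5)
        mesh = self._unit_triangle_mesh()
        assert element_measure(mesh)[0] == pytest.approx(1.0)
        field = ElementField(np.ones(1))
        view = ViewState(10, 10)
        total = 0
        reps = 10_000
        for k in range(reps):
            cfg = DotMapConfig(b=5.0, seed=k)
            total += generate_dot_map(mesh, field, view, cfg).n_dots
        mean = total / reps
        assert abs(mean - 5.0) < 3 * math.sqrt(5.0 / reps)

    def test_counts_proportional_to_area(self):
        # areas 1 and 3 with uniform S -> expected counts in ratio 1:3
        mesh = SurfaceMesh(
            vertices=[[0, 0, 0], [2, 0, 0], [0, 1, 0], [-6, 0, 0], [0, -1, 0]],
            triangles=[[0, 1, 2], [0, 3, 4]],
        )
        np.testing.assert_allclose(element_measure(mesh), [1.0, 3.0])
        field = ElementField(np.ones(2))
        view = ViewState(10, 10)
        rng = np.random.default_rng(0)
        counts = np.zeros(2)
        reps = 10_000
        b = 2.0
        for _ in range(reps):
            counts += generate_dot_map(mesh, field, view, DotMapConfig(b=b), rng=rng).counts
        lam = b * np.array([1.0, 3.0])
        se = np.sqrt(lam / reps)
        assert (np.abs(counts / reps - lam) < 3 * se).all()

    def test_identical_seed_bit_identical(self, disc16):
        field = ElementField(disc16.field("S").values)
        view = ViewState(10, 8.0)
        cfg = DotMapConfig(b=2000.0, seed=123)
        c1 = generate_dot_map(disc16, field, view, cfg)
        c2 = generate_dot_map(disc16, field, view, cfg)
        np.testing.assert_array_equal(c1.points, c2.points)
        np.testing.assert_array_equal(c1.counts, c2.counts)

    def test_different_seeds_differ(self, disc16):
        field = ElementField(disc16.field("S").values)
        view = ViewState(10, 10)
        c1 = generate_dot_map(disc16, field, view, DotMapConfig(b=500.0, seed=1))
        c2 = generate_dot_map(disc16, field, view, DotMapConfig(b=500.0, seed=2))
        assert c1.n_dots >= 100
        assert c1.n_dots != c2.n_dots or not np.array_equal(c1.points, c2.points)

    def test_counts_sum_matches_points(self, disc16):
        field = ElementField(disc16.field("S").values)
        cloud = generate_dot_map(disc16, field, ViewState(10, 10), DotMapConfig(b=800.0))
        assert cloud.counts.sum() == cloud.n_dots
        assert (cloud.counts <= cloud.caps).all()

    def test_points_inside_source_elements(self, disc16):
        field = ElementField(disc16.field("S").values)
        cloud = generate_dot_map(disc16, field, ViewState(10, 10), DotMapConfig(b=800.0))
        v = disc16.vertices
        for el in np.unique(cloud.element_index)[:50]:
            tri = disc16.triangles[el]
            pts = cloud.points[cloud.element_index == el]
            w = barycentric_triangle(pts, v[tri[0]], v[tri[1]], v[tri[2]])
            assert (w >= -1e-9).all() and (w.sum(axis=1) <= 1 + 1e-9).all()

    def test_monotone_in_s_b_and_v(self):
        # expected counts rise with S, b and V; verify on realized means
        view = ViewState(10, 10)
        mesh = self._unit_triangle_mesh()
        reps = 3000

        def mean_count(field_val, b, mesh=mesh):
            rng = np.random.default_rng(99)
            field = ElementField(np.array([field_val]))
            return (
                sum(
                    generate_dot_map(mesh, field, view, DotMapConfig(b=b), rng=rng).n_dots
                    for _ in range(reps)
                )
                / reps
            )

        assert mean_count(0.2, 10.0) < mean_count(0.8, 10.0)
        assert mean_count(0.5, 5.0) < mean_count(0.5, 20.0)
        big = SurfaceMesh(
            vertices=[[0, 0, 0], [4, 0, 0], [0, 2, 0]], triangles=[[0, 1, 2]]
        )
        assert mean_count(0.5, 10.0) < mean_count(0.5, 10.0, mesh=big)

    def test_unnormalized_field_rejected(self, disc16):
        field = ElementField(np.full(disc16.n_elements, 2.0))
        with pytest.raises(ValueError, match="normalized"):
            generate_dot_map(disc16, field, ViewState(10, 10), DotMapConfig())

    def test_field_length_mismatch_rejected(self, disc16):
        with pytest.raises(ValueError):
            generate_dot_map(
                disc16, ElementField(np.ones(3)), ViewState(10, 10), DotMapConfig()
            )

    def test_volumetric_pipeline(self, single_tet_mesh):
        field = ElementField(np.ones(1))
        cfg = DotMapConfig(b=600.0, seed=5)
        cloud = generate_dot_map(single_tet_mesh, field, ViewState(10, 10), cfg)
        assert cloud.n_dots > 0
        v = single_tet_mesh.vertices
        w = barycentric_tetrahedron(cloud.points, v[0], v[1], v[2], v[3])
        assert (w >= -1e-9).all() and (w.sum(axis=1) <= 1 + 1e-9).all()

    def test_cap_limits_total(self):
        mesh = self._unit_triangle_mesh()
        field = ElementField(np.ones(1))
        cfg = DotMapConfig(b=1000.0, q=5.0, seed=0)  # cap = ceil(5*1) = 5
        cloud = generate_dot_map(mesh, field, ViewState(10, 10), cfg)
        assert cloud.n_dots <= 5


class TestViewStateAndConfig:
    def test_view_state_requires_positive(self):
        with pytest.raises(ValueError):
            ViewState(0, 1)
        with pytest.raises(ValueError):
            ViewState(1, -1)

    def test_zoom_ratio_quarters_at_double_distance(self):
        assert ViewState(10, 20).zoom_ratio == pytest.approx(0.25)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DotMapConfig(b=-1)
        with pytest.raises(ValueError):
            DotMapConfig(c=0)
        with pytest.raises(ValueError):
            DotMapConfig(q=0)
        with pytest.raises(ValueError):
            DotMapConfig(offset=-0.1)

    def test_chi_square_uniformity_against_subdivision(self, ref_triangle, ref_tetrahedron):
        from dotmap.density_analysis import (
            tetrahedron_subdivision_counts,
            triangle_subdivision_counts,
        )

        A, B, C = ref_triangle
        rng = np.random.default_rng(11)
        r = rng.random((100_000, 2))
        P = sample_point_triangle(A, B, C, r[:, 0], r[:, 1])
        assert chisquare(triangle_subdivision_counts(P, A, B, C)).pvalue > 0.001

        A, B, C, D = ref_tetrahedron
        r = rng.random((100_000, 3))
        Q = sample_point_tetrahedron(A, B, C, D, r[:, 0], r[:, 1], r[:, 2])
        assert chisquare(tetrahedron_subdivision_counts(Q, A, B, C, D)).pvalue > 0.001


class TestDotCloudExport:
    def test_csv_round_trip_fields(self, tmp_path, disc16):
        field = ElementField(disc16.field("S").values)
        cloud = generate_dot_map(disc16, field, ViewState(10, 10), DotMapConfig(b=300.0))
        path = tmp_path / "dots.csv"
        cloud.to_csv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "x,y,z,element_id"
        assert len(lines) == cloud.n_dots + 1

    def test_ply_header(self, tmp_path, disc16):
        field = ElementField(disc16.field("S").values)
        cloud = generate_dot_map(disc16, field, ViewState(10, 10), DotMapConfig(b=300.0))
        path = tmp_path / "dots.ply"
        cloud.to_ply(path)
        text = path.read_text()
        assert text.startswith("ply\nformat ascii 1.0")
        assert f"element vertex {cloud.n_dots}" in text
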