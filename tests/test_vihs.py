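"""Minimal-area rectangle, vertex scattering, and ViHS spline fitting."""

import numpy as np
import pytest
import shapely

from woundmetrics import (
    WoundEdge,
    WoundMask,
    build_instances,
    fit_vihs,
    min_area_rect,
    scatter_quads,
    trace_edge_subpixel,
)
from woundmetrics.errors import DegenerateGeometry
from conftest import make_surface


def _edge_from_xy(xy):
    xy = np.asarray(xy, float)
    return WoundEdge(vertices=xy[:, ::-1], xy=xy)


def _brute_force_min_rect_area(pts):
    """Independent oracle: try every convex-hull-edge orientation."""
    hull = shapely.MultiPoint(pts).convex_hull
    coords = np.asarray(hull.exterior.coords)[:-1]
    best = np.inf
    for k in range(len(coords)):
        d = coords[(k + 1) % len(coords)] - coords[k]
        th = np.arctan2(d[1], d[0])
        rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        q = pts @ rot.T
        area = np.ptp(q[:, 0]) * np.ptp(q[:, 1])
        best = min(best, area)
    return best


class TestMinAreaRect:
    def test_axis_aligned_unit_square(self):
        xy = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        quad = min_area_rect(_edge_from_xy(xy))
        assert shapely.Polygon(quad.vertices).area == pytest.approx(1.0)
        assert quad.angle_deg % 90 == pytest.approx(0.0)

    def test_rotation_equivariance(self):
        xy = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        th = np.deg2rad(45)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        quad = min_area_rect(_edge_from_xy(xy @ rot.T))
        assert shapely.Polygon(quad.vertices).area == pytest.approx(1.0)
        assert quad.angle_deg % 90 == pytest.approx(45.0)

    def test_matches_hull_edge_oracle_on_random_points(self):
        rng = np.random.default_rng(2024)
        for _ in range(5):
            pts = rng.normal(0, 5, size=(200, 2))
            quad = min_area_rect(_edge_from_xy(pts))
            area = shapely.Polygon(quad.vertices).area
            assert area == pytest.approx(_brute_force_min_rect_area(pts), abs=1e-9)
            # shapely's own minimum rotated rectangle agrees
            mrr = shapely.MultiPoint(pts).minimum_rotated_rectangle
            assert area == pytest.approx(mrr.area, rel=1e-9)
            # all points contained
            assert shapely.Polygon(quad.vertices).buffer(1e-9).covers(
                shapely.MultiPoint(pts)
            )

    def test_translation_equivariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 3, size=(60, 2))
        q0 = min_area_rect(_edge_from_xy(pts))
        q1 = min_area_rect(_edge_from_xy(pts + [10.0, -4.0]))
        assert np.allclose(q1.vertices - [10.0, -4.0], q0.vertices, atol=1e-9)

    def test_collinear_edge_rejected(self):
        xy = np.column_stack([np.linspace(0, 5, 12), np.linspace(0, 5, 12)])
        with pytest.raises(DegenerateGeometry):
            min_area_rect(_edge_from_xy(xy))


class TestMinAreaRectProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rect_covers_points_and_area_is_rotation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-8, 8, size=(rng.integers(3, 40), 2))
        if np.linalg.matrix_rank(pts - pts.mean(0)) < 2:
            return  # collinear draws are rejected by contract
        quad = min_area_rect(_edge_from_xy(pts))
        poly = shapely.Polygon(quad.vertices).buffer(1e-9)
        assert poly.covers(shapely.MultiPoint(pts))
        th = rng.uniform(0, np.pi)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        quad_r = min_area_rect(_edge_from_xy(pts @ rot.T))
        assert shapely.Polygon(quad_r.vertices).area == pytest.approx(
            shapely.Polygon(quad.vertices).area, rel=1e-9, abs=1e-12
        )


class TestScatter:
    @pytest.fixture()
    def rect(self):
        xy = np.array([[0, 0], [30, 0], [30, 20], [0, 20]], float)
        return min_area_rect(_edge_from_xy(xy))

    def test_zero_half_width_reproduces_rect(self, rect):
        quads = scatter_quads(rect, n=10, half_width=0.0, seed=1)
        assert len(quads) == 10
        for q in quads:
            assert np.allclose(q.vertices, rect.vertices)

    def test_displacements_bounded_in_rect_axes(self, rect):
        quads = scatter_quads(rect, n=2500, half_width=2.5, seed=3)
        disp = np.concatenate([q.vertices - rect.vertices for q in quads])
        local = disp @ rect.axes.T  # components along the rectangle's axes
        assert np.abs(local).max() <= 2.5 + 1e-12

    def test_displacements_uniform(self, rect):
        from scipy.stats import kstest

        quads = scatter_quads(rect, n=25000, half_width=2.5, seed=5)
        disp = np.concatenate([q.vertices - rect.vertices for q in quads])
        local = disp @ rect.axes.T
        for axis in (0, 1):
            p = kstest(local[:, axis], "uniform", args=(-2.5, 5.0)).pvalue
            assert p > 0.01

    def test_reproducible_given_seed(self, rect):
        a = scatter_quads(rect, n=5, half_width=2.5, seed=11)
        b = scatter_quads(rect, n=5, half_width=2.5, seed=11)
        for qa, qb in zip(a, b):
            assert (qa.vertices == qb.vertices).all()


class TestFit:
    def test_plane_reproduced_exactly(self, plane_surface):
        xy = np.array([[-12, -9], [12, -9], [12, 9], [-12, 9]], float)
        quad = min_area_rect(_edge_from_xy(xy))
        v = fit_vihs(plane_surface, None, quad)
        u = np.linspace(0, 1, 50)
        U, V = np.meshgrid(u, u)
        pts = v.spline.evaluate(U.ravel(), V.ravel())
        assert np.abs(pts[:, 2] - 10.0).max() < 1e-6

    def test_cylinder_reconstructed_under_wound(self):
        R = 50.0
        surf = make_surface(
            lambda x, y: 10.0 + np.sqrt(R**2 - x**2) - R, pitch=0.25
        )
        rr = np.hypot(surf.x, surf.y)
        mask = WoundMask(mask=rr < 10)
        edge = trace_edge_subpixel(mask, surf)
        v = fit_vihs(surf, mask, min_area_rect(edge))
        g = np.linspace(-9.0, 9.0, 50)
        GX, GY = np.meshgrid(g, g)
        sel = np.hypot(GX, GY) < 10
        u, vv, ok = v.spline.invert_xy(GX[sel], GY[sel])
        assert ok.all()
        z = v.spline.evaluate(u, vv)[:, 2]
        z_true = 10.0 + np.sqrt(R**2 - GX[sel] ** 2) - R
        assert np.sqrt(np.mean((z - z_true) ** 2)) < 0.1

    def test_wound_free_residual_below_noise(self):
        sigma = 0.1
        surf = make_surface(lambda x, y: 8.0, noise_sigma=sigma, seed=21)
        xy = np.array([[-15, -12], [15, -12], [15, 12], [-15, 12]], float)
        quad = min_area_rect(_edge_from_xy(xy))
        v = fit_vihs(surf, None, quad)
        inside = (np.abs(surf.x) < 14) & (np.abs(surf.y) < 11)
        u, vv, ok = v.spline.invert_xy(surf.x[inside], surf.y[inside])
        z = v.spline.evaluate(u, vv)[:, 2]
        rms = np.sqrt(np.mean((z - surf.z[inside]) ** 2))
        assert rms < sigma


class TestInstances:
    def test_default_ensemble_has_31_instances(self, small_gen):
        wounded, _, mask, _ = small_gen
        edge = trace_edge_subpixel(mask, wounded)
        instances, warnings = build_instances(wounded, mask, edge)
        assert len(instances) == 31
        assert not warnings
        assert instances[0].quad.provenance == "initial"
        assert all(i.quad.provenance == "scattered" for i in instances[1:])

    def test_zero_scatter_count_gives_single_instance(self, small_gen):
        wounded, _, mask, _ = small_gen
        edge = trace_edge_subpixel(mask, wounded)
        instances, _ = build_instances(wounded, mask, edge, n_scatter=0)
        assert len(instances) == 1

    def test_zero_half_width_gives_identical_surfaces(self, small_gen):
        wounded, _, mask, _ = small_gen
        edge = trace_edge_subpixel(mask, wounded)
        instances, _ = build_instances(
            wounded, mask, edge, n_scatter=5, half_width=0.0
        )
        ref = instances[0].spline.ctrl
        for inst in instances[1:]:
            assert np.abs(inst.spline.ctrl - ref).max() < 1e-9
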