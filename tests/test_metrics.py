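"""Deviation field, VDW integration, perimeter/area, and the full analysis."""

import numpy as np
import pytest

from woundmetrics import (
    AnalyzeConfig,
    WoundEdge,
    WoundMask,
    analyze,
    deviation_field,
    fit_vihs,
    integrate_vdw,
    measure_perimeter_area,
    min_area_rect,
    repeatability_stats,
)
from woundmetrics.errors import EmptyWound, StatsInsufficient
from conftest import make_surface


def _edge_from_xy(xy):
    xy = np.asarray(xy, float)
    return WoundEdge(vertices=xy[:, ::-1], xy=xy)


def _circle_edge(r=10.0, n=720, cx=0.0, cy=0.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return _edge_from_xy(np.stack([cx + r * np.cos(th), cy + r * np.sin(th)], -1))


def _plane_vihs(surface, half=(15.0, 12.0)):
    xy = np.array(
        [[-half[0], -half[1]], [half[0], -half[1]], [half[0], half[1]], [-half[0], half[1]]],
        float,
    )
    return fit_vihs(surface, None, min_area_rect(_edge_from_xy(xy)))


class TestDeviationField:
    def test_wound_free_plane_has_zero_deviation(self, plane_surface):
        v = _plane_vihs(plane_surface)
        fld = deviation_field(plane_surface, v, _circle_edge(8.0), h=0.5)
        sel = fld.valid & fld.in_wound
        assert sel.any()
        assert np.abs(fld.d[sel]).max() < 1e-6

    def test_square_depression_is_minus_two_inside(self):
        def z(x, y):
            inside = (np.abs(x) < 5) & (np.abs(y) < 5)
            return np.where(inside, 8.0, 10.0)

        surf = make_surface(z)
        flat = make_surface(lambda x, y: 10.0)
        v = _plane_vihs(flat)
        sq = np.array([[-5, -5], [5, -5], [5, 5], [-5, 5]], float)
        fld = deviation_field(surf, v, _edge_from_xy(sq), h=0.5)
        sel = fld.valid & fld.in_wound
        interior = sel & (np.abs(fld.x) < 4) & (np.abs(fld.y) < 4)
        outside = fld.valid & ~fld.in_wound & (np.abs(fld.x) > 6) & (np.abs(fld.x) < 12)
        assert np.allclose(fld.d[interior], -2.0, atol=1e-6)
        assert np.allclose(fld.d[outside], 0.0, atol=1e-6)

    def test_tilted_plane_area_elements_carry_metric_factor(self):
        slope = np.tan(np.deg2rad(30.0))
        surf = make_surface(lambda x, y: 10.0 + slope * x)
        v = _plane_vihs(surf)
        h = 0.5
        fld = deviation_field(surf, v, _circle_edge(8.0), h=h)
        sel = fld.valid & fld.in_wound
        expect = h * h / np.cos(np.deg2rad(30.0))
        assert np.allclose(fld.area_el[sel], expect, rtol=1e-6)


def _box(t, half, ramp=0.25):
    """Box profile with a one-grid-cell linear ramp centered on +-half, so
    its bilinear-interpolated integral equals 2*half exactly."""
    return np.clip((half + ramp / 2 - np.abs(t)) / ramp, 0.0, 1.0)


class TestIntegrateVdw:
    def _prism_field(self, h=0.25, depth=2.0):
        def z(x, y):
            return 10.0 - depth * _box(x, 5.0) * _box(y, 5.0)

        surf = make_surface(z, pitch=0.25)
        flat = make_surface(lambda x, y: 10.0, pitch=0.25)
        v = _plane_vihs(flat)
        sq = np.array([[-6, -6], [6, -6], [6, 6], [-6, 6]], float)
        return deviation_field(surf, v, _edge_from_xy(sq), h=h)

    def test_prism_cavity_volume(self):
        v_pos, v_neg, vdw = integrate_vdw(self._prism_field())
        assert vdw == pytest.approx(200.0, rel=0.01)
        assert v_pos == pytest.approx(0.0, abs=1e-6)
        assert vdw == v_pos + abs(v_neg)

    def test_symmetric_depression_and_protrusion(self):
        def z(x, y):
            dep = _box(x + 6, 3.0) * _box(y, 3.0)
            pro = _box(x - 6, 3.0) * _box(y, 3.0)
            return 10.0 - 2.0 * dep + 2.0 * pro

        surf = make_surface(z, pitch=0.25)
        flat = make_surface(lambda x, y: 10.0, pitch=0.25)
        v = _plane_vihs(flat)
        sq = np.array([[-12, -7], [12, -7], [12, 7], [-12, 7]], float)
        fld = deviation_field(surf, v, _edge_from_xy(sq), h=0.25)
        v_pos, v_neg, vdw = integrate_vdw(fld)
        V = 6 * 6 * 2.0
        assert v_pos == pytest.approx(V, rel=0.02)
        assert v_neg == pytest.approx(-V, rel=0.02)
        assert vdw == pytest.approx(2 * V, rel=0.02)

    def test_empty_wound_raises(self, plane_surface):
        v = _plane_vihs(plane_surface)
        edge = _circle_edge(3.0, cx=100.0, cy=100.0)  # off the quad entirely
        fld = deviation_field(plane_surface, v, edge, h=0.5)
        with pytest.raises(EmptyWound):
            integrate_vdw(fld)

    def test_quadrature_converges_under_refinement(self, small_gen):
        wounded, _, mask, _ = small_gen
        from woundmetrics import trace_edge_subpixel

        edge = trace_edge_subpixel(mask, wounded)
        v = fit_vihs(wounded, mask, min_area_rect(edge))
        vals = []
        for h in (0.5, 0.25):
            fld = deviation_field(wounded, v, edge, h=h)
            vals.append(integrate_vdw(fld)[2])
        assert abs(vals[0] - vals[1]) / vals[1] < 0.005


class TestPerimeterArea:
    def test_circle_on_plane_closed_form(self, plane_surface):
        v = _plane_vihs(plane_surface)
        edge = _circle_edge(10.0)
        fld = deviation_field(plane_surface, v, edge, h=0.25)
        p, a = measure_perimeter_area(v, edge, fld)
        assert p == pytest.approx(2 * np.pi * 10, rel=0.005)
        assert a == pytest.approx(np.pi * 100, rel=0.01)

    def test_tilted_square_metric_factor(self):
        slope = np.tan(np.deg2rad(60.0))
        surf = make_surface(lambda x, y: 10.0 + slope * x, extent=(36, 30))
        v = _plane_vihs(surf, half=(8.0, 8.0))
        sq = np.array([[-5, -5], [5, -5], [5, 5], [-5, 5]], float)
        edge = _edge_from_xy(sq)
        fld = deviation_field(surf, v, edge, h=0.25)
        p, a = measure_perimeter_area(v, edge, fld)
        assert a == pytest.approx(100.0 / np.cos(np.deg2rad(60.0)), rel=0.01)
        assert p == pytest.approx(2 * 10 + 2 * 10 / np.cos(np.deg2rad(60.0)), rel=0.005)

    def test_similarity_scaling(self, plane_surface):
        v = _plane_vihs(plane_surface)
        e1 = _circle_edge(5.0)
        e2 = _circle_edge(10.0)
        f1 = deviation_field(plane_surface, v, e1, h=0.25)
        f2 = deviation_field(plane_surface, v, e2, h=0.25)
        p1, a1 = measure_perimeter_area(v, e1, f1)
        p2, a2 = measure_perimeter_area(v, e2, f2)
        assert p2 / p1 == pytest.approx(2.0, rel=0.01)
        assert a2 / a1 == pytest.approx(4.0, rel=0.02)


class TestAnalyze:
    def test_default_run_yields_31_instances(self, small_gen):
        wounded, _, mask, _ = small_gen
        res = analyze(wounded, mask, AnalyzeConfig(master_seed=4))
        assert res.n_instances == 31
        assert len(res.instances) == 31
        for m in res.instances:
            assert m.vdw == m.v_pos + abs(m.v_neg)
        arr = np.array([[m.perimeter, m.area, m.vdw] for m in res.instances])
        assert res.summary.perimeter_mean == pytest.approx(arr[:, 0].mean())
        assert res.summary.vdw_std == pytest.approx(arr[:, 2].std(ddof=1))

    def test_zero_scatter_width_gives_zero_spread(self, small_gen):
        wounded, _, mask, _ = small_gen
        res = analyze(wounded, mask, AnalyzeConfig(half_width_mm=0.0, master_seed=4))
        assert res.summary.perimeter_std < 1e-6
        assert res.summary.area_std < 1e-6
        assert res.summary.vdw_std < 1e-6

    def test_accepts_edge_input(self, small_gen):
        wounded, _, mask, _ = small_gen
        from woundmetrics import trace_edge_subpixel

        edge = trace_edge_subpixel(mask, wounded)
        res = analyze(
            wounded, edge, AnalyzeConfig(master_seed=4, n_scatter=3)
        )
        assert res.n_instances == 4


class TestRepeatabilityStats:
    def test_identical_groups_report_p_one(self):
        out = repeatability_stats([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])
        assert out["kruskal_p"] >= 0.99
        assert out["group_std"] == [0.0, 0.0]

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(17)
        g1 = rng.normal(0, 1, 20)
        g2 = rng.normal(5, 1, 20)
        out = repeatability_stats([list(g1), list(g2)])
        assert out["kruskal_p"] < 0.001
        # independent rank-sum oracle agrees on the verdict
        from scipy.stats import ranksums

        assert ranksums(g1, g2).pvalue < 0.001

    def test_group_order_invariance(self):
        rng = np.random.default_rng(23)
        groups = [list(rng.normal(i, 1, 12)) for i in range(3)]
        a = repeatability_stats(groups)
        b = repeatability_stats(groups[::-1])
        assert a["kruskal_p"] == pytest.approx(b["kruskal_p"])
        assert a["levene_p"] == pytest.approx(b["levene_p"])

    def test_insufficient_data_rejected(self):
        with pytest.raises(StatsInsufficient):
            repeatability_stats([[1.0, 2.0]])
        with pytest.raises(StatsInsufficient):
            repeatability_stats([[1.0, 2.0], [3.0]])
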