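"""Wound measurements: perimeter, area, and volumetric deviation (VDW).

The wound volume is the volumetric difference between the measured
surface and the virtual healthy skin, integrated over the wound area:
the absolute negative volume (cavity below the ViHS) and positive volume
(tissue above it) are summed into the VDW, so a wound with equal cavity
and protrusion does not cancel to a misleading zero.

Deviation is measured along the scan z axis (the surface is a 2.5D
height field), perimeter and area are evaluated *on* the ViHS (the edge
is lifted to the spline; the area integrates spline area elements inside
the edge), which is what makes averaging over 31 ViHS instances
meaningful.  One analysis therefore yields 31 (perimeter, area, VDW)
triples whose mean is the reported result and whose sample standard
deviation quantifies anchoring sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import stats

from .errors import AnalysisFailed, EmptyWound, FieldDegenerate, StatsInsufficient
from .segmentation import WoundEdge, WoundMask, edge_to_mask, trace_edge_subpixel
from .surface import OrganizedSurface
from .vihs import FitConfig, VihsSurface, build_instances

#: how far (in parameter units) the spline is evaluated beyond the anchor
#: quad, so that vertex scattering can never truncate the wound domain
_COLLAR = 0.2


@dataclass
class DeviationField:
    """Signed z deviation sampled on a regular xy grid over one instance."""

    x: np.ndarray  # (ny, nx) cell-center coordinates
    y: np.ndarray
    h: float  # grid step, mm
    d: np.ndarray  # z_measured - z_vihs, NaN where undefined
    area_el: np.ndarray  # ViHS area element per cell, mm^2
    in_wound: np.ndarray
    valid: np.ndarray


@dataclass
class WoundMeasurement:
    """One ViHS instance's measurements (mm / mm^2 / mm^3)."""

    perimeter: float
    area: float
    v_pos: float
    v_neg: float
    vdw: float

    def __post_init__(self) -> None:
        assert self.vdw == self.v_pos + abs(self.v_neg)


@dataclass
class AnalysisSummary:
    perimeter_mean: float
    perimeter_std: float
    area_mean: float
    area_std: float
    vdw_mean: float
    vdw_std: float


@dataclass
class AnalysisResult:
    """Per-instance measurements plus the averaged result."""

    instances: list[WoundMeasurement]
    summary: AnalysisSummary
    n_instances: int
    warnings: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def deviation_field(
    surface: OrganizedSurface,
    vihs: VihsSurface,
    edge: WoundEdge,
    h: float = 0.25,
) -> DeviationField:
    """Sample measured-minus-ViHS deviation on a step-``h`` xy grid.

    The grid covers the union of the anchor quad and the wound edge;
    ViHS z comes from Newton inversion of the spline's xy map (cells
    beyond a thin extension collar around the parameter square are
    dropped), measured z from bilinear interpolation of the organized
    grid, and the area element from the spline's slopes.
    """
    if h <= 0:
        raise ValueError("grid step must be positive")
    qx, qy = vihs.quad.vertices[:, 0], vihs.quad.vertices[:, 1]
    ex, ey = edge.xy[:, 0], edge.xy[:, 1]
    x0 = min(qx.min(), ex.min()) - h
    x1 = max(qx.max(), ex.max()) + h
    y0 = min(qy.min(), ey.min()) - h
    y1 = max(qy.max(), ey.max()) + h
    xs = np.arange(x0 + h / 2, x1, h)
    ys = np.arange(y0 + h / 2, y1, h)
    xx, yy = np.meshgrid(xs, ys)

    poly = shapely.Polygon(edge.xy)
    in_wound = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)

    u, v, ok = vihs.spline.invert_xy(xx.ravel(), yy.ravel())
    in_domain = (
        (u > -_COLLAR) & (u < 1 + _COLLAR) & (v > -_COLLAR) & (v < 1 + _COLLAR)
    )
    # divergence only counts where an inverse must exist: inside the anchor
    # quad, or wound cells that still map into the extension collar
    in_quad = shapely.contains_xy(vihs.quad.polygon(), xx.ravel(), yy.ravel())
    relevant = in_quad | (in_wound.ravel() & in_domain)
    bad = relevant & ~ok
    if bad.sum() > 0.01 * max(relevant.sum(), 1):
        raise FieldDegenerate(
            f"parameter inversion diverged at {bad.sum()} of {relevant.sum()} cells"
        )
    z_vihs, dzdx, dzdy = vihs.spline.z_and_slopes(u, v)
    z_meas = surface.interp_z(xx.ravel(), yy.ravel())
    valid = ok & in_domain & np.isfinite(z_meas) & np.isfinite(z_vihs)
    d = np.where(valid, z_meas - z_vihs, np.nan).reshape(xx.shape)
    area_el = (h * h) * np.sqrt(1.0 + dzdx**2 + dzdy**2)
    area_el = np.where(valid, area_el, np.nan).reshape(xx.shape)
    return DeviationField(
        x=xx,
        y=yy,
        h=h,
        d=d,
        area_el=area_el,
        in_wound=in_wound,
        valid=valid.reshape(xx.shape),
    )


def integrate_vdw(fld: DeviationField) -> tuple[float, float, float]:
    """(v_pos, v_neg, vdw) by prism quadrature over in-wound cells."""
    cells = fld.in_wound & fld.valid
    if not cells.any():
        raise EmptyWound("no in-wound cells in the deviation field")
    d = fld.d[cells]
    h2 = fld.h * fld.h
    v_pos = float(np.sum(np.maximum(d, 0.0)) * h2)
    v_neg = float(np.sum(np.minimum(d, 0.0)) * h2)
    return v_pos, v_neg, v_pos + abs(v_neg)


def measure_perimeter_area(
    vihs: VihsSurface, edge: WoundEdge, fld: DeviationField
) -> tuple[float, float]:
    """Perimeter of the edge lifted onto the ViHS; area of the ViHS patch
    inside the edge (sum of in-wound area elements)."""
    closed = np.vstack([edge.xy, edge.xy[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_out = max(int(np.ceil(s[-1] / fld.h)), 32)
    si = np.linspace(0.0, s[-1], n_out, endpoint=False)
    px = np.interp(si, s, closed[:, 0])
    py = np.interp(si, s, closed[:, 1])
    u, v, _ = vihs.spline.invert_xy(px, py)
    z = vihs.spline.evaluate(u, v)[:, 2]
    pts = np.stack([px, py, z], axis=-1)
    dseg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    perimeter = float(dseg.sum())

    cells = fld.in_wound & fld.valid
    area = float(np.nansum(np.where(cells, fld.area_el, 0.0)))
    return perimeter, area


@dataclass
class AnalyzeConfig:
    """End-to-end analysis parameters (defaults follow the method)."""

    n_scatter: int = 30
    half_width_mm: float = 2.5
    h_mm: float = 0.25
    master_seed: int = 0
    edge_smooth_px: float = 3.0
    fit: FitConfig = field(default_factory=FitConfig)

    def to_dict(self) -> dict:
        return asdict(self)


def analyze(
    surface: OrganizedSurface,
    wound: WoundMask | WoundEdge,
    config: AnalyzeConfig | None = None,
) -> AnalysisResult:
    """Full measurement: ViHS ensemble, per-instance metrics, averages.

    ``wound`` is either a segmentation mask (the measurement edge is then
    its smoothed sub-pixel contour) or an already-extracted edge.  With
    the default scatter settings this evaluates 31 ViHS instances; the
    reported perimeter, area and VDW are their averages.
    """
    cfg = config or AnalyzeConfig()
    if isinstance(wound, WoundMask):
        mask = wound
        edge = trace_edge_subpixel(mask, surface, smooth_px=cfg.edge_smooth_px)
    else:
        edge = wound
        mask = edge_to_mask(edge, surface.rows, surface.cols)
    instances, warnings = build_instances(
        surface,
        mask,
        edge,
        n_scatter=cfg.n_scatter,
        half_width=cfg.half_width_mm,
        seed=cfg.master_seed,
        config=cfg.fit,
    )
    measurements: list[WoundMeasurement] = []
    for k, inst in enumerate(instances):
        try:
            fld = deviation_field(surface, inst, edge, h=cfg.h_mm)
            v_pos, v_neg, vdw = integrate_vdw(fld)
            perim, area = measure_perimeter_area(inst, edge, fld)
            measurements.append(
                WoundMeasurement(
                    perimeter=perim, area=area, v_pos=v_pos, v_neg=v_neg, vdw=vdw
                )
            )
        except (EmptyWound, FieldDegenerate) as exc:
            warnings.append(f"instance {k} failed: {exc}")
    expected = cfg.n_scatter + 1
    if len(measurements) < max(expected // 2, 1):
        raise AnalysisFailed(
            f"only {len(measurements)} of {expected} ViHS instances succeeded"
        )
    arr = np.array([[m.perimeter, m.area, m.vdw] for m in measurements])
    std = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(3)
    summary = AnalysisSummary(
        perimeter_mean=float(arr[:, 0].mean()),
        perimeter_std=float(std[0]),
        area_mean=float(arr[:, 1].mean()),
        area_std=float(std[1]),
        vdw_mean=float(arr[:, 2].mean()),
        vdw_std=float(std[2]),
    )
    return AnalysisResult(
        instances=measurements,
        summary=summary,
        n_instances=len(measurements),
        warnings=warnings,
        config=cfg.to_dict(),
    )


def repeatability_stats(groups: list[list[float]]) -> dict:
    """Per-group spread plus Levene and one-way Kruskal-Wallis tests.

    Repeatability is reported as one standard deviation per group; the
    homogeneity of variance is checked with Levene's test and location
    differences with the Kruskal-Wallis test, both at the conventional
    95% confidence level.  When every value is identical across groups
    the K-W p-value is reported as 1.0 (an all-ties configuration carries
    no evidence against the null).
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise StatsInsufficient("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    stds = [float(a.std(ddof=1)) for a in arrays]
    flat = np.concatenate(arrays)
    if np.allclose(flat, flat[0]):
        levene_p = 1.0
        kw_p = 1.0
    else:
        levene_p = float(stats.levene(*arrays).pvalue)
        try:
            kw_p = float(stats.kruskal(*arrays).pvalue)
        except ValueError:  # all numbers identical within groups
            kw_p = 1.0
    return {
        "group_std": stds,
        "levene_p": levene_p,
        "kruskal_p": kw_p,
        "confidence_level": 0.95,
    }
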