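"""Wound-edge determination on the scan's 2D color image.

Three interchangeable back-ends produce a single-component wound mask:

* ``segment_ced`` — Canny edge detection on an operator-chosen color
  channel, followed by automatic/manual edge closing and interior fill;
* ``segment_growcut`` — a cellular automaton in which seeded labels
  conquer 8-neighbors according to color-similarity-weighted strength;
* ``segment_grabcut`` — iterated Gaussian-mixture color modelling with a
  min-cut labeling under hard seed constraints.

Masks convert to closed boundary polylines (Moore tracing, or a smoothed
sub-pixel contour for measurement) and back (polygon rasterization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .errors import EdgeNotClosed, EmptyInput, EmptyMask, SeedMissing
from .surface import ColorImage, OrganizedSurface

LABEL_UNKNOWN = 0
LABEL_WOUND = 1
LABEL_BACKGROUND = 2

#: clockwise Moore neighborhood starting east
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


@dataclass
class SeedLabels:
    """Per-pixel operator seed labels: 0 unknown, 1 wound, 2 background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)

    def require_both(self) -> None:
        if not (self.labels == LABEL_WOUND).any():
            raise SeedMissing("no wound seed pixels")
        if not (self.labels == LABEL_BACKGROUND).any():
            raise SeedMissing("no background seed pixels")

    @classmethod
    def read_png(cls, path: str | Path) -> "SeedLabels":
        import imageio.v3 as iio

        return cls(labels=iio.imread(Path(path)))

    def write_png(self, path: str | Path) -> None:
        import imageio.v3 as iio

        iio.imwrite(Path(path), self.labels)


@dataclass
class WoundMask:
    """Boolean wound mask; a single 4-connected foreground component."""

    mask: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class WoundEdge:
    """Closed wound-boundary polyline.

    ``vertices`` are (row, col) grid positions (float for sub-pixel
    contours); ``xy`` the matching physical coordinates in mm.  The
    polyline is implicitly closed (last vertex connects to the first).
    """

    vertices: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.vertices) < 3:
            raise EmptyMask("a closed edge needs at least three vertices")

    def __len__(self) -> int:
        return len(self.vertices)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"vertices_rc": self.vertices.tolist(), "xy_mm": self.xy.tolist()}
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "WoundEdge":
        d = json.loads(Path(path).read_text())
        return cls(vertices=np.array(d["vertices_rc"]), xy=np.array(d["xy_mm"]))


# ---------------------------------------------------------------------------
# shared helpers


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 4-connected foreground component."""
    lab, n = ndimage.label(mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if n == 0:
        return np.zeros_like(mask)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def _grid_to_xy(surface: OrganizedSurface | None, rc: np.ndarray) -> np.ndarray:
    """Physical xy for (possibly fractional) grid positions."""
    rc = np.asarray(rc, dtype=float)
    if surface is None:
        return rc[:, ::-1].copy()
    xcol, yrow = surface.axes()
    x = np.interp(rc[:, 1], np.arange(len(xcol)), xcol)
    y = np.interp(rc[:, 0], np.arange(len(yrow)), yrow)
    return np.stack([x, y], axis=-1)


def _finalize_mask(raw: np.ndarray, invalid: np.ndarray | None) -> np.ndarray:
    if invalid is not None:
        raw = raw & ~invalid
    return _largest_component(raw)


# ---------------------------------------------------------------------------
# Canny edge detector back-end


def _extract_channel(image: ColorImage, channel: str) -> np.ndarray:
    from skimage.color import rgb2gray, rgb2hsv

    px = image.pixels.astype(float) / 255.0
    if channel in ("R", "G", "B"):
        return px[..., "RGB".index(channel)]
    if channel == "gray":
        return rgb2gray(image.pixels)
    if channel in ("hue", "sat"):
        hsv = rgb2hsv(image.pixels)
        return hsv[..., 0 if channel == "hue" else 1]
    raise ValueError(f"unknown channel {channel!r}")


def canny_edges(
    image: ColorImage,
    channel: str = "R",
    t_low: float | None = None,
    t_high: float | None = None,
    sigma: float = 1.4,
) -> np.ndarray:
    """Canny edge map on one color channel (thresholds on [0, 1] gradients)."""
    from skimage.feature import canny

    chan = _extract_channel(image, channel)
    ok = ~image.invalid
    return canny(chan, sigma=sigma, low_threshold=t_low, high_threshold=t_high, mask=ok)


def _bridge_gaps(edge_map: np.ndarray, gap_max: float) -> np.ndarray:
    """Connect nearby loose endpoints of the edge map with straight segments."""
    from skimage.draw import line
    from skimage.morphology import skeletonize

    skel = skeletonize(edge_map)
    nb = ndimage.convolve(skel.astype(int), np.ones((3, 3)), mode="constant")
    endpoints = np.argwhere(skel & (nb <= 2))  # itself + at most one neighbor
    out = edge_map.copy()
    used = set()
    for i, p in enumerate(endpoints):
        if i in used:
            continue
        best, best_d = None, gap_max
        for j in range(i + 1, len(endpoints)):
            if j in used:
                continue
            d = float(np.hypot(*(endpoints[j] - p)))
            if 1.5 < d <= best_d:
                best, best_d = j, d
        if best is not None:
            q = endpoints[best]
            rr, cc = line(p[0], p[1], q[0], q[1])
            out[rr, cc] = True
            used.update((i, best))
    return out


def segment_ced(
    image: ColorImage,
    channel: str = "R",
    t_low: float | None = None,
    t_high: float | None = None,
    close_radius: int = 2,
    manual_strokes: list[np.ndarray] | None = None,
    sigma: float = 1.4,
    gap_max: float = 10.0,
) -> WoundMask:
    """Canny-based wound segmentation with automatic/manual edge closing.

    Pipeline: Canny on the chosen channel, morphological closing (disk of
    ``close_radius``), union with rasterized manual stroke polylines,
    bridging of residual endpoint gaps up to ``gap_max`` px, then border
    flood fill — the enclosed interior is the wound.  Raises
    :class:`EdgeNotClosed` when no interior exists (add strokes or raise
    ``close_radius``).
    """
    from skimage.draw import line
    from skimage.morphology import closing, dilation, disk

    if image.pixels.size == 0:
        raise EmptyInput("empty image")
    if t_low is not None and t_high is not None and t_low > t_high:
        raise ValueError("t_low must not exceed t_high")
    edges = canny_edges(image, channel, t_low, t_high, sigma)
    if close_radius > 0:
        edges = closing(edges, disk(close_radius))
    if manual_strokes:
        for poly in manual_strokes:
            poly = np.asarray(poly, dtype=int)
            for (r0, c0), (r1, c1) in zip(poly[:-1], poly[1:]):
                rr, cc = line(r0, c0, r1, c1)
                edges[rr, cc] = True
    if gap_max > 0:
        edges = _bridge_gaps(edges, gap_max)
    filled = ndimage.binary_fill_holes(edges)
    interior = filled & ~edges
    if not interior.any():
        raise EdgeNotClosed("Canny contour does not enclose a region")
    interior = _largest_component(interior)
    # the Canny ridge straddles the true boundary: include its inner half
    mask = interior | (edges & dilation(interior))
    return WoundMask(mask=_finalize_mask(mask, image.invalid))


# ---------------------------------------------------------------------------
# GrowCut back-end

_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def segment_growcut(
    image: ColorImage, seeds: SeedLabels, max_iter: int = 2000
) -> WoundMask:
    """Cellular-automaton segmentation seeded with wound/background labels.

    Neighbor q conquers p iff ``g(||C_p - C_q||) * theta_q > theta_p`` with
    ``g(d) = 1 - d / d_max`` (d_max the maximal attainable RGB distance);
    on conquest p takes q's label and attack strength.  Runs to a fixed
    point (no relabel) or ``max_iter`` sweeps; seeds (strength 1) can
    never be conquered.
    """
    seeds.require_both()
    rows, cols = image.rows, image.cols
    if seeds.labels.shape != (rows, cols):
        raise SeedMissing("seed image does not match the color image")
    d_max = float(np.sqrt(3.0) * 255.0)

    C = np.full((rows + 2, cols + 2, 3), 1e6)
    C[1:-1, 1:-1] = image.pixels.astype(float)
    theta = np.full((rows + 2, cols + 2), -1.0)
    labels = np.zeros((rows + 2, cols + 2), dtype=np.uint8)
    lab0 = seeds.labels.copy()
    lab0[image.invalid] = LABEL_BACKGROUND  # invalid cells anchor the background
    theta[1:-1, 1:-1] = np.where(lab0 != LABEL_UNKNOWN, 1.0, 0.0)
    labels[1:-1, 1:-1] = lab0

    warnings: list[str] = []
    converged = False
    core = (slice(1, -1), slice(1, -1))
    for _ in range(max_iter):
        best = theta[core].copy()
        new_lab = labels[core].copy()
        changed = np.zeros((rows, cols), dtype=bool)
        for dr, dc in _SHIFTS:
            sl = (slice(1 + dr, rows + 1 + dr), slice(1 + dc, cols + 1 + dc))
            dist = np.linalg.norm(C[core] - C[sl], axis=-1)
            att = (1.0 - np.minimum(dist / d_max, 1.0)) * theta[sl]
            take = att > best
            if take.any():
                best[take] = att[take]
                new_lab[take] = labels[sl][take]
                changed |= take
        if not changed.any():
            converged = True
            break
        theta[core] = best
        labels[core] = new_lab
    if not converged:
        warnings.append(f"growcut did not converge within {max_iter} iterations")
    mask = labels[core] == LABEL_WOUND
    return WoundMask(mask=_finalize_mask(mask, image.invalid), warnings=warnings)


# ---------------------------------------------------------------------------
# GrabCut-style back-end


def _fit_gmm(colors: np.ndarray, seed: int):
    from sklearn.mixture import GaussianMixture

    n = min(5, len(np.unique(colors, axis=0)))
    gmm = GaussianMixture(
        n_components=max(n, 1),
        covariance_type="full",
        reg_covar=1e-2,
        random_state=seed,
        max_iter=50,
    )
    gmm.fit(colors)
    return gmm


def segment_grabcut(
    image: ColorImage, seeds: SeedLabels, n_iter: int = 5, seed: int = 0
) -> WoundMask:
    """Iterative foreground extraction under hard seed constraints.

    Alternates 5-component Gaussian-mixture color models for wound and
    background with a min-cut labeling (8-neighborhood contrast-weighted
    smoothness, Boykov–Jolly graph construction).  WOUND/BACKGROUND seeds
    are hard constraints; unknown pixels start as foreground.
    """
    seeds.require_both()
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rows, cols = image.rows, image.cols
    if seeds.labels.shape != (rows, cols):
        raise SeedMissing("seed image does not match the color image")
    n_px = rows * cols
    colors = image.pixels.reshape(-1, 3).astype(float)
    hard_fg = (seeds.labels == LABEL_WOUND).ravel()
    hard_bg = ((seeds.labels == LABEL_BACKGROUND) | image.invalid).ravel()

    # contrast-adaptive smoothness weights over the 8-neighborhood
    gamma = 50.0
    idx = np.arange(n_px).reshape(rows, cols)
    pairs_p, pairs_q, pairs_w2, pairs_len = [], [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0 = slice(0, rows - dr)
        c0 = slice(max(0, -dc), cols - max(0, dc))
        r1 = slice(dr, rows)
        c1 = slice(max(0, dc), cols - max(0, -dc))
        p = idx[r0, c0].ravel()
        q = idx[r1, c1].ravel()
        d2 = np.sum((colors[p] - colors[q]) ** 2, axis=1)
        pairs_p.append(p)
        pairs_q.append(q)
        pairs_w2.append(d2)
        pairs_len.append(np.hypot(dr, dc))
    all_d2 = np.concatenate(pairs_w2)
    beta = 1.0 / (2.0 * max(all_d2.mean(), 1e-12))
    n_p = np.concatenate(pairs_p)
    n_q = np.concatenate(pairs_q)
    n_w = np.concatenate(
        [
            gamma / ln * np.exp(-beta * d2)
            for d2, ln in zip(pairs_w2, pairs_len)
        ]
    )

    SCALE = 1000.0
    INF = np.int64(1) << 40
    src, sink = n_px, n_px + 1
    fg = ~hard_bg  # initial labeling: unknown counts as foreground
    rng = np.random.default_rng(seed)
    for _ in range(n_iter):
        s_fg = int(rng.integers(1 << 31))
        s_bg = int(rng.integers(1 << 31))
        if not fg.any() or fg.all():
            break
        gmm_fg = _fit_gmm(colors[fg], s_fg)
        gmm_bg = _fit_gmm(colors[~fg], s_bg)
        d_fg = -gmm_fg.score_samples(colors)  # cost of labeling foreground
        d_bg = -gmm_bg.score_samples(colors)
        d_fg = np.clip(d_fg, 0.0, 1e5)
        d_bg = np.clip(d_bg, 0.0, 1e5)
        cap_src = np.rint(d_bg * SCALE).astype(np.int64)  # cut when p is background
        cap_sink = np.rint(d_fg * SCALE).astype(np.int64)
        cap_src[hard_fg] = INF
        cap_sink[hard_fg] = 0
        cap_sink[hard_bg] = INF
        cap_src[hard_bg] = 0
        wn = np.rint(n_w * SCALE).astype(np.int64)
        rows_i = np.concatenate([np.full(n_px, src), np.arange(n_px), n_p, n_q])
        cols_i = np.concatenate([np.arange(n_px), np.full(n_px, sink), n_q, n_p])
        data = np.concatenate([cap_src, cap_sink, wn, wn])
        graph = csr_matrix(
            (data, (rows_i, cols_i)), shape=(n_px + 2, n_px + 2), dtype=np.int64
        )
        graph32 = graph.astype(np.int32) if data.max() < (1 << 31) else None
        if graph32 is None:
            # clip t-link infinities into int32 range; n-links are small
            graph = graph.copy()
            graph.data = np.minimum(graph.data, (1 << 30)).astype(np.int64)
            graph32 = graph.astype(np.int32)
        res = maximum_flow(graph32, src, sink)
        residual = graph32 - res.flow
        residual.data = np.maximum(residual.data, 0)
        residual.eliminate_zeros()
        order = breadth_first_order(residual, src, directed=True, return_predecessors=False)
        reach = np.zeros(n_px + 2, dtype=bool)
        reach[order] = True
        new_fg = reach[:n_px]
        new_fg[hard_fg] = True
        new_fg[hard_bg] = False
        if (new_fg == fg).all():
            fg = new_fg
            break
        fg = new_fg
    mask = fg.reshape(rows, cols)
    return WoundMask(mask=_finalize_mask(mask, image.invalid))


# ---------------------------------------------------------------------------
# mask <-> edge


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Clockwise Moore-neighbor boundary trace of the foreground."""
    rr, cc = np.nonzero(mask)
    start = (int(rr[0]), int(cc[0]))  # topmost, then leftmost
    first = np.lexsort((cc, rr))[0]
    start = (int(rr[first]), int(cc[first]))

    def is_fg(p):
        r, c = p
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]

    contour = [start]
    backtrack = (start[0], start[1] - 1)
    p = start
    state0 = None
    for _ in range(4 * mask.size):
        d0 = _MOORE.index((backtrack[0] - p[0], backtrack[1] - p[1]))
        nxt = None
        for k in range(1, 9):
            cand = _MOORE[(d0 + k) % 8]
            q = (p[0] + cand[0], p[1] + cand[1])
            if is_fg(q):
                nxt = q
                prev = _MOORE[(d0 + k - 1) % 8]
                backtrack = (p[0] + prev[0], p[1] + prev[1])
                break
        if nxt is None:  # isolated pixel
            break
        state = (nxt, backtrack)
        if state0 is None:
            state0 = state
        elif state == state0:
            break
        p = nxt
        contour.append(p)
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return np.array(contour)


def mask_to_edge(mask: WoundMask, surface: OrganizedSurface | None = None) -> WoundEdge:
    """Trace the outer boundary of the largest component (holes filled)."""
    m = ndimage.binary_fill_holes(_largest_component(mask.mask))
    if not m.any():
        raise EmptyMask("mask has no foreground")
    contour = _moore_trace(m)
    if len(contour) < 3:
        raise EmptyMask("degenerate contour (fewer than three boundary pixels)")
    return WoundEdge(vertices=contour, xy=_grid_to_xy(surface, contour))


def trace_edge_subpixel(
    mask: WoundMask,
    surface: OrganizedSurface | None = None,
    smooth_px: float = 3.0,
) -> WoundEdge:
    """Sub-pixel wound contour for measurement.

    Marching-squares contour at level 0.5 (the mid-crack boundary, which
    is unbiased for digitized smooth shapes), resampled to uniform arc
    length and smoothed with a periodic moving average of ``smooth_px``
    pixels to remove rasterization jaggedness.
    """
    from skimage.measure import find_contours

    m = ndimage.binary_fill_holes(_largest_component(mask.mask))
    if not m.any():
        raise EmptyMask("mask has no foreground")
    contours = find_contours(m.astype(float), 0.5)
    if not contours:
        raise EmptyMask("no contour found")
    contour = max(contours, key=len)[:-1]  # drop duplicated closing vertex
    if len(contour) < 8:
        raise EmptyMask("degenerate contour")
    # resample to uniform spacing along the closed polyline
    step = 0.25
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n_out = max(int(np.ceil(total / step)), 16)
    si = np.linspace(0.0, total, n_out, endpoint=False)
    res = np.stack(
        [np.interp(si, s, closed[:, 0]), np.interp(si, s, closed[:, 1])], axis=-1
    )
    w = max(int(round(smooth_px / step)) | 1, 1)
    if w > 1:
        res = np.stack(
            [ndimage.uniform_filter1d(res[:, k], size=w, mode="wrap") for k in (0, 1)],
            axis=-1,
        )
    res = res[:: max(n_out // max(int(total / 0.5), 16), 1)]
    return WoundEdge(vertices=res, xy=_grid_to_xy(surface, res))


def edge_to_mask(edge: WoundEdge, rows: int, cols: int) -> WoundMask:
    """Rasterize a closed edge polyline to a boundary-inclusive mask."""
    import shapely
    from skimage.draw import polygon, polygon_perimeter

    warnings = []
    ring = shapely.LinearRing(edge.vertices) if len(edge) >= 3 else None
    if ring is not None and not ring.is_simple:
        warnings.append("self-intersecting edge; even-odd fill applied")
    r, c = edge.vertices[:, 0], edge.vertices[:, 1]
    mask = np.zeros((rows, cols), dtype=bool)
    rr, cc = polygon(r, c, shape=(rows, cols))
    mask[rr, cc] = True
    rr, cc = polygon_perimeter(
        np.rint(r).astype(int), np.rint(c).astype(int), shape=(rows, cols)
    )
    mask[rr, cc] = True
    return WoundMask(mask=mask, warnings=warnings)


_BACKENDS = {
    "ced": segment_ced,
    "growcut": segment_growcut,
    "grabcut": segment_grabcut,
}


def segment(image: ColorImage, backend: str, **kwargs) -> WoundMask:
    """Dispatch to a segmentation back-end by name."""
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown backend {backend!r}") from None
    return fn(image, **kwargs)
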