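"""Virtual healthy skin (ViHS) approximation.

The ViHS is the surface intact skin would form across the wound: the
reference against which wound depth and volume are measured.  It is
anchored to the wound edge by circumscribing the minimal-area rectangle
around the edge's xy footprint, then fit as a tensor-product cubic
B-spline: the four rectangle edges are sampled from the measured surface
(healthy cells only), the interior is initialized as the Coons patch of
those boundary curves, and interior control points are refined by
penalized least squares against healthy cells inside the rectangle.

Robustness to the anchoring comes from an ensemble: each rectangle
vertex is scattered uniformly inside a 5 x 5 mm square (in the
rectangle's own axes), one ViHS per scattered quad, 31 instances in
total by default, whose measurements are averaged downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import BSpline
from scipy.spatial import QhullError, ConvexHull, cKDTree

from .errors import DegenerateGeometry, ScatterFailed, VihsUnderconstrained
from .segmentation import WoundEdge, WoundMask
from .surface import OrganizedSurface


@dataclass
class VihsQuad:
    """Four anchor vertices in physical xy (mm), counterclockwise."""

    vertices: np.ndarray
    provenance: str = "initial"  # or "scattered"
    scatter_seed: int | None = None
    axes: np.ndarray | None = None  # unit long/short axis of the parent rectangle
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.shape != (4, 2):
            raise DegenerateGeometry("quad needs exactly four xy vertices")

    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    @property
    def is_simple(self) -> bool:
        return shapely.LinearRing(self.vertices).is_simple


def min_area_rect(edge: WoundEdge) -> VihsQuad:
    """Minimal-area enclosing rectangle of the edge's xy vertices.

    Enumerates convex-hull edge orientations (one side of the optimal
    rectangle is collinear with a hull edge).  Vertices are returned
    counterclockwise starting from the corner that is extreme along
    minus-long-axis then minus-short-axis; the long-axis angle is
    reported in [0, 180) degrees.
    """
    pts = np.asarray(edge.xy, dtype=float)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometry("edge points are collinear") from exc
    hp = pts[hull.vertices]
    dirs = np.diff(np.vstack([hp, hp[:1]]), axis=0)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    best = None
    for ux, uy in dirs:
        u = np.array([ux, uy])
        v = np.array([-uy, ux])
        pu = hp @ u
        pv = hp @ v
        w, hgt = pu.max() - pu.min(), pv.max() - pv.min()
        area = w * hgt
        if best is None or area < best[0] - 1e-12:
            best = (area, u, v, pu.min(), pu.max(), pv.min(), pv.max())
    area, u, v, u0, u1, v0, v1 = best
    if area <= 0:
        raise DegenerateGeometry("degenerate enclosing rectangle")
    # orient: long axis first, pointing into [0, 180) degrees
    if (u1 - u0) < (v1 - v0):
        u, v, (u0, u1), (v0, v1) = v, u, (v0, v1), (u0, u1)
    if u[1] < 0 or (u[1] == 0 and u[0] < 0):
        u, v = -u, -v
        u0, u1 = -u1, -u0
        v0, v1 = -v1, -v0
    if u[0] * v[1] - u[1] * v[0] < 0:  # enforce CCW corner order
        v = -v
        v0, v1 = -v1, -v0
    corners = np.array(
        [
            u0 * u + v0 * v,
            u1 * u + v0 * v,
            u1 * u + v1 * v,
            u0 * u + v1 * v,
        ]
    )
    angle = float(np.degrees(np.arctan2(u[1], u[0])) % 180.0)
    return VihsQuad(
        vertices=corners,
        provenance="initial",
        axes=np.stack([u, v]),
        angle_deg=angle,
    )


def scatter_quads(
    rect: VihsQuad,
    n: int = 30,
    half_width: float = 2.5,
    seed: int | np.random.SeedSequence = 0,
    max_retries: int = 100,
) -> list[VihsQuad]:
    """Perturb each rectangle vertex uniformly in a square of side
    ``2 * half_width`` aligned with the rectangle's own axes.

    Self-intersecting draws are redrawn; after ``max_retries`` failures
    :class:`ScatterFailed` is raised (only plausible for tiny rectangles).
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    rng = np.random.default_rng(seed)
    axes = rect.axes
    if axes is None:
        e0 = rect.vertices[1] - rect.vertices[0]
        e0 = e0 / np.linalg.norm(e0)
        axes = np.stack([e0, np.array([-e0[1], e0[0]])])
    out: list[VihsQuad] = []
    for k in range(n):
        for _ in range(max_retries):
            offsets = rng.uniform(-half_width, half_width, size=(4, 2))
            verts = rect.vertices + offsets @ axes
            quad = VihsQuad(
                vertices=verts,
                provenance="scattered",
                scatter_seed=k,
                axes=axes,
                angle_deg=rect.angle_deg,
            )
            if half_width == 0 or quad.is_simple:
                out.append(quad)
                break
        else:
            raise ScatterFailed(f"no simple quad after {max_retries} draws")
    return out


# ---------------------------------------------------------------------------
# tensor-product B-spline surface


def _open_uniform_knots(n_ctrl: int, degree: int = 3) -> np.ndarray:
    if n_ctrl <= degree:
        raise ValueError("need more control points than the degree")
    interior = np.linspace(0.0, 1.0, n_ctrl - degree + 1)[1:-1]
    return np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])


def _basis(t: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return BSpline.design_matrix(t.ravel(), knots, degree, extrapolate=True).toarray()


def _greville(knots: np.ndarray, degree: int = 3) -> np.ndarray:
    n = len(knots) - degree - 1
    return np.array([knots[i + 1 : i + degree + 1].mean() for i in range(n)])


def _deriv_ctrl(ctrl: np.ndarray, knots: np.ndarray, degree: int = 3):
    """Control points and knots of the derivative spline along axis 0."""
    denom = knots[degree + 1 : -1] - knots[1 : -degree - 1]
    q = degree * (ctrl[1:] - ctrl[:-1]) / denom.reshape(-1, *([1] * (ctrl.ndim - 1)))
    return q, knots[1:-1]


@dataclass
class BSplineSurface:
    """Non-rational tensor-product cubic B-spline surface in 3D.

    All NURBS weights are 1: unit weights keep the least-squares fit
    linear and suffice for free-form skin.  The surface extends as a
    polynomial beyond the [0, 1]^2 parameter square, which lets slightly
    clipped anchor quads still cover the whole wound.
    """

    ctrl: np.ndarray  # (n, m, 3)
    knots_u: np.ndarray
    knots_v: np.ndarray
    degree: int = 3

    def evaluate(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        Bu = _basis(u, self.knots_u, self.degree)
        Bv = _basis(v, self.knots_v, self.degree)
        return np.einsum("ni,nj,ijk->nk", Bu, Bv, self.ctrl)

    def derivatives(self, u: np.ndarray, v: np.ndarray):
        """First partials S_u and S_v at paired parameter values."""
        qu, tu = _deriv_ctrl(self.ctrl, self.knots_u, self.degree)
        qv, tv = _deriv_ctrl(
            np.swapaxes(self.ctrl, 0, 1), self.knots_v, self.degree
        )
        Bu = _basis(u, self.knots_u, self.degree)
        Bv = _basis(v, self.knots_v, self.degree)
        Bu1 = _basis(u, tu, self.degree - 1)
        Bv1 = _basis(v, tv, self.degree - 1)
        su = np.einsum("ni,nj,ijk->nk", Bu1, Bv, qu)
        sv = np.einsum("ni,nj,ijk->nk", Bv1, Bu, qv)
        return su, sv

    def corners_xy(self) -> np.ndarray:
        uv = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        return self.evaluate(uv[:, 0], uv[:, 1])[:, :2]

    def invert_xy(
        self,
        x: np.ndarray,
        y: np.ndarray,
        tol: float = 1e-6,
        max_iter: int = 40,
    ):
        """Newton inversion of the (u, v) -> (x, y) map, vectorized.

        Returns (u, v, converged).  The initial guess is the affine map
        fitted to the four parameter-square corners.
        """
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        corners = self.corners_xy()
        # affine initial guess: [x, y] ~ M @ [u, v] + c fitted to the corners
        U = np.array([[0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)
        coef, *_ = np.linalg.lstsq(U, corners, rcond=None)
        M, c = coef[:2].T, coef[2]
        uv = (np.stack([x, y], axis=-1) - c) @ np.linalg.inv(M).T
        u, v = uv[:, 0].copy(), uv[:, 1].copy()
        target = np.stack([x, y], axis=-1)
        for _ in range(max_iter):
            res = target - self.evaluate(u, v)[:, :2]
            if np.nanmax(np.linalg.norm(res, axis=1), initial=0.0) < tol:
                break
            su, sv = self.derivatives(u, v)
            det = su[:, 0] * sv[:, 1] - sv[:, 0] * su[:, 1]
            det = np.where(np.abs(det) < 1e-12, np.nan, det)
            du = (sv[:, 1] * res[:, 0] - sv[:, 0] * res[:, 1]) / det
            dv = (-su[:, 1] * res[:, 0] + su[:, 0] * res[:, 1]) / det
            u += np.clip(np.nan_to_num(du), -0.5, 0.5)
            v += np.clip(np.nan_to_num(dv), -0.5, 0.5)
            u = np.clip(u, -1.0, 2.0)
            v = np.clip(v, -1.0, 2.0)
        res = target - self.evaluate(u, v)[:, :2]
        err = np.linalg.norm(res, axis=1)
        return u, v, err < 10 * tol

    def z_and_slopes(self, u: np.ndarray, v: np.ndarray):
        """z, dz/dx, dz/dy at paired parameters (chain rule through the
        inverse of the parametric xy Jacobian)."""
        pts = self.evaluate(u, v)
        su, sv = self.derivatives(u, v)
        det = su[:, 0] * sv[:, 1] - sv[:, 0] * su[:, 1]
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        # [dz/dx, dz/dy] = [z_u, z_v] @ inv([[x_u, x_v], [y_u, y_v]])
        dzdx = (su[:, 2] * sv[:, 1] - sv[:, 2] * su[:, 1]) / det
        dzdy = (-su[:, 2] * sv[:, 0] + sv[:, 2] * su[:, 0]) / det
        return pts[:, 2], dzdx, dzdy


@dataclass
class VihsSurface:
    """A fitted virtual-healthy-skin instance."""

    spline: BSplineSurface
    quad: VihsQuad
    fit_rms: float = float("nan")
    n_samples: int = 0
    refined: bool = True


@dataclass
class FitConfig:
    """ViHS fit parameters (units mm unless stated)."""

    n_ctrl: int = 8
    lambda_smooth: float = 0.02
    margin_mm: float = 5.0
    min_samples: int = 50
    boundary_step_mm: float = 0.5
    sample_radius_factor: float = 3.0  # healthy lookup radius, in grid pitches
    max_fit_samples: int = 4000


class _HealthyLookup:
    """IDW z lookup restricted to valid, non-wound surface cells."""

    def __init__(self, surface: OrganizedSurface, wound_mask: WoundMask | None):
        ok = surface.valid.copy()
        if wound_mask is not None:
            ok &= ~wound_mask.mask
        self.xy = np.stack([surface.x[ok], surface.y[ok]], axis=-1)
        self.z = surface.z[ok]
        if len(self.z) == 0:
            raise VihsUnderconstrained("no healthy cells on the surface")
        self.tree = cKDTree(self.xy)
        self.radius = max(surface.pitch_x, surface.pitch_y)

    def query(self, pts: np.ndarray, radius: float) -> np.ndarray:
        """IDW z at each point; NaN where no healthy neighbor in radius."""
        out = np.full(len(pts), np.nan)
        groups = self.tree.query_ball_point(pts, r=radius)
        for i, idx in enumerate(groups):
            if not idx:
                continue
            idx = np.asarray(idx)
            d = np.linalg.norm(self.xy[idx] - pts[i], axis=1)
            w = 1.0 / (d * d + 1e-12)
            out[i] = float((w @ self.z[idx]) / w.sum())
        return out


def _fill_line_gaps(t: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN samples along a boundary curve."""
    bad = np.isnan(z)
    if bad.all():
        raise VihsUnderconstrained("an entire quad edge lies over the wound")
    if bad.any():
        z = z.copy()
        z[bad] = np.interp(t[bad], t[~bad], z[~bad])
    return z


def _fit_boundary_curve(
    t: np.ndarray, data: np.ndarray, knots: np.ndarray, degree: int = 3
) -> np.ndarray:
    """LS cubic B-spline through boundary samples with clamped endpoints."""
    B = _basis(t, knots, degree)
    n = B.shape[1]
    ctrl = np.zeros((n, data.shape[1]))
    ctrl[0] = data[0]
    ctrl[-1] = data[-1]
    A = B[:, 1:-1]
    rhs = data - np.outer(B[:, 0], ctrl[0]) - np.outer(B[:, -1], ctrl[-1])
    AtA = A.T @ A + 1e-9 * np.eye(n - 2)
    ctrl[1:-1] = np.linalg.solve(AtA, A.T @ rhs)
    return ctrl


def _second_diff_matrix(n: int, m: int) -> np.ndarray:
    """Thin-plate style penalty rows on an n x m control grid (flattened)."""
    rows = []
    idx = np.arange(n * m).reshape(n, m)
    for i in range(1, n - 1):
        for j in range(m):
            r = np.zeros(n * m)
            r[idx[i - 1, j]], r[idx[i, j]], r[idx[i + 1, j]] = 1, -2, 1
            rows.append(r)
    for i in range(n):
        for j in range(1, m - 1):
            r = np.zeros(n * m)
            r[idx[i, j - 1]], r[idx[i, j]], r[idx[i, j + 1]] = 1, -2, 1
            rows.append(r)
    for i in range(n - 1):
        for j in range(m - 1):
            r = np.zeros(n * m)
            r[idx[i, j]], r[idx[i + 1, j]] = 1, -1
            r[idx[i, j + 1]], r[idx[i + 1, j + 1]] = -1, 1
            rows.append(np.sqrt(2.0) * r)
    return np.array(rows)


def fit_vihs(
    surface: OrganizedSurface,
    wound_mask: WoundMask | None,
    quad: VihsQuad,
    config: FitConfig | None = None,
) -> VihsSurface:
    """Fit one ViHS instance over an anchor quad.

    Boundary curves are least-squares cubic B-splines through measured
    healthy z along each quad edge (wound-covered spans interpolated in
    arc length from flanking healthy samples); the interior starts as the
    Coons patch of those curves and interior control z is then refined by
    penalized least squares against healthy cells inside the quad.  The
    smoothness penalty acts on the *correction* to the Coons patch, so a
    zero correction is penalty-free and data-free regions stay on the
    Coons surface.
    """
    cfg = config or FitConfig()
    lookup = _HealthyLookup(surface, wound_mask)
    radius = cfg.sample_radius_factor * max(surface.pitch_x, surface.pitch_y)

    corners = quad.vertices
    corner_z = lookup.query(corners, radius)
    for k in range(4):
        r = radius
        while np.isnan(corner_z[k]) and r < 16 * radius:
            r *= 2.0
            corner_z[k] = lookup.query(corners[k : k + 1], r)[0]
    if np.isnan(corner_z).all():
        raise VihsUnderconstrained("no healthy samples near any quad corner")

    knots = _open_uniform_knots(cfg.n_ctrl)
    edge_curves = []
    # edges in parameter order: u at v=0, v at u=1, u at v=1, v at u=0
    edge_pairs = [(0, 1), (1, 2), (3, 2), (0, 3)]
    for a, b in edge_pairs:
        p0, p1 = corners[a], corners[b]
        length = np.linalg.norm(p1 - p0)
        m = max(int(np.ceil(length / cfg.boundary_step_mm)) + 1, 8)
        t = np.linspace(0.0, 1.0, m)
        pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        z = lookup.query(pts, radius)
        z[0] = corner_z[a] if np.isfinite(corner_z[a]) else z[0]
        z[-1] = corner_z[b] if np.isfinite(corner_z[b]) else z[-1]
        z = _fill_line_gaps(t, z)
        data = np.column_stack([pts, z])
        edge_curves.append(_fit_boundary_curve(t, data, knots))
    bottom, right, top, left = edge_curves

    # discrete Coons patch of the four boundary control polygons
    g = _greville(knots)
    n = cfg.n_ctrl
    P = np.zeros((n, n, 3))
    c00, c10, c11, c01 = bottom[0], bottom[-1], top[-1], top[0]
    for i in range(n):
        for j in range(n):
            gu, gv = g[i], g[j]
            P[i, j] = (
                (1 - gv) * bottom[i]
                + gv * top[i]
                + (1 - gu) * left[j]
                + gu * right[j]
                - (
                    (1 - gu) * (1 - gv) * c00
                    + gu * (1 - gv) * c10
                    + gu * gv * c11
                    + (1 - gu) * gv * c01
                )
            )
    spline = BSplineSurface(ctrl=P, knots_u=knots, knots_v=knots)

    # interior refinement against healthy cells inside the quad
    poly = quad.polygon()
    inside = shapely.contains_xy(poly, lookup.xy[:, 0], lookup.xy[:, 1])
    samples_xy = lookup.xy[inside]
    samples_z = lookup.z[inside]
    if len(samples_z) > cfg.max_fit_samples:
        stride = int(np.ceil(len(samples_z) / cfg.max_fit_samples))
        samples_xy = samples_xy[::stride]
        samples_z = samples_z[::stride]
    refined = False
    rms = float("nan")
    if len(samples_z) >= cfg.min_samples:
        u, v, ok = spline.invert_xy(samples_xy[:, 0], samples_xy[:, 1])
        keep = ok & (u > 0) & (u < 1) & (v > 0) & (v < 1)
        if keep.sum() >= cfg.min_samples:
            u, v, zd = u[keep], v[keep], samples_z[keep]
            Bu = _basis(u, knots)
            Bv = _basis(v, knots)
            full = Bu[:, :, None] * Bv[:, None, :]
            D = full.reshape(len(u), n * n)
            adjustable = np.ones((n, n), dtype=bool)
            for ci, cj in ((0, 0), (0, -1), (-1, 0), (-1, -1)):
                adjustable[ci, cj] = False  # corners stay on the measured surface
            ivar = adjustable.ravel()
            z0 = P[:, :, 2].ravel()
            r0 = zd - D @ z0  # residual against the Coons patch
            A = D[:, ivar]
            L = _second_diff_matrix(n, n)
            Li = L[:, ivar]
            nvar = ivar.sum()
            lam = cfg.lambda_smooth * len(u) / max(len(L), 1)
            AtA = A.T @ A + lam * (Li.T @ Li) + 1e-9 * np.eye(nvar)
            rhs = A.T @ r0
            dz = np.linalg.solve(AtA, rhs)
            znew = z0.copy()
            znew[ivar] += dz
            P = P.copy()
            P[:, :, 2] = znew.reshape(n, n)
            spline = BSplineSurface(ctrl=P, knots_u=knots, knots_v=knots)
            rms = float(np.sqrt(np.mean((D @ znew - zd) ** 2)))
            refined = True
    return VihsSurface(
        spline=spline,
        quad=quad,
        fit_rms=rms,
        n_samples=int(len(samples_z)),
        refined=refined,
    )


def build_instances(
    surface: OrganizedSurface,
    wound_mask: WoundMask | None,
    edge: WoundEdge,
    n_scatter: int = 30,
    half_width: float = 2.5,
    seed: int = 0,
    config: FitConfig | None = None,
) -> tuple[list[VihsSurface], list[str]]:
    """The 1 + n ViHS ensemble: initial min-area rectangle plus scattered quads.

    Failed fits are dropped with a warning; the caller sees the surviving
    count.  Order is deterministic: the initial instance first, then the
    scattered quads in draw order.
    """
    rect = min_area_rect(edge)
    quads = [rect] + scatter_quads(rect, n=n_scatter, half_width=half_width, seed=seed)
    instances: list[VihsSurface] = []
    warnings: list[str] = []
    for k, quad in enumerate(quads):
        try:
            instances.append(fit_vihs(surface, wound_mask, quad, config))
        except VihsUnderconstrained as exc:
            warnings.append(f"instance {k} dropped: {exc}")
    return instances, warnings
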