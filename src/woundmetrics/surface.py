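"""Colored organized 3D surfaces: the canonical input of the pipeline.

A laser-triangulation scan yields a 2.5D range image: a regular grid of
3D points (mm) with one RGB color per point, some cells invalid (no laser
return).  :class:`OrganizedSurface` models that grid; helpers read/write
PLY point clouds and depth/color image pairs and resample unorganized
point clouds onto a grid.

Conventions: row 0 is the top of the image, column 0 the left; physical x
grows with the column index and y with the row index; z points toward the
scanner, so healthy skin is the high-z reference and the wound cavity lies
at lower z.  Invalid cells carry NaN coordinates internally and a zero
sentinel in 16-bit depth files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ColorMissing, DegenerateGeometry, EmptyInput, FormatError

_GRID_MAGIC = "woundmetrics-grid"


@dataclass
class OrganizedSurface:
    """Regular grid of colored 3D points in millimetres.

    Attributes
    ----------
    xyz : (rows, cols, 3) float array
        Point coordinates in mm; NaN at invalid cells.
    valid : (rows, cols) bool array
        True where the cell holds a measured point.
    rgb : (rows, cols, 3) uint8 array
        Per-cell color; undefined content at invalid cells.
    pitch_x, pitch_y : float
        Nominal grid spacing in mm along columns / rows.
    """

    xyz: np.ndarray
    valid: np.ndarray
    rgb: np.ndarray
    pitch_x: float
    pitch_y: float

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.rgb = np.asarray(self.rgb, dtype=np.uint8)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise FormatError("xyz must have shape (rows, cols, 3)")
        if self.valid.shape != self.xyz.shape[:2] or self.rgb.shape != self.xyz.shape:
            raise FormatError("valid/rgb shapes do not match xyz grid")
        if not (self.pitch_x > 0 and self.pitch_y > 0):
            raise FormatError("grid pitch must be positive")
        if not np.isfinite(self.xyz[self.valid]).all():
            raise FormatError("non-finite coordinates at valid cells")

    @property
    def rows(self) -> int:
        return self.xyz.shape[0]

    @property
    def cols(self) -> int:
        return self.xyz.shape[1]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[..., 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[..., 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[..., 2]

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-column x and per-row y coordinates for separable grids.

        Raises ``FormatError`` when x varies along rows or y along columns
        by more than 1e-6 mm (i.e. the grid is not axis-separable).
        """
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            xcol = np.nanmean(np.where(self.valid, self.x, np.nan), axis=0)
            yrow = np.nanmean(np.where(self.valid, self.y, np.nan), axis=1)
        dev_x = np.nanmax(np.abs(self.x - xcol[None, :])) if self.valid.any() else 0.0
        dev_y = np.nanmax(np.abs(self.y - yrow[:, None])) if self.valid.any() else 0.0
        if dev_x > 1e-6 or dev_y > 1e-6:
            raise FormatError("grid is not axis-separable")
        # fill gaps in the axes from the nominal pitch
        c = np.arange(self.cols)
        r = np.arange(self.rows)
        if np.isnan(xcol).any():
            ok = ~np.isnan(xcol)
            xcol = np.interp(c, c[ok], xcol[ok])
        if np.isnan(yrow).any():
            ok = ~np.isnan(yrow)
            yrow = np.interp(r, r[ok], yrow[ok])
        return xcol, yrow

    def interp_z(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear z at physical (x, y); NaN outside or near invalid cells."""
        from scipy.interpolate import RegularGridInterpolator

        xcol, yrow = self.axes()
        zgrid = np.where(self.valid, self.z, np.nan)
        itp = RegularGridInterpolator(
            (yrow, xcol), zgrid, bounds_error=False, fill_value=np.nan
        )
        pts = np.stack([np.asarray(y, float).ravel(), np.asarray(x, float).ravel()], axis=-1)
        return itp(pts).reshape(np.shape(x))

    def check_pitch(self) -> None:
        """Verify the declared pitch against the median adjacent-cell spacing."""
        # columns step along x (coordinate 0), rows along y (coordinate 1)
        for axis, coord, pitch in ((1, 0, self.pitch_x), (0, 1, self.pitch_y)):
            d = np.diff(self.xyz[..., coord], axis=axis)
            pair_ok = self.valid & np.roll(self.valid, -1, axis=axis)
            pair_ok = np.delete(pair_ok, -1, axis=axis)
            if pair_ok.sum() == 0:
                continue
            med = float(np.median(np.abs(d[pair_ok])))
            if not (0.75 * pitch <= med <= 1.25 * pitch):
                raise FormatError(
                    f"median spacing {med:.4g} mm disagrees with pitch {pitch:.4g} mm"
                )


@dataclass
class ColorImage:
    """2D color image aligned with an :class:`OrganizedSurface` grid.

    Pixel (r, c) carries the color of surface cell (r, c); cells that are
    invalid on the surface are black and flagged in ``invalid``.
    """

    pixels: np.ndarray
    invalid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.invalid is None:
            self.invalid = np.zeros(self.pixels.shape[:2], dtype=bool)
        self.invalid = np.asarray(self.invalid, dtype=bool)

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


def extract_color_image(surface: OrganizedSurface) -> ColorImage:
    """Flatten the surface colors into the 2D image used for segmentation."""
    pixels = surface.rgb.copy()
    pixels[~surface.valid] = 0
    return ColorImage(pixels=pixels, invalid=~surface.valid)


# ---------------------------------------------------------------------------
# PLY


def write_surface(surface: OrganizedSurface, path: str | Path) -> None:
    """Write an axis-separable organized surface as ASCII PLY.

    Grid metadata (shape, pitch, origin) goes into header comments so the
    grid round-trips exactly; only valid cells emit vertices.  Colors are
    stored as the conventional uchar red/green/blue properties.
    """
    path = Path(path)
    xcol, yrow = surface.axes()
    rr, cc = np.nonzero(surface.valid)
    xyz = surface.xyz[rr, cc]
    rgb = surface.rgb[rr, cc]
    lines = [
        "ply",
        "format ascii 1.0",
        f"comment {_GRID_MAGIC} rows={surface.rows} cols={surface.cols} "
        f"pitch_x={surface.pitch_x!r} pitch_y={surface.pitch_y!r} "
        f"origin_x={float(xcol[0])!r} origin_y={float(yrow[0])!r}",
        f"element vertex {len(rr)}",
        "property double x",
        "property double y",
        "property double z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        "end_header",
    ]
    body = [
        f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g} {c[0]:d} {c[1]:d} {c[2]:d}"
        for p, c in zip(xyz, rgb)
    ]
    path.write_text("\n".join(lines + body) + "\n")


def _parse_grid_comment(path: Path) -> dict | None:
    try:
        with open(path, "rb") as fh:
            head = fh.read(4096).decode("ascii", errors="replace")
    except OSError as exc:  # pragma: no cover - filesystem failure
        raise FormatError(str(exc)) from exc
    for line in head.splitlines():
        if line.startswith("comment " + _GRID_MAGIC):
            fields = dict(tok.split("=") for tok in line.split()[2:])
            return {k: float(v) for k, v in fields.items()}
        if line.strip() == "end_header":
            break
    return None


def _load_ply_points(path: Path) -> tuple[np.ndarray, np.ndarray]:
    import trimesh

    try:
        obj = trimesh.load(str(path), process=False)
    except Exception as exc:
        raise FormatError(f"unreadable PLY: {exc}") from exc
    if hasattr(obj, "vertices"):
        verts = np.asarray(obj.vertices, dtype=float)
    else:  # pragma: no cover - scene container
        raise FormatError("PLY contains no vertex element")
    if len(verts) == 0:
        raise EmptyInput("PLY has no vertices")
    colors = None
    if isinstance(obj, trimesh.PointCloud):
        if obj.colors is not None and len(obj.colors) == len(verts):
            colors = np.asarray(obj.colors)[:, :3]
    elif hasattr(obj, "visual") and obj.visual is not None:
        vc = getattr(obj.visual, "vertex_colors", None)
        if vc is not None and len(vc) == len(verts):
            colors = np.asarray(vc)[:, :3]
    if colors is None:
        raise ColorMissing("PLY lacks per-vertex red/green/blue")
    return verts, colors.astype(np.uint8)


def _grid_from_ply(path: Path, meta: dict) -> OrganizedSurface:
    verts, colors = _load_ply_points(path)
    rows, cols = int(meta["rows"]), int(meta["cols"])
    px, py = meta["pitch_x"], meta["pitch_y"]
    ci = np.rint((verts[:, 0] - meta["origin_x"]) / px).astype(int)
    ri = np.rint((verts[:, 1] - meta["origin_y"]) / py).astype(int)
    if (ci < 0).any() or (ci >= cols).any() or (ri < 0).any() or (ri >= rows).any():
        raise FormatError("PLY vertices fall outside the declared grid")
    xyz = np.full((rows, cols, 3), np.nan)
    rgb = np.zeros((rows, cols, 3), dtype=np.uint8)
    valid = np.zeros((rows, cols), dtype=bool)
    xyz[ri, ci] = verts
    rgb[ri, ci] = colors
    valid[ri, ci] = True
    return OrganizedSurface(xyz=xyz, valid=valid, rgb=rgb, pitch_x=px, pitch_y=py)


# ---------------------------------------------------------------------------
# depth/color image pair


def write_depth_pair(surface: OrganizedSurface, prefix: str | Path) -> None:
    """Write ``<prefix>.json`` + 16-bit depth PNG + 8-bit color PNG.

    Depth is stored as ``z = z_offset + code * z_scale`` with code 0
    reserved as the invalid-cell sentinel.
    """
    import imageio.v3 as iio

    prefix = Path(prefix)
    xcol, yrow = surface.axes()
    z = surface.z[surface.valid]
    if z.size == 0:
        raise EmptyInput("surface has no valid cells")
    z_min, z_max = float(z.min()), float(z.max())
    z_scale = max((z_max - z_min) / 65000.0, 1e-6)
    z_offset = z_min - z_scale  # code 1 encodes z_min; 0 stays sentinel
    code = np.zeros(surface.valid.shape, dtype=np.uint16)
    code[surface.valid] = np.rint(
        (surface.z[surface.valid] - z_offset) / z_scale
    ).astype(np.uint16)
    color = surface.rgb.copy()
    color[~surface.valid] = 0
    depth_name = prefix.name + ".depth.png"
    color_name = prefix.name + ".color.png"
    iio.imwrite(prefix.parent / depth_name, code)
    iio.imwrite(prefix.parent / color_name, color)
    meta = {
        "format": "woundmetrics-depth-pair",
        "depth": depth_name,
        "color": color_name,
        "pitch_mm": [surface.pitch_x, surface.pitch_y],
        "z_scale": z_scale,
        "z_offset": z_offset,
        "origin_x": float(xcol[0]),
        "origin_y": float(yrow[0]),
    }
    (prefix.parent / (prefix.name + ".json")).write_text(json.dumps(meta, indent=1))


def _read_depth_pair(path: Path) -> OrganizedSurface:
    import imageio.v3 as iio

    try:
        meta = json.loads(path.read_text())
        code = iio.imread(path.parent / meta["depth"])
        color = iio.imread(path.parent / meta["color"])
        px, py = meta["pitch_mm"]
        z_scale, z_offset = meta["z_scale"], meta["z_offset"]
    except (OSError, KeyError, ValueError) as exc:
        raise FormatError(f"bad depth-pair input: {exc}") from exc
    if code.ndim != 2 or color.shape[:2] != code.shape:
        raise FormatError("depth and color images disagree in shape")
    rows, cols = code.shape
    valid = code > 0
    if not valid.any():
        raise EmptyInput("depth image is entirely invalid")
    z = np.where(valid, z_offset + code.astype(float) * z_scale, np.nan)
    x0 = float(meta.get("origin_x", 0.0))
    y0 = float(meta.get("origin_y", 0.0))
    xx = x0 + np.arange(cols) * px
    yy = y0 + np.arange(rows) * py
    xyz = np.stack(
        [np.broadcast_to(xx, (rows, cols)), np.broadcast_to(yy[:, None], (rows, cols)), z],
        axis=-1,
    ).copy()
    xyz[~valid] = np.nan
    return OrganizedSurface(
        xyz=xyz, valid=valid, rgb=color[..., :3], pitch_x=px, pitch_y=py
    )


# ---------------------------------------------------------------------------
# entry points


def read_surface(path: str | Path, format: str = "ply") -> OrganizedSurface:
    """Read a colored surface from ``ply`` or ``depth_pair`` input.

    PLY files written by :func:`write_surface` restore the original grid
    exactly; foreign PLY point clouds are resampled onto a regular grid
    (pitch estimated from the median nearest-neighbor distance).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "depth_pair":
        return _read_depth_pair(path)
    if format != "ply":
        raise FormatError(f"unknown format {format!r}")
    meta = _parse_grid_comment(path)
    if meta is not None:
        return _grid_from_ply(path, meta)
    verts, colors = _load_ply_points(path)
    tree = cKDTree(verts[:, :2])
    d, _ = tree.query(verts[:, :2], k=2)
    pitch = float(np.median(d[:, 1]))
    if pitch <= 0:
        raise DegenerateGeometry("coincident points; cannot infer pitch")
    return resample_to_grid(verts, colors, pitch)


def resample_to_grid(
    points: np.ndarray, colors: np.ndarray, pitch: float
) -> OrganizedSurface:
    """Resample scattered colored points onto a regular xy grid.

    Each cell takes the inverse-distance-weighted (power 2) average of
    neighbors within ``2 * pitch``; cells with no neighbor are invalid.
    Points already on a regular grid of the same pitch are reproduced
    exactly (the nearest neighbor then sits at distance ~0).
    """
    points = np.asarray(points, dtype=float)
    colors = np.asarray(colors)
    if pitch <= 0:
        raise DegenerateGeometry("pitch must be positive")
    if len(points) < 3:
        raise DegenerateGeometry("need at least three points")
    centered = points[:, :2] - points[:, :2].mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometry("points are collinear in xy")

    x0, y0 = points[:, 0].min(), points[:, 1].min()
    cols = int(np.floor((points[:, 0].max() - x0) / pitch + 0.5)) + 1
    rows = int(np.floor((points[:, 1].max() - y0) / pitch + 0.5)) + 1
    gx = x0 + np.arange(cols) * pitch
    gy = y0 + np.arange(rows) * pitch
    gxx, gyy = np.meshgrid(gx, gy)
    cell_xy = np.stack([gxx.ravel(), gyy.ravel()], axis=-1)

    tree = cKDTree(points[:, :2])
    neighbors = tree.query_ball_point(cell_xy, r=2.0 * pitch)
    z = np.full(rows * cols, np.nan)
    rgb = np.zeros((rows * cols, 3))
    valid = np.zeros(rows * cols, dtype=bool)
    eps = 1e-9 * pitch
    for i, idx in enumerate(neighbors):
        if not idx:
            continue
        idx = np.asarray(idx)
        d = np.hypot(
            points[idx, 0] - cell_xy[i, 0], points[idx, 1] - cell_xy[i, 1]
        )
        j = np.argmin(d)
        if d[j] < eps:  # exact hit: reproduce the sample
            z[i] = points[idx[j], 2]
            rgb[i] = colors[idx[j], :3]
        else:
            w = 1.0 / (d * d)
            w /= w.sum()
            z[i] = float(w @ points[idx, 2])
            rgb[i] = w @ colors[idx, :3]
        valid[i] = True

    xyz = np.stack([gxx.ravel(), gyy.ravel(), z], axis=-1)
    xyz[~valid] = np.nan
    return OrganizedSurface(
        xyz=xyz.reshape(rows, cols, 3),
        valid=valid.reshape(rows, cols),
        rgb=np.clip(np.rint(rgb), 0, 255).astype(np.uint8).reshape(rows, cols, 3),
        pitch_x=pitch,
        pitch_y=pitch,
    )
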