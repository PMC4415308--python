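"""Synthetic laser-scan surfaces with wounds of known geometry.

Emulates what a laser-triangulation profilometer returns when scanning a
lower leg: an organized grid of 3D points (mm) with per-point RGB, a
gently curved base surface (cylinder section plus low-amplitude
undulation plus sensor noise), and a wound carved as an elliptical
cavity with a smooth wall profile.  Because the cavity is analytic, its
perimeter, area, and volume are known exactly (to brute-force quadrature
accuracy) and serve as the expected values for bias experiments.

Ground truth is always computed on the noise-free base, independently of
the measurement code in :mod:`woundmetrics.metrics`: agreement between
the two is evidential, not circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import SpecInvalid
from .segmentation import (
    LABEL_BACKGROUND,
    LABEL_UNKNOWN,
    LABEL_WOUND,
    SeedLabels,
    WoundMask,
)
from .surface import OrganizedSurface


@dataclass
class BaseSpec:
    """Healthy-skin base surface: cylinder + undulation + noise.

    ``cylinder_radius`` is the leg's local radius of curvature in mm
    (``inf`` for a plane); the cylinder axis lies in the xy plane at
    ``axis_angle_deg`` from the x axis.  Undulation adds a low sinusoidal
    relief; ``noise_sigma`` is per-point Gaussian range noise in mm.
    """

    cylinder_radius: float = 90.0
    axis_angle_deg: float = 90.0
    undulation_amplitude: float = 0.0
    undulation_wavelength: float = 50.0
    undulation_angle_deg: float = 20.0
    noise_sigma: float = 0.05
    z0: float = 20.0


@dataclass
class WoundShape:
    """Elliptical cavity: semi-axes a, b (mm), depth (mm), wall profile."""

    center: tuple[float, float] = (0.0, 0.0)
    a: float = 12.0
    b: float = 9.0
    angle_deg: float = 0.0
    depth: float = 4.0
    taper_width: float = 4.0
    profile: str = "cosine"  # or "supergauss"
    supergauss_m: int = 3
    supergauss_s: float = 0.7


@dataclass
class Texture:
    """Colors of skin and wound tissue with per-pixel variation."""

    skin_rgb: tuple[int, int, int] = (205, 160, 130)
    skin_sigma: float = 8.0
    wound_rgb: tuple[int, int, int] = (150, 40, 40)
    wound_sigma: float = 10.0
    edge_blur_px: float = 1.5


@dataclass
class SyntheticWoundSpec:
    """Full recipe for one synthetic wounded surface."""

    base: BaseSpec = field(default_factory=BaseSpec)
    wound: WoundShape = field(default_factory=WoundShape)
    texture: Texture = field(default_factory=Texture)
    extent: tuple[float, float] = (64.0, 56.0)  # physical width x height, mm
    pitch: float = 0.25
    seed: int = 0
    name: str = "wound"
    family: str = "default"
    role: str = "before"  # or "after"

    def validate(self) -> None:
        w = self.wound
        if not (w.a > 0 and w.b > 0 and w.depth > 0):
            raise SpecInvalid("wound semi-axes and depth must be positive")
        if self.base.noise_sigma < 0 or self.pitch <= 0:
            raise SpecInvalid("noise sigma must be >= 0 and pitch > 0")
        r = max(w.a, w.b)
        hw, hh = self.extent[0] / 2.0, self.extent[1] / 2.0
        if (abs(w.center[0]) + r + 1.0 > hw) or (abs(w.center[1]) + r + 1.0 > hh):
            raise SpecInvalid("wound footprint exceeds the surface footprint")


@dataclass
class GroundTruth:
    """Oracle-computed expected values for one synthetic wound."""

    perimeter: float
    area: float
    volume: float
    resolution: float


# ---------------------------------------------------------------------------
# analytic geometry


def base_z(spec: SyntheticWoundSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Noise-free healthy-skin height at physical (x, y)."""
    b = spec.base
    z = np.full(np.broadcast(x, y).shape, float(b.z0))
    if np.isfinite(b.cylinder_radius):
        phi = np.deg2rad(b.axis_angle_deg)
        # signed distance from the cylinder axis (through the origin)
        u = -np.sin(phi) * x + np.cos(phi) * y
        arg = b.cylinder_radius**2 - u**2
        if np.any(arg <= 0):
            raise SpecInvalid("surface footprint exceeds the cylinder radius")
        z = z + np.sqrt(arg) - b.cylinder_radius
    if b.undulation_amplitude != 0.0:
        psi = np.deg2rad(b.undulation_angle_deg)
        t = np.cos(psi) * x + np.sin(psi) * y
        z = z + b.undulation_amplitude * np.sin(2.0 * np.pi * t / b.undulation_wavelength)
    return z


def wound_rho(spec: SyntheticWoundSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normalized elliptical radius (1 on the wound boundary)."""
    w = spec.wound
    th = np.deg2rad(w.angle_deg)
    dx, dy = x - w.center[0], y - w.center[1]
    xr = np.cos(th) * dx + np.sin(th) * dy
    yr = -np.sin(th) * dx + np.cos(th) * dy
    return np.hypot(xr / w.a, yr / w.b)


def depth_profile(spec: SyntheticWoundSpec, rho: np.ndarray) -> np.ndarray:
    """Cavity depth as a function of normalized radius; 0 at and beyond 1."""
    w = spec.wound
    rho = np.asarray(rho, dtype=float)
    d = np.zeros_like(rho)
    inside = rho < 1.0
    if w.profile == "cosine":
        tau = np.clip(w.taper_width / np.sqrt(w.a * w.b), 1e-6, 1.0)
        t = np.clip((rho - (1.0 - tau)) / tau, 0.0, 1.0)
        d[inside] = w.depth * 0.5 * (1.0 + np.cos(np.pi * t[inside]))
    elif w.profile == "supergauss":
        m, s = w.supergauss_m, w.supergauss_s
        edge = np.exp(-((1.0 / s) ** (2 * m)))
        f = (np.exp(-((rho / s) ** (2 * m))) - edge) / (1.0 - edge)
        d[inside] = w.depth * f[inside]
    else:
        raise SpecInvalid(f"unknown profile {w.profile!r}")
    return d


# ---------------------------------------------------------------------------
# generation


def generate(
    spec: SyntheticWoundSpec,
) -> tuple[OrganizedSurface, OrganizedSurface, WoundMask, GroundTruth]:
    """Build (wounded, healthy, true_mask, truth) for one spec.

    Both surfaces share the same noise realization, so outside the wound
    they are bitwise identical; the cavity depth reaches zero exactly on
    the ellipse boundary.
    """
    spec.validate()
    hw, hh = spec.extent[0] / 2.0, spec.extent[1] / 2.0
    xs = np.arange(-hw, hw + spec.pitch / 2, spec.pitch)
    ys = np.arange(-hh, hh + spec.pitch / 2, spec.pitch)
    xx, yy = np.meshgrid(xs, ys)
    rows, cols = xx.shape

    ss = np.random.SeedSequence(spec.seed)
    rng_noise, rng_tex = [np.random.default_rng(s) for s in ss.spawn(2)]

    z_healthy = base_z(spec, xx, yy)
    if spec.base.noise_sigma > 0:
        z_healthy = z_healthy + rng_noise.normal(0.0, spec.base.noise_sigma, xx.shape)
    rho = wound_rho(spec, xx, yy)
    z_wounded = z_healthy - depth_profile(spec, rho)
    true_mask = rho < 1.0

    # texture: skin everywhere, wound tissue inside, blended over the rim
    wgt = ndimage.gaussian_filter(true_mask.astype(float), spec.texture.edge_blur_px)
    skin = np.array(spec.texture.skin_rgb, dtype=float)
    wound_c = np.array(spec.texture.wound_rgb, dtype=float)
    rgb = skin + (wound_c - skin) * wgt[..., None]
    sig = spec.texture.skin_sigma + (spec.texture.wound_sigma - spec.texture.skin_sigma) * wgt
    rgb = rgb + rng_tex.normal(0.0, 1.0, rgb.shape) * sig[..., None]
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    valid = np.ones((rows, cols), dtype=bool)

    def _surf(z):
        xyz = np.stack([xx, yy, z], axis=-1)
        return OrganizedSurface(
            xyz=xyz, valid=valid, rgb=rgb, pitch_x=spec.pitch, pitch_y=spec.pitch
        )

    return (
        _surf(z_wounded),
        _surf(z_healthy),
        WoundMask(mask=true_mask),
        oracle_truth(spec),
    )


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_truth(spec: SyntheticWoundSpec, resolution: float | None = None) -> GroundTruth:
    """Expected perimeter/area/volume by dense quadrature on the analytic base.

    A grid at ``pitch / 8`` covers the ellipse; boundary cells get
    fractional coverage from 4x4 subsampling.  The perimeter is the
    length of a dense ellipse polyline lifted onto the (noise-free) base
    surface.  No code is shared with :mod:`woundmetrics.metrics`.
    """
    spec.validate()
    w = spec.wound
    s = spec.pitch / 8.0 if resolution is None else float(resolution)

    r_max = max(w.a, w.b)
    cx, cy = w.center
    xs = np.arange(cx - r_max - 2 * s, cx + r_max + 2 * s, s)
    ys = np.arange(cy - r_max - 2 * s, cy + r_max + 2 * s, s)
    xx, yy = np.meshgrid(xs, ys)
    rho = wound_rho(spec, xx, yy)
    # classify cells: fully inside / outside / boundary band
    band = s * 4.0 / min(w.a, w.b)
    frac = (rho < 1.0 - band).astype(float)
    edge_cells = (rho >= 1.0 - band) & (rho < 1.0 + band)
    if edge_cells.any():
        er, ec = np.nonzero(edge_cells)
        off = (np.arange(4) + 0.5) / 4.0 - 0.5
        ox, oy = np.meshgrid(off * s, off * s)
        sub_x = xx[er, ec][:, None] + ox.ravel()[None, :]
        sub_y = yy[er, ec][:, None] + oy.ravel()[None, :]
        sub_in = wound_rho(spec, sub_x, sub_y) < 1.0
        frac[er, ec] = sub_in.mean(axis=1)

    # base-surface metric factor by central differences (noise-free base)
    h = s / 2.0
    zx = (base_z(spec, xx + h, yy) - base_z(spec, xx - h, yy)) / (2 * h)
    zy = (base_z(spec, xx, yy + h) - base_z(spec, xx, yy - h)) / (2 * h)
    metric = np.sqrt(1.0 + zx**2 + zy**2)
    area = float(np.sum(frac * metric) * s * s)
    volume = float(np.sum(frac * depth_profile(spec, rho)) * s * s)

    # perimeter: dense ellipse polyline lifted to the base surface
    n_theta = max(int(np.ceil(8.0 * np.pi * r_max / s)), 4096)
    th = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    ang = np.deg2rad(w.angle_deg)
    ex = cx + w.a * np.cos(th) * np.cos(ang) - w.b * np.sin(th) * np.sin(ang)
    ey = cy + w.a * np.cos(th) * np.sin(ang) + w.b * np.sin(th) * np.cos(ang)
    ez = base_z(spec, ex, ey)
    pts = np.stack([ex, ey, ez], axis=-1)
    perimeter = float(
        np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1).sum()
    )
    return GroundTruth(perimeter=perimeter, area=area, volume=volume, resolution=s)


# ---------------------------------------------------------------------------
# standard verification suite


def standard_suite(master_seed: int = 0) -> list[SyntheticWoundSpec]:
    """Six wounds in three before/after pairs for the bias experiment.

    Families: a shallow flat wound on a nearly planar base, a deep
    steep-walled cavity on a cylindrical leg, and a tilted elongated
    wound on an undulating base.  Each family has a larger "before" and a
    smaller "after" variant (simulated healing); depths span 3-6 mm and
    cavity volumes roughly 800-2200 mm^3.
    """
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]

    flat = BaseSpec(cylinder_radius=250.0, noise_sigma=0.05)
    leg = BaseSpec(cylinder_radius=90.0, noise_sigma=0.05)
    undul = BaseSpec(
        cylinder_radius=120.0,
        undulation_amplitude=0.6,
        undulation_wavelength=55.0,
        undulation_angle_deg=25.0,
        noise_sigma=0.05,
    )

    def spec(base, wound, extent, seed, name, family, role):
        return SyntheticWoundSpec(
            base=base,
            wound=wound,
            extent=extent,
            seed=seed,
            name=name,
            family=family,
            role=role,
        )

    suite = [
        spec(
            flat,
            WoundShape(a=17.0, b=13.0, depth=3.0, taper_width=4.0, profile="cosine"),
            (64.0, 56.0),
            seeds[0],
            "shallow-before",
            "shallow",
            "before",
        ),
        spec(
            flat,
            WoundShape(a=13.0, b=10.0, depth=3.0, taper_width=4.0, profile="cosine"),
            (56.0, 50.0),
            seeds[1],
            "shallow-after",
            "shallow",
            "after",
        ),
        spec(
            leg,
            WoundShape(
                a=15.5, b=12.5, depth=6.0, profile="supergauss", supergauss_m=3,
                supergauss_s=0.75,
            ),
            (62.0, 56.0),
            seeds[2],
            "deep-before",
            "deep",
            "before",
        ),
        spec(
            leg,
            WoundShape(
                a=12.0, b=10.0, depth=6.0, profile="supergauss", supergauss_m=3,
                supergauss_s=0.75,
            ),
            (54.0, 50.0),
            seeds[3],
            "deep-after",
            "deep",
            "after",
        ),
        spec(
            undul,
            WoundShape(
                a=16.0, b=10.0, angle_deg=28.0, depth=4.0, taper_width=4.0,
                profile="cosine",
            ),
            (64.0, 54.0),
            seeds[4],
            "irregular-before",
            "irregular",
            "before",
        ),
        spec(
            undul,
            WoundShape(
                a=12.0, b=8.0, angle_deg=28.0, depth=4.0, taper_width=4.0,
                profile="cosine",
            ),
            (56.0, 48.0),
            seeds[5],
            "irregular-after",
            "irregular",
            "after",
        ),
    ]
    return suite


def seeds_from_mask(
    true_mask: WoundMask, margin_px: int = 8
) -> SeedLabels:
    """Operator-style seed labels derived from a known wound mask.

    The eroded mask becomes the definite-wound region, the complement of
    the dilated mask the definite-background region (mirroring how an
    operator paints a core stroke inside the wound and a ring outside).
    """
    from skimage.morphology import dilation, disk, erosion

    se = disk(margin_px)
    labels = np.full(true_mask.mask.shape, LABEL_UNKNOWN, dtype=np.uint8)
    labels[erosion(true_mask.mask, se)] = LABEL_WOUND
    labels[~dilation(true_mask.mask, se)] = LABEL_BACKGROUND
    return SeedLabels(labels=labels)


def shrunken(spec: SyntheticWoundSpec, factor: float = 0.5) -> SyntheticWoundSpec:
    """A geometrically scaled-down copy of a spec (testing helper)."""
    w = spec.wound
    return replace(
        spec,
        wound=replace(w, a=w.a * factor, b=w.b * factor, taper_width=w.taper_width * factor),
    )
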