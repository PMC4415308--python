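"""Shared fixtures: compact synthetic surfaces generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from woundmetrics import OrganizedSurface, generate
from woundmetrics.synthetic import BaseSpec, SyntheticWoundSpec, Texture, WoundShape


def make_surface(
    zfunc,
    extent=(50.0, 44.0),
    pitch=0.5,
    rgb=(200, 160, 130),
    noise_sigma=0.0,
    seed=0,
) -> OrganizedSurface:
    """Organized surface with z = zfunc(x, y) over a centered extent."""
    hw, hh = extent[0] / 2.0, extent[1] / 2.0
    xs = np.arange(-hw, hw + pitch / 2, pitch)
    ys = np.arange(-hh, hh + pitch / 2, pitch)
    xx, yy = np.meshgrid(xs, ys)
    z = np.asarray(zfunc(xx, yy), dtype=float) + np.zeros_like(xx)
    if noise_sigma > 0:
        z = z + np.random.default_rng(seed).normal(0.0, noise_sigma, z.shape)
    xyz = np.stack([xx, yy, z], axis=-1)
    return OrganizedSurface(
        xyz=xyz,
        valid=np.ones(xx.shape, dtype=bool),
        rgb=np.full(xx.shape + (3,), np.array(rgb, dtype=np.uint8)),
        pitch_x=pitch,
        pitch_y=pitch,
    )


@pytest.fixture(scope="session")
def plane_surface() -> OrganizedSurface:
    return make_surface(lambda x, y: 10.0)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticWoundSpec:
    """A compact wound (coarse pitch) that keeps unit tests fast."""
    return SyntheticWoundSpec(
        base=BaseSpec(cylinder_radius=150.0, noise_sigma=0.05),
        wound=WoundShape(a=10.0, b=7.5, depth=3.0, taper_width=3.0),
        texture=Texture(),
        extent=(44.0, 38.0),
        pitch=0.5,
        seed=11,
        name="test-wound",
    )


@pytest.fixture(scope="session")
def small_gen(small_spec):
    """(wounded, healthy, true_mask, truth) of the compact wound."""
    return generate(small_spec)
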