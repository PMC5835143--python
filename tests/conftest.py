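"""Shared fixtures: small synthetic scenes used across test modules."""

from __future__ import annotations

import math

import numpy as np
import pytest

from synmesh.synthdata import (
    FootprintSpec,
    HoleSpec,
    SimulationConfig,
    render_mesh_movie,
)

# 7 holes on a rough grid so every part of the ROI is near a hole (the
# background-subtraction window then stays neutral across the mesh)
GRID_HOLES = [
    HoleSpec((4.2, 4.2), 0.06),
    HoleSpec((6.4, 4.0), 0.5),
    HoleSpec((8.6, 4.3), 1.0),
    HoleSpec((4.0, 6.5), 0.1),
    HoleSpec((8.7, 6.4), 0.2),
    HoleSpec((4.3, 8.6), 0.3),
    HoleSpec((6.5, 8.7), 0.15),
]


def make_mesh_config(**overrides) -> SimulationConfig:
    """A 12.8 um field holding a plateaued 110 um^2 synapse footprint."""
    kwargs = dict(
        image_size_px=(320, 320),
        footprint_spec=FootprintSpec(110.0, 110.0, 0.5),
        n_frames=1,
        rng_seed=1,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def crisp_holes_scene():
    """Noise-free, blur-free mesh with the 7 grid holes."""
    cfg = make_mesh_config(
        hole_spec=list(GRID_HOLES),
        noise_gaussian_sd=0.0,
        psf_fwhm_um=0.0,
        recon_sigma_um=0.0,
    )
    movie, truth = render_mesh_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def realistic_holes_scene():
    """Imaging-model mesh (PSF + reconstruction filter + read noise)."""
    cfg = make_mesh_config(
        hole_spec=list(GRID_HOLES),
        noise_gaussian_sd=0.21,
        psf_fwhm_um=0.13,
        recon_sigma_um=0.08,
    )
    movie, truth = render_mesh_movie(cfg)
    return cfg, movie, truth


def disk_image(shape, centers_radii, value=1.0):
    """Binary-ish image with filled discs; centers/radii in pixels."""
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cy, cx), r in centers_radii:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = value
    return img


def gaussian_spot_image(shape, spots, floor=0.0):
    """Image with Gaussian bumps: spots = [(cy, cx, sigma, amplitude)]."""
    img = np.full(shape, floor, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx, sigma, amp in spots:
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return img


def radius_px(area_um2: float, px: float) -> float:
    return math.sqrt(area_um2 / math.pi) / px
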