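"""Mesh dynamism: dense optical flow, kymographs, directional decomposition.

The flow estimator is the Farneback dense algorithm — local quadratic
polynomial expansion of each frame followed by iterative displacement
estimation over a Gaussian-weighted neighborhood, wrapped in a coarse-to-
fine image pyramid. Defaults reproduce the published parameterization
(3 pyramid levels, scale 0.5, 3 iterations, neighborhood 5, filter size 15,
quiver display decimated by 5 with arrow scale 2).

Kymographs are space x time matrices sampled along a user line; their
directional decomposition partitions the 2-D Fourier plane into a static
band (|temporal frequency| <= 1 bin) and forward/backward half-planes by
the sign of the spatial x temporal frequency product, so the three
components sum to the total exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import CalibratedImage, SynapseMovie


@dataclass
class FarnebackParams:
    """The published Farneback parameterization."""

    num_pyramid_levels: int = 3
    pyramid_scale: float = 0.5
    num_iterations: int = 3
    neighborhood_size: int = 5
    filter_size: int = 15


@dataclass
class FlowField:
    """Per-pixel displacement between a consecutive frame pair.

    ``dx``/``dy`` are in px/frame; positive dx points toward increasing x
    (column index). ``velocity_um_per_s`` converts using the calibration.
    """

    dx: np.ndarray
    dy: np.ndarray
    frame_pair: tuple[int, int]
    pixel_size_um: float
    frame_interval_s: float
    decimation: int = 5
    display_scale: float = 2.0

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)

    def velocity_um_per_s(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.pixel_size_um / self.frame_interval_s
        return self.dx * k, self.dy * k


@dataclass
class KymographBundle:
    line_um: np.ndarray  # (N, 2) polyline vertices in um
    total: np.ndarray  # (positions, frames)
    pixel_size_um: float
    frame_interval_s: float
    forward: np.ndarray | None = None
    backward: np.ndarray | None = None
    static: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Farneback dense optical flow
# ---------------------------------------------------------------------------


def _poly_expansion(img: np.ndarray, n: int, sigma: float):
    """Quadratic polynomial expansion f ~ x'Ax + b'x + c per pixel.

    Gaussian applicability of half-width n; returns (A, b) fields with
    A of shape (..., 2, 2) and b of shape (..., 2) in (x, y) order.
    """
    x = np.arange(-n, n + 1, dtype=float)
    a = np.exp(-(x**2) / (2 * sigma**2))
    # separable moment sums of the applicability
    s0 = a.sum()
    s2 = (a * x**2).sum()
    s4 = (a * x**4).sum()
    # normal-equation matrix for basis (1, x, y, x^2, y^2, xy); block solve
    # via its known sparsity: x, y and xy decouple; (1, x^2, y^2) couple.
    G11 = s0 * s0
    Gx2 = s0 * s2
    Gx4 = s0 * s4
    Gx2y2 = s2 * s2

    k0, k1, k2 = a, a * x, a * x**2

    def corr(img, ky, kx):
        out = ndi.correlate1d(img, ky, axis=0, mode="reflect")
        return ndi.correlate1d(out, kx, axis=1, mode="reflect")

    m00 = corr(img, k0, k0)
    m10 = corr(img, k0, k1)  # x moment
    m01 = corr(img, k1, k0)  # y moment
    m20 = corr(img, k0, k2)
    m02 = corr(img, k2, k0)
    m11 = corr(img, k1, k1)

    # solve the coupled 3x3 system for (c, cxx, cyy)
    M = np.array([[G11, Gx2, Gx2], [Gx2, Gx4, Gx2y2], [Gx2, Gx2y2, Gx4]])
    Minv = np.linalg.inv(M)
    cxx = Minv[1, 0] * m00 + Minv[1, 1] * m20 + Minv[1, 2] * m02
    cyy = Minv[2, 0] * m00 + Minv[2, 1] * m20 + Minv[2, 2] * m02
    cx = m10 / Gx2
    cy = m01 / Gx2
    cxy = m11 / Gx2y2

    A = np.empty(img.shape + (2, 2))
    A[..., 0, 0] = cxx
    A[..., 1, 1] = cyy
    A[..., 0, 1] = A[..., 1, 0] = cxy / 2
    b = np.stack([cx, cy], axis=-1)
    return A, b


def _warp(arr: np.ndarray, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    ny, nx = arr.shape[:2]
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    coords = [yy + dy, xx + dx]
    if arr.ndim == 2:
        return ndi.map_coordinates(arr, coords, order=1, mode="nearest")
    out = np.empty_like(arr)
    flat = arr.reshape(ny, nx, -1)
    outf = out.reshape(ny, nx, -1)
    for k in range(flat.shape[-1]):
        outf[..., k] = ndi.map_coordinates(
            flat[..., k], coords, order=1, mode="nearest"
        )
    return out


def _flow_two_frames(
    f1: np.ndarray, f2: np.ndarray, params: FarnebackParams
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement field (dx, dy) such that f1(x) ~ f2(x + d)."""
    n = params.neighborhood_size // 2
    poly_sigma = max(params.neighborhood_size / 4.0, 0.8)
    w_sigma = params.filter_size / 4.0

    # build pyramid (level 0 = full resolution)
    levels = [np.asarray(f1, dtype=float)], [np.asarray(f2, dtype=float)]
    for _ in range(params.num_pyramid_levels - 1):
        zoom = params.pyramid_scale
        levels[0].append(
            ndi.zoom(ndi.gaussian_filter(levels[0][-1], 1.0), zoom, order=1)
        )
        levels[1].append(
            ndi.zoom(ndi.gaussian_filter(levels[1][-1], 1.0), zoom, order=1)
        )
    dx = dy = None
    for lvl in range(params.num_pyramid_levels - 1, -1, -1):
        a1, b1 = _poly_expansion(levels[0][lvl], n, poly_sigma)
        a2, b2 = _poly_expansion(levels[1][lvl], n, poly_sigma)
        shape = levels[0][lvl].shape
        if dx is None:
            dx = np.zeros(shape)
            dy = np.zeros(shape)
        else:
            factor_y = shape[0] / dx.shape[0]
            factor_x = shape[1] / dx.shape[1]
            dx = ndi.zoom(dx, (factor_y, factor_x), order=1) * factor_x
            dy = ndi.zoom(dy, (factor_y, factor_x), order=1) * factor_y
        for _ in range(params.num_iterations):
            a2w = _warp(a2, dx, dy)
            b2w = _warp(b2, dx, dy)
            A = 0.5 * (a1 + a2w)
            d0 = np.stack([dx, dy], axis=-1)
            db = -0.5 * (b2w - b1) + np.einsum("...ij,...j->...i", A, d0)
            # weighted least squares over the neighborhood
            AtA = np.einsum("...ki,...kj->...ij", A, A)
            Atb = np.einsum("...ki,...k->...i", A, db)
            for idx in np.ndindex(2, 2):
                AtA[(...,) + idx] = ndi.gaussian_filter(
                    AtA[(...,) + idx], w_sigma
                )
            for idx in range(2):
                Atb[..., idx] = ndi.gaussian_filter(Atb[..., idx], w_sigma)
            # solve for the residual relative to the prior displacement,
            # with Tikhonov damping at the scale of the typical normal
            # matrix: where the expansion carries no coherent signal (pure
            # noise) the damped residual is ~zero, while for coherent
            # texture the iterations converge to the unbiased displacement
            lam = 0.2 * float(
                np.median(AtA[..., 0, 0] + AtA[..., 1, 1])
            ) + 1e-12
            r0 = Atb[..., 0] - AtA[..., 0, 0] * dx - AtA[..., 0, 1] * dy
            r1 = Atb[..., 1] - AtA[..., 1, 0] * dx - AtA[..., 1, 1] * dy
            a00 = AtA[..., 0, 0] + lam
            a11 = AtA[..., 1, 1] + lam
            a01 = AtA[..., 0, 1]
            det = a00 * a11 - a01 * a01
            dx = dx + (a11 * r0 - a01 * r1) / det
            dy = dy + (a00 * r1 - a01 * r0) / det
            # displacements beyond the filter span are not estimable at one
            # level; clamping keeps the solver stable on degenerate input
            limit = float(params.filter_size)
            np.clip(dx, -limit, limit, out=dx)
            np.clip(dy, -limit, limit, out=dy)
    return dx, dy


def to_8bit(stack: np.ndarray) -> np.ndarray:
    """Linear min-max scaling of a whole stack to 8-bit, as done before flow."""
    lo, hi = float(stack.min()), float(stack.max())
    if hi == lo:
        return np.zeros_like(stack, dtype=np.uint8)
    return ((stack - lo) / (hi - lo) * 255.0).astype(np.uint8)


def compute_flow(
    movie: SynapseMovie,
    params: FarnebackParams | None = None,
    *,
    channel: str = "actin",
) -> list[FlowField]:
    """Dense optical flow for every consecutive frame pair of a movie.

    Frames are linearly rescaled to 8-bit (per movie) before estimation.
    The returned displacement d satisfies frame_t(x) ~ frame_{t+1}(x + ...):
    a structure moving toward +x between t and t+1 yields positive dx.
    """
    params = params or FarnebackParams()
    if movie.n_frames < 2:
        raise ValueError("optical flow needs at least 2 frames")
    stack = to_8bit(movie.channels[channel]).astype(float)
    fields = []
    for t in range(movie.n_frames - 1):
        dx, dy = _flow_two_frames(stack[t + 1], stack[t], params)
        # d maps frame t+1 back onto frame t; negate to report motion t->t+1
        fields.append(
            FlowField(
                dx=-dx,
                dy=-dy,
                frame_pair=(t, t + 1),
                pixel_size_um=movie.pixel_size_um,
                frame_interval_s=movie.frame_interval_s,
            )
        )
    return fields


def quiver_plot(field: FlowField, ax=None, background: np.ndarray | None = None):
    """Quiver display of a flow field (decimation 5, arrow scale 2)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    d = field.decimation
    ny, nx = field.dx.shape
    yy, xx = np.mgrid[0:ny:d, 0:nx:d]
    if background is not None:
        ax.imshow(background, cmap="gray")
    ax.quiver(
        xx,
        yy,
        field.dx[::d, ::d] * field.display_scale,
        -field.dy[::d, ::d] * field.display_scale,
        color="orange",
        angles="xy",
        scale_units="xy",
        scale=1,
    )
    ax.set_aspect("equal")
    return ax


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------


def _line_samples(line_um: np.ndarray, pixel_size_um: float):
    """Positions sampled at 1-px spacing along a polyline, plus unit normals."""
    v = np.asarray(line_um, dtype=float) / pixel_size_um  # to px, (x, y)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 2:
        raise ValueError("line must be an (N, 2) polyline in um")
    pts = []
    normals = []
    for p, q in zip(v[:-1], v[1:]):
        seg = q - p
        length = np.hypot(*seg)
        if length == 0:
            continue
        n_steps = int(math.ceil(length))
        ts = np.arange(n_steps + 1) / max(n_steps, 1)
        if pts:
            ts = ts[1:]
        for t in ts:
            pts.append(p + t * seg)
            normals.append(np.array([-seg[1], seg[0]]) / length)
    if not pts:
        raise ValueError("line has zero length")
    return np.array(pts), np.array(normals)


def extract_kymograph(
    movie: SynapseMovie,
    line_um: np.ndarray,
    width_px: int = 1,
    *,
    channel: str = "actin",
) -> KymographBundle:
    """Sample intensity along a line for every frame (rows = positions).

    Bilinear interpolation; with ``width_px`` > 1 the intensity is averaged
    across that many parallel lines centred on the given one.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    pts, normals = _line_samples(line_um, movie.pixel_size_um)
    ny, nx = movie.frame_shape
    offsets = np.arange(width_px) - (width_px - 1) / 2
    sample_xy = pts[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    if (
        sample_xy[..., 0].min() < 0
        or sample_xy[..., 0].max() > nx - 1
        or sample_xy[..., 1].min() < 0
        or sample_xy[..., 1].max() > ny - 1
    ):
        raise ValueError("line (with width) extends outside the image")
    stack = movie.channels[channel]
    kymo = np.empty((len(pts), movie.n_frames))
    coords = [sample_xy[..., 1].ravel(), sample_xy[..., 0].ravel()]
    for t in range(movie.n_frames):
        vals = ndi.map_coordinates(stack[t], coords, order=1)
        kymo[:, t] = vals.reshape(width_px, len(pts)).mean(axis=0)
    return KymographBundle(
        line_um=np.asarray(line_um, dtype=float),
        total=kymo,
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
    )


def decompose_kymograph(
    kymo: KymographBundle, static_band_bins: int = 1
) -> KymographBundle:
    """Split a kymograph into forward, backward and static components.

    The 2-D DFT plane is partitioned exactly: bins with |f_t| <=
    ``static_band_bins`` (and the purely temporal f_x = 0 column) form the
    static component; the remainder splits by the sign of f_x * f_t —
    negative product = motion toward increasing position ("forward", since
    a ridge x = v t with v > 0 has support on f_t = -v f_x). The partition
    is symmetric under frequency negation, so all components are real, and
    forward + backward + static reconstructs the total to machine
    precision.
    """
    total = kymo.total
    if total.shape[0] < 8 or total.shape[1] < 8:
        raise ValueError("kymograph must be at least 8x8")
    if not np.all(np.isfinite(total)):
        raise ValueError("kymograph contains non-finite values")
    F = np.fft.fft2(total)
    fx = np.fft.fftfreq(total.shape[0], d=1.0)[:, None]  # spatial (rows)
    ft_bins = np.fft.fftfreq(total.shape[1], d=1.0 / total.shape[1])[None, :]
    static_sel = (np.abs(ft_bins) <= static_band_bins) | (fx == 0)
    prod = fx * ft_bins
    fwd_sel = ~static_sel & (prod < 0)
    bwd_sel = ~static_sel & (prod > 0)
    rest = ~static_sel & (prod == 0)  # f_t != 0 with f_x = 0 is already static
    static_sel = static_sel | rest
    out = KymographBundle(
        line_um=kymo.line_um,
        total=total,
        pixel_size_um=kymo.pixel_size_um,
        frame_interval_s=kymo.frame_interval_s,
        forward=np.real(np.fft.ifft2(F * fwd_sel)),
        backward=np.real(np.fft.ifft2(F * bwd_sel)),
        static=np.real(np.fft.ifft2(F * static_sel)),
    )
    return out


def component_energies(bundle: KymographBundle) -> dict[str, float]:
    """Non-DC energy of each component (squared deviation from its mean)."""
    out = {}
    for name in ("total", "forward", "backward", "static"):
        m = getattr(bundle, name)
        if m is None:
            continue
        out[name] = float(((m - m.mean()) ** 2).sum())
    return out


def rim_kymograph(
    movie: SynapseMovie,
    footprint_masks: np.ndarray,
    rim_width_um: float = 2.0,
    *,
    channel: str = "actin",
    n_angle_bins: int = 360,
) -> np.ndarray:
    """Mean intensity in the outer rim of the cell, binned by polar angle.

    The rim is the footprint minus its erosion by ``rim_width_um`` (default
    2 um, the standard inner-rim width for edge kymographs); rim pixels are
    binned by angle about the footprint centroid. Returns an
    (angle bins x frames) matrix with NaN for empty bins.
    """
    px = movie.pixel_size_um
    r_px = int(round(rim_width_um / px))
    stack = movie.channels[channel]
    n_frames = movie.n_frames
    if footprint_masks.shape != stack.shape:
        raise ValueError("footprint_masks must match movie geometry")
    out = np.full((n_angle_bins, n_frames), np.nan)
    yy, xx = np.mgrid[0 : stack.shape[1], 0 : stack.shape[2]]
    struct = ndi.generate_binary_structure(2, 1)
    for t in range(n_frames):
        mask = footprint_masks[t].astype(bool)
        if not mask.any():
            raise ValueError(f"empty footprint at frame {t}")
        eroded = ndi.binary_erosion(mask, struct, iterations=r_px)
        if not eroded.any():
            raise ValueError(
                f"footprint at frame {t} is smaller than the rim width"
            )
        rim = mask & ~eroded
        cy, cx = ndi.center_of_mass(mask)
        ang = np.arctan2(yy[rim] - cy, xx[rim] - cx)
        bins = ((ang + np.pi) / (2 * np.pi) * n_angle_bins).astype(int)
        bins = np.clip(bins, 0, n_angle_bins - 1)
        vals = stack[t][rim]
        sums = np.bincount(bins, weights=vals, minlength=n_angle_bins)
        counts = np.bincount(bins, minlength=n_angle_bins)
        with np.errstate(invalid="ignore"):
            out[:, t] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def line_profile(
    img: CalibratedImage, line_um: np.ndarray
) -> pd.DataFrame:
    """Bilinear intensity profile along a line; distance in um."""
    pts, _ = _line_samples(line_um, img.pixel_size_um)
    ny, nx = img.shape
    if (
        pts[:, 0].min() < 0
        or pts[:, 0].max() > nx - 1
        or pts[:, 1].min() < 0
        or pts[:, 1].max() > ny - 1
    ):
        raise ValueError("line extends outside the image")
    vals = ndi.map_coordinates(img.pixels, [pts[:, 1], pts[:, 0]], order=1)
    seg = np.diff(pts, axis=0)
    dist = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    return pd.DataFrame(
        {"distance_um": dist * img.pixel_size_um, "intensity": vals}
    )
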