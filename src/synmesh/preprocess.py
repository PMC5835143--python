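"""Shared raster preprocessing for clearance and viability analysis.

The clearance pipeline is: rolling-ball background subtraction (radius 50 px)
-> pixel intensities squared twice (x^4, rescaled to the original maximum)
-> automatic threshold by iterative intermeans on a 256-bin histogram, with
clearances taken as the below-threshold (dark) phase. The viability pipeline
uses a 10-30 px difference-of-Gaussians bandpass before thresholding.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .core import BinaryMask, CalibratedImage, Polarity


def rolling_ball_subtract(
    img: CalibratedImage, radius_px: int
) -> CalibratedImage:
    """Subtract a smooth background estimated by a rolling-window opening.

    The background is the grayscale opening of the image with a flat window
    of half-width ``radius_px`` — the flat-kernel limit of the classic
    rolling-ball filter, whose intensity curvature is negligible at the
    radii used here. Opening is anti-extensive and idempotent, so the
    result is non-negative, its mean never exceeds the input mean, and
    repeating the subtraction on its own output is a no-op for structures
    smaller than the window.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    pixels = img.pixels
    if radius_px > min(pixels.shape):
        raise ValueError(
            f"radius {radius_px} exceeds image extent {pixels.shape}"
        )
    size = 2 * radius_px + 1
    bg = ndi.grey_opening(pixels, size=(size, size))
    return img.with_pixels(np.clip(pixels - bg, 0.0, None))


def square_twice(img: CalibratedImage) -> CalibratedImage:
    """Raise intensities to the fourth power, rescaled to the input maximum.

    A rank-preserving contrast stretch that drives the dim phase (holes)
    toward zero relative to the mesh. Requires non-negative input — run
    background subtraction first.
    """
    pixels = img.pixels
    if (pixels < 0).any():
        raise ValueError("square_twice requires non-negative pixels")
    peak = pixels.max()
    if peak == 0:
        return img.with_pixels(np.zeros_like(pixels))
    out = (pixels / peak) ** 4 * peak
    return img.with_pixels(out)


def isodata_threshold(pixels: np.ndarray, n_bins: int = 256) -> float:
    """Iterative-intermeans (IsoData-variant) threshold.

    The histogram is binned to ``n_bins`` levels over the data range and
    the intermeans fixed point T = (mean below + mean above) / 2 is sought,
    matching the behaviour of the common "default" automatic threshold in
    interactive image-analysis tools: the split index scans upward from the
    lowest occupied bin and stops at the first (lowest) fixed point, so on
    images whose dark phase is a minority class the threshold lands just
    above it rather than splitting the bright phase.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    lo, hi = float(pixels.min()), float(pixels.max())
    if lo == hi:
        raise ValueError("no threshold: image is constant")
    hist, edges = np.histogram(pixels, bins=n_bins, range=(lo, hi))
    idx = np.arange(n_bins, dtype=float)
    csum = np.cumsum(hist)
    cmom = np.cumsum(hist * idx)
    total, total_mom = csum[-1], cmom[-1]
    occupied = np.nonzero(hist)[0]
    split = int(occupied[0])
    result = float(n_bins - 1)
    while split < n_bins - 1:
        n_lo = csum[split]
        n_hi = total - n_lo
        if n_lo == 0:
            split += 1
            continue
        if n_hi == 0:
            break
        mean_lo = cmom[split] / n_lo
        mean_hi = (total_mom - cmom[split]) / n_hi
        result = (mean_lo + mean_hi) / 2
        if split + 1 > result:
            break
        split += 1
    # map the bin-space threshold back to intensity units
    return float(lo + (result + 0.5) * (hi - lo) / n_bins)


def auto_threshold(
    img: CalibratedImage, polarity: Polarity | str = Polarity.FOREGROUND_DARK
) -> BinaryMask:
    """Threshold by iterative intermeans and return the requested phase.

    ``foreground_dark`` marks below-threshold pixels (clearances on a bright
    mesh); ``foreground_bright`` marks above-threshold pixels (cell on a
    dark background). The two polarities are exact mirrors: the bright case
    scans the inverted histogram, so inverting an image and flipping the
    polarity yields the identical mask.
    """
    polarity = Polarity(polarity)
    if polarity is Polarity.FOREGROUND_DARK:
        t = isodata_threshold(img.pixels)
        mask = img.pixels <= t
    else:
        t = -isodata_threshold(-img.pixels)
        mask = img.pixels >= t
    return BinaryMask(pixels=mask, polarity=polarity)


def bandpass(
    img: CalibratedImage, low_px: int, high_px: int
) -> CalibratedImage:
    """Difference-of-Gaussians bandpass retaining structures between scales.

    Sigmas follow the FWHM convention: sigma = size / 2.355. The DC
    component is removed (output mean ~ 0).
    """
    if not (0 < low_px < high_px):
        raise ValueError("need 0 < low_px < high_px")
    sigma_small = low_px / 2.355
    sigma_large = high_px / 2.355
    pixels = img.pixels.astype(float)
    out = ndi.gaussian_filter(pixels, sigma_small) - ndi.gaussian_filter(
        pixels, sigma_large
    )
    return img.with_pixels(out - out.mean())
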