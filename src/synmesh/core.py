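"""Core calibrated-raster containers shared by all analysis stages.

Every quantitative output of the package is expressed in physical units
(micrometres, seconds); the containers here carry the calibration needed to
convert between pixel/frame space and physical space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

CHANNEL_ROLES = ("actin", "granule", "reporter", "transmitted", "dead_marker")


class Polarity(str, Enum):
    """Which side of a threshold counts as foreground."""

    FOREGROUND_BRIGHT = "foreground_bright"
    FOREGROUND_DARK = "foreground_dark"


@dataclass
class CalibratedImage:
    """A single-channel 2-D raster with physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of finite intensities.
    pixel_size_um
        Edge length of one pixel in micrometres (> 0).
    frame_index
        Position of this frame within its parent movie.
    channel_role
        One of ``actin``, ``granule``, ``reporter``, ``transmitted``,
        ``dead_marker``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    frame_index: int = 0
    channel_role: str = "actin"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel_role {self.channel_role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """Return a copy carrying new pixel data but the same calibration."""
        return CalibratedImage(
            pixels=pixels,
            pixel_size_um=self.pixel_size_um,
            frame_index=self.frame_index,
            channel_role=self.channel_role,
        )


@dataclass
class BinaryMask:
    """Boolean raster produced by thresholding, same geometry as its source."""

    pixels: np.ndarray
    polarity: Polarity = Polarity.FOREGROUND_BRIGHT

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if isinstance(self.polarity, str):
            self.polarity = Polarity(self.polarity)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SynapseMovie:
    """Calibrated multi-channel time-lapse.

    ``channels`` maps a channel role to a (T, Y, X) stack; all stacks share
    the same geometry and time base.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    frame_interval_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("movie needs at least one channel")
        shapes = set()
        for name, stack in self.channels.items():
            stack = np.asarray(stack, dtype=float)
            if stack.ndim != 3:
                raise ValueError(f"channel {name!r} must be (T, Y, X)")
            self.channels[name] = stack
            shapes.add(stack.shape)
        if len(shapes) != 1:
            raise ValueError("all channels must share shape")
        if not (self.pixel_size_um > 0 and self.frame_interval_s > 0):
            raise ValueError("pixel_size_um and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    def frame(self, channel: str, t: int) -> CalibratedImage:
        """Extract one frame of one channel as a :class:`CalibratedImage`."""
        if channel not in self.channels:
            raise KeyError(
                f"channel {channel!r} not in movie (have {sorted(self.channels)})"
            )
        stack = self.channels[channel]
        if not (0 <= t < stack.shape[0]):
            raise IndexError(f"frame {t} out of range (0..{stack.shape[0] - 1})")
        return CalibratedImage(
            pixels=stack[t],
            pixel_size_um=self.pixel_size_um,
            frame_index=t,
            channel_role=channel,
        )

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s
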