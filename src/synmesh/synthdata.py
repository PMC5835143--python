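"""Ground-truthed synthetic synapse movies.

This module renders time-lapse movies that emulate the statistical structure
of live super-resolution recordings of the cytolytic immunological synapse:

* a dense cortical F-actin mesh built from randomly oriented fiber segments
  with node blobs at fiber crossings, carrying planted quasi-circular
  clearances (locally actin-depleted holes) that can open and close;
* bright punctate actin foci with exponentially distributed lifetimes plus a
  small long-lived (censored) tail;
* diffraction-limited lytic-granule spots that appear and disappear;
* an exocytosis-reporter channel with step-like intensity bursts;
* a spreading cell footprint that grows linearly to a plateau;
* Gaussian PSF blur followed by mixed Poisson-Gaussian noise.

Every planted object is echoed in a :class:`GroundTruth` record so that each
downstream analysis stage can be validated against known truth.

The forward model is deliberately phenomenological: fibers are straight
segments, not polymer physics; the mesh is static apart from hole dynamics.
That is sufficient because the analysis stages consume only intensity
statistics, geometry and timing, none of which depend on filament mechanics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import SynapseMovie

_SS = 4  # supersampling factor for sub-pixel rasterization


# ---------------------------------------------------------------------------
# configuration records
# ---------------------------------------------------------------------------


@dataclass
class HoleSpec:
    """A planted clearance: circular, centred at ``center_um`` (x, y)."""

    center_um: tuple[float, float]
    area_um2: float
    open_frame: int = 0
    close_frame: int | None = None  # exclusive; None = open to the end

    @property
    def radius_um(self) -> float:
        return math.sqrt(self.area_um2 / math.pi)


@dataclass
class FociSpec:
    count: int = 0
    mean_lifetime_s: float = 42.0  # TIRF-SIM foci turn over on this scale
    censored_fraction: float = 0.0306  # small long-lived subpopulation


@dataclass
class GranuleSpec:
    appear_frame: int
    disappear_frame: int  # exclusive
    center_um: tuple[float, float]
    diameter_um: float = 0.3


@dataclass
class BurstSpec:
    track_id: int
    burst_frame: int
    amplitude_fold: float


@dataclass
class FootprintSpec:
    initial_area_um2: float = 5.0
    plateau_area_um2: float = 64.0
    spread_rate_um2_per_s: float = 0.5


@dataclass
class SimulationConfig:
    """Full description of one synthetic movie.

    Defaults correspond to the live TIRF-SIM imaging regime: 40 nm pixels,
    5 s frame interval, 130 nm PSF FWHM.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.04
    frame_interval_s: float = 5.0
    n_frames: int = 60
    psf_fwhm_um: float = 0.13
    noise_gaussian_sd: float = 0.05
    noise_poisson_scale: float = 0.0  # photons per intensity unit; 0 = off
    # post-noise Gaussian applied by the super-resolution reconstruction
    # before export (band-limits the read noise); 0 disables it
    recon_sigma_um: float = 0.08
    mesh_density: float = 0.5
    hole_spec: list[HoleSpec] = field(default_factory=list)
    foci_spec: FociSpec = field(default_factory=FociSpec)
    granule_spec: list[GranuleSpec] = field(default_factory=list)
    burst_spec: list[BurstSpec] = field(default_factory=list)
    footprint_spec: FootprintSpec = field(default_factory=FootprintSpec)
    rng_seed: int = 0

    # rendering constants. The mature central mesh is visually homogeneous
    # and dense: a bright diffuse carpet (mesh_floor) with modest fiber
    # texture riding on it, so clearances are the only dark phase.
    mesh_floor: float = 1.0  # diffuse dense-mesh level
    fiber_texture: float = 0.12  # fiber amplitude above the carpet
    fiber_thickness_px: float = 2.0
    focus_amplitude: float = 1.8
    focus_sigma_um: float = 0.08

    def validate(self) -> None:
        ny, nx = self.image_size_px
        if ny <= 0 or nx <= 0:
            raise ValueError("image_size_px must be positive")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.noise_gaussian_sd < 0 or self.noise_poisson_scale < 0:
            raise ValueError("noise levels must be non-negative")
        if not (0 < self.mesh_density <= 1):
            raise ValueError("mesh_density must lie in (0, 1]")
        if self.foci_spec.mean_lifetime_s <= 0:
            raise ValueError("mean_lifetime_s must be positive")
        if not (0 <= self.foci_spec.censored_fraction <= 1):
            raise ValueError("censored_fraction must lie in [0, 1]")
        self._validate_holes()
        track_ids = set(range(len(self.granule_spec)))
        for b in self.burst_spec:
            if b.track_id not in track_ids:
                raise ValueError(f"burst track_id {b.track_id} has no granule")
            if not (0 <= b.burst_frame < self.n_frames):
                raise ValueError(
                    f"burst_frame {b.burst_frame} outside movie of "
                    f"{self.n_frames} frames"
                )

    def _validate_holes(self) -> None:
        ny, nx = self.image_size_px
        fov_x = nx * self.pixel_size_um
        fov_y = ny * self.pixel_size_um
        for i, h in enumerate(self.hole_spec):
            if h.area_um2 <= 0:
                raise ValueError(f"hole {i}: area must be positive")
            r = h.radius_um
            x, y = h.center_um
            if x - r < 0 or y - r < 0 or x + r > fov_x or y + r > fov_y:
                raise ValueError(
                    f"hole {i} (r={r:.3f} um at {h.center_um}) does not fit in "
                    f"the {fov_x:.2f} x {fov_y:.2f} um field"
                )
        for i, a in enumerate(self.hole_spec):
            for j in range(i + 1, len(self.hole_spec)):
                b = self.hole_spec[j]
                d = math.dist(a.center_um, b.center_um)
                if d < a.radius_um + b.radius_um:
                    raise ValueError(
                        f"holes {i} and {j} overlap "
                        f"(centre distance {d:.3f} um < sum of radii)"
                    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything planted in a synthetic movie, in analysis-ready tables."""

    holes: pd.DataFrame  # frame, hole_id, x_um, y_um, area_um2
    hole_masks: dict[int, np.ndarray]  # hole_id -> static boolean mask
    foci: pd.DataFrame  # focus_id, x_um, y_um, birth_frame, death_frame,
    #                     lifetime_s (continuous truth), censored
    granules: pd.DataFrame  # granule_id, appear_frame, disappear_frame, ...
    bursts: pd.DataFrame  # track_id, burst_frame, amplitude_fold
    footprint: pd.DataFrame  # frame, area_um2

    def holes_in_frame(self, frame: int) -> pd.DataFrame:
        return self.holes[self.holes["frame"] == frame]


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------


def _disk_occupancy(
    center_um: tuple[float, float],
    radius_um: float,
    shape: tuple[int, int],
    pixel_size_um: float,
) -> np.ndarray:
    """Per-pixel coverage fraction of a disk, computed on a 4x subgrid."""
    ny, nx = shape
    cx = center_um[0] / pixel_size_um
    cy = center_um[1] / pixel_size_um
    r = radius_um / pixel_size_um
    # restrict to a bounding box for speed
    x0 = max(0, int(cx - r) - 1)
    x1 = min(nx, int(cx + r) + 2)
    y0 = max(0, int(cy - r) - 1)
    y1 = min(ny, int(cy + r) + 2)
    occ = np.zeros(shape, dtype=float)
    if x1 <= x0 or y1 <= y0:
        return occ
    sub = (np.arange(_SS) + 0.5) / _SS
    ys = (y0 + np.add.outer(np.arange(y1 - y0), sub)).reshape(-1)
    xs = (x0 + np.add.outer(np.arange(x1 - x0), sub)).reshape(-1)
    dy2 = (ys[:, None] - cy) ** 2
    dx2 = (xs[None, :] - cx) ** 2
    inside = (dy2 + dx2) <= r * r
    block = inside.reshape(y1 - y0, _SS, x1 - x0, _SS).mean(axis=(1, 3))
    occ[y0:y1, x0:x1] = block
    return occ


def _gaussian_spot(
    canvas: np.ndarray,
    center_px: tuple[float, float],
    sigma_px: float,
    amplitude: float,
) -> None:
    """Add a 2-D Gaussian bump to ``canvas`` in place (center is (x, y))."""
    ny, nx = canvas.shape
    cx, cy = center_px
    half = int(math.ceil(4 * sigma_px)) + 1
    x0, x1 = max(0, int(cx) - half), min(nx, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(ny, int(cy) + half + 1)
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] += amplitude * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2)
    )


def _segment_intersection(p1, p2, p3, p4):
    """Intersection point of segments p1-p2 and p3-p4, or None."""
    d1 = (p2[0] - p1[0], p2[1] - p1[1])
    d2 = (p4[0] - p3[0], p4[1] - p3[1])
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-12:
        return None
    t = ((p3[0] - p1[0]) * d2[1] - (p3[1] - p1[1]) * d2[0]) / denom
    u = ((p3[0] - p1[0]) * d1[1] - (p3[1] - p1[1]) * d1[0]) / denom
    if 0 <= t <= 1 and 0 <= u <= 1:
        return (p1[0] + t * d1[0], p1[1] + t * d1[1])
    return None


def _draw_segment(canvas: np.ndarray, p1, p2, value: float) -> None:
    """Rasterize a 1-px line (coords are (x, y) in canvas pixels)."""
    from skimage.draw import line

    r0, c0 = int(round(p1[1])), int(round(p1[0]))
    r1, c1 = int(round(p2[1])), int(round(p2[0]))
    rr, cc = line(r0, c0, r1, c1)
    ok = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    canvas[rr[ok], cc[ok]] = np.maximum(canvas[rr[ok], cc[ok]], value)


def _downsample(canvas: np.ndarray) -> np.ndarray:
    ny, nx = canvas.shape
    return canvas.reshape(ny // _SS, _SS, nx // _SS, _SS).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def _footprint_areas(cfg: SimulationConfig) -> np.ndarray:
    fp = cfg.footprint_spec
    t = np.arange(cfg.n_frames) * cfg.frame_interval_s
    return np.minimum(
        fp.initial_area_um2 + fp.spread_rate_um2_per_s * t, fp.plateau_area_um2
    )


def _sample_foci(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw birth/death schedules; returns list of dicts (positions later)."""
    spec = cfg.foci_spec
    dt = cfg.frame_interval_s
    duration = cfg.n_frames * dt
    n_cens = int(round(spec.count * spec.censored_fraction))
    foci = []
    for i in range(spec.count):
        max_uncensored = duration - 3 * dt
        if i < n_cens or max_uncensored <= dt:
            # long-lived focus spanning the whole acquisition
            lifetime = duration * (1.5 + rng.exponential(1.0))
            birth_s, death_s = 0.0, duration
        else:
            lifetime = rng.exponential(spec.mean_lifetime_s)
            # keep the track strictly inside the movie so it is uncensored;
            # redraw the (negligible, for movies >> mean lifetime) tail
            for _ in range(1000):
                if lifetime < max_uncensored:
                    break
                lifetime = rng.exponential(spec.mean_lifetime_s)
            else:
                lifetime = max_uncensored * rng.uniform()
            birth_s = rng.uniform(dt, duration - lifetime - 2 * dt)
            death_s = birth_s + lifetime
        birth_frame = int(np.ceil(birth_s / dt - 1e-9))
        death_frame = int(np.floor(death_s / dt))  # last frame alive
        death_frame = max(death_frame, birth_frame)
        death_frame = min(death_frame, cfg.n_frames - 1)
        foci.append(
            dict(
                focus_id=i,
                birth_frame=birth_frame,
                death_frame=death_frame,
                lifetime_s=lifetime,
                censored=birth_frame == 0 or death_frame == cfg.n_frames - 1,
            )
        )
    return foci


def _place_foci(cfg, rng, foci, hole_list):
    """Assign positions: inside the initial footprint, away from holes and
    from temporally overlapping foci (so linking stays unambiguous)."""
    fp = cfg.footprint_spec
    r_foot = math.sqrt(fp.initial_area_um2 / math.pi) * 0.9
    ny, nx = cfg.image_size_px
    cx = nx * cfg.pixel_size_um / 2
    cy = ny * cfg.pixel_size_um / 2
    min_sep = 0.4  # um between coexisting foci
    placed = []
    for f in foci:
        for _ in range(200):
            rr = r_foot * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            x, y = cx + rr * math.cos(th), cy + rr * math.sin(th)
            ok = all(
                math.dist((x, y), h.center_um) > h.radius_um + 0.2
                for h in hole_list
            )
            if ok:
                for g in placed:
                    overlap = not (
                        f["death_frame"] < g["birth_frame"]
                        or g["death_frame"] < f["birth_frame"]
                    )
                    if overlap and math.dist((x, y), (g["x_um"], g["y_um"])) < min_sep:
                        ok = False
                        break
            if ok:
                break
        f["x_um"], f["y_um"] = x, y
        placed.append(f)
    return placed


def _render_mesh_canvas(cfg: SimulationConfig, rng: np.random.Generator):
    """Static fiber mesh + node blobs at supersampled resolution."""
    ny, nx = cfg.image_size_px
    ss_shape = (ny * _SS, nx * _SS)
    canvas = np.zeros(ss_shape, dtype=float)
    fp = cfg.footprint_spec
    r_foot_um = math.sqrt(fp.plateau_area_um2 / math.pi)
    cx_um = nx * cfg.pixel_size_um / 2
    cy_um = ny * cfg.pixel_size_um / 2
    n_fibers = max(4, int(round(cfg.mesh_density * fp.plateau_area_um2 * 4)))
    scale = _SS / cfg.pixel_size_um  # um -> ss px
    segments = []
    for _ in range(n_fibers):
        rr = r_foot_um * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        x0, y0 = cx_um + rr * math.cos(th), cy_um + rr * math.sin(th)
        ang = rng.uniform(0, math.pi)
        length = rng.uniform(1.0, 4.0)
        dx, dy = math.cos(ang) * length / 2, math.sin(ang) * length / 2
        p1 = ((x0 - dx) * scale, (y0 - dy) * scale)
        p2 = ((x0 + dx) * scale, (y0 + dy) * scale)
        segments.append((p1, p2))
        _draw_segment(canvas, p1, p2, cfg.fiber_texture * rng.uniform(0.8, 1.2))
    # thicken the 1-px skeleton to ~fiber_thickness_px at base resolution
    rad = max(1, int(round(cfg.fiber_thickness_px * _SS / 2)))
    canvas = ndi.grey_dilation(canvas, size=(2 * rad + 1, 2 * rad + 1))
    # node blobs where fibers cross
    n_nodes = 0
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            pt = _segment_intersection(*segments[i], *segments[j])
            if pt is not None and n_nodes < 400:
                _gaussian_spot(canvas, pt, 1.5 * _SS, 0.6 * cfg.fiber_texture)
                n_nodes += 1
    # saturate stacked structures: the mature central mesh is visually
    # homogeneous, without rare hot spots towering over the carpet
    return np.minimum(canvas, 1.3 * cfg.fiber_texture)


def render_mesh_movie(cfg: SimulationConfig) -> tuple[SynapseMovie, GroundTruth]:
    """Render a multi-channel synthetic synapse movie with ground truth.

    Channels produced: ``actin`` always; ``granule`` and ``reporter`` when
    ``granule_spec`` is non-empty.

    Identical ``cfg`` (including ``rng_seed``) yields bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    ny, nx = cfg.image_size_px
    px = cfg.pixel_size_um
    n_frames = cfg.n_frames

    mesh_ss = _render_mesh_canvas(cfg, rng)
    mesh = _downsample(mesh_ss) + cfg.mesh_floor

    # footprint occupancy per frame (soft edge from supersampling)
    areas = _footprint_areas(cfg)
    cx_um, cy_um = nx * px / 2, ny * px / 2
    foot_occ = [
        _disk_occupancy((cx_um, cy_um), math.sqrt(a / math.pi), (ny, nx), px)
        for a in areas
    ]
    footprint_df = pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "area_um2": [(o > 0.5).sum() * px**2 for o in foot_occ],
        }
    )

    # holes: hard carve at pixel resolution. The carved pixel set is the
    # top-k pixels by sub-pixel occupancy with k = ceil(occupancy sum), so
    # the rendered hole area equals the recorded sub-pixel truth to within
    # one pixel, never undershoots it (a hole planted exactly at a decision
    # boundary stays on the permissive side), and the noise-free binarized
    # image recovers the planted pixel set exactly.
    hole_masks: dict[int, np.ndarray] = {}
    hole_rows = []
    for hid, h in enumerate(cfg.hole_spec):
        occ = _disk_occupancy(h.center_um, h.radius_um, (ny, nx), px)
        k = int(np.ceil(occ.sum() - 1e-9))
        order = np.argsort(-occ, axis=None, kind="stable")[:k]
        mask = np.zeros(occ.shape, dtype=bool)
        mask.ravel()[order] = True
        hole_masks[hid] = mask
        area = float(occ.sum() * px**2)
        close = n_frames if h.close_frame is None else h.close_frame
        for t in range(max(0, h.open_frame), min(n_frames, close)):
            hole_rows.append(
                dict(
                    frame=t,
                    hole_id=hid,
                    x_um=h.center_um[0],
                    y_um=h.center_um[1],
                    area_um2=area,
                )
            )
    holes_df = pd.DataFrame(
        hole_rows, columns=["frame", "hole_id", "x_um", "y_um", "area_um2"]
    )

    foci = _sample_foci(cfg, rng)
    foci = _place_foci(cfg, rng, foci, cfg.hole_spec)
    foci_df = pd.DataFrame(
        foci,
        columns=[
            "focus_id",
            "birth_frame",
            "death_frame",
            "lifetime_s",
            "censored",
            "x_um",
            "y_um",
        ],
    )

    sigma_psf = cfg.psf_fwhm_um / 2.355 / px if cfg.psf_fwhm_um > 0 else 0.0
    focus_sigma_px = cfg.focus_sigma_um / px

    actin = np.empty((n_frames, ny, nx), dtype=float)
    for t in range(n_frames):
        frame = mesh * (foot_occ[t] > 0.5)
        for hid, h in enumerate(cfg.hole_spec):
            close = n_frames if h.close_frame is None else h.close_frame
            if h.open_frame <= t < close:
                frame = frame * ~hole_masks[hid]
        for f in foci:
            if f["birth_frame"] <= t <= f["death_frame"]:
                _gaussian_spot(
                    frame,
                    (f["x_um"] / px, f["y_um"] / px),
                    focus_sigma_px,
                    cfg.focus_amplitude,
                )
        actin[t] = frame

    channels = {"actin": actin}

    granule_rows = []
    if cfg.granule_spec:
        granule = np.zeros((n_frames, ny, nx), dtype=float)
        reporter = np.zeros((n_frames, ny, nx), dtype=float)
        bursts_by_track: dict[int, list[BurstSpec]] = {}
        for b in cfg.burst_spec:
            bursts_by_track.setdefault(b.track_id, []).append(b)
        for gid, g in enumerate(cfg.granule_spec):
            granule_rows.append(
                dict(
                    granule_id=gid,
                    appear_frame=g.appear_frame,
                    disappear_frame=g.disappear_frame,
                    x_um=g.center_um[0],
                    y_um=g.center_um[1],
                    diameter_um=g.diameter_um,
                )
            )
            sig = max(g.diameter_um / 2.355, 0.05) / px
            cpx = (g.center_um[0] / px, g.center_um[1] / px)
            for t in range(max(0, g.appear_frame), min(n_frames, g.disappear_frame)):
                _gaussian_spot(granule[t], cpx, sig, 1.0)
                amp = 0.2  # dim reporter baseline on each granule
                for b in bursts_by_track.get(gid, []):
                    if t >= b.burst_frame:
                        dt_s = (t - b.burst_frame) * cfg.frame_interval_s
                        amp += 0.2 * b.amplitude_fold * math.exp(-dt_s / 10.0)
                _gaussian_spot(reporter[t], cpx, sig, amp)
        channels["granule"] = granule
        channels["reporter"] = reporter

    bursts_df = pd.DataFrame(
        [vars(b) for b in cfg.burst_spec],
        columns=["track_id", "burst_frame", "amplitude_fold"],
    )
    granules_df = pd.DataFrame(
        granule_rows,
        columns=[
            "granule_id",
            "appear_frame",
            "disappear_frame",
            "x_um",
            "y_um",
            "diameter_um",
        ],
    )

    for name, stack in channels.items():
        if sigma_psf > 0:
            for t in range(n_frames):
                stack[t] = ndi.gaussian_filter(stack[t], sigma_psf)
        if cfg.noise_poisson_scale > 0:
            scale = cfg.noise_poisson_scale
            stack[:] = rng.poisson(np.clip(stack, 0, None) * scale) / scale
        if cfg.noise_gaussian_sd > 0:
            stack += rng.normal(0.0, cfg.noise_gaussian_sd, size=stack.shape)
        if cfg.recon_sigma_um > 0:
            s = cfg.recon_sigma_um / px
            for t in range(n_frames):
                stack[t] = ndi.gaussian_filter(stack[t], s)

    movie = SynapseMovie(
        channels=channels,
        pixel_size_um=px,
        frame_interval_s=cfg.frame_interval_s,
        metadata={"rng_seed": cfg.rng_seed},
    )
    truth = GroundTruth(
        holes=holes_df,
        hole_masks=hole_masks,
        foci=foci_df,
        granules=granules_df,
        bursts=bursts_df,
        footprint=footprint_df,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# reporter intensity traces
# ---------------------------------------------------------------------------


def render_trace_set(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-track reporter-intensity traces with degranulation labels.

    One trace per entry of ``cfg.granule_spec`` (track ids are positional).
    Non-burst tracks are a constant baseline plus Gaussian noise of SD
    ``cfg.noise_gaussian_sd``; burst tracks additionally carry a step of
    ``amplitude_fold`` x baseline at ``burst_frame`` that decays with a 10 s
    time constant (a pHluorin-like flash).

    Returns ``(traces, labels)``: ``traces`` has columns
    ``track_id, frame, time_s, intensity``; ``labels`` has
    ``track_id, is_burst, burst_frame``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    n_tracks = len(cfg.granule_spec)
    dt = cfg.frame_interval_s
    bursts = {b.track_id: b for b in cfg.burst_spec if b.amplitude_fold > 0}
    rows = []
    labels = []
    baseline = 1.0
    for tid in range(n_tracks):
        noise = rng.normal(0.0, cfg.noise_gaussian_sd, size=cfg.n_frames)
        trace = baseline + noise
        b = bursts.get(tid)
        if b is not None:
            t = np.arange(cfg.n_frames)
            step = np.where(
                t >= b.burst_frame,
                b.amplitude_fold * baseline
                * np.exp(-np.maximum(t - b.burst_frame, 0) * dt / 10.0),
                0.0,
            )
            trace = trace + step
        for t in range(cfg.n_frames):
            rows.append(
                dict(track_id=tid, frame=t, time_s=t * dt, intensity=trace[t])
            )
        labels.append(
            dict(
                track_id=tid,
                is_burst=b is not None,
                burst_frame=b.burst_frame if b is not None else -1,
            )
        )
    traces = pd.DataFrame(rows, columns=["track_id", "frame", "time_s", "intensity"])
    labels_df = pd.DataFrame(labels, columns=["track_id", "is_burst", "burst_frame"])
    return traces, labels_df


# ---------------------------------------------------------------------------
# convenience constructors
# ---------------------------------------------------------------------------


def random_hole_specs(
    n: int,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    area_range_um2: tuple[float, float] = (0.06, 1.0),
    min_gap_um: float = 0.3,
) -> list[HoleSpec]:
    """Draw ``n`` mutually non-overlapping holes inside the cell footprint.

    Areas are log-normal (median 0.15 um^2, sigma 0.8 in log space) clipped
    to ``area_range_um2`` — a broad right-skewed distribution consistent
    with clearances spanning ~0.01-3 um^2.
    """
    fp = cfg.footprint_spec
    ny, nx = cfg.image_size_px
    cx = nx * cfg.pixel_size_um / 2
    cy = ny * cfg.pixel_size_um / 2
    r_foot = math.sqrt(fp.plateau_area_um2 / math.pi)
    holes: list[HoleSpec] = []
    attempts = 0
    while len(holes) < n and attempts < 5000:
        attempts += 1
        area = float(
            np.clip(0.15 * math.exp(rng.normal(0, 0.8)), *area_range_um2)
        )
        r = math.sqrt(area / math.pi)
        rr = (r_foot - r - 0.3) * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        x, y = cx + rr * math.cos(th), cy + rr * math.sin(th)
        cand = HoleSpec((x, y), area)
        if all(
            math.dist(cand.center_um, h.center_um)
            > cand.radius_um + h.radius_um + min_gap_um
            for h in holes
        ):
            holes.append(cand)
    if len(holes) < n:
        raise RuntimeError(f"could only place {len(holes)}/{n} holes")
    return holes


def movie_snr(movie: SynapseMovie, truth: GroundTruth, frame: int = 0) -> float:
    """Planted-structure contrast over background noise SD.

    Contrast = mean actin intensity in the mesh (footprint minus holes)
    minus mean intensity inside planted holes; noise SD is estimated outside
    the footprint, where the noiseless image is zero.
    """
    img = movie.channels["actin"][frame]
    px = movie.pixel_size_um
    ny, nx = img.shape
    a = truth.footprint.loc[truth.footprint["frame"] == frame, "area_um2"].iloc[0]
    r = math.sqrt(a / math.pi) / px
    yy, xx = np.mgrid[0:ny, 0:nx]
    dist = np.hypot(yy - ny / 2, xx - nx / 2)
    inside = dist < 0.9 * r
    outside = dist > 1.3 * r
    hole_mask = np.zeros((ny, nx), dtype=bool)
    for hid, m in truth.hole_masks.items():
        active = (
            (truth.holes["hole_id"] == hid) & (truth.holes["frame"] == frame)
        ).any()
        if active:
            hole_mask |= m
    mesh_mean = img[inside & ~hole_mask].mean()
    hole_mean = img[hole_mask].mean() if hole_mask.any() else 0.0
    noise_sd = img[outside].std()
    if noise_sd == 0:
        return math.inf
    return float((mesh_mean - hole_mean) / noise_sd)
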