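"""File I/O: TIFF movies, ROI geometry, run configuration.

TIFF reading honors ImageJ-dialect pixel-size metadata, but an explicit
calibration in the run configuration always wins (a warning is logged on
conflict). All tabular outputs are CSV with calibrated units in the column
names.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import SynapseMovie
from .synthdata import (
    BurstSpec,
    FociSpec,
    FootprintSpec,
    GranuleSpec,
    GroundTruth,
    HoleSpec,
    SimulationConfig,
)

log = logging.getLogger("synmesh")


def read_movie(
    paths: dict[str, str | Path],
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> SynapseMovie:
    """Load a multi-channel movie from one TIFF stack per channel role.

    ``paths`` maps channel role (actin, granule, ...) to a TIFF path. Pixel
    size is taken from the config when given, else from ImageJ metadata of
    the first stack; a conflict logs a warning and the config wins.
    """
    channels = {}
    meta_px = None
    meta_dt = None
    for role, path in paths.items():
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            if arr.ndim == 2:
                arr = arr[None]
            channels[role] = arr.astype(float)
            try:
                res = tf.pages[0].tags["XResolution"].value
                unit = (tf.imagej_metadata or {}).get("unit", "")
                if unit in ("um", "micron", "µm") and res[0]:
                    meta_px = res[1] / res[0]
            except (KeyError, TypeError):
                pass
            if tf.imagej_metadata and "finterval" in tf.imagej_metadata:
                meta_dt = float(tf.imagej_metadata["finterval"])
    if pixel_size_um is None:
        pixel_size_um = meta_px
    elif meta_px is not None and not np.isclose(meta_px, pixel_size_um):
        log.warning(
            "pixel size: config %.4g um overrides TIFF metadata %.4g um",
            pixel_size_um,
            meta_px,
        )
    if pixel_size_um is None:
        raise ValueError("pixel size unknown: give pixel_size_um in the config")
    if frame_interval_s is None:
        frame_interval_s = meta_dt
    if frame_interval_s is None:
        raise ValueError(
            "frame interval unknown: give frame_interval_s in the config"
        )
    return SynapseMovie(
        channels=channels,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
    )


def write_movie(movie: SynapseMovie, out_dir: str | Path, stem: str = "movie"):
    """Write each channel as an ImageJ-dialect multi-page TIFF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for role, stack in movie.channels.items():
        path = out_dir / f"{stem}_{role}.tif"
        res = 1.0 / movie.pixel_size_um
        tifffile.imwrite(
            path,
            stack.astype(np.float32),
            imagej=True,
            resolution=(res, res),
            metadata={
                "unit": "um",
                "finterval": movie.frame_interval_s,
                "axes": "TYX",
            },
        )
        written.append(path)
    return written


def write_ground_truth(truth: GroundTruth, out_dir: str | Path):
    """Ground truth as CSV tables plus a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("holes", "foci", "granules", "bursts", "footprint"):
        getattr(truth, name).to_csv(out_dir / f"truth_{name}.csv", index=False)
    summary = {
        "n_holes": int(truth.holes["hole_id"].nunique())
        if len(truth.holes)
        else 0,
        "n_foci": int(len(truth.foci)),
        "n_granules": int(len(truth.granules)),
        "n_bursts": int(len(truth.bursts)),
    }
    (out_dir / "truth_summary.json").write_text(json.dumps(summary, indent=2))


def load_roi(path: str | Path) -> np.ndarray:
    """Load a polygonal ROI from a JSON file.

    Schema: ``{"polygon_um": [[x, y], ...]}``.
    """
    data = json.loads(Path(path).read_text())
    if "polygon_um" not in data:
        raise ValueError("ROI JSON must contain 'polygon_um'")
    return np.asarray(data["polygon_um"], dtype=float)


def load_line(path: str | Path) -> np.ndarray:
    """Load a polyline (``{"line_um": [[x, y], ...]}``) from JSON."""
    data = json.loads(Path(path).read_text())
    if "line_um" not in data:
        raise ValueError("line JSON must contain 'line_um'")
    return np.asarray(data["line_um"], dtype=float)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative description of a pipeline run (YAML-serializable)."""

    inputs: dict[str, str] = field(default_factory=dict)  # role -> path
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    out_dir: str = "out"
    seed: int = 0
    stages: list[str] = field(default_factory=list)
    params: dict[str, dict] = field(default_factory=dict)  # stage -> kwargs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from plain YAML/JSON data."""
    data = dict(data)
    if "hole_spec" in data:
        data["hole_spec"] = [
            HoleSpec(tuple(h["center_um"]), h["area_um2"],
                     h.get("open_frame", 0), h.get("close_frame"))
            for h in data["hole_spec"]
        ]
    if "foci_spec" in data:
        data["foci_spec"] = FociSpec(**data["foci_spec"])
    if "granule_spec" in data:
        data["granule_spec"] = [
            GranuleSpec(g["appear_frame"], g["disappear_frame"],
                        tuple(g["center_um"]), g.get("diameter_um", 0.3))
            for g in data["granule_spec"]
        ]
    if "burst_spec" in data:
        data["burst_spec"] = [BurstSpec(**b) for b in data["burst_spec"]]
    if "footprint_spec" in data:
        data["footprint_spec"] = FootprintSpec(**data["footprint_spec"])
    if "image_size_px" in data:
        data["image_size_px"] = tuple(data["image_size_px"])
    return SimulationConfig(**data)
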