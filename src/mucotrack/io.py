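"""File formats: multi-page TIFF stacks, trajectory/detection CSV, YAML config.

All tabular artifacts are plain CSV for inspectability; reports are
JSON; configuration is YAML. Trajectory CSV columns are
``particle, frame, x, y`` plus a ``units`` column; detection CSV adds
``mass, size, ecc``.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ImageStack, Trajectory
from .tracking import Detection

__all__ = [
    "write_image_stack",
    "read_image_stack",
    "tracks_to_dataframe",
    "dataframe_to_tracks",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_detections_csv",
    "write_json",
    "load_config_yaml",
    "dump_config_yaml",
]

logger = logging.getLogger(__name__)


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF with calibration in the metadata."""
    meta = {
        "frame_rate_hz": stack.frame_rate,
        "pixel_size_um": stack.pixel_size,
        "seed": stack.metadata.get("seed"),
    }
    tifffile.imwrite(str(path), stack.frames, photometric="minisblack", metadata=meta)


def _read_tiff_metadata(path: Path) -> dict:
    try:
        with tifffile.TiffFile(str(path)) as tf:
            meta = tf.shaped_metadata
            if meta:
                return dict(meta[0])
    except Exception:  # pragma: no cover - malformed metadata is non-fatal
        pass
    return {}


def read_image_stack(
    path: str | Path,
    frame_rate: float | None = None,
    pixel_size: float | None = None,
) -> ImageStack:
    """Load a multi-page TIFF or a directory of per-frame images.

    Directory frames are read in lexicographic filename order. Embedded
    TIFF calibration metadata is used when present; otherwise
    ``frame_rate`` and ``pixel_size`` must be supplied explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no image stack at {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if len(files) < 2:
            raise ValueError(f"directory {path} holds fewer than 2 frame images")
        frames = [iio.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame sizes in {path}: {sorted(shapes)}")
        data = np.stack(frames)
        meta: dict = {}
    else:
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            raise ValueError(f"{path} holds a single frame, not a stack")
        meta = _read_tiff_metadata(path)

    fr = frame_rate if frame_rate is not None else meta.get("frame_rate_hz")
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if fr is None or px is None:
        raise ValueError(
            "calibration missing: supply frame_rate (Hz) and pixel_size (um/px) "
            "explicitly when the file carries no metadata"
        )
    logger.info("read %d frames of %s from %s", data.shape[0], data.shape[1:], path)
    return ImageStack(frames=data, frame_rate=float(fr), pixel_size=float(px), metadata=meta)


def tracks_to_dataframe(tracks: Sequence[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into a tidy (particle, frame, x, y, units) table."""
    rows = []
    for t in tracks:
        rows.append(
            pd.DataFrame(
                {
                    "particle": t.particle_id,
                    "frame": t.frames,
                    "x": t.x,
                    "y": t.y,
                    "units": t.units,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["particle", "frame", "x", "y", "units"])
    return pd.concat(rows, ignore_index=True)


def dataframe_to_tracks(df: pd.DataFrame, frame_rate: float) -> list[Trajectory]:
    """Rebuild trajectories from a tidy table, validating frame order."""
    tracks = []
    for pid, grp in df.groupby("particle", sort=True):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(
                f"non-monotone frames for particle {pid}: trajectory invariant violated"
            )
        units = str(grp["units"].iloc[0]) if "units" in grp else "um"
        tracks.append(
            Trajectory(
                particle_id=int(pid),
                frames=frames,
                x=grp["x"].to_numpy(),
                y=grp["y"].to_numpy(),
                frame_rate=frame_rate,
                units=units,
            )
        )
    return tracks


def write_trajectories_csv(tracks: Sequence[Trajectory], path: str | Path) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def read_trajectories_csv(path: str | Path, frame_rate: float) -> list[Trajectory]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed trajectory CSV {path}: {err}") from err
    required = {"particle", "frame", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"trajectory CSV {path} lacks columns {sorted(required - set(df.columns))}"
        )
    return dataframe_to_tracks(df, frame_rate)


def write_detections_csv(
    detections: Sequence[Sequence[Detection]], path: str | Path
) -> None:
    rows = [
        {"frame": d.frame, "x": d.x, "y": d.y, "mass": d.mass, "size": d.size, "ecc": d.ecc}
        for per_frame in detections
        for d in per_frame
    ]
    pd.DataFrame(rows, columns=["frame", "x", "y", "mass", "size", "ecc"]).to_csv(
        path, index=False
    )


def write_json(obj: dict, path: str | Path) -> None:
    os.makedirs(Path(path).parent, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def dump_config_yaml(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
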