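"""Shared containers: calibrated image stacks and particle trajectories.

Coordinate conventions used throughout the package:

* images are ``(T, H, W)`` arrays, pixel-centered, origin at the top-left;
  ``x`` is the column coordinate, ``y`` the row coordinate;
* frame indices are 0-based and strictly increasing within a trajectory;
* positions are either in pixels (``units="px"``) or micrometres
  (``units="um"``); conversion multiplies by the pixel size in um/px.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageStack", "Trajectory"]


@dataclass
class ImageStack:
    """A calibrated time-lapse image sequence.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity data; any integer or float dtype.
    frame_rate : float
        Acquisition rate in Hz.
    pixel_size : float
        Lateral calibration in um/pixel.
    metadata : dict
        Free-form provenance (seed, simulation config, ...).
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("an image stack needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Elapsed time between first and last frame, seconds."""
        return (self.n_frames - 1) / self.frame_rate


@dataclass
class Trajectory:
    """One particle's ordered path through a movie.

    ``frames`` must be strictly increasing; gaps are allowed (they arise
    from linking with memory) and are respected by lag-based statistics.
    """

    particle_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    units: str = "um"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.frames.shape == self.x.shape == self.y.shape):
            raise ValueError("frames, x and y must have equal length")
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(
                f"frame indices must be strictly increasing (particle {self.particle_id})"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.units not in ("um", "px"):
            raise ValueError(f"units must be 'um' or 'px', got {self.units!r}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """(last frame - first frame) / frame rate, in seconds."""
        return (self.frames[-1] - self.frames[0]) / self.frame_rate

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) positions."""
        return np.column_stack([self.x, self.y])

    def to_um(self, pixel_size: float) -> "Trajectory":
        """Return a copy calibrated to micrometres."""
        if self.units == "um":
            return replace(self)
        if pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        return replace(self, x=self.x * pixel_size, y=self.y * pixel_size, units="um")
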