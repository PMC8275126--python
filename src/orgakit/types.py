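"""Core data containers shared across the analysis stages.

All interchange happens in physical units: positions and sizes in
micrometres, times in hours (frame intervals in minutes where noted).
Pixels appear only inside image operations; the pixel centre sits at
integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "IntensityTrace",
    "ImageFrame",
    "ImageStack",
    "Detection",
    "Track",
    "GroundTruth",
]

_UNIFORM_TOL = 1e-6


@dataclass
class IntensityTrace:
    """One aggregate's fluorescence time course.

    ``intensity_raw`` is the per-frame sum of fluorescence of the maximum
    projection (arbitrary units); ``intensity_norm`` is only present after
    min-max normalisation and then lies in [0, 1].
    """

    id: str
    times_h: np.ndarray
    intensity_raw: np.ndarray
    intensity_norm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.intensity_raw = np.asarray(self.intensity_raw, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.size < 5:
            raise ValueError("trace needs at least 5 frames")
        if self.intensity_raw.shape != self.times_h.shape:
            raise ValueError("times and intensities must have equal length")
        dt = np.diff(self.times_h)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(dt) > _UNIFORM_TOL:
            raise ValueError("frame spacing must be uniform")
        if self.intensity_norm is not None:
            self.intensity_norm = np.asarray(self.intensity_norm, dtype=float)

    @property
    def frame_interval_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])

    @property
    def n_frames(self) -> int:
        return int(self.times_h.size)


@dataclass
class ImageFrame:
    """A single 2D grey-level image with physical pixel calibration."""

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "fluorescence"  # or "bright_field"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class ImageStack:
    """A calibrated time-lapse stack, (T, Y, X) or (T, Z, Y, X).

    ``origin_um`` maps voxel index 0 of each spatial axis to a physical
    coordinate (x, y, z); voxels are isotropic at ``pixel_size_um``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_min: Optional[float] = None
    channel: str = "fluorescence"
    origin_um: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("stack must be (T, Y, X) or (T, Z, Y, X)")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 4

    def times_h(self) -> np.ndarray:
        if self.frame_interval_min is None:
            raise ValueError("stack has no frame interval calibration")
        return np.arange(self.n_frames) * self.frame_interval_min / 60.0


@dataclass(frozen=True)
class Detection:
    """A point observation in physical coordinates."""

    frame: int
    t_h: float
    x_um: float
    y_um: float
    z_um: float = 0.0
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame must be >= 0")
        for v in (self.x_um, self.y_um, self.z_um, self.t_h):
            if not np.isfinite(v):
                raise ValueError("coordinates must be finite")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x_um, self.y_um, self.z_um])


@dataclass
class Track:
    """An ordered chain of detections sharing one identity.

    Frames are strictly increasing; the nearest-neighbour linker emits
    contiguous tracks (no gaps), while simulated tracks may skip frames
    when observations were dropped.
    """

    id: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.detections) < 2:
            raise ValueError("track needs at least 2 detections")
        frames = [d.frame for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def times_h(self) -> np.ndarray:
        return np.array([d.t_h for d in self.detections])

    def positions(self) -> np.ndarray:
        """(n, 3) array of positions in micrometres."""
        return np.array([[d.x_um, d.y_um, d.z_um] for d in self.detections])

    def path_length_um(self) -> float:
        steps = np.diff(self.positions(), axis=0)
        return float(np.sqrt((steps**2).sum(axis=1)).sum())

    def duration_h(self) -> float:
        return float(self.detections[-1].t_h - self.detections[0].t_h)

    def frame_interval_min(self) -> float:
        """Native frame interval, from consecutive-frame detection pairs."""
        f = self.frames
        t = self.times_h
        consec = np.flatnonzero(np.diff(f) == 1)
        if consec.size == 0:
            # fall back to per-frame spacing implied by any gap
            df = np.diff(f)
            return float(np.median(np.diff(t) / df) * 60.0)
        return float(np.median(t[consec + 1] - t[consec]) * 60.0)


@dataclass
class GroundTruth:
    """Generator-side labels for downstream verification.

    Only the fields relevant to the generating operation are populated.
    """

    true_onsets_h: Optional[np.ndarray] = None
    domain_labels: Optional[np.ndarray] = None
    domain_areas_um2: Optional[np.ndarray] = None
    domain_perimeters_um: Optional[np.ndarray] = None
    domain_centers_um: Optional[np.ndarray] = None
    organoid_area_um2: Optional[float] = None
    track_classes: Optional[dict[int, str]] = None  # id -> outward|inward
    true_positions: Optional[dict[int, np.ndarray]] = None  # id -> (n, 4) frame,x,y,z
    true_speed_um_per_min: Optional[float] = None
    true_D_um2_per_min: Optional[float] = None
    switch_time_h: Optional[float] = None


def tracks_to_frames(tracks: Sequence[Track]) -> list[list[Detection]]:
    """Scatter track detections into per-frame lists (linker input layout)."""
    if not tracks:
        return []
    last = max(int(t.frames[-1]) for t in tracks)
    frames: list[list[Detection]] = [[] for _ in range(last + 1)]
    for tr in tracks:
        for d in tr.detections:
            frames[d.frame].append(d)
    return frames
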