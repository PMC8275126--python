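"""Radial directionality of tracks relative to the organoid centre.

A track is outward when its end is farther from the centre than its start
by more than a deadband, inward when closer, static otherwise. Angular
histograms bin each track's mean angle between step vectors and the local
outward radial direction, separately per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .types import Detection, Track

__all__ = [
    "CenterTrajectory",
    "estimate_center",
    "classify_track",
    "summarize_fractions",
    "direction_histogram",
    "analyze_directionality",
    "DirectionalityResult",
]

DEFAULT_DEADBAND_UM = 2.0


@dataclass
class CenterTrajectory:
    """Per-frame organoid centre (x, y, z in micrometres)."""

    frames: np.ndarray
    centers_um: np.ndarray  # (n_frames, 3)

    def at(self, frame: int) -> np.ndarray:
        i = np.searchsorted(self.frames, frame)
        i = min(max(i, 0), len(self.frames) - 1)
        if self.frames[i] != frame and i > 0 and abs(self.frames[i - 1] - frame) < abs(self.frames[i] - frame):
            i -= 1
        return self.centers_um[i]

    @classmethod
    def constant(cls, center_um, frames) -> "CenterTrajectory":
        frames = np.asarray(frames, dtype=int)
        return cls(frames=frames, centers_um=np.tile(np.asarray(center_um, float), (len(frames), 1)))


def estimate_center(
    frames: list[list[Detection]],
    smooth_window: int = 5,
    constant: bool = False,
) -> CenterTrajectory:
    """Centre trajectory from per-frame detection centroids.

    Centroids are smoothed with a centered moving average; an empty frame
    carries the previous centre forward with a warning. ``constant=True``
    collapses to the global mean centre for all frames.
    """
    raw = []
    prev = None
    for f, dets in enumerate(frames):
        if dets:
            prev = np.array([[d.x_um, d.y_um, d.z_um] for d in dets]).mean(axis=0)
        elif prev is None:
            raise ValueError("first frame has no detections")
        else:
            warnings.warn(f"frame {f} empty; carrying previous centre", stacklevel=2)
        raw.append(prev.copy())
    centers = np.array(raw)
    idx = np.arange(len(frames))
    if constant:
        return CenterTrajectory.constant(centers.mean(axis=0), idx)
    if smooth_window > 1:
        kernel = np.ones(smooth_window)
        den = np.convolve(np.ones(len(centers)), kernel, mode="same")
        centers = np.stack(
            [np.convolve(centers[:, k], kernel, mode="same") / den for k in range(3)], axis=1
        )
    return CenterTrajectory(frames=idx, centers_um=centers)


def net_radial_displacement(track: Track, centre: CenterTrajectory) -> float:
    """Signed change in distance to centre between track start and end (um)."""
    d0, d1 = track.detections[0], track.detections[-1]
    r0 = np.linalg.norm(d0.position - centre.at(d0.frame))
    r1 = np.linalg.norm(d1.position - centre.at(d1.frame))
    return float(r1 - r0)


def classify_track(
    track: Track, centre: CenterTrajectory, deadband_um: float = DEFAULT_DEADBAND_UM
) -> str:
    """outward / inward / static by net radial displacement vs the deadband."""
    net = net_radial_displacement(track, centre)
    if net > deadband_um:
        return "outward"
    if net < -deadband_um:
        return "inward"
    return "static"


def summarize_fractions(classes: list[str]) -> dict:
    """Class fractions with exact binomial 95% confidence intervals."""
    if not classes:
        raise ValueError("no classified tracks")
    n = len(classes)
    out = {}
    for cls in ("outward", "inward", "static"):
        k = sum(c == cls for c in classes)
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95)
        out[f"{cls}_fraction"] = k / n
        out[f"{cls}_ci95"] = (float(ci.low), float(ci.high))
    out["n"] = n
    return out


def mean_step_angle_deg(track: Track, centre: CenterTrajectory) -> float:
    """Mean angle (degrees) between step vectors and the outward radial
    direction at each step's start; NaN if no informative steps."""
    pos = track.positions()
    frames = track.frames
    angles = []
    for i in range(len(pos) - 1):
        step = pos[i + 1] - pos[i]
        radial = pos[i] - centre.at(int(frames[i]))
        ns, nr = np.linalg.norm(step), np.linalg.norm(radial)
        if ns > 0 and nr > 0:
            cosang = np.clip(step @ radial / (ns * nr), -1.0, 1.0)
            angles.append(np.degrees(np.arccos(cosang)))
    return float(np.mean(angles)) if angles else float("nan")


def direction_histogram(
    tracks: list[Track],
    centre: CenterTrajectory,
    n_bins: int = 18,
    deadband_um: float = DEFAULT_DEADBAND_UM,
) -> dict:
    """Angular histograms of per-track mean step angles, split by class.

    Bins cover [0, 180] degrees; counts are per-track (one mean angle per
    track) and emitted separately for outward- and inward-classified
    tracks.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    angles = {"outward": [], "inward": []}
    for t in tracks:
        cls = classify_track(t, centre, deadband_um)
        if cls in angles:
            a = mean_step_angle_deg(t, centre)
            if np.isfinite(a):
                angles[cls].append(a)
    return {
        "bin_edges_deg": edges,
        "count_outward": np.histogram(angles["outward"], bins=edges)[0],
        "count_inward": np.histogram(angles["inward"], bins=edges)[0],
    }


@dataclass
class DirectionalityResult:
    per_track: list[dict]
    summary: dict
    histogram: dict


def analyze_directionality(
    tracks: list[Track],
    centre: CenterTrajectory | None = None,
    deadband_um: float = DEFAULT_DEADBAND_UM,
    n_bins: int = 18,
) -> DirectionalityResult:
    """Full directionality analysis of a track set."""
    from .types import tracks_to_frames

    if centre is None:
        centre = estimate_center(tracks_to_frames(tracks))
    per_track = []
    classes = []
    for t in tracks:
        cls = classify_track(t, centre, deadband_um)
        classes.append(cls)
        per_track.append(
            {
                "id": t.id,
                "net_radial_um": net_radial_displacement(t, centre),
                "class": cls,
                "mean_angle_deg": mean_step_angle_deg(t, centre),
            }
        )
    return DirectionalityResult(
        per_track=per_track,
        summary=summarize_fractions(classes),
        histogram=direction_histogram(tracks, centre, n_bins, deadband_um),
    )
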