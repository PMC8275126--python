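"""Reporter-expression onset detection from fluorescence time courses.

The onset of a trace is the time of the global maximum of the first
derivative of its (optionally smoothed) normalized intensity. Derivatives
use central differences on the uniform frame grid, one-sided at the ends;
ties break to the earliest frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import ImageStack, IntensityTrace

__all__ = [
    "OnsetResult",
    "summarize_frame",
    "normalize_trace",
    "detect_onset",
    "summarize_onsets",
]


@dataclass(frozen=True)
class OnsetResult:
    """Onset call for one trace."""

    trace_id: str
    onset_h: float
    derivative_peak: float  # normalized units per hour
    smoothed: bool
    window: int
    censored: bool = False  # derivative maximum at the final frame


def summarize_frame(stack: ImageStack, trace_id: str = "stack") -> IntensityTrace:
    """Collapse a calibrated stack to one intensity trace.

    Per frame: maximum intensity projection over z (identity for 2D
    time-lapse), then sum over all pixels.
    """
    if stack.frame_interval_min is None:
        raise ValueError("stack lacks frame-interval calibration")
    if stack.n_frames < 5:
        raise ValueError("need at least 5 frames for a trace")
    data = stack.data
    if stack.is_3d:
        data = data.max(axis=1)
    raw = data.reshape(stack.n_frames, -1).sum(axis=1)
    return IntensityTrace(id=trace_id, times_h=stack.times_h(), intensity_raw=raw)


def normalize_trace(trace: IntensityTrace) -> IntensityTrace:
    """Min-max normalize the raw intensity to [0, 1].

    Affine transforms a*x + b (a > 0) of the input produce identical
    output; a constant trace is degenerate and refused.
    """
    raw = trace.intensity_raw
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        raise ValueError(f"trace {trace.id!r} is constant; normalization undefined")
    return IntensityTrace(
        id=trace.id,
        times_h=trace.times_h,
        intensity_raw=raw,
        intensity_norm=(raw - lo) / (hi - lo),
    )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; shorter effective window at the edges."""
    if window == 1:
        return y.astype(float)
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return num / den


def first_derivative(y: np.ndarray, dt_h: float) -> np.ndarray:
    """Central differences on a uniform grid, one-sided at the ends."""
    return np.gradient(y, dt_h)


def detect_onset(trace: IntensityTrace, smooth_window: int = 3) -> OnsetResult:
    """Onset = time of the global first-derivative maximum.

    ``smooth_window`` frames of centered moving average are applied before
    differentiation (1 disables smoothing; must be odd). A maximum at the
    final frame is flagged censored: the true onset may lie beyond the
    movie.
    """
    if trace.intensity_norm is None:
        raise ValueError("trace must be normalized first (normalize_trace)")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    y = _moving_average(trace.intensity_norm, smooth_window)
    deriv = first_derivative(y, trace.frame_interval_h)
    idx = int(np.argmax(deriv))  # argmax takes the earliest tie
    return OnsetResult(
        trace_id=trace.id,
        onset_h=float(trace.times_h[idx]),
        derivative_peak=float(deriv[idx]),
        smoothed=smooth_window > 1,
        window=smooth_window,
        censored=idx == trace.n_frames - 1,
    )


def summarize_onsets(results: list[OnsetResult]) -> dict:
    """Cohort mean and standard error over non-censored onsets."""
    onsets = np.array([r.onset_h for r in results if not r.censored])
    if onsets.size == 0:
        raise ValueError("all onsets censored; cohort summary undefined")
    n = int(onsets.size)
    if n == 1:
        warnings.warn("single onset: SEM undefined, reporting 0", stacklevel=2)
        sem = 0.0
    else:
        sem = float(onsets.std(ddof=1) / np.sqrt(n))
    return {"mean_h": float(onsets.mean()), "sem_h": sem, "n": n}
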