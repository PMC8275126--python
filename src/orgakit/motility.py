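"""Mean-squared-displacement and velocity-autocorrelation analysis.

Time-averaged MSD per track, pair-count-weighted ensemble averaging, a
constrained fit of MSD(tau) = 2*dim*D*tau + (v*tau)^2 with regime
classification, normalized velocity autocorrelation, and a
persistence-based estimator for the diffusive-to-directed switch time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .types import Track

__all__ = [
    "MSDResult",
    "VACResult",
    "MotionFit",
    "compute_msd",
    "ensemble_msd",
    "fit_motion_model",
    "velocity_autocorrelation",
    "ensemble_vac",
    "crop_track",
    "estimate_switch_time",
]

DEFAULT_MAX_LAG_FRACTION = 0.25
REGIME_DIFFUSIVE_MAX = 0.25  # quadratic share of MSD at window end
REGIME_DIRECTED_MIN = 0.75


@dataclass
class MotionFit:
    D_um2_per_min: float
    v_um_per_min: float
    regime: str  # diffusive | directed | mixed | undetermined
    window: tuple[int, int]  # first/last lag index fitted


@dataclass
class MSDResult:
    lags_min: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    fit: Optional[MotionFit] = None


@dataclass
class VACResult:
    lags_min: np.ndarray
    vac: np.ndarray
    n_pairs: np.ndarray


def _positions_by_frame(track: Track) -> tuple[np.ndarray, np.ndarray, float]:
    frames = track.frames
    pos = track.positions()
    dt_min = track.frame_interval_min()
    return frames, pos, dt_min


def compute_msd(track: Track, max_lag_fraction: float = DEFAULT_MAX_LAG_FRACTION) -> MSDResult:
    """Time-averaged MSD of one track.

    For each lag of ell frames up to floor(max_lag_fraction * (len - 1)),
    the mean of |r(t + ell) - r(t)|^2 over every valid start t. Frame gaps
    (dropped observations) simply contribute no pairs at affected lags.
    """
    if len(track) < 4:
        raise ValueError("track shorter than 4 detections")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    frames, pos, dt_min = _positions_by_frame(track)
    max_lag = int(np.floor(max_lag_fraction * (len(track) - 1)))
    max_lag = max(max_lag, 1)

    msd = np.zeros(max_lag + 1)
    n_pairs = np.zeros(max_lag + 1, dtype=int)
    n_pairs[0] = len(track)
    contiguous = bool(np.all(np.diff(frames) == 1))
    if contiguous:
        for lag in range(1, max_lag + 1):
            if lag >= len(track):
                break
            d = pos[lag:] - pos[:-lag]
            msd[lag] = float(np.mean((d**2).sum(axis=1)))
            n_pairs[lag] = len(track) - lag
    else:
        index = {int(f): i for i, f in enumerate(frames)}
        for lag in range(1, max_lag + 1):
            d2 = [
                ((pos[index[f + lag]] - pos[i]) ** 2).sum()
                for i, f in enumerate(int(f) for f in frames)
                if f + lag in index
            ]
            if d2:
                msd[lag] = float(np.mean(d2))
                n_pairs[lag] = len(d2)
    return MSDResult(
        lags_min=np.arange(max_lag + 1) * dt_min,
        msd_um2=msd,
        n_pairs=n_pairs,
    )


def ensemble_msd(
    tracks: Sequence[Track], max_lag_fraction: float = DEFAULT_MAX_LAG_FRACTION
) -> MSDResult:
    """Pair-count-weighted mean of per-track MSDs on a common lag grid."""
    per_track = []
    for t in tracks:
        if len(t) >= 4:
            per_track.append(compute_msd(t, max_lag_fraction))
    if not per_track:
        raise ValueError("no eligible tracks (need length >= 4)")
    dt_min = per_track[0].lags_min[1] - per_track[0].lags_min[0]
    max_lag = max(r.msd_um2.size for r in per_track) - 1
    num = np.zeros(max_lag + 1)
    den = np.zeros(max_lag + 1)
    for r in per_track:
        k = r.msd_um2.size
        num[:k] += r.msd_um2 * r.n_pairs
        den[:k] += r.n_pairs
    msd = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return MSDResult(
        lags_min=np.arange(max_lag + 1) * dt_min,
        msd_um2=msd,
        n_pairs=den.astype(int),
    )


def fit_motion_model(msd: MSDResult, dim: int = 3) -> MotionFit:
    """Constrained least squares of MSD(tau) = 2*dim*D*tau + v^2*tau^2.

    Both coefficients are non-negative. The regime is read from the
    quadratic term's share of the model MSD at the window end: diffusive
    below 0.25, directed above 0.75, mixed between, undetermined when the
    fit degenerates.
    """
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    valid = np.flatnonzero((msd.n_pairs > 0) & (msd.lags_min > 0))
    if valid.size < 4:
        raise ValueError("need at least 4 informative lags to fit")
    tau = msd.lags_min[valid]
    y = msd.msd_um2[valid]
    X = np.column_stack([2.0 * dim * tau, tau**2])
    coef, residual = nnls(X, y)
    D, v2 = float(coef[0]), float(coef[1])
    v = float(np.sqrt(v2))

    tau_end = tau[-1]
    model_end = 2.0 * dim * D * tau_end + v2 * tau_end**2
    if model_end <= 0:
        scale = float(np.sqrt(np.mean(y**2)))
        regime = "undetermined" if residual > 1e-9 * max(scale, 1.0) else "diffusive"
        return MotionFit(D, v, regime, (int(valid[0]), int(valid[-1])))
    share = v2 * tau_end**2 / model_end
    if share < REGIME_DIFFUSIVE_MAX:
        regime = "diffusive"
    elif share > REGIME_DIRECTED_MIN:
        regime = "directed"
    else:
        regime = "mixed"
    return MotionFit(D, v, regime, (int(valid[0]), int(valid[-1])))


def _velocities(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference velocities (um/min) at consecutive frames.

    Returns (start frames, velocity vectors)."""
    frames, pos, dt_min = _positions_by_frame(track)
    consec = np.flatnonzero(np.diff(frames) == 1)
    v = (pos[consec + 1] - pos[consec]) / dt_min
    return frames[consec], v


def velocity_autocorrelation(track: Track, max_lag: Optional[int] = None) -> VACResult:
    """Normalized velocity autocorrelation of one track.

    VAC(ell) = <v(t).v(t+ell)> normalized by the geometric mean of the
    second moments of the two velocity windows, which pins VAC(0) = 1 and
    bounds |VAC| <= 1 (Cauchy-Schwarz). For stationary tracks this equals
    <v(t).v(t+ell)> / <|v|^2>.
    """
    if len(track) < 3:
        raise ValueError("track shorter than 3 detections")
    vf, v = _velocities(track)
    if v.shape[0] < 2:
        raise ValueError("not enough consecutive steps for velocities")
    if np.allclose(v, 0.0):
        raise ValueError("zero total speed; VAC normalization undefined")
    if max_lag is None:
        max_lag = v.shape[0] - 1
    index = {int(f): i for i, f in enumerate(vf)}
    lags = np.arange(max_lag + 1)
    vac = np.zeros(max_lag + 1)
    n_pairs = np.zeros(max_lag + 1, dtype=int)
    dt_min = track.frame_interval_min()
    for lag in lags:
        pairs = [(i, index[int(f) + lag]) for f, i in zip(vf, range(len(vf))) if int(f) + lag in index]
        if not pairs:
            continue
        a = v[[p[0] for p in pairs]]
        b = v[[p[1] for p in pairs]]
        num = float((a * b).sum())
        den = float(np.sqrt((a**2).sum() * (b**2).sum()))
        if den > 0:
            vac[lag] = num / den
        n_pairs[lag] = len(pairs)
    return VACResult(lags_min=lags * dt_min, vac=vac, n_pairs=n_pairs)


def ensemble_vac(tracks: Sequence[Track], max_lag: Optional[int] = None) -> VACResult:
    """Ensemble velocity autocorrelation pooled over tracks."""
    num: dict[int, float] = {}
    den_a: dict[int, float] = {}
    den_b: dict[int, float] = {}
    n_pairs: dict[int, int] = {}
    dt_min = None
    for t in tracks:
        if len(t) < 3:
            continue
        vf, v = _velocities(t)
        if v.shape[0] < 2 or np.allclose(v, 0.0):
            continue
        dt_min = dt_min or t.frame_interval_min()
        top = v.shape[0] - 1 if max_lag is None else min(max_lag, v.shape[0] - 1)
        if np.all(np.diff(vf) == 1):
            for lag in range(top + 1):
                a = v[: v.shape[0] - lag]
                b = v[lag:]
                num[lag] = num.get(lag, 0.0) + float((a * b).sum())
                den_a[lag] = den_a.get(lag, 0.0) + float((a**2).sum())
                den_b[lag] = den_b.get(lag, 0.0) + float((b**2).sum())
                n_pairs[lag] = n_pairs.get(lag, 0) + a.shape[0]
        else:
            index = {int(f): i for i, f in enumerate(vf)}
            for lag in range(top + 1):
                for i, f in enumerate(vf):
                    j = index.get(int(f) + lag)
                    if j is None:
                        continue
                    num[lag] = num.get(lag, 0.0) + float(v[i] @ v[j])
                    den_a[lag] = den_a.get(lag, 0.0) + float(v[i] @ v[i])
                    den_b[lag] = den_b.get(lag, 0.0) + float(v[j] @ v[j])
                    n_pairs[lag] = n_pairs.get(lag, 0) + 1
    if not num:
        raise ValueError("no eligible tracks for ensemble VAC")
    top = max(num)
    lags = np.arange(top + 1)
    vac = np.zeros(top + 1)
    np_arr = np.zeros(top + 1, dtype=int)
    for lag in lags:
        if lag in num:
            den = np.sqrt(den_a[lag] * den_b[lag])
            vac[lag] = num[lag] / den if den > 0 else 0.0
            np_arr[lag] = n_pairs[lag]
    return VACResult(lags_min=lags * (dt_min or 1.0), vac=vac, n_pairs=np_arr)


def crop_track(track: Track, t_min_h: float = -np.inf, t_max_h: float = np.inf) -> Optional[Track]:
    """Restrict a track to a time window; None if fewer than 2 detections remain."""
    dets = [d for d in track.detections if t_min_h <= d.t_h <= t_max_h]
    if len(dets) < 2:
        return None
    return Track(id=track.id, detections=dets)


def estimate_switch_time(
    tracks: Sequence[Track],
    persistence_threshold: float = 0.5,
    smooth_window: int = 3,
) -> float:
    """Estimate when motion turns from diffusive to directed.

    For every frame the mean cosine between a cell's consecutive step
    vectors is computed across cells (near 0 for Brownian motion, near 1
    for persistent radial migration), lightly smoothed, and the first
    up-crossing of ``persistence_threshold`` is interpolated to a time in
    hours. The reported time is when directed stepping starts, i.e. one
    frame before the first persistent pair.
    """
    acc: dict[int, list[float]] = {}
    dt_h = None
    for t in tracks:
        vf, v = _velocities(t)
        if v.shape[0] < 2:
            continue
        dt_h = dt_h or t.frame_interval_min() / 60.0
        index = {int(f): i for i, f in enumerate(vf)}
        for i, f in enumerate(vf):
            j = index.get(int(f) + 1)
            if j is None:
                continue
            na, nb = np.linalg.norm(v[i]), np.linalg.norm(v[j])
            if na > 0 and nb > 0:
                acc.setdefault(int(f) + 1, []).append(float(v[i] @ v[j] / (na * nb)))
    if not acc or dt_h is None:
        raise ValueError("not enough consecutive steps to estimate a switch time")
    frames = np.array(sorted(acc))
    c = np.array([np.mean(acc[f]) for f in frames])
    if smooth_window > 1:
        kernel = np.ones(smooth_window)
        c = np.convolve(c, kernel, mode="same") / np.convolve(
            np.ones_like(c), kernel, mode="same"
        )
    above = np.flatnonzero(c > persistence_threshold)
    if above.size == 0:
        raise ValueError("no persistent regime found")
    k = int(above[0])
    # frame `frames[k]` is the middle frame of the first persistent step pair;
    # the first directed step started one frame earlier
    return float((frames[k] - 1) * dt_h)
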