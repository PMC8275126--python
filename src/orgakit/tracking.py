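"""Spot detection and simple linear track linking.

Detection: scale-normalized Laplacian-of-Gaussian maxima with sub-pixel
centre-of-mass refinement. Linking: greedy mutual-nearest-neighbour
frame-to-frame assignment inside a hard distance gate — no gap closing,
no merging or splitting.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .types import Detection, ImageStack, Track

__all__ = [
    "detect_spots",
    "detect_movie",
    "link_tracks",
    "select_representative_tracks",
]


def detect_spots(
    volume: np.ndarray,
    pixel_size_um: float,
    sigma_um: float,
    quality_min: float,
    frame: int = 0,
    t_h: float = 0.0,
    origin_um: tuple = (0.0, 0.0, 0.0),
) -> list[Detection]:
    """Detect bright spots in one (Z, Y, X) or (Y, X) volume.

    The response is -sigma^2 * LoG (positive at bright blobs); local maxima
    above ``quality_min`` are refined by centre-of-mass in a 3^3 (3^2 in 2D)
    neighbourhood of the raw image and returned in physical coordinates.
    """
    if sigma_um < pixel_size_um:
        raise ValueError("sigma_um below pixel pitch; spots are unresolvable")
    vol = np.asarray(volume, dtype=float)
    is_3d = vol.ndim == 3
    if vol.ndim not in (2, 3):
        raise ValueError("volume must be 2D or 3D")
    s_px = sigma_um / pixel_size_um
    response = -(s_px**2) * ndimage.gaussian_laplace(vol, s_px)
    peak = ndimage.maximum_filter(response, size=3, mode="constant", cval=-np.inf)
    candidates = np.argwhere((response >= peak) & (response > quality_min))

    detections = []
    for idx in candidates:
        lo = np.maximum(idx - 1, 0)
        hi = np.minimum(idx + 2, vol.shape)
        patch = vol[tuple(slice(a, b) for a, b in zip(lo, hi))]
        w = patch - patch.min()
        total = w.sum()
        if total > 0:
            grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
            center = np.array([(g * w).sum() / total for g in grids])
        else:
            center = idx.astype(float)
        if is_3d:
            z, y, x = center
        else:
            (y, x), z = center, 0.0
        detections.append(
            Detection(
                frame=frame,
                t_h=t_h,
                x_um=float(x * pixel_size_um + origin_um[0]),
                y_um=float(y * pixel_size_um + origin_um[1]),
                z_um=float(z * pixel_size_um + origin_um[2]),
                intensity=float(response[tuple(idx)]),
            )
        )
    return detections


def detect_movie(stack: ImageStack, sigma_um: float, quality_min: float) -> list[list[Detection]]:
    """Run spot detection on every frame of a calibrated stack."""
    dt_h = (stack.frame_interval_min or 0.0) / 60.0
    return [
        detect_spots(
            stack.data[f],
            stack.pixel_size_um,
            sigma_um,
            quality_min,
            frame=f,
            t_h=f * dt_h,
            origin_um=stack.origin_um,
        )
        for f in range(stack.n_frames)
    ]


def link_tracks(frames: list[list[Detection]], max_disp_um: float) -> list[Track]:
    """Greedy mutual-nearest-neighbour frame-to-frame linking.

    Candidate pairs within ``max_disp_um`` are sorted by distance and
    accepted when both endpoints are still unassigned; unmatched detections
    start new tracks. Ties in distance break on coordinates so the result
    is independent of detection order within a frame. Tracks shorter than
    two detections are dropped.
    """
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be positive")
    open_tracks: list[list[Detection]] = []  # currently extendable
    closed: list[list[Detection]] = []
    for frame_dets in frames:
        dets = list(frame_dets)
        if not open_tracks:
            open_tracks = [[d] for d in sorted(dets, key=lambda d: (d.x_um, d.y_um, d.z_um))]
            continue
        ends = np.array([[t[-1].x_um, t[-1].y_um, t[-1].z_um] for t in open_tracks])
        if dets:
            pts = np.array([[d.x_um, d.y_um, d.z_um] for d in dets])
            dist = np.sqrt(((ends[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
            ii, jj = np.nonzero(dist <= max_disp_um)
            order = sorted(
                range(len(ii)),
                key=lambda k: (
                    dist[ii[k], jj[k]],
                    tuple(ends[ii[k]]),
                    tuple(pts[jj[k]]),
                ),
            )
        else:
            ii = jj = np.empty(0, dtype=int)
            order = []
        used_end: set[int] = set()
        used_det: set[int] = set()
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            if i in used_end or j in used_det:
                continue
            used_end.add(i)
            used_det.add(j)
            open_tracks[i].append(dets[j])
        next_open = [t for i, t in enumerate(open_tracks) if i in used_end]
        closed.extend(t for i, t in enumerate(open_tracks) if i not in used_end)
        starters = [dets[j] for j in range(len(dets)) if j not in used_det]
        next_open.extend([[d] for d in sorted(starters, key=lambda d: (d.x_um, d.y_um, d.z_um))])
        open_tracks = next_open
    closed.extend(open_tracks)

    tracks = []
    for chain in closed:
        if len(chain) >= 2:
            tracks.append(Track(id=len(tracks), detections=chain))
    return tracks


def select_representative_tracks(tracks: list[Track], n: int) -> list[Track]:
    """Pick the ``n`` tracks best combining total path length and duration.

    Tracks are ranked separately by total distance travelled and by
    duration (rank 1 = largest); the selection score is the product of the
    two ranks, smaller being better, with track id breaking ties.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(tracks):
        warnings.warn(f"requested {n} tracks but only {len(tracks)} available", stacklevel=2)
        n = len(tracks)
    lengths = np.array([t.path_length_um() for t in tracks])
    durations = np.array([t.duration_h() for t in tracks])

    def _rank_desc(x: np.ndarray) -> np.ndarray:
        # rank 1 for the largest value; ties share the smallest applicable rank
        order = np.argsort(-x, kind="stable")
        ranks = np.empty(len(x), dtype=float)
        ranks[order] = np.arange(1, len(x) + 1)
        for v in np.unique(x):
            sel = x == v
            ranks[sel] = ranks[sel].min()
        return ranks

    score = _rank_desc(lengths) * _rank_desc(durations)
    chosen = sorted(range(len(tracks)), key=lambda i: (score[i], tracks[i].id))[:n]
    return [tracks[i] for i in chosen]
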