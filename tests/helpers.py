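"""Shared track-building helpers for the test suite."""

import numpy as np

from orgakit.types import Detection, Track


def make_track(positions, dt_min=15.0, track_id=0, start_frame=0):
    """Track from an (n, 3) position array at a uniform frame interval."""
    positions = np.asarray(positions, dtype=float)
    dets = [
        Detection(
            frame=start_frame + i,
            t_h=(start_frame + i) * dt_min / 60.0,
            x_um=float(p[0]),
            y_um=float(p[1]),
            z_um=float(p[2]),
        )
        for i, p in enumerate(positions)
    ]
    return Track(id=track_id, detections=dets)


def static_track(position, n_frames=4, dt_min=15.0, track_id=0):
    return make_track(np.tile(np.asarray(position, float), (n_frames, 1)), dt_min, track_id)


def ballistic_track(v_um_per_min, n_frames=20, dt_min=15.0, direction=(1.0, 0.0, 0.0),
                    origin=(0.0, 0.0, 0.0), track_id=0):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    steps = np.arange(n_frames)[:, None] * v_um_per_min * dt_min * d
    return make_track(np.asarray(origin, float) + steps, dt_min=dt_min, track_id=track_id)


def brownian_tracks(rng, n_tracks, n_frames, D_um2_per_min, dt_min=15.0):
    sigma = np.sqrt(2.0 * D_um2_per_min * dt_min)
    tracks = []
    for i in range(n_tracks):
        steps = rng.normal(0.0, sigma, size=(n_frames - 1, 3))
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        tracks.append(make_track(pos, dt_min=dt_min, track_id=i))
    return tracks
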