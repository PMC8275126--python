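"""Synthetic time-lapse data with ground truth.

Three generators mirror the structures the analysis stages expect:
sigmoidal fluorescence-onset cohorts, organoid image pairs with 1-4
expression domains, and 3D nuclear tracks that switch from Brownian
diffusion to radially directed migration. Every generator returns a
:class:`~orgakit.types.GroundTruth` record so downstream stages can be
verified without real microscopy data.
"""

from __future__ import annotations

import math

import numpy as np

from .config import SimConfig, TrackConfig
from .types import Detection, GroundTruth, ImageFrame, ImageStack, IntensityTrace, Track

__all__ = [
    "simulate_intensity_cohort",
    "simulate_organoid_image",
    "simulate_tracks",
    "render_track_movie",
    "PlacementError",
]

# logistic scale s such that the 10-90% rise spans rise_time_h:
# logistic(t0 + s*ln 9) = 0.9, so rise = 2 s ln 9
_LN9 = math.log(9.0)


class PlacementError(RuntimeError):
    """Domain disks could not be placed under the gap constraint."""


def logistic_onset_curve(
    times_h: np.ndarray, onset_h: float, rise_time_h: float, baseline: float
) -> np.ndarray:
    """Noise-free intensity curve: baseline + logistic rise to plateau 1.

    The inflection (steepest rise) sits exactly at ``onset_h``.
    """
    s = rise_time_h / (2.0 * _LN9)
    return baseline + (1.0 - baseline) / (1.0 + np.exp(-(times_h - onset_h) / s))


def simulate_intensity_cohort(cfg: SimConfig) -> tuple[list[IntensityTrace], GroundTruth]:
    """Generate a cohort of fluorescence traces with known onset times.

    Onsets are drawn from Normal(onset_mean_h, onset_sd_h); each trace is a
    logistic rise centred at its onset with additive Gaussian noise
    (``noise_sd`` as a fraction of the plateau).
    """
    if cfg.cohort is None:
        raise ValueError("SimConfig.cohort block is required")
    c = cfg.cohort
    if c.duration_h < c.onset_mean_h + 3.0 * c.rise_time_h:
        raise ValueError(
            "duration_h too short: onset would be censored "
            f"(need >= {c.onset_mean_h + 3 * c.rise_time_h:g} h)"
        )
    rng = np.random.default_rng(cfg.seed)
    dt_h = c.frame_interval_min / 60.0
    n_frames = int(math.floor(c.duration_h / dt_h + 1e-9)) + 1
    times = np.arange(n_frames) * dt_h

    onsets = rng.normal(c.onset_mean_h, c.onset_sd_h, size=c.n_traces)
    traces = []
    for i, onset in enumerate(onsets):
        clean = logistic_onset_curve(times, onset, c.rise_time_h, c.baseline)
        noisy = clean + rng.normal(0.0, c.noise_sd, size=times.shape) if c.noise_sd > 0 else clean
        traces.append(IntensityTrace(id=f"agg{i:03d}", times_h=times, intensity_raw=noisy))
    return traces, GroundTruth(true_onsets_h=onsets)


def _rasterize_disk(size_px: int, cx_px: float, cy_px: float, r_px: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    return (xx - cx_px) ** 2 + (yy - cy_px) ** 2 <= r_px**2


def simulate_organoid_image(
    cfg: SimConfig, max_attempts: int = 5000
) -> tuple[ImageFrame, ImageFrame, GroundTruth]:
    """Render a bright-field/fluorescence image pair of one organoid.

    Bright field: dark organoid disk (bg_intensity) on a bright background
    (fg_intensity). Fluorescence: ``n_domains`` bright disks inside the
    organoid on a dark background. Domain centres are rejection-sampled so
    disks fit inside the organoid with pairwise gap >= min_domain_gap_um.
    """
    if cfg.image is None:
        raise ValueError("SimConfig.image block is required")
    im = cfg.image
    rng = np.random.default_rng(cfg.seed)
    px = im.pixel_size_um
    center_px = (im.size_px - 1) / 2.0
    r_org_um = im.organoid_radius_um
    r_dom_um = im.domain_radius_um

    # sample domain centres in um relative to organoid centre
    max_c = r_org_um - r_dom_um  # centre radius so the disk fits inside
    min_sep = 2.0 * r_dom_um + im.min_domain_gap_um
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < im.n_domains:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {im.n_domains} domains of radius {r_dom_um} um "
                f"inside organoid radius {r_org_um} um with gap {im.min_domain_gap_um} um"
            )
        attempts += 1
        if max_c <= 0:
            cand = np.zeros(2)
        else:
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rad = max_c * math.sqrt(rng.uniform())
            cand = np.array([rad * math.cos(ang), rad * math.sin(ang)])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)

    bf = np.full((im.size_px, im.size_px), im.fg_intensity, dtype=float)
    org_mask = _rasterize_disk(im.size_px, center_px, center_px, r_org_um / px)
    bf[org_mask] = im.bg_intensity

    fluor = np.full((im.size_px, im.size_px), im.bg_intensity, dtype=float)
    labels = np.zeros((im.size_px, im.size_px), dtype=np.int32)
    for k, c_um in enumerate(centers, start=1):
        dom = _rasterize_disk(
            im.size_px, center_px + c_um[0] / px, center_px + c_um[1] / px, r_dom_um / px
        )
        fluor[dom] = im.fg_intensity
        labels[dom] = k

    if im.noise_sd > 0:
        bf = bf + rng.normal(0.0, im.noise_sd, bf.shape)
        fluor = fluor + rng.normal(0.0, im.noise_sd, fluor.shape)

    gt = GroundTruth(
        domain_labels=labels,
        domain_areas_um2=np.full(im.n_domains, math.pi * r_dom_um**2),
        domain_perimeters_um=np.full(im.n_domains, 2.0 * math.pi * r_dom_um),
        domain_centers_um=np.array(centers),
        organoid_area_um2=math.pi * r_org_um**2,
    )
    return (
        ImageFrame(bf, px, channel="bright_field"),
        ImageFrame(fluor, px, channel="fluorescence"),
        gt,
    )


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * r


def simulate_true_positions(cfg: TrackConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """True (noise-free) positions, shape (n_cells, n_frames, 3), and per-cell
    radial signs (+1 outward, -1 inward).

    Brownian steps (per-axis variance 2*D*dt) before the switch frame, then
    radial steps of length v*dt along the current radial direction.
    """
    n_frames = cfg.n_steps + 1
    pos = np.empty((cfg.n_cells, n_frames, 3))
    pos[:, 0] = _uniform_in_sphere(rng, cfg.n_cells, cfg.aggregate_radius_um)
    signs = np.where(rng.uniform(size=cfg.n_cells) < cfg.p_outward, 1.0, -1.0)

    sigma = math.sqrt(2.0 * cfg.D_um2_per_min * cfg.dt_min)
    step_len = cfg.v_um_per_min * cfg.dt_min
    for i in range(cfg.n_steps):
        t_min = i * cfg.dt_min
        if t_min >= cfg.t_switch_h * 60.0 - 1e-9:
            cur = pos[:, i]
            norms = np.linalg.norm(cur, axis=1, keepdims=True)
            # cells exactly at the origin get a random direction
            zero = norms[:, 0] < 1e-12
            unit = np.where(norms > 1e-12, cur / np.maximum(norms, 1e-12), 0.0)
            if zero.any():
                rnd = _uniform_in_sphere(rng, int(zero.sum()), 1.0)
                rnd /= np.linalg.norm(rnd, axis=1, keepdims=True)
                unit[zero] = rnd
            pos[:, i + 1] = cur + signs[:, None] * step_len * unit
        else:
            pos[:, i + 1] = pos[:, i] + rng.normal(0.0, sigma, size=(cfg.n_cells, 3))
    return pos, signs


def simulate_tracks(cfg: SimConfig) -> tuple[list[Track], GroundTruth]:
    """Generate 3D nuclear tracks with a diffusive-to-directed regime switch.

    Observed positions are the true positions plus isotropic Gaussian
    localisation noise; observations are dropped independently with
    ``miss_rate`` (tracks then skip frames). Cells left with fewer than two
    observations are omitted.
    """
    if cfg.tracks is None:
        raise ValueError("SimConfig.tracks block is required")
    tc = cfg.tracks
    rng = np.random.default_rng(cfg.seed)
    true_pos, signs = simulate_true_positions(tc, rng)
    n_frames = true_pos.shape[1]

    obs = true_pos
    if tc.loc_noise_um > 0:
        obs = obs + rng.normal(0.0, tc.loc_noise_um, size=obs.shape)
    keep = rng.uniform(size=(tc.n_cells, n_frames)) >= tc.miss_rate

    dt_h = tc.dt_min / 60.0
    tracks: list[Track] = []
    classes: dict[int, str] = {}
    truth: dict[int, np.ndarray] = {}
    for c in range(tc.n_cells):
        frames = np.flatnonzero(keep[c])
        if frames.size < 2:
            continue
        dets = [
            Detection(
                frame=int(f),
                t_h=float(f * dt_h),
                x_um=float(obs[c, f, 0]),
                y_um=float(obs[c, f, 1]),
                z_um=float(obs[c, f, 2]),
            )
            for f in frames
        ]
        tracks.append(Track(id=c, detections=dets))
        classes[c] = "outward" if signs[c] > 0 else "inward"
        truth[c] = np.column_stack([frames, true_pos[c, frames]])

    gt = GroundTruth(
        track_classes=classes,
        true_positions=truth,
        true_speed_um_per_min=tc.v_um_per_min,
        true_D_um2_per_min=tc.D_um2_per_min,
        switch_time_h=tc.t_switch_h,
    )
    return tracks, gt


def render_track_movie(
    tracks: list[Track],
    cfg: SimConfig,
    spot_sigma_um: float = 2.0,
    amplitude: float = 100.0,
    bg_noise_sd: float = 0.0,
    margin_um: float | None = None,
) -> ImageStack:
    """Render tracks as isotropic Gaussian spots in a (T, Z, Y, X) stack.

    The field of view is fitted to the track bounding box plus a margin of
    4 sigma; the stack's ``origin_um`` records the voxel-to-physical offset.
    """
    if cfg.image is None:
        raise ValueError("SimConfig.image block is required for rendering")
    px = cfg.image.pixel_size_um
    if spot_sigma_um < px:
        raise ValueError("spot sigma below one pixel: spots would be undetectable")
    dt_min = cfg.tracks.dt_min if cfg.tracks is not None else None
    if margin_um is None:
        margin_um = 4.0 * spot_sigma_um

    if tracks:
        allpos = np.vstack([t.positions() for t in tracks])
        lo = allpos.min(axis=0) - margin_um
        hi = allpos.max(axis=0) + margin_um
        n_frames = max(int(t.frames[-1]) for t in tracks) + 1
    else:
        lo = np.zeros(3)
        hi = np.full(3, cfg.image.size_px * px)
        n_frames = 1
    shape = np.maximum(np.ceil((hi - lo) / px).astype(int) + 1, 4)  # (x, y, z) extents
    nx, ny, nz = (int(s) for s in shape)

    rng = np.random.default_rng(cfg.seed + 1)
    data = np.zeros((n_frames, nz, ny, nx), dtype=float)
    if bg_noise_sd > 0:
        data += rng.normal(0.0, bg_noise_sd, size=data.shape)

    s_px = spot_sigma_um / px
    half = int(math.ceil(4.0 * s_px))
    for tr in tracks:
        for d in tr.detections:
            cx = (d.x_um - lo[0]) / px
            cy = (d.y_um - lo[1]) / px
            cz = (d.z_um - lo[2]) / px
            x0, x1 = max(0, int(cx) - half), min(nx, int(cx) + half + 1)
            y0, y1 = max(0, int(cy) - half), min(ny, int(cy) + half + 1)
            z0, z1 = max(0, int(cz) - half), min(nz, int(cz) + half + 1)
            if x0 >= x1 or y0 >= y1 or z0 >= z1:
                continue
            zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
            r2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
            data[d.frame, z0:z1, y0:y1, x0:x1] += amplitude * np.exp(-r2 / (2.0 * s_px**2))

    return ImageStack(
        data=data,
        pixel_size_um=px,
        frame_interval_min=dt_min,
        channel="fluorescence",
        origin_um=(float(lo[0]), float(lo[1]), float(lo[2])),
    )
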