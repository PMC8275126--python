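"""File interchange: calibrated TIFF stacks, track-table CSVs, trace CSVs.

Track tables use the TrackMate-dialect columns TRACK_ID, FRAME,
POSITION_X, POSITION_Y, POSITION_Z, POSITION_T, QUALITY with positions in
micrometres and POSITION_T in hours; extra columns are preserved on read.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .types import Detection, ImageStack, IntensityTrace, Track

__all__ = [
    "read_tiff_stack",
    "write_tiff_stack",
    "read_track_csv",
    "write_track_csv",
    "read_trace_csv",
    "write_trace_csv",
]

TRACK_COLUMNS = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y", "POSITION_Z", "POSITION_T"]


def write_tiff_stack(path, stack: ImageStack) -> None:
    """Write a calibrated stack as ImageJ-flavoured multi-page TIFF.

    Pixel size goes into the resolution tags (pixels per micrometre);
    frame interval and origin go into the ImageJ metadata block.
    """
    axes = "TZYX" if stack.is_3d else "TYX"
    meta = {
        "axes": axes,
        "unit": "um",
        "origin_um": list(stack.origin_um),
        "channel": stack.channel,
    }
    if stack.frame_interval_min is not None:
        meta["finterval"] = stack.frame_interval_min * 60.0  # seconds, ImageJ convention
    data = stack.data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata=meta,
    )


def read_tiff_stack(
    path,
    pixel_size_um: Optional[float] = None,
    frame_interval_min: Optional[float] = None,
    channel: Optional[str] = None,
) -> ImageStack:
    """Read a multi-page TIFF into a calibrated stack.

    Calibration comes from the TIFF/ImageJ tags; explicit arguments
    override them. Missing pixel size with no override is refused.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.imagej_metadata or {}
        px = pixel_size_um
        # trust the resolution tags only when the file declares a micron unit
        if px is None and meta.get("unit") in ("um", "micron", "µm"):
            xres = tif.pages[0].tags.get("XResolution")
            if xres is not None:
                num, den = xres.value
                if num:
                    px = den / num
        if px is None or px <= 0:
            raise ValueError("missing pixel-size calibration and no override given")
        fi = frame_interval_min
        if fi is None and "finterval" in meta:
            fi = float(meta["finterval"]) / 60.0
        origin = meta.get("origin_um", (0.0, 0.0, 0.0))
        if isinstance(origin, str):  # ImageJ metadata stores lists as strings
            origin = json.loads(origin)
        origin = tuple(float(v) for v in origin)
        ch = channel or meta.get("channel", "fluorescence")
    if data.ndim == 2:
        data = data[None]
    return ImageStack(
        data=data,
        pixel_size_um=float(px),
        frame_interval_min=fi,
        channel=ch,
        origin_um=origin,
    )


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for d in t.detections:
            rows.append(
                {
                    "TRACK_ID": t.id,
                    "FRAME": d.frame,
                    "POSITION_X": d.x_um,
                    "POSITION_Y": d.y_um,
                    "POSITION_Z": d.z_um,
                    "POSITION_T": d.t_h,
                    "QUALITY": d.intensity,
                }
            )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS + ["QUALITY"])


def write_track_csv(path, tracks: list[Track]) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def read_track_csv(path) -> list[Track]:
    """Read a track table; rows are grouped by TRACK_ID and sorted by FRAME.

    Duplicate (TRACK_ID, FRAME) rows are refused with their row numbers.
    Tracks with a single detection are skipped (a track needs >= 2).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing column(s): {missing}")
    dup = df.duplicated(subset=["TRACK_ID", "FRAME"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based incl. header
        raise ValueError(f"duplicate (TRACK_ID, FRAME) rows at lines {rows}")
    tracks = []
    for tid, grp in df.groupby("TRACK_ID", sort=True):
        grp = grp.sort_values("FRAME")
        if len(grp) < 2:
            continue
        dets = [
            Detection(
                frame=int(r.FRAME),
                t_h=float(r.POSITION_T),
                x_um=float(r.POSITION_X),
                y_um=float(r.POSITION_Y),
                z_um=float(r.POSITION_Z),
                intensity=float(getattr(r, "QUALITY", 0.0)),
            )
            for r in grp.itertuples()
        ]
        tracks.append(Track(id=int(tid), detections=dets))
    return tracks


def write_trace_csv(path, traces: list[IntensityTrace]) -> None:
    rows = []
    for tr in traces:
        for t, v in zip(tr.times_h, tr.intensity_raw):
            rows.append({"id": tr.id, "time_h": t, "intensity": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trace_csv(path) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    missing = [c for c in ("id", "time_h", "intensity") if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing column(s): {missing}")
    traces = []
    for tid, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("time_h")
        traces.append(
            IntensityTrace(
                id=str(tid),
                times_h=grp["time_h"].to_numpy(),
                intensity_raw=grp["intensity"].to_numpy(),
            )
        )
    return traces


def write_ground_truth_json(path, gt) -> None:
    """Ground-truth sidecar as JSON (arrays as lists, label images omitted)."""
    from .stats import _jsonable

    payload = {}
    for key, val in vars(gt).items():
        if key == "domain_labels":
            continue
        if val is not None:
            payload[key] = _jsonable(val)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
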