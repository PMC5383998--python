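"""Movie, track, and config I/O."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .behavior import BehaviorParams, Calibration, RoiSet
from .detection import SegmentationParams
from .tracking import LinkingParams, Track, TrackPoint

IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}
TRACK_COLUMNS = ["track_id", "frame_index", "time_s", "x_px", "y_px", "source"]

__all__ = [
    "read_movie",
    "count_frames",
    "write_frames",
    "write_tracks",
    "read_tracks",
    "load_assay_config",
]


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(float)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        rgb = frame[..., :3].astype(float)
        return rgb @ np.array([0.2125, 0.7154, 0.0721])
    raise ValueError(f"unsupported frame shape {frame.shape}")


def _sequence_files(path: Path) -> list[Path]:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS)
    if not files:
        raise FileNotFoundError(f"no image files found in {path}")
    return files


def count_frames(path) -> int | None:
    """Number of frames, when knowable without decoding the whole movie."""
    path = Path(path)
    if path.is_dir():
        return len(_sequence_files(path))
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            return len(tf.pages)
    return None


def read_movie(path) -> Iterator[np.ndarray]:
    """Yield grayscale float frames in temporal order.

    ``path`` may be a directory of image files (lexicographic order), a
    multi-page TIFF, or a video container readable by imageio.  Color frames
    are converted to grayscale by luminance.  Mixed frame sizes raise a
    format error.
    """
    path = Path(path)
    shape = None

    def check(frame: np.ndarray, label: str) -> np.ndarray:
        nonlocal shape
        gray = _to_gray(frame)
        if shape is None:
            shape = gray.shape
        elif gray.shape != shape:
            raise ValueError(f"mixed frame sizes: {label} is {gray.shape}, expected {shape}")
        return gray

    if path.is_dir():
        for f in _sequence_files(path):
            try:
                frame = iio.imread(f)
            except Exception as exc:
                raise IOError(f"unreadable frame {f.name}: {exc}") from exc
            yield check(frame, f.name)
    elif path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            for i, page in enumerate(tf.pages):
                yield check(page.asarray(), f"page {i}")
    else:
        for i, frame in enumerate(iio.imiter(path)):
            yield check(frame, f"frame {i}")


def write_frames(frames, out_dir, fmt: str = "png") -> list[Path]:
    """Write frames as a zero-padded 16-bit image sequence."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        arr = np.clip(np.asarray(frame), 0, 65535).astype(np.uint16)
        p = out_dir / f"frame_{i:05d}.{fmt}"
        iio.imwrite(p, arr)
        paths.append(p)
    return paths


def write_tracks(tracks: list[Track], path, fps: float = 1.0) -> None:
    """Track CSV: one row per point, sorted by (track_id, frame_index)."""
    rows = [
        (t.id, p.frame_index, p.frame_index / fps, p.position[0], p.position[1], p.source)
        for t in tracks
        for p in t.points
    ]
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.sort_values(["track_id", "frame_index"]).to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track file missing columns: {missing}")
    extra = [c for c in df.columns if c not in TRACK_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown track columns: {extra}", stacklevel=2)
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame_index")
        points = [
            TrackPoint(int(r.frame_index), (float(r.x_px), float(r.y_px)), str(r.source))
            for r in sub.itertuples(index=False)
        ]
        tracks.append(Track(id=int(tid), points=points, state="terminated"))
    return tracks


def load_assay_config(path) -> dict:
    """Load and validate an assay config (YAML).

    Recognized blocks: calibration, segmentation, linking, behavior, rois.
    Unit suffixes in key names (_px, _mm, _s) are the source of truth; ROI
    circles given in mm are converted to px via the calibration.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    calib = Calibration(**raw.get("calibration", {}))
    seg = SegmentationParams(**raw.get("segmentation", {}))
    link = LinkingParams(**raw.get("linking", {}))
    beh = BehaviorParams(**raw.get("behavior", {}))
    rois = None
    if "rois" in raw:
        circles = {}
        for label, spec in raw["rois"].items():
            if "center_mm" in spec:
                cx, cy = (v * calib.px_per_mm for v in spec["center_mm"])
                r = spec["radius_mm"] * calib.px_per_mm
            else:
                cx, cy = spec["center_px"]
                r = spec["radius_px"]
            circles[label] = (float(cx), float(cy), float(r))
        rois = RoiSet(circles)
    return {
        "calibration": calib,
        "segmentation": seg,
        "linking": link,
        "behavior": beh,
        "rois": rois,
        "raw": raw,
    }
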