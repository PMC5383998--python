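"""Chemotaxis and locomotion analytics over centroid tracks.

The statistics here follow the standard C. elegans chemotaxis vocabulary:
*bearing* B is the signed angle between the animal's velocity and the vector
pointing from the animal to the attractant peak (0 deg = heading straight at
the target, |B| = 180 deg = heading directly away); a *sharp turn* is a pair
of succeeding movement vectors enclosing an angle above a threshold (100 deg
by default); a *pirouette* is a bout of sharp turns — turns separated by runs
shorter than a critical duration T_crit (5 s by default) merge into one
event, and the straight stretches between events are the *runs*.  Entry and
exit bearings (B_before / B_after) are circular means over a short window of
steps on either side of the bout, and the directional change is
dB = B_before - B_after.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import Track

SUBPIXEL_STEP_PX = 0.5  # displacements below this are treated as zero velocity

__all__ = [
    "Calibration",
    "BehaviorParams",
    "PirouetteEvent",
    "RoiSet",
    "AttractionField",
    "step_vectors",
    "speed_series",
    "bearing_series",
    "directness_projection",
    "detect_sharp_turns",
    "detect_pirouettes",
    "pirouette_probability_vs_distance",
    "roi_kinetics",
    "chemotaxis_rate",
    "attraction_field",
    "delta_bearing_histogram",
]


@dataclass
class Calibration:
    """Spatial and temporal scale of a movie (reference assays: 1 frame/s)."""

    px_per_mm: float = 10.0
    frames_per_second: float = 1.0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0 or self.frames_per_second <= 0:
            raise ValueError("calibration scales must be positive")


@dataclass
class BehaviorParams:
    sharp_turn_deg: float = 100.0
    t_crit_s: float = 5.0
    bearing_window_steps: int = 3
    reversal_deg: float = 150.0

    def __post_init__(self) -> None:
        if not 0 < self.sharp_turn_deg < 180:
            raise ValueError("sharp_turn_deg must lie in (0, 180)")
        if self.t_crit_s <= 0:
            raise ValueError("t_crit_s must be positive")


@dataclass
class PirouetteEvent:
    start_s: float
    end_s: float
    B_before: float  # deg in (-180, 180], NaN when the pre-window is incomplete
    B_after: float

    @property
    def delta_B(self) -> float:
        return _wrap_deg(self.B_before - self.B_after)


@dataclass
class RoiSet:
    """Labeled circular regions: canonical labels are start / cue / control."""

    circles: dict[str, tuple[float, float, float]]  # label -> (cx, cy, radius) px

    def __post_init__(self) -> None:
        for label, (_, _, r) in self.circles.items():
            if r <= 0:
                raise ValueError(f"ROI {label!r} has non-positive radius")


@dataclass
class AttractionField:
    """Per-bin occupancy and mean movement direction over an arena grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy: np.ndarray  # (ny, nx) point counts
    direction: np.ndarray = field(repr=False)  # (ny, nx, 2) mean unit step vectors


def _wrap_deg(a):
    """Wrap angle(s) to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


def step_vectors(track: Track) -> np.ndarray:
    """Per-step displacement vectors (px/frame), sub-pixel steps zeroed.

    Step t is p_{t+1} - p_t; displacements below SUBPIXEL_STEP_PX are treated
    as zero velocity (excluded from angle computations downstream, counted as
    zero speed).
    """
    pos = track.positions()
    v = np.diff(pos, axis=0)
    small = np.hypot(v[:, 0], v[:, 1]) < SUBPIXEL_STEP_PX
    v[small] = 0.0
    return v


def speed_series(track: Track, calib: Calibration, include_predicted: bool = True) -> np.ndarray:
    """Per-step speed in mm/s; NaN at steps that start from a predicted point
    when ``include_predicted`` is False."""
    if len(track.points) < 2:
        return np.empty(0)
    v = step_vectors(track)
    speed = np.hypot(v[:, 0], v[:, 1]) * calib.frames_per_second / calib.px_per_mm
    if not include_predicted:
        pred = np.array([p.source == "predicted" for p in track.points])
        mask = pred[:-1] | pred[1:]
        speed = np.where(mask, np.nan, speed)
    return speed


def _bearing_from(v: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Signed angle (deg) from target-direction d to velocity v, per row.

    NaN where either vector vanishes.
    """
    cross = d[:, 0] * v[:, 1] - d[:, 1] * v[:, 0]
    dot = d[:, 0] * v[:, 0] + d[:, 1] * v[:, 1]
    with np.errstate(invalid="ignore"):
        b = np.degrees(np.arctan2(cross, dot))
    bad = (np.hypot(v[:, 0], v[:, 1]) == 0) | (np.hypot(d[:, 0], d[:, 1]) == 0)
    b[bad] = np.nan
    return _wrap_deg(np.where(b == -180.0, 180.0, b))


def bearing_series(track: Track, target: tuple[float, float]) -> np.ndarray:
    """Per-step bearing B (deg) in (-180, 180]; 0 = straight at the target.

    NaN at zero-velocity steps and where the animal sits on the target.
    """
    pos = track.positions()
    v = step_vectors(track)
    d = np.asarray(target, dtype=float) - pos[:-1]
    return _bearing_from(v, d)


def directness_projection(
    track: Track,
    target: tuple[float, float],
    calib: Calibration,
    stop_at_first_visit_radius_px: float | None = None,
) -> np.ndarray:
    """Projection of velocity on the animal->target direction, mm/s.

    proj(t) = <v(t), d(t)> / |d(t)| = speed(t) * cos(B(t)).  Steps where the
    animal sits on the target are NaN.  With
    ``stop_at_first_visit_radius_px`` set, steps after the first entry into
    that radius are masked (first-visit filtering for revisiting animals).
    """
    pos = track.positions()
    v = step_vectors(track) * calib.frames_per_second / calib.px_per_mm
    d = np.asarray(target, dtype=float) - pos[:-1]
    norm = np.hypot(d[:, 0], d[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        proj = (v[:, 0] * d[:, 0] + v[:, 1] * d[:, 1]) / norm
    proj[norm == 0] = np.nan
    if stop_at_first_visit_radius_px is not None:
        dist = np.hypot(*(pos - np.asarray(target)).T)
        inside = np.nonzero(dist <= stop_at_first_visit_radius_px)[0]
        if inside.size:
            proj[int(inside[0]) :] = np.nan
    return proj


def _turn_angles(track: Track) -> np.ndarray:
    """Unsigned angle (deg) between succeeding step vectors; NaN where either
    step has zero velocity.  Entry t describes the corner at point t+1."""
    v = step_vectors(track)
    a, b = v[:-1], v[1:]
    na = np.hypot(a[:, 0], a[:, 1])
    nb = np.hypot(b[:, 0], b[:, 1])
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
    ang = np.abs(np.degrees(np.arctan2(cross, dot)))
    ang[(na == 0) | (nb == 0)] = np.nan
    return ang


def detect_sharp_turns(track: Track, params: BehaviorParams, threshold_deg: float | None = None) -> np.ndarray:
    """Indices t (corner at point index t+1) where succeeding movement vectors
    enclose an angle strictly greater than the threshold."""
    if len(track.points) < 3:
        return np.empty(0, dtype=int)
    thr = params.sharp_turn_deg if threshold_deg is None else threshold_deg
    ang = _turn_angles(track)
    with np.errstate(invalid="ignore"):
        return np.nonzero(ang > thr)[0]


def _circular_mean_deg(angles: np.ndarray) -> float:
    angles = np.asarray(angles, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        return float("nan")
    rad = np.radians(angles)
    return _wrap_deg(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


def detect_pirouettes(
    track: Track,
    params: BehaviorParams,
    calib: Calibration,
    target: tuple[float, float] | None = None,
) -> tuple[list[PirouetteEvent], list[tuple[float, float]]]:
    """Group sharp turns into pirouettes and report the intervening runs.

    Sharp turns separated by runs shorter than ``t_crit_s`` merge into one
    pirouette; runs at least that long separate events and are returned as
    (start_s, end_s) bouts, including the leading and trailing stretches of
    the track.  B_before / B_after are circular means of the bearing over
    ``bearing_window_steps`` steps strictly before the first / after the last
    turn of the bout (NaN when the window is incomplete or no target is
    given).
    """
    fps = calib.frames_per_second
    turns = detect_sharp_turns(track, params)
    t0 = track.points[0].frame_index / fps
    t1 = track.points[-1].frame_index / fps
    if turns.size == 0:
        return [], [(t0, t1)] if t1 > t0 else []

    bearings = (
        bearing_series(track, target) if target is not None else None
    )
    # corner time of turn index k: point index k+1 relative to track start
    corner_times = (track.points[0].frame_index + turns + 1) / fps
    bouts: list[list[int]] = [[0]]
    for k in range(1, len(turns)):
        if corner_times[k] - corner_times[bouts[-1][-1]] < params.t_crit_s:
            bouts[-1].append(k)
        else:
            bouts.append([k])

    w = params.bearing_window_steps
    events: list[PirouetteEvent] = []
    for bout in bouts:
        first, last = turns[bout[0]], turns[bout[-1]]
        if bearings is not None:
            pre = bearings[first - w + 1 : first + 1] if first - w + 1 >= 0 else np.empty(0)
            post = bearings[last + 1 : last + 1 + w]
            b_before = _circular_mean_deg(pre) if len(pre) == w else float("nan")
            b_after = _circular_mean_deg(post) if len(post) == w else float("nan")
        else:
            b_before = b_after = float("nan")
        events.append(
            PirouetteEvent(
                start_s=float(corner_times[bout[0]]),
                end_s=float(corner_times[bout[-1]]),
                B_before=b_before,
                B_after=b_after,
            )
        )

    runs: list[tuple[float, float]] = []
    cursor = t0
    for ev in events:
        if ev.start_s > cursor:
            runs.append((cursor, ev.start_s))
        cursor = ev.end_s
    if t1 > cursor:
        runs.append((cursor, t1))
    return events, runs


def pirouette_probability_vs_distance(
    tracks: list[Track],
    events_per_track: list[list[PirouetteEvent]],
    target: tuple[float, float],
    distance_edges_px: np.ndarray,
    calib: Calibration,
) -> np.ndarray:
    """Pirouette initiation rate (events/s) per distance-from-target bin.

    Each bin's estimate is (#initiations while in the bin) / (track-seconds
    spent in the bin); bins never visited are NaN.
    """
    edges = np.asarray(distance_edges_px, dtype=float)
    nbin = len(edges) - 1
    initiations = np.zeros(nbin)
    seconds = np.zeros(nbin)
    dt = 1.0 / calib.frames_per_second
    for track, events in zip(tracks, events_per_track):
        pos = track.positions()
        dist = np.hypot(*(pos - np.asarray(target)).T)
        idx = np.digitize(dist, edges) - 1
        ok = (idx >= 0) & (idx < nbin)
        np.add.at(seconds, idx[ok], dt)
        frame0 = track.points[0].frame_index
        for ev in events:
            k = int(round(ev.start_s * calib.frames_per_second)) - frame0
            if 0 <= k < len(dist) and ok[k]:
                initiations[idx[k]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = initiations / seconds
    rate[seconds == 0] = np.nan
    return rate


def roi_kinetics(
    tracks: list[Track],
    rois: RoiSet,
    n_frames: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame occupancy counts and cumulative first arrivals per ROI.

    Returns (counts, cumulative): both indexed by frame with one column per
    ROI label.  A track is counted in a frame when its position lies inside
    the circle; the cumulative series counts distinct tracks that have
    entered the ROI by that frame and is therefore non-decreasing.
    """
    labels = list(rois.circles)
    _warn_on_overlap(rois)
    counts = np.zeros((n_frames, len(labels)), dtype=int)
    first_entry = {lab: [] for lab in labels}
    for track in tracks:
        frames = np.array([p.frame_index for p in track.points])
        pos = track.positions()
        for j, lab in enumerate(labels):
            cx, cy, r = rois.circles[lab]
            inside = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy) <= r
            valid = inside & (frames < n_frames)
            counts[frames[valid], j] += 1
            if valid.any():
                first_entry[lab].append(int(frames[valid].min()))
    cumulative = np.zeros((n_frames, len(labels)), dtype=int)
    for j, lab in enumerate(labels):
        for f in first_entry[lab]:
            cumulative[f:, j] += 1
    idx = pd.RangeIndex(n_frames, name="frame_index")
    return (
        pd.DataFrame(counts, index=idx, columns=labels),
        pd.DataFrame(cumulative, index=idx, columns=labels),
    )


def _warn_on_overlap(rois: RoiSet) -> None:
    items = list(rois.circles.items())
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (la, (xa, ya, ra)), (lb, (xb, yb, rb)) = items[i], items[j]
            if np.hypot(xa - xb, ya - yb) < ra + rb:
                warnings.warn(f"ROIs {la!r} and {lb!r} overlap; tracks may count in both", stacklevel=3)


def chemotaxis_rate(
    cumulative_arrivals: np.ndarray,
    times_s: np.ndarray,
    normalize_by: float | None = None,
) -> tuple[float, float]:
    """OLS slope (and its standard error) of cumulative arrivals vs time.

    ``normalize_by`` (e.g. the number of animals loaded) rescales the series
    to a fraction before fitting.  A constant series has slope 0.
    """
    y = np.asarray(cumulative_arrivals, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two points to fit a rate")
    if normalize_by:
        y = y / normalize_by
    if np.ptp(y) == 0:
        return 0.0, 0.0
    fit = stats.linregress(t, y)
    return float(fit.slope), float(fit.stderr)


def attraction_field(
    tracks: list[Track],
    arena_wh_px: tuple[float, float],
    nx: int = 35,
    ny: int = 25,
) -> AttractionField:
    """Bin the arena into nx x ny cells; per cell report the point occupancy
    and the mean unit direction of steps originating in it."""
    w, h = arena_wh_px
    x_edges = np.linspace(0, w, nx + 1)
    y_edges = np.linspace(0, h, ny + 1)
    occupancy = np.zeros((ny, nx), dtype=int)
    vec_sum = np.zeros((ny, nx, 2))
    vec_n = np.zeros((ny, nx), dtype=int)
    for track in tracks:
        pos = track.positions()
        ix = np.clip(np.digitize(pos[:, 0], x_edges) - 1, 0, nx - 1)
        iy = np.clip(np.digitize(pos[:, 1], y_edges) - 1, 0, ny - 1)
        in_arena = (pos[:, 0] >= 0) & (pos[:, 0] <= w) & (pos[:, 1] >= 0) & (pos[:, 1] <= h)
        np.add.at(occupancy, (iy[in_arena], ix[in_arena]), 1)
        v = step_vectors(track)
        norm = np.hypot(v[:, 0], v[:, 1])
        moving = (norm > 0) & in_arena[:-1]
        unit = np.zeros_like(v)
        unit[moving] = v[moving] / norm[moving, None]
        np.add.at(vec_sum, (iy[:-1][moving], ix[:-1][moving]), unit[moving])
        np.add.at(vec_n, (iy[:-1][moving], ix[:-1][moving]), 1)
    direction = np.zeros((ny, nx, 2))
    nz = vec_n > 0
    direction[nz] = vec_sum[nz] / vec_n[nz, None]
    return AttractionField(x_edges=x_edges, y_edges=y_edges, occupancy=occupancy, direction=direction)


def delta_bearing_histogram(
    events: list[PirouetteEvent],
    bins: int | np.ndarray = 10,
) -> dict[str, object]:
    """Histograms of cos(dB) for on-course vs off-course pirouette entries.

    Events are split by entry bearing: on-course when |B_before| < 90 deg,
    off-course otherwise.  Events with undefined bearings are skipped and
    their count reported.
    """
    edges = np.linspace(-1, 1, bins + 1) if np.isscalar(bins) else np.asarray(bins)
    groups = {"on_course": [], "off_course": []}
    skipped = 0
    for ev in events:
        if not (np.isfinite(ev.B_before) and np.isfinite(ev.B_after)):
            skipped += 1
            continue
        key = "on_course" if abs(ev.B_before) < 90.0 else "off_course"
        groups[key].append(np.cos(np.radians(ev.delta_B)))
    out: dict[str, object] = {"bin_edges": edges, "n_skipped": skipped}
    for key, vals in groups.items():
        hist, _ = np.histogram(vals, bins=edges)
        out[key] = hist
    return out
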