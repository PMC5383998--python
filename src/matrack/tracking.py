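"""Multi-animal track linking.

Animal-classified detections are linked frame-to-frame by greedy
nearest-neighbor matching against each active track's *predicted* position.
The predictor is a constant-acceleration extrapolation over the last three
points (a minimal Kalman-type motion model): when a track finds no match —
because of a collision, an occlusion, or a missed detection — the prediction
itself is appended as a provisional point, and tracking resumes seamlessly if
the animal reappears within the next three frames.  A track unmatched for a
fourth consecutive frame is terminated and its trailing never-confirmed
predictions are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detection import Entity, MahalanobisAnimalClassifier, SegmentationParams, segment_entities

MAX_MISSING_FRAMES = 3

__all__ = [
    "TrackPoint",
    "Track",
    "LinkingParams",
    "predict_position",
    "assign_entities",
    "step_tracks",
    "track_movie",
    "track_length_heatmap",
    "score_collisions",
    "score_detection",
    "filter_active_tracks",
    "estimate_gate",
]


@dataclass
class TrackPoint:
    frame_index: int
    position: tuple[float, float]
    source: str  # "observed" | "predicted"


@dataclass
class Track:
    """One animal's trajectory: consecutive frames, observed or predicted."""

    id: int
    points: list[TrackPoint] = field(default_factory=list)
    state: str = "active"
    missing_count: int = 0

    @property
    def last_frame(self) -> int:
        return self.points[-1].frame_index

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points], dtype=float)

    def duration_s(self, fps: float = 1.0) -> float:
        return (self.points[-1].frame_index - self.points[0].frame_index) / fps

    def path_length_px(self) -> float:
        pos = self.positions()
        if len(pos) < 2:
            return 0.0
        return float(np.hypot(*np.diff(pos, axis=0).T).sum())


@dataclass
class LinkingParams:
    """Linking configuration.

    gate_px: maximum allowed match distance between a predicted position and
    a detection centroid (None -> estimated from the data, see
    :func:`estimate_gate`).  collision_radius_px: proximity defining a
    collision event between two animals (default 15 px, ~0.4 mm at the
    reference calibration).  use_predictor=False falls back to matching
    against the last observed position with no occlusion bridging.
    """

    gate_px: float | None = None
    collision_radius_px: float = 15.0
    use_predictor: bool = True
    min_track_frames: int = 3

    def __post_init__(self) -> None:
        if self.gate_px is not None and self.gate_px <= 0:
            raise ValueError("gate_px must be positive")


def predict_position(track: Track) -> tuple[float, float]:
    """Constant-acceleration extrapolation from the last three points.

    With >= 3 points: next = 3*p_t - 3*p_{t-1} + p_{t-2} (i.e. p + v + a,
    with v and a finite differences of the last positions).  With 2 points:
    constant velocity 2*p_t - p_{t-1}.  With 1 point: the point itself.
    """
    if not track.points:
        raise ValueError("cannot predict from an empty track")
    pos = track.positions()
    if len(pos) >= 3:
        nxt = 3 * pos[-1] - 3 * pos[-2] + pos[-3]
    elif len(pos) == 2:
        nxt = 2 * pos[-1] - pos[-2]
    else:
        nxt = pos[-1]
    return float(nxt[0]), float(nxt[1])


def _reference_position(track: Track, use_predictor: bool) -> tuple[float, float]:
    if use_predictor:
        return predict_position(track)
    return track.points[-1].position


def assign_entities(
    active: Sequence[Track],
    detections: Sequence[Entity],
    params: LinkingParams,
) -> tuple[dict[int, int], list[int], list[int]]:
    """Greedy one-to-one matching by ascending prediction-to-detection distance.

    Returns (assignment, unmatched_track_idx, unmatched_detection_idx) where
    ``assignment`` maps track list-index -> detection list-index.  Pairs
    farther apart than ``gate_px`` are never matched.
    """
    gate = params.gate_px if params.gate_px is not None else np.inf
    if not active or not detections:
        return {}, list(range(len(active))), list(range(len(detections)))
    preds = np.array([_reference_position(t, params.use_predictor) for t in active])
    cents = np.array([d.centroid for d in detections])
    dists = np.hypot(
        preds[:, None, 0] - cents[None, :, 0], preds[:, None, 1] - cents[None, :, 1]
    )
    order = np.dstack(np.unravel_index(np.argsort(dists, axis=None), dists.shape))[0]
    assignment: dict[int, int] = {}
    used_det: set[int] = set()
    for ti, di in order:
        ti, di = int(ti), int(di)
        if dists[ti, di] > gate:
            break
        if ti in assignment or di in used_det:
            continue
        assignment[ti] = di
        used_det.add(di)
    unmatched_tracks = [i for i in range(len(active)) if i not in assignment]
    unmatched_dets = [j for j in range(len(detections)) if j not in used_det]
    return assignment, unmatched_tracks, unmatched_dets


def _strip_trailing_predictions(track: Track) -> None:
    while track.points and track.points[-1].source == "predicted":
        track.points.pop()


def step_tracks(
    tracks: list[Track],
    detections: Sequence[Entity],
    frame_index: int,
    params: LinkingParams,
    next_id: int,
) -> int:
    """Advance all tracks by one frame in place; returns the next free track id.

    Matched tracks append an observed point and reset their miss counter;
    unmatched active tracks coast on their prediction for up to
    ``MAX_MISSING_FRAMES`` frames, after which they are terminated and
    trailing unconfirmed predictions are removed.  Every unmatched detection
    seeds a new track.
    """
    active = [t for t in tracks if t.state == "active"]
    assignment, unmatched_t, unmatched_d = assign_entities(active, detections, params)
    for ti, di in assignment.items():
        track = active[ti]
        track.points.append(
            TrackPoint(frame_index, detections[di].centroid, "observed")
        )
        track.missing_count = 0
    max_missing = MAX_MISSING_FRAMES if params.use_predictor else 0
    for ti in unmatched_t:
        track = active[ti]
        track.missing_count += 1
        if track.missing_count > max_missing:
            track.state = "terminated"
            _strip_trailing_predictions(track)
        else:
            # first miss: full constant-acceleration prediction; further
            # misses coast at constant velocity so the extrapolation never
            # compounds its own acceleration estimate
            if track.missing_count == 1 or len(track.points) < 2:
                pred = predict_position(track)
            else:
                pos = track.positions()
                nxt = 2 * pos[-1] - pos[-2]
                pred = (float(nxt[0]), float(nxt[1]))
            track.points.append(TrackPoint(frame_index, pred, "predicted"))
    for di in unmatched_d:
        tracks.append(
            Track(
                id=next_id,
                points=[TrackPoint(frame_index, detections[di].centroid, "observed")],
            )
        )
        next_id += 1
    return next_id


def estimate_gate(
    detections_per_frame: Sequence[Sequence[Entity]],
    n_frames: int = 50,
    factor: float = 4.0,
    fallback_px: float = 20.0,
) -> float:
    """Gate = ``factor`` x median nearest-neighbor displacement between
    consecutive frames over the first ``n_frames`` frames."""
    steps: list[float] = []
    for prev, cur in zip(detections_per_frame[: n_frames - 1], detections_per_frame[1:n_frames]):
        if not prev or not cur:
            continue
        p = np.array([e.centroid for e in prev])
        c = np.array([e.centroid for e in cur])
        d = np.hypot(p[:, None, 0] - c[None, :, 0], p[:, None, 1] - c[None, :, 1])
        steps.extend(d.min(axis=1))
    if not steps:
        return fallback_px
    gate = factor * float(np.median(steps))
    return gate if gate > 0 else fallback_px


def track_movie(
    frames: Iterable[np.ndarray],
    model: MahalanobisAnimalClassifier | None,
    seg: SegmentationParams,
    link: LinkingParams,
) -> list[Track]:
    """Segment, classify, and link a whole movie into tracks.

    ``model=None`` disables the one-class filter (every segmented entity is
    treated as an animal).  Deterministic: identical inputs give identical
    tracks.  Tracks confirmed on fewer than ``link.min_track_frames`` frames
    are dropped from the output.
    """
    detections_per_frame: list[list[Entity]] = []
    for idx, frame in enumerate(frames):
        try:
            entities = segment_entities(frame, seg, frame_index=idx)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"failed to process frame {idx}: {exc}") from exc
        if model is not None and entities:
            feats = np.array([e.features for e in entities])
            keep = model.predict(feats)
            entities = [e for e, k in zip(entities, keep) if k]
        detections_per_frame.append(entities)

    params = link
    if link.gate_px is None:
        params = LinkingParams(
            gate_px=estimate_gate(detections_per_frame),
            collision_radius_px=link.collision_radius_px,
            use_predictor=link.use_predictor,
            min_track_frames=link.min_track_frames,
        )

    tracks: list[Track] = []
    next_id = 0
    for idx, detections in enumerate(detections_per_frame):
        next_id = step_tracks(tracks, detections, idx, params, next_id)
    for t in tracks:
        if t.state == "active":
            t.state = "terminated"
            _strip_trailing_predictions(t)
    n_obs = lambda t: sum(p.source == "observed" for p in t.points)
    return [t for t in tracks if n_obs(t) >= params.min_track_frames]


def filter_active_tracks(tracks: Sequence[Track], activity_min_px: float = 2.0) -> list[Track]:
    """Drop tracks with total path length below ``activity_min_px``.

    Used in aging assays so that dead (immobile) animals do not bias the
    population speed statistics downward.
    """
    return [t for t in tracks if t.path_length_px() >= activity_min_px]


def track_length_heatmap(
    tracks: Sequence[Track],
    window_edges_s: np.ndarray,
    fps: float = 1.0,
) -> np.ndarray:
    """Mean track length (s) inside every time window [t_i, t_j].

    Cell (i, j) with i <= j holds the mean, over tracks overlapping the
    window, of the duration of their overlap with it; cells with i > j or no
    overlapping track are NaN.
    """
    edges = np.asarray(window_edges_s, dtype=float)
    k = len(edges)
    out = np.full((k, k), np.nan)
    spans = [
        (t.points[0].frame_index / fps, t.points[-1].frame_index / fps) for t in tracks
    ]
    for i in range(k):
        for j in range(i, k):
            lo, hi = edges[i], edges[j]
            overlaps = [
                min(b, hi) - max(a, lo) for a, b in spans if min(b, hi) >= max(a, lo)
            ]
            if overlaps:
                out[i, j] = float(np.mean(overlaps))
    return out


def _track_position_at(track: Track, frame: int) -> tuple[float, float] | None:
    for p in track.points:
        if p.frame_index == frame:
            return p.position
    return None


def _identity_at(
    tracks: Sequence[Track],
    truth_xy: tuple[float, float],
    frame: int,
    match_radius_px: float,
) -> int | None:
    """Track id closest to a ground-truth position at ``frame`` within radius."""
    best, best_d = None, match_radius_px
    for t in tracks:
        pos = _track_position_at(t, frame)
        if pos is None:
            continue
        d = float(np.hypot(pos[0] - truth_xy[0], pos[1] - truth_xy[1]))
        if d <= best_d:
            best, best_d = t.id, d
    return best


def score_collisions(
    tracks: Sequence[Track],
    truth: pd.DataFrame,
    collision_events: Sequence[dict],
    match_radius_px: float = 5.0,
    margin_frames: int = 2,
) -> dict[str, float]:
    """Fraction of two-animal collisions after which 0, 1, or 2 identities persist.

    ``truth`` has columns frame_index, walker_id, x_px, y_px.  For each
    collision event, each participant's nearest track id is looked up just
    before and just after the event; the participant is resolved if the same
    id follows it through.  Returns ``{"resolved_0": f0, "resolved_1": f1,
    "resolved_2": f2, "n_events": n}`` (empty dict if no events).
    """
    if not collision_events:
        return {}
    counts = {0: 0, 1: 0, 2: 0}
    scored = 0
    for ev in collision_events:
        t0, t1 = int(ev["start_frame"]), int(ev["end_frame"])
        before, after = t0 - margin_frames, t1 + margin_frames
        resolved = 0
        usable = True
        for wid in ev["participants"]:
            sub = truth[truth.walker_id == wid]
            row_b = sub[sub.frame_index == before]
            row_a = sub[sub.frame_index == after]
            if row_b.empty or row_a.empty:
                usable = False
                break
            id_b = _identity_at(
                tracks, (row_b.x_px.iloc[0], row_b.y_px.iloc[0]), before, match_radius_px
            )
            id_a = _identity_at(
                tracks, (row_a.x_px.iloc[0], row_a.y_px.iloc[0]), after, match_radius_px
            )
            if id_b is not None and id_b == id_a:
                resolved += 1
        if usable:
            counts[resolved] += 1
            scored += 1
    if scored == 0:
        return {}
    return {
        "resolved_0": counts[0] / scored,
        "resolved_1": counts[1] / scored,
        "resolved_2": counts[2] / scored,
        "n_events": scored,
    }


def score_detection(
    detections_xy: Sequence[tuple[float, float]],
    truth_xy: Sequence[tuple[float, float]],
    match_radius_px: float = 5.0,
) -> tuple[float, float, float]:
    """Precision, recall, and F-score of detections against ground truth.

    One-to-one greedy matching by ascending distance within
    ``match_radius_px``.  Degenerate cases report 0 (never NaN).
    """
    n_det, n_tru = len(detections_xy), len(truth_xy)
    tp = 0
    if n_det and n_tru:
        det = np.asarray(detections_xy, dtype=float)
        tru = np.asarray(truth_xy, dtype=float)
        d = np.hypot(det[:, None, 0] - tru[None, :, 0], det[:, None, 1] - tru[None, :, 1])
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        used_d: set[int] = set()
        used_t: set[int] = set()
        for di, ti in order:
            di, ti = int(di), int(ti)
            if d[di, ti] > match_radius_px:
                break
            if di in used_d or ti in used_t:
                continue
            used_d.add(di)
            used_t.add(ti)
            tp += 1
    precision = tp / n_det if n_det else 0.0
    recall = tp / n_tru if n_tru else 0.0
    fscore = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, fscore
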