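import numpy as np
import pytest

from matrack import (
    LinkingParams,
    SegmentationParams,
    benchmark_suite,
    classify_entity,
    fit_classifier,
    generate_scene,
    score_detection,
    segment_entities,
    track_movie,
)


@pytest.fixture(scope="session")
def bench():
    """Canonical fixture scenes + manifest (seed fixed for the whole run)."""
    scenes, manifest = benchmark_suite(seed=1)
    return scenes, manifest


@pytest.fixture(scope="session")
def bench_seg(bench):
    _, manifest = bench
    return SegmentationParams(**manifest["segmentation"])


def train_from_truth(frames, truth, seg, train_frames=(0, 25, 49), beta=0.01):
    """Fit the one-class classifier from ground-truth walker positions
    (stands in for user clicks on genuine animals)."""
    feats = []
    for f in train_frames:
        ents = segment_entities(frames[f], seg, f)
        tp = truth.positions[truth.positions.frame_index == f]
        for rec in tp.itertuples():
            d = [np.hypot(e.centroid[0] - rec.x_px, e.centroid[1] - rec.y_px) for e in ents]
            if d and min(d) < 3.0:
                feats.append(ents[int(np.argmin(d))].features)
    return fit_classifier(np.array(feats), beta_fnr=beta)


def detection_metrics(frames, truth, seg, model):
    """Per-frame precision/recall and classified/raw counts over a movie."""
    precisions, recalls, kept_counts, raw_counts = [], [], [], []
    for f, frame in enumerate(frames):
        ents = segment_entities(frame, seg, f)
        kept = [e for e in ents if classify_entity(e, model) == "animal"]
        tp = truth.positions[truth.positions.frame_index == f]
        p, r, _ = score_detection(
            [e.centroid for e in kept], list(zip(tp.x_px, tp.y_px))
        )
        precisions.append(p)
        recalls.append(r)
        kept_counts.append(len(kept))
        raw_counts.append(len(ents))
    return (
        np.array(precisions),
        np.array(recalls),
        np.array(kept_counts),
        np.array(raw_counts),
    )


@pytest.fixture(scope="session")
def detection_scene_run(bench, bench_seg):
    """Detection scene: frames, truth, fitted model, per-frame metrics."""
    scenes, _ = bench
    frames, truth = generate_scene(scenes["detection"])
    model = train_from_truth(frames, truth, bench_seg)
    metrics = detection_metrics(frames, truth, bench_seg, model)
    return frames, truth, model, metrics


@pytest.fixture(scope="session")
def density_series_run(bench, bench_seg):
    """Mean continuous track length at 10/50/100/200 walkers."""
    scenes, _ = bench
    means = {}
    for n in (10, 50, 100, 200):
        frames, _ = generate_scene(scenes[f"density_{n}"])
        tracks = track_movie(frames, None, bench_seg, LinkingParams(gate_px=12))
        means[n] = float(np.mean([t.duration_s(1.0) for t in tracks]))
    return means


@pytest.fixture(scope="session")
def predictor_benefit_run(bench, bench_seg):
    """Mean track length with and without the motion predictor on the
    crossing/dropout scene."""
    scenes, _ = bench
    frames, _ = generate_scene(scenes["predictor_benefit"])
    out = {}
    for pred in (True, False):
        tracks = track_movie(
            frames, None, bench_seg, LinkingParams(gate_px=12, use_predictor=pred)
        )
        out[pred] = float(np.mean([t.duration_s(1.0) for t in tracks]))
    return out
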