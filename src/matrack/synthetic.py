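"""Synthetic dark-field movies with known ground truth.

Emulates the test conditions of multi-worm chemotaxis recordings: bright
blob-like animals moving over a noisy dark background, with background
clutter (condensation droplets, trail marks) whose count grows linearly in
time, plus programmed two-animal collisions and occlusion windows.  Every
generated scene carries its exact ground truth (per-frame positions,
collision events, occlusion windows), so detection, tracking, and behavior
analytics can be scored without any external data.

Animals are rendered as isotropic Gaussian spots; clutter spots are smaller
and dimmer by default, giving the blob features (area, intensity statistics)
a configurable separation from the animal class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WalkerSpec",
    "SceneConfig",
    "GroundTruth",
    "generate_scene",
    "make_crossing_pair",
    "find_collision_events",
    "benchmark_suite",
]


@dataclass
class WalkerSpec:
    """One programmed walker: linear or random-walk motion.

    ``random_walk`` is a correlated (persistent) walk — constant step length
    ``step_sd_px`` with per-frame heading diffusion ``turn_sd_rad`` —
    emulating the heading persistence of crawling animals.
    ``occluded_frames`` lists frames where the walker exists (and is logged
    in the ground truth) but is not rendered.
    """

    start_xy: tuple[float, float]
    velocity_px_f: tuple[float, float] = (0.0, 0.0)
    kind: str = "linear"  # "linear" | "random_walk"
    step_sd_px: float = 1.5  # random-walk step length (px/frame)
    turn_sd_rad: float = 0.25  # random-walk heading diffusion per frame
    occluded_frames: tuple[int, ...] = ()


@dataclass
class SceneConfig:
    arena_wh_px: tuple[int, int] = (200, 200)
    n_frames: int = 60
    walkers: list[WalkerSpec] = field(default_factory=list)
    walker_peak: float = 200.0
    walker_sigma_px: float = 2.5
    clutter_initial: int = 0
    clutter_growth_per_frame: float = 0.0
    clutter_peak: float = 60.0
    clutter_sigma_px: float = 1.1
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.arena_wh_px
        if w * h < 100 * max(1, len(self.walkers)):
            raise ValueError("arena too small for the requested walker count")


@dataclass
class GroundTruth:
    positions: pd.DataFrame  # frame_index, walker_id, x_px, y_px, rendered
    collision_events: list[dict]
    occlusion_windows: dict[int, tuple[int, ...]]
    clutter_counts: list[int] = field(default_factory=list)  # per frame


def _render_spot(frame: np.ndarray, x: float, y: float, peak: float, sigma: float) -> None:
    h, w = frame.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    xs = np.arange(max(x0, 0), min(x1, w))
    ys = np.arange(max(y0, 0), min(y1, h))
    if xs.size == 0 or ys.size == 0:
        return
    gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
    frame[np.ix_(ys, xs)] += peak * gy[:, None] * gx[None, :]


def _walker_positions(spec: WalkerSpec, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Positions over all frames.  Random walkers reflect off the arena
    bounds; linear walkers may leave the arena (NaN afterwards: track end)."""
    w, h = config.arena_wh_px
    pos = np.empty((config.n_frames, 2))
    pos[0] = spec.start_xy
    heading = rng.uniform(-np.pi, np.pi)
    for t in range(1, config.n_frames):
        if spec.kind == "linear":
            pos[t] = pos[t - 1] + spec.velocity_px_f
        elif spec.kind == "random_walk":
            heading += rng.normal(0.0, spec.turn_sd_rad)
            pos[t] = pos[t - 1] + spec.step_sd_px * np.array(
                [np.cos(heading), np.sin(heading)]
            )
            # reflecting bounds (mirror the heading component as well)
            for k, bound in enumerate((w - 1.0, h - 1.0)):
                if pos[t, k] < 0 or pos[t, k] > bound:
                    pos[t, k] = -pos[t, k] if pos[t, k] < 0 else 2 * bound - pos[t, k]
                    heading = np.pi - heading if k == 0 else -heading
        else:
            raise ValueError(f"unknown walker kind {spec.kind!r}")
    if spec.kind == "linear":
        margin = 2.0
        outside = (
            (pos[:, 0] < margin)
            | (pos[:, 0] > w - 1 - margin)
            | (pos[:, 1] < margin)
            | (pos[:, 1] > h - 1 - margin)
        )
        if outside.any():
            first = int(np.argmax(outside))
            pos[first:] = np.nan
    return pos


def find_collision_events(
    positions: pd.DataFrame, collision_radius_px: float = 15.0
) -> list[dict]:
    """Collision events: maximal frame runs where a pair of walkers is closer
    than ``collision_radius_px``.  Each event dict has start_frame,
    end_frame, participants."""
    events: list[dict] = []
    ids = sorted(positions.walker_id.unique())
    by_id = {
        wid: positions[positions.walker_id == wid].set_index("frame_index")[["x_px", "y_px"]]
        for wid in ids
    }
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            pa, pb = by_id[ids[a]], by_id[ids[b]]
            common = pa.index.intersection(pb.index)
            if common.empty:
                continue
            d = np.hypot(
                pa.loc[common, "x_px"].to_numpy() - pb.loc[common, "x_px"].to_numpy(),
                pa.loc[common, "y_px"].to_numpy() - pb.loc[common, "y_px"].to_numpy(),
            )
            close = d < collision_radius_px
            frames = common.to_numpy()
            start = None
            for k, frame in enumerate(frames):
                if close[k] and start is None:
                    start = frame
                run_ends = (not close[k]) or k == len(frames) - 1
                if start is not None and run_ends:
                    end = frame if close[k] else frames[k - 1]
                    events.append(
                        {
                            "start_frame": int(start),
                            "end_frame": int(end),
                            "participants": (int(ids[a]), int(ids[b])),
                        }
                    )
                    start = None
    events.sort(key=lambda e: e["start_frame"])
    return events


def generate_scene(
    config: SceneConfig, collision_radius_px: float = 15.0
) -> tuple[list[np.ndarray], GroundTruth]:
    """Render a movie and its ground truth.  Deterministic given the seed."""
    rng = np.random.default_rng(config.rng_seed)
    w, h = config.arena_wh_px
    walker_rngs = [
        np.random.default_rng(child)
        for child in np.random.SeedSequence(config.rng_seed).spawn(len(config.walkers) + 1)
    ]
    clutter_rng = walker_rngs[-1]
    all_pos = [
        _walker_positions(spec, config, walker_rngs[i])
        for i, spec in enumerate(config.walkers)
    ]

    # clutter spots persist once created (trail marks / condensation)
    clutter_xy: list[tuple[float, float]] = [
        (clutter_rng.uniform(5, w - 5), clutter_rng.uniform(5, h - 5))
        for _ in range(config.clutter_initial)
    ]

    frames: list[np.ndarray] = []
    records = []
    clutter_counts: list[int] = []
    for t in range(config.n_frames):
        frame = np.zeros((h, w))
        target_count = config.clutter_initial + config.clutter_growth_per_frame * t
        while len(clutter_xy) < int(round(target_count)):
            clutter_xy.append((clutter_rng.uniform(5, w - 5), clutter_rng.uniform(5, h - 5)))
        clutter_counts.append(len(clutter_xy))
        for cx, cy in clutter_xy:
            _render_spot(frame, cx, cy, config.clutter_peak, config.clutter_sigma_px)
        for wid, (spec, pos) in enumerate(zip(config.walkers, all_pos)):
            x, y = pos[t]
            if np.isnan(x):
                continue
            rendered = t not in spec.occluded_frames
            if rendered:
                _render_spot(frame, x, y, config.walker_peak, config.walker_sigma_px)
            records.append((t, wid, float(x), float(y), rendered))
        if config.noise_sd > 0:
            frame = np.clip(frame + rng.normal(0.0, config.noise_sd, frame.shape), 0, None)
        frames.append(frame)

    positions = pd.DataFrame(
        records, columns=["frame_index", "walker_id", "x_px", "y_px", "rendered"]
    )
    occlusions = {
        wid: spec.occluded_frames
        for wid, spec in enumerate(config.walkers)
        if spec.occluded_frames
    }
    truth = GroundTruth(
        positions=positions,
        collision_events=find_collision_events(positions, collision_radius_px),
        occlusion_windows=occlusions,
        clutter_counts=clutter_counts,
    )
    return frames, truth


def make_crossing_pair(
    angle_deg: float,
    speed_px_f: float,
    arena_wh_px: tuple[int, int] = (200, 200),
    n_frames: int = 60,
    speed2_px_f: float | None = None,
) -> list[WalkerSpec]:
    """Two linear walkers whose paths cross at the scene center mid-movie.

    The paths intersect at ``angle_deg`` (0 < angle < 180); both walkers
    reach the center at the same frame, so their minimum mutual distance is
    zero at the crossing.  Shallower angles keep the pair within collision
    range for longer.  ``speed2_px_f`` gives the second walker a different
    speed (unequal speeds keep the matching problem non-degenerate at the
    symmetric crossing point).
    """
    if not 0.0 < angle_deg < 180.0:
        raise ValueError("crossing angle must lie strictly between 0 and 180 deg")
    if speed_px_f <= 0 or (speed2_px_f is not None and speed2_px_f <= 0):
        raise ValueError("speed must be positive")
    cx, cy = arena_wh_px[0] / 2.0, arena_wh_px[1] / 2.0
    t_cross = n_frames // 2
    half = np.radians(angle_deg) / 2.0
    speeds = (speed_px_f, speed_px_f if speed2_px_f is None else speed2_px_f)
    specs = []
    for sign, speed in zip((+1.0, -1.0), speeds):
        direction = np.array([np.cos(sign * half), np.sin(sign * half)])
        v = speed * direction
        start = np.array([cx, cy]) - t_cross * v
        specs.append(WalkerSpec(start_xy=(float(start[0]), float(start[1])), velocity_px_f=(float(v[0]), float(v[1]))))
    return specs


def _grid_starts(n: int, arena_wh_px: tuple[int, int], margin: float = 15.0) -> list[tuple[float, float]]:
    w, h = arena_wh_px
    cols = int(np.ceil(np.sqrt(n * w / h)))
    rows = int(np.ceil(n / cols))
    xs = np.linspace(margin, w - margin, cols)
    ys = np.linspace(margin, h - margin, rows)
    pts = [(float(x), float(y)) for y in ys for x in xs]
    return pts[:n]


def benchmark_suite(seed: int = 0) -> tuple[dict[str, SceneConfig], dict[str, object]]:
    """The canonical fixture set used by the acceptance checks.

    Returns (scenes, manifest):

    * ``detection`` — constant walkers, clutter growing linearly;
    * ``density_10/50/100/200`` — random walkers at increasing density in a
      shared arena with shared noise settings;
    * ``crossing`` — programmed two-walker collisions at several angles;
    * ``occlusion_gap_1..4`` — one walker hidden for 1-4 consecutive frames;
    * ``three_way`` — crossing walkers plus clutter, for the
      ML-off/predictor-off comparisons.
    """
    rng = np.random.default_rng(seed)
    scenes: dict[str, SceneConfig] = {}

    det_walkers = [
        WalkerSpec(start_xy=xy, kind="random_walk", step_sd_px=1.2)
        for xy in _grid_starts(12, (220, 220), margin=25)
    ]
    scenes["detection"] = SceneConfig(
        arena_wh_px=(220, 220),
        n_frames=50,
        walkers=det_walkers,
        clutter_initial=5,
        clutter_growth_per_frame=1.0,
        noise_sd=2.0,
        rng_seed=int(rng.integers(2**31)),
    )

    for n in (10, 50, 100, 200):
        walkers = [
            WalkerSpec(start_xy=xy, kind="random_walk", step_sd_px=2.0)
            for xy in _grid_starts(n, (400, 400), margin=12)
        ]
        scenes[f"density_{n}"] = SceneConfig(
            arena_wh_px=(400, 400),
            n_frames=50,
            walkers=walkers,
            noise_sd=2.0,
            rng_seed=int(rng.integers(2**31)),
        )

    # fast, unequal-speed crossing: the collision is unambiguous to score and
    # brief enough (1-2 merged frames) for the predictor to bridge cleanly
    scenes["crossing"] = SceneConfig(
        arena_wh_px=(300, 300),
        n_frames=50,
        walkers=make_crossing_pair(90.0, 7.0, (300, 300), 50, speed2_px_f=4.0),
        walker_sigma_px=2.0,
        rng_seed=int(rng.integers(2**31)),
    )

    # 20 walkers on crossing paths with ~3% detection dropout (occlusions)
    pb_walkers: list[WalkerSpec] = []
    pb_rng = np.random.default_rng(seed + 17)
    for _ in range(10):
        pair = make_crossing_pair(
            float(pb_rng.uniform(40, 140)), 3.0, (500, 500), 60,
            speed2_px_f=float(pb_rng.uniform(1.5, 2.5)),
        )
        dx, dy = pb_rng.uniform(-160, 160, 2)
        for s in pair:
            occl = tuple(int(f) for f in pb_rng.choice(60, size=2, replace=False))
            pb_walkers.append(
                WalkerSpec(
                    start_xy=(s.start_xy[0] + dx, s.start_xy[1] + dy),
                    velocity_px_f=s.velocity_px_f,
                    occluded_frames=occl,
                )
            )
    scenes["predictor_benefit"] = SceneConfig(
        arena_wh_px=(500, 500), n_frames=60, walkers=pb_walkers,
        rng_seed=int(rng.integers(2**31)),
    )

    for gap in (1, 2, 3, 4):
        walker = WalkerSpec(
            start_xy=(20.0, 100.0),
            velocity_px_f=(2.5, 0.0),
            occluded_frames=tuple(range(25, 25 + gap)),
        )
        scenes[f"occlusion_gap_{gap}"] = SceneConfig(
            arena_wh_px=(200, 200), n_frames=50, walkers=[walker],
            rng_seed=int(rng.integers(2**31)),
        )

    three_way = [
        WalkerSpec(start_xy=xy, kind="random_walk", step_sd_px=2.0)
        for xy in _grid_starts(20, (300, 300), margin=20)
    ]
    scenes["three_way"] = SceneConfig(
        arena_wh_px=(300, 300),
        n_frames=50,
        walkers=three_way,
        clutter_initial=10,
        clutter_growth_per_frame=1.0,
        noise_sd=2.0,
        rng_seed=int(rng.integers(2**31)),
    )

    manifest = {
        "seed": seed,
        "walker_counts": {name: len(cfg.walkers) for name, cfg in scenes.items()},
        "n_frames": {name: cfg.n_frames for name, cfg in scenes.items()},
        "density_arena": (400, 400),
        "segmentation": {"sigma_log": 2.5, "binarize_threshold": 5.0, "min_area_px": 4},
    }
    return scenes, manifest
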