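"""Point-worm chemotaxis simulation under three pirouette-exit strategies.

A simulated worm is a point moving at constant speed; at each time step it
may initiate a pirouette (an instantaneous reorientation) with a per-second
probability that depends on its current bearing toward the target: worms
heading roughly at the target (|B| < 90 deg, "directed") pirouette rarely,
worms heading away ("undirected") pirouette five times as often — the
classic biased-random-walk (klinokinesis) picture.  What distinguishes the
three strategies is how the directional change dB = B_before - B_after is
drawn at each pirouette:

* ``uniform_random`` — dB uniform on (-180, 180];
* ``empirical_unconditional`` — dB drawn from one pooled distribution of
  observed directional changes, ignoring the entry bearing;
* ``empirical_conditional`` — dB drawn from a distribution conditioned on
  whether the worm entered the pirouette on-course or off-course.

The default conditional sampler is a synthetic stand-in for experimental
exit-angle tables: a two-component wrapped-normal mixture with modes at
0 deg and 180 deg, mirroring the observed bimodality of post-pirouette
directional changes.  The mode that keeps on-course worms on course (dB ~ 0)
and the mode that turns off-course worms around (|dB| ~ 180) each carry the
dominant weight (0.9) in their group; the angular spread (60 deg) gives the
turn-around mode enough dispersion that a flip can land near the target
direction from any off-course entry bearing.  Empirical dB tables exported
by the behavior module can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "ExitAngleModel",
    "SimResult",
    "default_models",
    "sample_exit_angle",
    "simulate_worm",
    "simulate_strategy",
    "compare_strategies",
]

STRATEGIES = ("uniform_random", "empirical_unconditional", "empirical_conditional")


def _wrap_deg(a):
    a = np.asarray(a, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


@dataclass
class SimConfig:
    """Simulation geometry and kinetics.

    Start and target are 30 mm apart by default (the triangle-edge source
    separation of the reference chemotaxis assay); runs are straight at
    ``speed_mm_s`` and pirouettes are instantaneous.  Per-second pirouette
    probabilities: 0.03 while directed at the target, five-fold (0.15) while
    undirected.
    """

    start_xy: tuple[float, float] = (0.0, 0.0)
    target_xy: tuple[float, float] = (30.0, 0.0)
    speed_mm_s: float = 0.15
    p_pir_directed: float = 0.03
    p_pir_undirected: float = 0.15
    arrival_radius_mm: float = 2.0
    max_time_s: float = 3600.0
    dt_s: float = 1.0
    n_worms: int = 250
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_mm_s <= 0 or self.dt_s <= 0:
            raise ValueError("speed and dt must be positive")
        for p in (self.p_pir_directed, self.p_pir_undirected):
            if not 0.0 <= p * self.dt_s <= 1.0:
                raise ValueError("per-step pirouette probability must lie in [0, 1]")


def _wrapped_mixture_sampler(
    weight_zero: float, spread_deg: float = 30.0
) -> Callable[[np.random.Generator], float]:
    """Two-mode wrapped-normal mixture: mode 0 deg with ``weight_zero``,
    mode 180 deg with the remainder; both with the same angular spread."""

    def draw(rng: np.random.Generator) -> float:
        mode = 0.0 if rng.random() < weight_zero else 180.0
        return _wrap_deg(rng.normal(mode, spread_deg))

    return draw


def _table_sampler(values_deg: np.ndarray) -> Callable[[np.random.Generator], float]:
    values = np.asarray(values_deg, dtype=float)
    if values.size == 0:
        raise ValueError("empty directional-change table")

    def draw(rng: np.random.Generator) -> float:
        return _wrap_deg(values[rng.integers(values.size)])

    return draw


@dataclass
class ExitAngleModel:
    """How the directional change dB is drawn at a pirouette."""

    strategy: str
    on_course_sampler: Callable[[np.random.Generator], float] | None = None
    off_course_sampler: Callable[[np.random.Generator], float] | None = None
    pooled_sampler: Callable[[np.random.Generator], float] | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @classmethod
    def from_tables(
        cls, strategy: str, on_course_deg: np.ndarray, off_course_deg: np.ndarray
    ) -> "ExitAngleModel":
        """Build a model from observed dB tables (e.g. the behavior module's
        events CSV) instead of the parametric stand-in."""
        pooled = np.concatenate([np.asarray(on_course_deg), np.asarray(off_course_deg)])
        return cls(
            strategy=strategy,
            on_course_sampler=_table_sampler(on_course_deg),
            off_course_sampler=_table_sampler(off_course_deg),
            pooled_sampler=_table_sampler(pooled),
        )


def default_models(
    weight_preferred: float = 0.9, spread_deg: float = 60.0
) -> dict[str, ExitAngleModel]:
    """The three strategies with the default synthetic exit-angle mixtures.

    On-course entries favor dB ~ 0 (keep going) and off-course entries favor
    |dB| ~ 180 (turn around), each with weight ``weight_preferred``; the
    pooled sampler mixes the two groups equally.
    """
    on = _wrapped_mixture_sampler(weight_preferred, spread_deg)
    off = _wrapped_mixture_sampler(1.0 - weight_preferred, spread_deg)

    def pooled(rng: np.random.Generator) -> float:
        return on(rng) if rng.random() < 0.5 else off(rng)

    return {
        "uniform_random": ExitAngleModel("uniform_random"),
        "empirical_unconditional": ExitAngleModel(
            "empirical_unconditional", pooled_sampler=pooled
        ),
        "empirical_conditional": ExitAngleModel(
            "empirical_conditional", on_course_sampler=on, off_course_sampler=off
        ),
    }


def sample_exit_angle(
    model: ExitAngleModel, B_before_deg: float, rng: np.random.Generator
) -> float:
    """Draw the directional change dB (deg) for a pirouette entered at
    bearing ``B_before_deg``."""
    if model.strategy == "uniform_random":
        return _wrap_deg(rng.uniform(-180.0, 180.0))
    if model.strategy == "empirical_unconditional":
        return model.pooled_sampler(rng)
    sampler = (
        model.on_course_sampler
        if abs(_wrap_deg(B_before_deg)) < 90.0
        else model.off_course_sampler
    )
    return sampler(rng)


def _bearing_deg(heading_rad: float, pos: np.ndarray, target: np.ndarray) -> float:
    """Signed angle from the worm->target direction to the heading."""
    d = target - pos
    target_ang = np.arctan2(d[1], d[0])
    return _wrap_deg(np.degrees(heading_rad - target_ang))


@dataclass
class SimResult:
    strategy: str
    arrival_s: np.ndarray  # censored runs entered at max_time_s
    censored: np.ndarray
    trajectories: list[np.ndarray] | None = None

    @property
    def mean_s(self) -> float:
        return float(self.arrival_s.mean())

    @property
    def sem_s(self) -> float:
        return float(self.arrival_s.std(ddof=1) / np.sqrt(len(self.arrival_s)))


def simulate_worm(
    config: SimConfig,
    model: ExitAngleModel,
    rng: np.random.Generator,
    record_trajectory: bool = False,
) -> tuple[float, bool, np.ndarray | None]:
    """Simulate one worm; returns (arrival_time_s, censored, trajectory).

    Censored runs report max_time_s.  At each step the worm advances
    speed*dt along its heading; with the bearing-dependent per-step
    probability it then pirouettes: the new heading satisfies
    B_after = B_before - dB exactly.
    """
    pos = np.array(config.start_xy, dtype=float)
    target = np.array(config.target_xy, dtype=float)
    heading = rng.uniform(-np.pi, np.pi)
    traj = [pos.copy()] if record_trajectory else None
    t = 0.0
    if np.hypot(*(pos - target)) <= config.arrival_radius_mm:
        return 0.0, False, np.array(traj) if traj is not None else None
    while t < config.max_time_s:
        pos = pos + config.speed_mm_s * config.dt_s * np.array(
            [np.cos(heading), np.sin(heading)]
        )
        t += config.dt_s
        if traj is not None:
            traj.append(pos.copy())
        if np.hypot(*(pos - target)) <= config.arrival_radius_mm:
            return t, False, np.array(traj) if traj is not None else None
        b = _bearing_deg(heading, pos, target)
        p = config.p_pir_directed if abs(b) < 90.0 else config.p_pir_undirected
        if rng.random() < p * config.dt_s:
            db = sample_exit_angle(model, b, rng)
            heading = heading - np.radians(db)  # B_after = B_before - dB
    return config.max_time_s, True, np.array(traj) if traj is not None else None


def simulate_strategy(
    config: SimConfig,
    model: ExitAngleModel,
    record_trajectories: bool = False,
) -> SimResult:
    """Simulate ``config.n_worms`` independent worms under one strategy.

    Each worm uses its own counter-derived RNG substream, so results are
    reproducible and independent of evaluation order.
    """
    seq = np.random.SeedSequence(config.rng_seed)
    children = seq.spawn(config.n_worms)
    arrivals = np.empty(config.n_worms)
    censored = np.zeros(config.n_worms, dtype=bool)
    trajs: list[np.ndarray] | None = [] if record_trajectories else None
    for i, child in enumerate(children):
        t, c, traj = simulate_worm(
            config, model, np.random.default_rng(child), record_trajectories
        )
        arrivals[i], censored[i] = t, c
        if trajs is not None:
            trajs.append(traj)
    return SimResult(model.strategy, arrivals, censored, trajs)


def compare_strategies(
    config: SimConfig,
    models: dict[str, ExitAngleModel] | None = None,
) -> pd.DataFrame:
    """Simulate all three strategies and test the conditional one against
    each alternative (one-sided Wilcoxon rank-sum: conditional arrives
    earlier).  Censored worms are entered at max_time_s.

    Returns one row per strategy with mean_s, sem_s, n_censored and, for the
    non-conditional strategies, the rank-sum p-value against the conditional
    strategy (NaN when every run of both groups is censored).
    """
    if models is None:
        models = default_models()
    if config.n_worms < 2:
        raise ValueError("need at least 2 worms per strategy")
    results: dict[str, SimResult] = {}
    for k, name in enumerate(STRATEGIES):
        cfg = SimConfig(**{**config.__dict__, "rng_seed": config.rng_seed + 1000 * k})
        results[name] = simulate_strategy(cfg, models[name])
    cond = results["empirical_conditional"]
    rows = []
    for name in STRATEGIES:
        res = results[name]
        pval = np.nan
        if name != "empirical_conditional":
            if res.censored.all() and cond.censored.all():
                pval = np.nan  # indeterminate: nothing ever arrived
            else:
                pval = float(
                    stats.ranksums(cond.arrival_s, res.arrival_s, alternative="less").pvalue
                )
        rows.append(
            {
                "strategy": name,
                "mean_s": res.mean_s,
                "sem_s": res.sem_s,
                "n_worms": len(res.arrival_s),
                "n_censored": int(res.censored.sum()),
                "p_vs_conditional": pval,
            }
        )
    return pd.DataFrame(rows).set_index("strategy")
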