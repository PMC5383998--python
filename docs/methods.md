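# Methods

## Detection model

Candidate entities are the connected components of a thresholded
Laplacian-of-Gaussian response. The kernel is built explicitly (not via a
separable approximation): the analytic LoG at scale σ_LoG, truncated at
radius ⌈4σ⌉ px, negated so bright blobs give positive extrema, and re-centered
to an exactly zero sum so constant images map to an identically zero
response. Boundaries use nearest-edge replication, which preserves that
property. Binarization is a single fixed scalar threshold on the signed
response; polarity defaults to bright-on-dark with a config flag to invert.
Components smaller than `min_area_px` (default 3; the canonical fixtures use
4) are dropped; connectivity defaults to 8. Centroids are unweighted means
of member-pixel coordinates, reported 0-based as (x, y) = (column, row).
Features are computed from the *original* intensities of the member pixels,
in the fixed order (area, mean, median, min, max); extensions must append,
never reorder.

The one-class classifier estimates μ and the sample covariance Σ (ddof = 1)
from the training matrix of user-marked entities (m ≥ n + 1 required). The
acceptance threshold T(β) is the nearest-rank empirical quantile of the
training Mahalanobis distances at rank ⌈(1 − β)·m⌉, with β the target
false-negative rate, default 0.01. β = 0 therefore accepts every training
row (threshold = max training distance). If the covariance condition number
exceeds 1e8 the model adds ε·trace(Σ)/n to the diagonal (ε = 1e-6; ε alone
when the trace vanishes) and warns. Acceptance is inclusive: D(x) = T(β) is
an animal. Training clicks are snapped to the nearest segmented entity
within 10 px by default; unsnappable clicks are dropped with a warning.

The classifier is a scikit-learn estimator (`fit` / `predict` /
`mahalanobis`, `get_params`/`set_params`, fitted attributes with trailing
underscores), so it composes with sklearn model-selection tooling; the rest
of the pipeline (tracker, analytics, simulator) is not fit/predict-shaped
and is exposed as plain functions over dataclass configs.

## Tracking model

Matching is greedy on ascending distance between track predictions and
detection centroids, gated at `gate_px`; each track takes at most one
detection and vice versa. When no gate is given it is estimated as 4× the
median consecutive-frame nearest-neighbor displacement over the first 50
frames (fallback 20 px). Greedy equals the optimal assignment whenever
inter-animal spacing dominates prediction error — the regime the gate is
meant to enforce — and a brute-force oracle test guards that regime;
globally optimal assignment is deliberately out of scope.

Prediction uses the last three points: next = 3pₜ − 3pₜ₋₁ + pₜ₋₂
(constant-acceleration), degrading to constant velocity with two points and
to the point itself with one. While a track is coasting unmatched, the full
constant-acceleration step is applied only on the first miss; subsequent
misses extrapolate at constant velocity. Re-estimating acceleration from a
track's own predictions compounds one corrupted observation (e.g. the
centroid of two merged animals) into a runaway trajectory; freezing the
velocity keeps occlusion bridging exact for smooth motion while bounding
that failure mode. A track unmatched for four consecutive frames is
terminated, its trailing unconfirmed predictions removed (interior
predictions that were later confirmed are kept, flagged `predicted`).
Unmatched detections seed new tracks; tracks with fewer than 3 observed
frames (configurable) are not exported. An activity filter
(`filter_active_tracks`, default 2 px total path) excludes immobile animals
from speed statistics in aging assays so dead worms do not bias population
means.

## Behavior analytics

All angles are signed degrees in (−180, 180]; the off-course condition
"90° < B < 270°" is expressed as |B| > 90° (the same set under this
convention). Steps shorter than 0.5 px are treated as zero velocity:
excluded from every angle computation, counted as zero speed. Sharp turns
use a strict inequality (exactly 100° is not a turn). Pirouette bouts merge
turns whose corner times differ by less than T_crit = 5 s; a gap of exactly
5 s separates events. Entry/exit bearings are circular means over 3 steps
strictly before the first / after the last turn of the bout, NaN when the
window is incomplete; we deliberately do not skip windows that overlap a
preceding event. Reversals are operationalized as sharp turns above 150°
(`reversal_deg`): centroid tracks cannot distinguish a true reversal from a
very sharp turn, so this is a declared stand-in, exposed as a parameter.
Pirouette-probability-vs-distance reports initiations per track-second per
distance bin, NaN (not zero) for unvisited bins. Attraction fields bin the
arena 35×25 by default; per-bin direction is the mean of unit step vectors
of steps originating in the bin, so its norm is ≤ 1 by construction.
Chemotaxis rate β₁ is the OLS slope (with standard error) of the normalized
cumulative-arrival series against time. The first-visit filter masks a
track's projections after its first entry into the cue region.

## Simulator

A worm is a point at constant speed (default 0.15 mm/s) with instantaneous
pirouettes; the only stochastic elements are the per-step pirouette decision
and the exit angle. Per-second pirouette probabilities are 0.03 while
|B| < 90° and 0.15 otherwise (taken literally; note 0.03/s corresponds to
1.8, not 2, pirouettes per minute). Start and target are 30 mm apart
(equilateral-triangle assay geometry); arrival radius 2 mm, dt = 1 s,
horizon 3600 s (censored runs report the horizon), 250 worms per strategy,
no heading noise during runs by default. After a pirouette the new bearing
satisfies B_after = B_before − ΔB exactly. Each worm runs on its own
counter-derived RNG substream, so results are order-independent and
reproducible from one seed.

The experimental exit-angle tables that strategy (2) and (3) would sample
from are not part of this package, so the default samplers are a synthetic
stand-in: a two-mode wrapped-normal mixture with modes at ΔB = 0° and 180°
(matching the observed bimodality of post-pirouette directional changes),
weight 0.9 on the group-preferred mode (0° for on-course entries, 180° for
off-course) and angular spread 60°. The weight makes the group tendency
decisive — at near-even weights the conditioned strategy is statistically
indistinguishable from uniform sampling, defeating the comparison the
simulator exists to make — and the wide spread is what lets a turn-around
mode centred at 180° redirect a worm whose entry bearing is anywhere in the
off-course half-plane. Both parameters are config-exposed, and
`ExitAngleModel.from_tables` accepts real ΔB tables (e.g. exported from the
behavior module's events CSV).

**Known limitation.** Under this minimal model the advantage of the
conditioned strategy over uniform exits saturates near a 30% reduction in
mean time-to-target: sweeping the mixture weight to 1.0, spreads 15–90°,
and geometry variants (30–60 mm separation, 1–5 mm arrival radius) never
exceeds ≈ 33%, and even self-consistent empirical tables harvested from
ideal steering simulations reach only ≈ 39%. The reason is structural:
sampling ΔB from a group distribution can only mirror-flip an off-course
bearing, not aim the exit at the target, so precise target-ward exits are
unreachable no matter how the stand-in is parameterized. Reported reductions
from `scripts/acceptance.py` (~31%) should be read with this ceiling in
mind. The *direction* of the effect — conditioned exits significantly faster
than both alternatives at n = 250 (rank-sum p ≪ 0.01) — is robust to every
parameterization we tested. The pooled (unconditional) sampler measures
equal to or slightly slower than uniform sampling here, so no ordering claim
between those two is asserted.

## Synthetic fixtures

Walkers are rendered as isotropic Gaussian spots (default peak 200,
σ = 2.5 px); animal elongation is not modeled because the classifier uses
only scalar blob features. Clutter spots are smaller and dimmer (peak 60,
σ = 1.1 px), persist once created (trail marks / condensation), and their
count grows linearly in time; the walker/clutter feature margin is set by
these render parameters. Random walkers are correlated walks (constant step,
default heading diffusion 0.25 rad/frame) with reflecting bounds — a
white-noise walk is neither realistic for crawling animals nor predictable
by any motion model. Linear walkers may exit the arena, ending their ground
truth. Noise-free rendered centroids match stored truth within 0.5 px.
`make_crossing_pair` intersects two linear walkers at the scene center at
the same frame; unequal speeds (`speed2_px_f`) keep the matching problem
non-degenerate at the crossing. The canonical `benchmark_suite` scenes
(detection with growing clutter; densities 10/50/100/200 in a shared 400×400
arena; a fast 90° crossing; occlusion gaps 1–4; a 20-walker crossing scene
with ~3% occlusion dropout) use 50–60 frames and arenas of 220–500 px, sized
so the full suite of property checks runs in about a minute on one core.

What passing these fixtures does *not* show about real movies: blobs here
are radially symmetric and noise is Gaussian and stationary, clutter is
feature-separable by construction, and collisions involve exactly two
animals on linear paths. Real worm movies add elongated, undulating shapes,
illumination drift, and multi-animal pile-ups; detection accuracy and
collision resolution on such data must be validated against manual
annotation, for which `score_detection` / `score_collisions` accept any
gold-standard position table.

## Numerical conventions

Angles wrap to (−180, 180] with −180 mapped to +180. Circular means are
vector means. Mahalanobis distances clip tiny negative quadratic forms to
zero before the square root. Track CSVs round-trip positions exactly
(shortest-repr floats on write, `float_precision="round_trip"` on read).
Heatmap cells for zero-width windows touched by a track report 0;
windows no track overlaps report NaN. Precision/recall/F-score report 0, not
NaN, in degenerate cases (no detections or no truth).
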