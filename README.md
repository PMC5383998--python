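# matrack — a multi-animal tracker with chemotaxis analytics

`matrack` tracks many unmarked animals at once in grayscale time-lapse
movies — dozens to hundreds of *C. elegans* worms on an assay plate, but
nothing in the pipeline is worm-specific — and turns the resulting centroid
trajectories into quantitative behavior: speeds, bearings, sharp turns,
pirouettes, runs, ROI occupancy kinetics, attraction fields, and a
biased-random-walk chemotaxis simulator. It is aimed at labs running
high-throughput behavioral assays (chemotaxis, aging/proteotoxicity
locomotion screens) who need long individual tracks despite background
clutter and frequent animal collisions.

## The method

**Detection.** Each frame is convolved with a zero-sum Laplacian-of-Gaussian
kernel whose Gaussian scale σ_LoG selects the blob size of interest; the
thresholded response is split into connected components, and each candidate
entity is summarized by five features: area and the mean, median, minimum,
and maximum of its member-pixel intensities. Because the user only ever
marks *positive* examples (a few clicks on genuine animals), classification
is one-class: from the m×n training matrix S the model estimates μ = E(S)
and the covariance Σ, and accepts a query x as an animal iff its Mahalanobis
distance

    D(x) = sqrt((x − μ)ᵀ Σ⁻¹ (x − μ)) ≤ T(β)

where T(β) is the empirical (1 − β) quantile (nearest rank) of the training
distances, so β is the target false-negative rate (default 0.01). This makes
the detector robust to clutter that accumulates over long recordings
(condensation, trail marks): the raw entity count grows with time while the
animal-classified count stays flat.

**Tracking.** Animal-classified detections are linked frame-to-frame by
greedy nearest-neighbor matching against each track's *predicted* position,
extrapolated from its recent velocity and acceleration (next = 3pₜ − 3pₜ₋₁ +
pₜ₋₂; a minimal Kalman-style motion model). An unmatched track coasts on its
prediction and reclaims the animal when it reappears; after three
consecutive unmatched frames the track is terminated and its unconfirmed
predictions discarded. This bridges collisions and short occlusions and
measurably lengthens tracks.

**Behavior.** Bearing B is the signed angle between the velocity and the
animal→target vector (0° = straight at the target). Sharp turns are step
pairs enclosing > 100°; bouts of sharp turns separated by runs shorter than
T_crit = 5 s merge into pirouettes, with entry/exit bearings B_before /
B_after averaged over three steps on either side. Directness is the
projection proj(t) = ⟨v(t), d(t)⟩/|d(t)| = speed·cos(B). ROI kinetics count
animals in labeled circles per frame; attraction fields bin the arena
(default 35×25) into per-bin occupancy and mean movement direction.

**Simulation.** Point-worms move at constant speed and pirouette with
bearing-dependent per-second probability (0.03 on-course, 0.15 off-course).
Three exit-angle strategies are compared: uniform ΔB, pooled-empirical ΔB,
and ΔB conditioned on whether the worm entered the pirouette on- or
off-course. The conditioned strategy reaches the target fastest.

**Synthetic ground truth.** `matrack.synthetic` renders movies of
Gaussian-blob walkers with programmed collisions, occlusions, sensor noise,
and linearly growing clutter, together with exact per-frame truth — every
stage of the pipeline is validated against these fixtures.

## Worked example

```python
from matrack import SimConfig, compare_strategies

print(compare_strategies(SimConfig(n_worms=250, rng_seed=7)).round(3).to_string())
```

```
                          mean_s   sem_s  n_worms  n_censored  p_vs_conditional
strategy                                                                       
uniform_random           622.068  14.784      250           0               0.0
empirical_unconditional  643.148  15.253      250           0               0.0
empirical_conditional    431.440   8.103      250           0               NaN
```

Reading: 250 simulated worms per strategy start 30 mm from the target.
Worms that pick their pirouette exit angle conditioned on their entry
bearing arrive in 431 s on average, against 622 s for uniformly random
exits — about 31% faster, and the one-sided rank-sum test against each
alternative is significant far below p = 0.01. No worm was censored at the
3600 s horizon.

The same pipeline runs from the shell:

```bash
mat synth    --config scene.yaml --out scene/          # render a ground-truth movie
mat train    --movie scene/frames --clicks clicks.csv --sigma 2.5 --thresh 5 --out model.json
mat track    --movie scene/frames --model model.json --out tracks.csv
mat analyze  --tracks tracks.csv --config assay.yaml --out report/
mat simulate --seed 7 --out sim.csv
```

`mat track --no-ml` and `--no-predictor` disable the classifier and the
motion predictor for ablation comparisons.

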