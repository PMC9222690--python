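# Methods

## Problem and model

The optic disc in a disc-centered fundus ROI is a bright, approximately
elliptical region whose rim carries a strong radial intensity step in the
red channel. `discswarm` casts boundary detection as `N` coupled 1-D
extremum problems: partition an annular search region around the disc
center into `N` equal angular sectors, and in each sector find the point of
maximal radial gradient. A candidate boundary ("edge") is one point per
sector, closed by wrap; its fitness is the sum of its members' gradient
values. A particle swarm with one subgroup per sector optimizes all `np`
candidate edges simultaneously.

The active-shape flavor comes from the velocity rule: besides the usual
personal-best and subgroup-best pulls, each particle is attracted toward
the same-label particles of the two adjacent sectors. Vessels crossing the
rim produce gradient ridges that can exceed the rim's own gradient inside a
single sector; the neighbor coupling makes an isolated sector's deviation
energetically unfavorable, so contours stay coherent across such
distractors. With the coupling weight `c_a = 0` the update reduces exactly
to standard PSO (verified bit-for-bit in the tests, sharing the RNG
stream).

## Search space and fitness

- ROI standardized to 256×256 by a separable Lanczos resampler with fixed
  8-tap support (a = 4), border clamp, and weight normalization (constants
  are reproduced exactly; same-size input is returned unchanged). Written
  in numpy because the scientific stack here exposes only a = 3 kernels.
- Red channel scaled to [0, 1]; Gaussian pre-smoothing with σ = 2 px
  suppresses pixel noise before differentiation.
- Annulus: `R_min = 0.3·(W/2)` = 38.4 px, `R_max = 0.7·(W/2)` = 89.6 px at
  W = 256 — wide enough to bracket disc radii ≈ 40–85 px while excluding
  the cup rim. Radial step `δr = 1` px. The angular step defaults to
  `2π/(N·round(360/N))` so the column count is an exact multiple of `N`
  (350 columns ≈ 1.03° at N = 50); an explicit `δθ` must satisfy the same
  divisibility or is rejected, since equal, exactly partitioned sectors are
  an invariant of the search space.
- Fitness of a grid point: magnitude of the central difference of the
  smoothed red channel over ±δr along the ray, bilinear sampling at
  off-grid coordinates. The magnitude (not the signed derivative) is used:
  it matches a bright-disc-on-dark-background rim regardless of local
  polarity reversals under vessels. Fitness is identically 0 outside the
  annulus.
- Continuous particle positions are scored by nearest-grid-point lookup —
  the exploration area is defined as a discrete point set, and this keeps
  the per-sector optimum a well-defined grid maximum that an exhaustive
  search can verify.
- Disc center: supplied explicitly, or "auto" = intensity-weighted centroid
  of the brightest 1% of red pixels. The auto center is biased a few pixels
  toward the bright side of the illumination ramp; this is harmless as long
  as the rim stays inside the annulus (the ROI is assumed disc-centered).

## Swarm

State per particle: polar position `(r, θ)`, velocity, personal best `PP`;
per subgroup: best `GP_i`. Defaults `N = 50`, `np = 30`, 100 iterations,
`c_p = c_g = 1.7`, `c_a = 0.3`, constant inertia `ω = 0.8`. Four inertia
schedules are available: constant; linear descent `ω_max → ω_min`
(0.9 → 0.4); random `(1 + rand)/2`; chaotic-random
`ω = 0.5·z + 0.5·rand` with a logistic-map state `z ← 4z(1−z)` seeded once
per run (the two mixing coefficients are configurable).

Numerical choices:

- Initialization: each candidate edge starts as a circle — one radius drawn
  uniformly from `[R_min, R_max]` shared by all its members; angles start
  at sector midpoints; velocities at zero. Circular starts reflect the
  near-circular prior on disc shape.
- Every `rand` in the velocity rule is an independent uniform draw per term
  and per component (standard PSO practice). The two neighbor draws are
  consumed only when `c_a > 0`, so the `c_a = 0` stream coincides with
  standard PSO's.
- Angular differences are wrapped signed differences in [−π, π), so
  attraction across the 0/2π seam points the short way.
- Velocity clamp: |v_r| ≤ 0.2·(R_max − R_min), |v_θ| ≤ 0.2·(2π/N) per step,
  preventing sector ping-ponging. Position clamp: `r` to the annulus, `θ`
  to the particle's own sector (upper bound kept one grid step inside the
  half-open edge); a clamped component has its velocity zeroed.
- Bests: `PP` is replaced when the new value is ≥ the old (ties move to the
  newer position); `GP_i` takes the best `PP` when that is ≥ its value,
  ties to the lowest particle label. Both are therefore non-decreasing,
  which the tests assert on every run.
- The final contour is built from the personal-best positions (stable
  bests, not transient positions) of the label whose edge fitness is
  maximal; ties go to the lowest label. A 2-D `(r, θ)` search is the
  default; a `radius_only` mode restricts motion to the radial axis.

Contour finishing: periodic cubic spline through the `N` members
parameterized by angle (interpolates them exactly), sampled at 360 points;
alternatively a direct least-squares ellipse fit (rejected with a pointer
to the spline when the points are degenerate). The mask is the polygon
interior; self-intersecting or fully off-image boundaries are errors.

## Metrics

Region-fraction confusion values (see `metrics.py`): misses normalized by
the ground-truth disc area `OA`, false alarms by `BA − OA` where
`BA = total − OA`, so `TP + FN = 1` and `TN + FP = 1` identically. The
normalizations are applied to the set differences `SA\OA` and `OA\SA`; a
strict scalar-area variant (which ignores position entirely) and a
standard pixel-count mode are provided for comparability. When the
prediction is nested inside the truth, the fractional Dice coincides with
the standard pixelwise Dice. Soft ground-truth maps (expert-vote
averages) are binarized at a configurable support level, default 75%.
Batch evaluation emits the cumulative table: fraction of images with
`E ≤ τ` for `τ ∈ {0.1, …, 0.5}`, plus mean E/Acc/Dice.

## Synthetic data

The generator renders what the fitness field actually sees: background red
level 0.45 with a ±2.5% linear illumination ramp in a random direction; a
disc step of +0.2–0.3 with a smoothstep edge 2 px wide (its radial
derivative peaks exactly on the true ellipse); a cup at 40% of the disc
radius, +0.15 brighter (inside `R_min` for default geometry, as in real
ROIs); 3 vessel strokes of width 3 px, 0.3 darker, random walks steered
from outside the annulus through the rim toward the disc center — the
distractor the neighbor coupling exists to survive; optional Gaussian
pixel noise (σ = 0.05 in the standard noisy condition). Green and blue
carry 60% / 30% of the red contrast. The ground-truth mask is the exact
ellipse interior. Suites sample disc radius uniformly from [45, 80] px.

What it does not emulate: texture, peripapillary atrophy, vessel branching
inside the disc, non-elliptical rims, varying illumination fields, camera
noise statistics. Passing tests therefore demonstrate correct mechanics
and robustness to the modelled distractors, not clinical performance.

## Study sizes used by the tests and acceptance script

Radius recovery: 20 noisy vesselled discs at the default operating point.
Subgroup optimality: one vessel-free disc, 4 sectors × 10 particles × 200
iterations × 20 seeds, compared against the exhaustive per-sector grid
maximum. Reduction check: 1000 random swarm states. Subgroup-count sweep:
8 noise-free images (pixel noise off, vessels kept — with vessels absent a
coarse 10-sector polygon already fits a circle, and the benefit of more
sectors disappears) at N = 10 vs N = 50. Each run takes well under a
second, so the full suite completes in seconds.

## Known limitations

- The annulus must bracket the rim: discs far off-center or outside
  ~[40, 85] px radius at 256×256 need explicit `R_min`/`R_max`.
- The auto-center heuristic assumes the disc (or cup) is the brightest
  region; bright artifacts defeat it — pass `--center x,y` instead.
- Nearest-grid fitness quantizes the radial landscape to `δr`; boundary
  localization is accurate to about one grid step by construction.
- The N = 10 vs N = 50 ranking on synthetic suites has a small margin that
  can invert for individual suites; the reported sweep states the suite
  seed it uses.
- One contour only: no cup segmentation, no cup-to-disc ratio.
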