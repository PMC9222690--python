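"""Subgroup-partitioned particle swarm contour optimizer.

The swarm is organised as ``N`` subgroups (one per angular sector of the
exploration annulus) of ``np`` particles each. The ``j``-th particles of all
subgroups, taken in sector order and closed by wrap, form the ``j``-th
candidate disc boundary (an *edge*), scored by the sum of its members'
fitness values. Each particle moves in 2-D polar coordinates (r, theta)
inside its own sector, pulled toward its personal best, its subgroup's best,
and — the key modification over standard PSO — the same-label particles in
the two adjacent subgroups, which keeps candidate contours coherent where
vessel gradients locally outshine the disc boundary.

State is stored as arrays with a leading component axis: index 0 is the
radial component, index 1 the angular component; the remaining axes are
(subgroup, particle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .boundary import fit_boundary, rasterize_mask
from .polar import TWO_PI, ExplorationArea

__all__ = [
    "SwarmConfig",
    "InertiaSchedule",
    "Particle",
    "SwarmState",
    "EdgeContour",
    "SegmentationResult",
    "initialize_swarm",
    "velocity_update",
    "position_update",
    "update_personal_best",
    "update_subgroup_best",
    "edge_fitness",
    "run_swarm",
]

INERTIA_STRATEGIES = ("constant", "linear", "random", "chaotic")


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters.

    Defaults follow the headline operating point: 50 subgroups of 30
    particles, 100 iterations, constant inertia 0.8, cognitive and social
    accelerations 1.7 and adjacent-subgroup attraction 0.3.
    """

    n_subgroups: int = 50
    n_particles: int = 30
    iterations: int = 100
    inertia: str = "constant"
    omega: float = 0.8  # constant-strategy weight
    omega_max: float = 0.9  # linear-descending endpoints
    omega_min: float = 0.4
    chaotic_z_coef: float = 0.5
    chaotic_rand_coef: float = 0.5
    cp: float = 1.7
    cg: float = 1.7
    ca: float = 0.3
    velocity_clamp: float = 0.2  # fraction of the annulus/sector extent per step
    radius_only: bool = False
    fit_method: str = "spline"

    def __post_init__(self) -> None:
        if self.n_subgroups < 3:
            raise ValueError(f"n_subgroups must be >= 3, got {self.n_subgroups}")
        if self.n_particles < 2:
            raise ValueError(f"n_particles must be >= 2, got {self.n_particles}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if min(self.cp, self.cg, self.ca) < 0:
            raise ValueError("cp, cg and ca must be non-negative")
        if self.inertia not in INERTIA_STRATEGIES:
            raise ValueError(
                f"unknown inertia strategy {self.inertia!r}; valid: {INERTIA_STRATEGIES}"
            )
        if not (0 < self.velocity_clamp <= 1):
            raise ValueError("velocity_clamp must be in (0, 1]")
        if self.fit_method not in ("spline", "ellipse"):
            raise ValueError("fit_method must be 'spline' or 'ellipse'")


class InertiaSchedule:
    """Iteration-indexed inertia weight.

    * ``constant``: omega = c.
    * ``linear``: omega descends from omega_max to omega_min over the run.
    * ``random``: omega = (1 + rand)/2, uniform in [0.5, 1].
    * ``chaotic``: a logistic-map state z (seeded once per run, z <- 4z(1-z)
      each call) mixed with a fresh uniform draw,
      omega = z_coef*z + rand_coef*rand.
    """

    def __init__(self, config: SwarmConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self._z = float(rng.random()) if config.inertia == "chaotic" else math.nan

    def __call__(self, k: int, itermax: int) -> float:
        c = self.config
        if not (0 <= k <= itermax):
            raise ValueError(f"iteration index {k} outside [0, {itermax}]")
        if c.inertia == "constant":
            return c.omega
        if c.inertia == "linear":
            return c.omega_max - (c.omega_max - c.omega_min) * k / itermax
        if c.inertia == "random":
            return (1.0 + float(self.rng.random())) / 2.0
        # chaotic
        self._z = 4.0 * self._z * (1.0 - self._z)
        return c.chaotic_z_coef * self._z + c.chaotic_rand_coef * float(self.rng.random())


class Particle(NamedTuple):
    """Read-only view of one particle (for inspection and tests)."""

    subgroup: int
    label: int
    position: tuple[float, float]  # (r, theta)
    velocity: tuple[float, float]
    best_position: tuple[float, float]
    best_value: float


@dataclass
class SwarmState:
    """Positions, velocities and bests of the whole swarm as arrays."""

    pos: np.ndarray  # (2, N, np)
    vel: np.ndarray  # (2, N, np)
    pbest: np.ndarray  # (2, N, np)
    pbest_val: np.ndarray  # (N, np)
    gbest: np.ndarray  # (2, N)
    gbest_val: np.ndarray  # (N,)

    @property
    def n_subgroups(self) -> int:
        return self.pos.shape[1]

    @property
    def n_particles(self) -> int:
        return self.pos.shape[2]

    def particle(self, i: int, j: int) -> Particle:
        return Particle(
            subgroup=i,
            label=j,
            position=(float(self.pos[0, i, j]), float(self.pos[1, i, j])),
            velocity=(float(self.vel[0, i, j]), float(self.vel[1, i, j])),
            best_position=(float(self.pbest[0, i, j]), float(self.pbest[1, i, j])),
            best_value=float(self.pbest_val[i, j]),
        )


@dataclass(frozen=True)
class EdgeContour:
    """One candidate disc boundary: the label-j particle of every subgroup."""

    label: int
    r: np.ndarray  # (N,)
    theta: np.ndarray  # (N,)
    fitness: float

    def to_xy(self, center: tuple[float, float]) -> np.ndarray:
        xc, yc = center
        return np.column_stack(
            (xc + self.r * np.cos(self.theta), yc + self.r * np.sin(self.theta))
        )


@dataclass
class SegmentationResult:
    edge: EdgeContour
    boundary: np.ndarray  # dense closed polyline, (M, 2) image coordinates
    mask: np.ndarray  # (size, size) bool
    trace: np.ndarray  # per-iteration best edge fitness, non-decreasing
    config: SwarmConfig


# ---------------------------------------------------------------------------
# Swarm operations
# ---------------------------------------------------------------------------


def _sector_bounds(area: ExplorationArea) -> tuple[np.ndarray, np.ndarray]:
    edges = area.sector_edges
    return edges[:-1], edges[1:]


def initialize_swarm(
    area: ExplorationArea, config: SwarmConfig, rng: np.random.Generator
) -> SwarmState:
    """Seed the swarm: each candidate edge j starts as a circle of random
    radius (all its members share one radius drawn uniformly from
    [rmin, rmax]); every particle sits at its sector midpoint with zero
    velocity; personal bests are the initial positions."""
    if area.n_subgroups != config.n_subgroups:
        raise ValueError("exploration area and config disagree on the subgroup count")
    n, m = config.n_subgroups, config.n_particles
    g = area.grid
    radii = rng.uniform(g.rmin, g.rmax, size=m)
    lo, hi = _sector_bounds(area)
    pos = np.empty((2, n, m))
    pos[0] = np.broadcast_to(radii, (n, m))
    pos[1] = np.broadcast_to(((lo + hi) / 2.0)[:, None], (n, m))
    vel = np.zeros_like(pos)
    pbest = pos.copy()
    pbest_val = area.fitness_at(pos[0], pos[1])
    best_j = np.argmax(pbest_val, axis=1)  # first max -> lowest label
    gbest = pbest[:, np.arange(n), best_j]
    gbest_val = pbest_val[np.arange(n), best_j]
    return SwarmState(pos, vel, pbest, pbest_val.copy(), gbest.copy(), gbest_val.copy())


def _wrap_angle(d: np.ndarray) -> np.ndarray:
    """Signed angular difference wrapped into [-pi, pi)."""
    return (d + np.pi) % TWO_PI - np.pi


def velocity_update(
    pos: np.ndarray,
    vel: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    omega: float,
    area: ExplorationArea,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One velocity step for the whole swarm.

    v <- omega*v + cp*rand*(pbest - x) + cg*rand*(gbest - x)
           + ca*rand*(right neighbor - x) + ca*rand*(left neighbor - x)

    Neighbors are the same-label particles of the adjacent subgroups,
    wrapping modulo N. Every ``rand`` factor is an independent uniform draw
    per term and per component; angular differences are wrapped signed
    differences. With ca = 0 no neighbor draws are consumed, so the update
    (and the RNG stream) reduces exactly to the standard PSO rule. The
    result is clamped component-wise to ``velocity_clamp`` times the annulus
    width (radial) / sector width (angular).
    """
    shape = pos.shape
    d_p = pbest - pos
    d_g = gbest[:, :, None] - pos
    d_p[1] = _wrap_angle(d_p[1])
    d_g[1] = _wrap_angle(d_g[1])
    r_p = rng.random(shape)
    r_g = rng.random(shape)
    v = omega * vel + config.cp * r_p * d_p + config.cg * r_g * d_g
    if config.ca > 0:
        d_right = np.roll(pos, -1, axis=1) - pos  # subgroup i+1 (wraps)
        d_left = np.roll(pos, 1, axis=1) - pos  # subgroup i-1 (wraps)
        d_right[1] = _wrap_angle(d_right[1])
        d_left[1] = _wrap_angle(d_left[1])
        r_a1 = rng.random(shape)
        r_a2 = rng.random(shape)
        v = v + config.ca * r_a1 * d_right + config.ca * r_a2 * d_left
    g = area.grid
    vmax_r = config.velocity_clamp * (g.rmax - g.rmin)
    vmax_t = config.velocity_clamp * (TWO_PI / config.n_subgroups)
    v[0] = np.clip(v[0], -vmax_r, vmax_r)
    v[1] = np.clip(v[1], -vmax_t, vmax_t)
    if config.radius_only:
        v[1] = 0.0
    return v


def position_update(
    pos: np.ndarray, vel: np.ndarray, area: ExplorationArea
) -> tuple[np.ndarray, np.ndarray]:
    """x <- x + v, then confine: r is clamped to [rmin, rmax] and theta to
    the particle's own sector (upper bound open, enforced one grid step
    inside). A clamped component has its velocity zeroed."""
    g = area.grid
    new = pos + vel
    v = vel.copy()
    hit_r = (new[0] < g.rmin) | (new[0] > g.rmax)
    new[0] = np.clip(new[0], g.rmin, g.rmax)
    v[0][hit_r] = 0.0
    lo, hi = _sector_bounds(area)
    lo = lo[:, None]
    hi_in = (hi - g.delta_theta)[:, None]  # keep off the half-open upper edge
    hit_t = (new[1] < lo) | (new[1] > hi_in)
    new[1] = np.clip(new[1], lo, hi_in)
    v[1][hit_t] = 0.0
    return new, v


def update_personal_best(state: SwarmState, area: ExplorationArea) -> None:
    """Replace each personal best iff the current position is at least as
    fit (ties move to the newer position)."""
    vals = area.fitness_at(state.pos[0], state.pos[1])
    better = vals >= state.pbest_val
    state.pbest[:, better] = state.pos[:, better]
    state.pbest_val[better] = vals[better]


def update_subgroup_best(state: SwarmState) -> None:
    """Replace each subgroup best with its best personal best when that is
    at least as fit; ties between particles go to the lowest label."""
    best_j = np.argmax(state.pbest_val, axis=1)
    idx = np.arange(state.n_subgroups)
    cand_val = state.pbest_val[idx, best_j]
    better = cand_val >= state.gbest_val
    state.gbest[:, better] = state.pbest[:, idx, best_j][:, better]
    state.gbest_val[better] = cand_val[better]


def edge_fitness(edge: EdgeContour, area: ExplorationArea) -> float:
    """Sum of the members' fitness values (zero for off-annulus members)."""
    return float(np.sum(area.fitness_at(edge.r, edge.theta)))


def _best_edge(state: SwarmState, area: ExplorationArea) -> EdgeContour:
    totals = state.pbest_val.sum(axis=0)
    j = int(np.argmax(totals))  # ties -> lowest label
    return EdgeContour(
        label=j,
        r=state.pbest[0, :, j].copy(),
        theta=state.pbest[1, :, j].copy(),
        fitness=float(totals[j]),
    )


def run_swarm(
    area: ExplorationArea,
    config: SwarmConfig,
    rng: np.random.Generator | int,
    image_size: int | None = None,
) -> SegmentationResult:
    """Run the full optimization and return the segmented disc.

    Each iteration: draw the inertia weight, update all velocities and
    positions, then refresh personal and subgroup bests. The candidate edge
    whose personal-best members sum to the highest fitness becomes the
    result; it is densified by periodic-spline (or ellipse) fitting and
    rasterized to a binary mask.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    state = initialize_swarm(area, config, rng)
    schedule = InertiaSchedule(config, rng)
    trace = np.empty(config.iterations)
    for k in range(config.iterations):
        omega = schedule(k, config.iterations)
        state.vel = velocity_update(
            state.pos, state.vel, state.pbest, state.gbest, omega, area, config, rng
        )
        state.pos, state.vel = position_update(state.pos, state.vel, area)
        update_personal_best(state, area)
        update_subgroup_best(state)
        trace[k] = state.pbest_val.sum(axis=0).max()
    edge = _best_edge(state, area)
    center = area.grid.center
    boundary = fit_boundary(edge, center, method=config.fit_method)
    size = image_size if image_size is not None else int(
        math.ceil(max(center) + area.grid.rmax)
    )
    mask = rasterize_mask(boundary, size)
    return SegmentationResult(edge=edge, boundary=boundary, mask=mask, trace=trace, config=config)
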