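"""Annular polar exploration area over a fundus ROI.

The optic disc appears as a bright quasi-elliptical region in a disc-centered
ROI crop. The search space for the contour optimizer is a discretized annulus
around the disc center: ``n_radial`` radii between ``rmin`` and ``rmax`` times
``n_angular`` angles, each grid point carrying a non-negative fitness equal to
the magnitude of the radial derivative of the (Gaussian-smoothed) red channel.
Points outside the annulus have fitness zero by definition.

The annulus is partitioned into ``n_subgroups`` equal angular sectors; one
swarm subgroup searches each sector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RoiImage",
    "PolarGrid",
    "ExplorationArea",
    "standardize_roi",
    "red_channel",
    "radial_gradient",
    "build_exploration_area",
]

TWO_PI = 2.0 * math.pi

# ---------------------------------------------------------------------------
# Lanczos-4 resampling (fixed 8x8 support, separable)
# ---------------------------------------------------------------------------


def _lanczos_weights(d: np.ndarray, a: int = 4) -> np.ndarray:
    w = np.sinc(d) * np.sinc(d / a)
    w[np.abs(d) >= a] = 0.0
    return w


def _resize_axis(arr: np.ndarray, n_out: int, axis: int, a: int = 4) -> np.ndarray:
    """Resample one axis with a fixed-support Lanczos-a kernel.

    Border samples are clamped; weights are renormalized to sum to 1 so a
    constant signal is reproduced exactly.
    """
    n_in = arr.shape[axis]
    if n_in == n_out:
        return arr
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    left = np.floor(src).astype(np.int64) - a + 1
    taps = left[:, None] + np.arange(2 * a)[None, :]
    w = _lanczos_weights(src[:, None] - taps, a)
    w /= w.sum(axis=1, keepdims=True)
    taps = np.clip(taps, 0, n_in - 1)
    moved = np.moveaxis(np.asarray(arr, dtype=np.float64), axis, 0)
    out = np.einsum("ok,ok...->o...", w, moved[taps])
    return np.moveaxis(out, 0, axis)


@dataclass(frozen=True)
class RoiImage:
    """A standardized square RGB ROI crop (8-bit per channel)."""

    pixels: np.ndarray  # (size, size, 3) uint8

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"RoiImage requires an RGB array (H, W, 3); got shape {p.shape}")
        if p.shape[0] != p.shape[1]:
            raise ValueError("RoiImage must be square; use standardize_roi first")

    @property
    def size(self) -> int:
        return int(self.pixels.shape[0])


def standardize_roi(image: np.ndarray, size: int = 256) -> RoiImage:
    """Resize an RGB ROI to ``size`` x ``size`` with Lanczos-4 resampling.

    Same-size inputs pass through pixel-identical. Non-square inputs are
    resized anisotropically (no letterboxing).
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an RGB image with 3 channels, got shape {arr.shape}"
        )
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError("image must contain at least one pixel")
    if arr.shape[0] == size and arr.shape[1] == size:
        return RoiImage(arr.astype(np.uint8, copy=True))
    out = _resize_axis(arr, size, axis=0)
    out = _resize_axis(out, size, axis=1)
    return RoiImage(np.clip(np.rint(out), 0, 255).astype(np.uint8))


def red_channel(image: RoiImage) -> np.ndarray:
    """Red channel of a standardized ROI as a float field in [0, 1].

    The red channel carries the cleanest disc/background contrast in fundus
    photographs, so the gradient fitness is computed from it alone.
    """
    return image.pixels[:, :, 0].astype(np.float64) / 255.0


# ---------------------------------------------------------------------------
# Polar grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolarGrid:
    """Discrete annular grid around a center point.

    Radii run ``rmin, rmin + delta_r, ...`` (``n_radial`` values, the last one
    not exceeding ``rmax``); angles run ``0, delta_theta, ...`` counterclockwise
    from the +x axis (``n_angular`` values covering [0, 2*pi)).
    """

    center: tuple[float, float]  # (xc, yc), x = column, y = row
    rmin: float
    rmax: float
    delta_r: float = 1.0
    delta_theta: float = TWO_PI / 360.0

    def __post_init__(self) -> None:
        if not (0.0 < self.rmin < self.rmax):
            raise ValueError(f"need 0 < rmin < rmax; got rmin={self.rmin}, rmax={self.rmax}")
        if self.delta_r <= 0 or self.delta_theta <= 0:
            raise ValueError("delta_r and delta_theta must be positive")
        if self.n_radial < 2:
            raise ValueError("annulus too thin: fewer than 2 radial samples")
        if self.n_angular < 1:
            raise ValueError("delta_theta too large: no angular samples")

    @property
    def n_radial(self) -> int:
        return int(math.floor((self.rmax - self.rmin) / self.delta_r)) + 1

    @property
    def n_angular(self) -> int:
        return int(math.floor(TWO_PI / self.delta_theta + 1e-9))

    def radii(self) -> np.ndarray:
        return self.rmin + self.delta_r * np.arange(self.n_radial)

    def angles(self) -> np.ndarray:
        return self.delta_theta * np.arange(self.n_angular)

    def cartesian(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every grid point, shape (n_radial, n_angular)."""
        r = self.radii()[:, None]
        t = self.angles()[None, :]
        xc, yc = self.center
        return xc + r * np.cos(t), yc + r * np.sin(t)


# ---------------------------------------------------------------------------
# Radial gradient fitness
# ---------------------------------------------------------------------------


def _check_grid_inside(field: np.ndarray, grid: PolarGrid, margin: float) -> None:
    h, w = field.shape
    xc, yc = grid.center
    reach = grid.rmax + margin
    if xc - reach < 0 or yc - reach < 0 or xc + reach > w - 1 or yc + reach > h - 1:
        raise ValueError(
            f"exploration annulus (center=({xc:.1f},{yc:.1f}), reach={reach:.1f} px) "
            f"extends outside the {w}x{h} image"
        )


def radial_gradient(
    field: np.ndarray, grid: PolarGrid, sigma: float = 2.0
) -> np.ndarray:
    """Per-grid-point fitness: |d(field)/dr| along rays from the grid center.

    The field is Gaussian-smoothed (``sigma`` pixels) first; the radial
    derivative is estimated by central differences over ``delta_r`` with
    bilinear sampling at the off-grid coordinates. Values are non-negative.
    """
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 2:
        raise ValueError("field must be a 2-D scalar array")
    _check_grid_inside(field, grid, margin=grid.delta_r)
    smoothed = ndimage.gaussian_filter(field, sigma) if sigma > 0 else field
    r = grid.radii()[:, None]
    t = grid.angles()[None, :]
    xc, yc = grid.center
    cos_t, sin_t = np.cos(t), np.sin(t)

    def sample(radius: np.ndarray) -> np.ndarray:
        x = xc + radius * cos_t
        y = yc + radius * sin_t
        return ndimage.map_coordinates(smoothed, [y.ravel(), x.ravel()], order=1).reshape(
            x.shape
        )

    outer = sample(r + grid.delta_r)
    inner = sample(r - grid.delta_r)
    return np.abs(outer - inner) / (2.0 * grid.delta_r)


# ---------------------------------------------------------------------------
# Exploration area
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExplorationArea:
    """Polar grid + fitness field + angular sector partition.

    ``sector_edges`` has ``n_subgroups + 1`` entries ``0, 2*pi/N, ..., 2*pi``;
    sector ``i`` (0-based) covers the half-open interval
    ``[sector_edges[i], sector_edges[i+1])``. The sectors are pairwise
    disjoint and their union is the full angle range.
    """

    grid: PolarGrid
    fitness: np.ndarray  # (n_radial, n_angular), >= 0
    n_subgroups: int
    sector_edges: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_subgroups < 1:
            raise ValueError("need at least one sector")
        if self.fitness.shape != (self.grid.n_radial, self.grid.n_angular):
            raise ValueError("fitness shape does not match the grid")
        if np.any(self.fitness < 0):
            raise ValueError("fitness must be non-negative")
        edges = TWO_PI * np.arange(self.n_subgroups + 1) / self.n_subgroups
        object.__setattr__(self, "sector_edges", edges)

    def sector_of(self, theta: np.ndarray | float) -> np.ndarray:
        """0-based sector index for each angle (angles wrapped into [0, 2*pi))."""
        t = np.asarray(theta, dtype=np.float64) % TWO_PI
        # tiny epsilon so angles a rounding error below a boundary still land
        # in the sector that owns the boundary; the partition stays exact
        idx = np.floor(t * self.n_subgroups / TWO_PI + 1e-9).astype(np.int64)
        return np.clip(idx, 0, self.n_subgroups - 1)

    def fitness_at(self, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Fitness of continuous positions: nearest grid point, 0 off-annulus."""
        r = np.asarray(r, dtype=np.float64)
        theta = np.asarray(theta, dtype=np.float64)
        g = self.grid
        i = np.clip(np.rint((r - g.rmin) / g.delta_r).astype(np.int64), 0, g.n_radial - 1)
        j = np.rint((theta % TWO_PI) / g.delta_theta).astype(np.int64) % g.n_angular
        vals = self.fitness[i, j]
        return np.where((r < g.rmin) | (r > g.rmax), 0.0, vals)

    def sector_columns(self, i: int) -> np.ndarray:
        """Indices of grid angle columns belonging to 0-based sector ``i``."""
        return np.nonzero(self.sector_of(self.grid.angles()) == i)[0]

    def sector_max(self, i: int) -> float:
        """Exhaustive maximum fitness over sector ``i``'s grid points."""
        cols = self.sector_columns(i)
        return float(self.fitness[:, cols].max()) if cols.size else 0.0


def _auto_center(red: np.ndarray, quantile: float = 0.99) -> tuple[float, float]:
    """Intensity-weighted centroid of the brightest pixels of the red channel."""
    thresh = np.quantile(red, quantile)
    mask = red >= thresh
    ys, xs = np.nonzero(mask)
    w = red[ys, xs]
    return float(np.sum(xs * w) / np.sum(w)), float(np.sum(ys * w) / np.sum(w))


def default_radii(size: int) -> tuple[float, float]:
    """Default annulus radii: 30% and 70% of half the image width."""
    return 0.3 * size / 2.0, 0.7 * size / 2.0


def auto_delta_theta(n_subgroups: int) -> float:
    """Angular step giving roughly 1-degree columns while keeping the column
    count an exact multiple of the sector count."""
    per_sector = max(1, round(360 / n_subgroups))
    return TWO_PI / (n_subgroups * per_sector)


def build_exploration_area(
    image: RoiImage,
    center: tuple[float, float] | str = "auto",
    rmin: float | None = None,
    rmax: float | None = None,
    delta_r: float = 1.0,
    delta_theta: float | None = None,
    n_subgroups: int = 50,
    sigma: float = 2.0,
) -> ExplorationArea:
    """Build the annular exploration area for a standardized ROI.

    ``center="auto"`` resolves to the intensity-weighted centroid of the
    brightest 1% of red-channel pixels (the ROI is assumed disc-centered).
    ``rmin``/``rmax`` default to 30%/70% of half the image width. When
    ``delta_theta`` is omitted it is chosen so the number of angle columns is
    an exact multiple of ``n_subgroups``.
    """
    red = red_channel(image)
    if isinstance(center, str):
        if center != "auto":
            raise ValueError(f"unknown center mode {center!r}; use 'auto' or (x, y)")
        pc = _auto_center(red)
    else:
        pc = (float(center[0]), float(center[1]))
    lo, hi = default_radii(image.size)
    rmin = lo if rmin is None else float(rmin)
    rmax = hi if rmax is None else float(rmax)
    if delta_theta is None:
        delta_theta = auto_delta_theta(n_subgroups)
    grid = PolarGrid(pc, rmin, rmax, delta_r, delta_theta)
    if grid.n_angular % n_subgroups != 0:
        raise ValueError(
            f"n_angular={grid.n_angular} is not a multiple of n_subgroups={n_subgroups}; "
            "adjust delta_theta (or omit it for an automatic choice)"
        )
    _check_grid_inside(red, grid, margin=grid.delta_r)
    fitness = radial_gradient(red, grid, sigma=sigma)
    return ExplorationArea(grid=grid, fitness=fitness, n_subgroups=n_subgroups)
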