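"""Contour finishing: densify a sparse edge and rasterize it to a mask."""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon, box
from skimage.draw import polygon2mask
from skimage.measure import EllipseModel

if TYPE_CHECKING:  # pragma: no cover
    from .swarm import EdgeContour

__all__ = ["fit_boundary", "rasterize_mask", "periodic_spline"]


def periodic_spline(edge: "EdgeContour", center: tuple[float, float]) -> CubicSpline:
    """Periodic cubic spline through the edge's member points, parameterized
    by their polar angle. Interpolates every member exactly."""
    order = np.argsort(edge.theta)
    t = edge.theta[order]
    xy = edge.to_xy(center)[order]
    t_ext = np.append(t, t[0] + 2 * np.pi)
    xy_ext = np.vstack([xy, xy[:1]])
    return CubicSpline(t_ext, xy_ext, bc_type="periodic", axis=0)


def fit_boundary(
    edge: "EdgeContour",
    center: tuple[float, float],
    method: str = "spline",
    n_samples: int = 360,
) -> np.ndarray:
    """Fit a dense closed polyline through an edge's member points.

    ``spline`` interpolates the points with a periodic cubic spline (passes
    through all of them); ``ellipse`` fits a least-squares ellipse, which
    smooths outliers but constrains the shape. Returns (n_samples, 2) image
    coordinates in angular order.
    """
    n = edge.r.size
    if method == "spline":
        if n < 4:
            raise ValueError("spline fitting needs at least 4 points")
        spline = periodic_spline(edge, center)
        t0 = float(np.sort(edge.theta)[0])
        ts = t0 + 2 * np.pi * np.arange(n_samples) / n_samples
        return np.asarray(spline(ts))
    if method == "ellipse":
        if n < 5:
            raise ValueError("ellipse fitting needs at least 5 points")
        pts = edge.to_xy(center)
        model = EllipseModel.from_estimate(pts)
        if (
            not model
            or not np.all(np.isfinite(model.axis_lengths))
            or min(model.axis_lengths) <= 0
        ):
            raise ValueError(
                "ellipse fit is degenerate (near-collinear points); try method='spline'"
            )
        ts = 2 * np.pi * np.arange(n_samples) / n_samples
        return np.asarray(model.predict_xy(ts))
    raise ValueError(f"unknown fit method {method!r}; use 'spline' or 'ellipse'")


def rasterize_mask(boundary: np.ndarray, size: int) -> np.ndarray:
    """Rasterize a closed polyline to a (size, size) boolean interior mask.

    Raises on self-intersecting boundaries and on boundaries that do not
    overlap the image at all.
    """
    pts = np.asarray(boundary, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("boundary must be an (M, 2) polyline with M >= 3")
    poly = Polygon(pts)
    if not poly.is_valid:
        raise ValueError("boundary polyline is self-intersecting")
    if not poly.intersects(box(0, 0, size - 1, size - 1)):
        raise ValueError("boundary lies entirely outside the image")
    # polygon2mask takes (row, col) = (y, x)
    return polygon2mask((size, size), pts[:, ::-1])
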