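"""Closed sub-pixel contours and the geometry helpers shared across modules.

Pixel-grid convention used throughout the package: 0-based, row-major,
coordinates are pixel centers, points stored as (y, x) with y increasing
downward.  Winding is counter-clockwise as seen on screen (x right, y
down), enforced by a signed-area check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError


@dataclass
class NucleusContour:
    """An ordered, closed sequence of sub-pixel boundary points for one nucleus.

    ``points`` is an (n, 2) array of (y, x); closure is implicit (the last
    point connects back to the first; the first point is not repeated).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ContractError(f"contour needs an (n>=3, 2) point array, got shape {pts.shape}")
        # Drop an explicit duplicate closing point if present.
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 1]

    def perimeter(self) -> float:
        return float(np.sum(np.hypot(*np.diff(np.vstack([self.points, self.points[:1]]), axis=0).T)))

    def signed_area(self) -> float:
        """Shoelace area; negative means counter-clockwise on screen (y down)."""
        y, x = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def is_ccw(self) -> bool:
        return self.signed_area() < 0

    def ensure_ccw(self) -> "NucleusContour":
        if self.is_ccw():
            return self
        return NucleusContour(self.points[::-1].copy())

    def resampled(self, n_points: int) -> "NucleusContour":
        return NucleusContour(resample_closed(self.points, n_points))


def resample_closed(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polyline to ``n_points`` uniformly spaced in arc length.

    The first output point coincides with the first input point, so
    repeated resampling is stable.
    """
    pts = np.asarray(points, dtype=np.float64)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(np.diff(closed[:, 0]), np.diff(closed[:, 1]))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ContractError("contour has zero perimeter")
    target = np.linspace(0.0, total, n_points, endpoint=False)
    y = np.interp(target, s, closed[:, 0])
    x = np.interp(target, s, closed[:, 1])
    return np.column_stack([y, x])


def ellipse_points(
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    orientation: float = 0.0,
    n_points: int = 720,
) -> np.ndarray:
    """Points (y, x) on an ellipse at uniformly spaced parametric angles.

    ``orientation`` rotates the semi-major axis ``a`` from the +x direction
    toward +y (screen-clockwise), in radians.
    """
    cy, cx = center
    a, b = semi_axes
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    ex = a * np.cos(t)
    ey = b * np.sin(t)
    cos_o, sin_o = np.cos(orientation), np.sin(orientation)
    x = cx + cos_o * ex - sin_o * ey
    y = cy + sin_o * ex + cos_o * ey
    return np.column_stack([y, x])


def point_to_ellipse_distances(
    points: np.ndarray,
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    orientation: float = 0.0,
    n_dense: int = 8192,
) -> np.ndarray:
    """Distance from each (y, x) point to a densely sampled true ellipse."""
    from scipy.spatial import cKDTree

    dense = ellipse_points(center, semi_axes, orientation, n_dense)
    tree = cKDTree(dense)
    d, _ = tree.query(np.asarray(points, dtype=np.float64))
    return d


def hausdorff_to_ellipse(
    contour: NucleusContour,
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    orientation: float = 0.0,
) -> float:
    """Symmetric Hausdorff distance between a contour and a true ellipse."""
    from scipy.spatial import cKDTree

    dense = ellipse_points(center, semi_axes, orientation, 4096)
    pts = resample_closed(contour.points, 1024)
    d1 = cKDTree(dense).query(pts)[0].max()
    d2 = cKDTree(pts).query(dense)[0].max()
    return float(max(d1, d2))
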