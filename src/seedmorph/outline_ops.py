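"""Outline extraction from binary silhouettes and seed size measurement.

A seed silhouette (binary mask) is traced with sub-pixel contouring at the
0.5 level, resampled to a fixed number of points equally spaced along the
boundary arclength, oriented counterclockwise, and re-anchored so that the
first point sits at the seed base (the pointier end of the principal axis).

Size follows the convention of measuring length and width on the dorsal
view, thickness as the maximum width of the lateral view, and surface as
the dorsal silhouette area.  Length is the maximal caliper (Feret) extent,
so measurements do not depend on how the seed was oriented in the image.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure as _skmeasure

from .eft_core import DegenerateOutlineError

__all__ = ["Outline", "SizeVector", "extract_outline", "measure_size", "polygon_area"]


class SegmentationError(ValueError):
    """Mask does not contain exactly one usable foreground component."""


@dataclass
class Outline:
    """Ordered closed 2-D polygon (one view of one seed).

    ``points`` is an ``(N, 2)`` array of ``(x, y)`` vertices in consistent
    length units; closure is implicit (last vertex connects to the first).
    The first point is the seed base when produced by :func:`extract_outline`.
    """

    points: np.ndarray
    view: str | None = None
    touches_border: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if np.isnan(pts).any():
            raise ValueError("outline contains NaN coordinates")
        if len(pts) < 3:
            raise DegenerateOutlineError("an outline needs at least 3 points")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def area(self) -> float:
        return polygon_area(self.points)


def polygon_area(points: np.ndarray) -> float:
    """Shoelace area of a closed polygon (absolute value)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _signed_area(points: np.ndarray) -> float:
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return float(0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def resample_equal_arclength(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polygon to ``n_points`` equally spaced by
    cumulative arclength, keeping the first vertex as the start."""
    pts = np.asarray(points, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        raise DegenerateOutlineError("zero-perimeter outline")
    ti = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(ti, t, closed[:, 0])
    y = np.interp(ti, t, closed[:, 1])
    return np.column_stack([x, y])


def _principal_axis(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    cov = c.T @ c / len(c)
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    if w[-1] <= 0:
        raise DegenerateOutlineError("collinear outline has no principal plane")
    return axis


def _base_index(points: np.ndarray) -> int:
    """Pick the seed-base vertex: the extreme point at the principal-axis
    end with the smaller local curvature radius (pointier end), estimated
    from the perpendicular spread of nearby boundary points.  Ties break
    toward minimal y."""
    axis = _principal_axis(points)
    centred = points - points.mean(axis=0)
    proj = centred @ axis
    perp = centred @ np.array([-axis[1], axis[0]])
    span = proj.max() - proj.min()
    ends = []
    for extreme, side in ((proj.argmax(), 1.0), (proj.argmin(), -1.0)):
        near = np.abs(proj - proj[extreme]) < 0.12 * span
        # larger perpendicular spread near the tip -> blunter -> larger radius
        spread = perp[near].std() if near.sum() >= 3 else np.inf
        ends.append((spread, points[extreme, 1], int(extreme)))
    ends.sort(key=lambda e: (e[0], e[1]))
    return ends[0][2]


def extract_outline(
    mask: np.ndarray,
    n_points: int = 64,
    scale: float = 1.0,
    view: str | None = None,
    base_index: int | None = None,
    min_pixels: int = 50,
) -> Outline:
    """Trace a binary mask into a standardized closed outline.

    The single foreground component is contoured at level 0.5 (sub-pixel),
    resampled to ``n_points`` equal arclength steps, oriented
    counterclockwise in a y-up Cartesian frame, and rotated so that the
    first point is the seed base.  ``scale`` converts pixels to physical
    units (e.g. cm per pixel).  ``base_index`` overrides the automatic base
    choice (index into the resampled outline).
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise SegmentationError("mask must be a 2-D array")
    binary = m > 0 if m.dtype != bool else m
    labels, n_comp = _skmeasure.label(binary, return_num=True)
    sizes = np.bincount(labels.ravel())[1:]
    big = np.flatnonzero(sizes >= min_pixels)
    if len(big) != 1:
        raise SegmentationError(
            f"expected exactly one component of >= {min_pixels} px, found {len(big)}"
        )
    binary = labels == big[0] + 1
    touches = bool(
        binary[0, :].any() or binary[-1, :].any() or binary[:, 0].any() or binary[:, -1].any()
    )
    contours = _skmeasure.find_contours(binary.astype(float), 0.5)
    contour = max(contours, key=len)  # outer boundary
    rows, cols = contour[:, 0], contour[:, 1]
    # image row order inverted once: continuous Cartesian, y increasing upward
    pts = np.column_stack([cols, (binary.shape[0] - 1) - rows]) * scale
    pts = resample_equal_arclength(pts, n_points)
    if _signed_area(pts) < 0:
        pts = pts[::-1]
    start = _base_index(pts) if base_index is None else int(base_index) % n_points
    pts = np.roll(pts, -start, axis=0)
    return Outline(points=pts, view=view, touches_border=touches)


@dataclass(frozen=True)
class SizeVector:
    """The four seed size parameters (length, width, thickness in cm,
    surface in cm^2)."""

    length: float
    width: float
    thickness: float
    surface: float

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0 and self.thickness > 0 and self.surface > 0):
            raise ValueError("size parameters must satisfy length >= width > 0, thickness > 0, surface > 0")


def _caliper_length_axis(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximal caliper (Feret) extent and its direction."""
    try:
        hull = points[ConvexHull(points).vertices]
    except Exception as exc:  # qhull flat input
        raise DegenerateOutlineError("collinear outline") from exc
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length = float(np.sqrt(d2[i, j]))
    if length == 0:
        raise DegenerateOutlineError("degenerate outline")
    return length, (hull[i] - hull[j]) / length


def _extent_along(points: np.ndarray, direction: np.ndarray) -> float:
    proj = points @ direction
    return float(proj.max() - proj.min())


def measure_size(dorsal: Outline, lateral: Outline, method: str = "caliper") -> SizeVector:
    """Measure the four size parameters from the two views.

    ``method="caliper"`` (default) defines length as the maximal Feret
    extent of the dorsal outline and width as the extent perpendicular to
    that axis; ``method="axis"`` uses the principal axis instead.  Thickness
    is the extent of the lateral outline perpendicular to its principal
    axis; surface is the dorsal polygon area.
    """
    dp, lp = dorsal.points, lateral.points
    if method == "caliper":
        length, axis = _caliper_length_axis(dp)
    elif method == "axis":
        axis = _principal_axis(dp)
        length = _extent_along(dp, axis)
    else:
        raise ValueError("method must be 'caliper' or 'axis'")
    width = _extent_along(dp, np.array([-axis[1], axis[0]]))
    lat_axis = _principal_axis(lp)
    thickness = _extent_along(lp, np.array([-lat_axis[1], lat_axis[0]]))
    surface = polygon_area(dp)
    return SizeVector(length=length, width=width, thickness=thickness, surface=surface)
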