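"""Automatic contour initialization and slice-wise propagation.

The initial contour for a slice is derived from the binary head image alone:

1. find the left-most and right-most head voxels of the slice,
2. measure their distance ``d_lr``,
3. approximate the brain as a square (axial) or a rectangle with an 8:7
   (coronal) or 4:3 (sagittal) width:height ratio, width = ``d_lr``,
4. place a circle at the shape's centre with radius one third of the width,
5. build a binary level-set field phi0 = -rho inside the circle, +rho
   outside (no signed-distance function, no re-initialization ever).

Segmentation covers slices from one tenth to nine tenths of the stack, and
a converged slice mask seeds the level set of its neighbours, which is both
faster and more accurate than a fresh circle on every slice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import EmptySliceError, GeometryError

logger = logging.getLogger(__name__)

#: width:height of the brain bounding shape per orientation.
_RATIOS = {"axial": 1.0, "coronal": 7.0 / 8.0, "sagittal": 3.0 / 4.0}

Point = Tuple[int, int]


@dataclass(frozen=True)
class InitialContour:
    """A circular initial contour on one slice."""

    center: Tuple[float, float]  # (row, col)
    radius: float
    bounding_shape: Tuple[int, int]  # (width, height)
    orientation: str

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError(f"initial radius must be positive, got {self.radius}")


@dataclass
class LevelSetField:
    """A binary level-set field over one slice; the contour is {phi = 0}.

    Sign convention: phi = -rho strictly inside the contour, +rho outside.
    """

    phi: np.ndarray
    rho: float = 1.0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        if self.rho <= 0:
            raise ValueError("rho must be positive")

    def interior(self) -> np.ndarray:
        return self.phi < 0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def find_lr_extremes(head_slice: np.ndarray) -> Tuple[Point, Point]:
    """Left-most and right-most in-voxels of a binary head slice.

    Row ties are broken by the median row among the tied voxels (the lower
    middle element for an even count), which keeps the result deterministic.
    """
    head_slice = np.asarray(head_slice, dtype=bool)
    rows, cols = np.nonzero(head_slice)
    if rows.size == 0:
        raise EmptySliceError("head slice has no in-voxels")

    def _at_col(col: int) -> Point:
        tied = np.sort(rows[cols == col])
        return int(tied[tied.size // 2]), int(col)

    return _at_col(int(cols.min())), _at_col(int(cols.max()))


def lr_distance(left: Point, right: Point) -> float:
    """Euclidean distance between the extreme voxels."""
    return math.hypot(left[0] - right[0], left[1] - right[1])


def bounding_shape(d_lr: float, orientation: str) -> Tuple[int, int]:
    """Brain bounding shape (width, height) from the left-right distance.

    Axial slices use a square; coronal and sagittal use 8:7 and 4:3
    width:height rectangles.  Half-voxel values round up.
    """
    if d_lr <= 0:
        raise ValueError(f"d_lr must be positive, got {d_lr}")
    if orientation not in _RATIOS:
        raise ValueError(f"unknown orientation {orientation!r}")
    width = _round_half_up(d_lr)
    height = _round_half_up(d_lr * _RATIOS[orientation])
    return width, height


def initial_circle(
    shape: Tuple[int, int],
    anchor: Tuple[float, float],
    orientation: str,
    grid_shape: Optional[Tuple[int, int]] = None,
) -> InitialContour:
    """Circle at the centre of the bounding shape, radius one third of width.

    ``anchor`` is the (row, col) centre where the bounding shape is placed.
    """
    width, height = shape
    if width <= 0 or height <= 0:
        raise ValueError(f"bounding shape must be positive, got {shape}")
    radius = width / 3.0
    contour = InitialContour(
        center=(float(anchor[0]), float(anchor[1])),
        radius=radius,
        bounding_shape=(int(width), int(height)),
        orientation=orientation,
    )
    if grid_shape is not None:
        r0, c0 = contour.center
        if (
            r0 - radius < 0
            or c0 - radius < 0
            or r0 + radius > grid_shape[0] - 1
            or c0 + radius > grid_shape[1] - 1
        ):
            raise GeometryError(
                f"initial circle (center {contour.center}, r={radius:.1f}) exits "
                f"the {grid_shape} slice"
            )
    return contour


def init_level_set(
    contour: InitialContour, grid_shape: Tuple[int, int], rho: float = 1.0
) -> LevelSetField:
    """Binary level-set field: -rho strictly inside the circle, +rho outside."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    rr, cc = np.meshgrid(
        np.arange(grid_shape[0], dtype=np.float64),
        np.arange(grid_shape[1], dtype=np.float64),
        indexing="ij",
    )
    inside = (rr - contour.center[0]) ** 2 + (cc - contour.center[1]) ** 2 < contour.radius**2
    phi = np.where(inside, -rho, rho)
    return LevelSetField(phi=phi, rho=rho)


def auto_initial_contour(
    head_slice: np.ndarray,
    orientation: str,
    min_radius: float = 3.0,
) -> InitialContour:
    """Full automatic initialization (steps 1-4) on one head-mask slice.

    The bounding shape is anchored horizontally at the midpoint between the
    left/right extremes and vertically at the median row of head voxels.  If
    the circle is not fully inside the head mask (pathological slices), the
    radius shrinks in 10% steps down to ``min_radius``.
    """
    head_slice = np.asarray(head_slice, dtype=bool)
    left, right = find_lr_extremes(head_slice)
    d_lr = lr_distance(left, right)
    if d_lr <= 0:
        d_lr = 1.0
    shape = bounding_shape(d_lr, orientation)
    rows = np.nonzero(head_slice)[0]
    rows_sorted = np.sort(rows)
    anchor = (
        float(rows_sorted[rows_sorted.size // 2]),
        (left[1] + right[1]) / 2.0,
    )
    contour = initial_circle(shape, anchor, orientation)

    radius = contour.radius
    rr, cc = np.meshgrid(
        np.arange(head_slice.shape[0]), np.arange(head_slice.shape[1]), indexing="ij"
    )
    dist2 = (rr - anchor[0]) ** 2 + (cc - anchor[1]) ** 2
    while radius > min_radius:
        inside = dist2 < radius**2
        if head_slice[inside].all() and inside.any():
            break
        radius *= 0.9
    radius = max(radius, min_radius)
    return InitialContour(
        center=anchor,
        radius=radius,
        bounding_shape=contour.bounding_shape,
        orientation=orientation,
    )


def slice_range(n_slices: int) -> Tuple[int, int]:
    """1-based inclusive slice range from one tenth to nine tenths.

    60 slices -> (6, 54).  Fewer than 10 slices falls back to the full range
    with a logged warning.
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    if n_slices < 10:
        logger.warning(
            "volume has only %d slices; segmenting the full range", n_slices
        )
        return 1, n_slices
    start = max(n_slices // 10, 1)
    end = min((9 * n_slices) // 10, n_slices)
    return start, end


def propagate_contour(prev_mask: np.ndarray, rho: float = 1.0) -> LevelSetField:
    """Seed a slice's level set from the neighbouring slice's brain mask."""
    prev_mask = np.asarray(prev_mask, dtype=bool)
    if not prev_mask.any():
        raise EmptySliceError("previous slice mask is empty; use circle initialization")
    phi = np.where(prev_mask, -rho, rho)
    return LevelSetField(phi=phi, rho=rho)
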