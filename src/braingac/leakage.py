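"""Detection and correction of contour leakage through weak boundaries.

Where CSF is thin or absent, non-brain tissue (e.g. muscle near the
cerebellum) abuts brain at similar intensity and the contour escapes through
the gap.  Such leakage tongues carry points of high curvature on the zero
level set, so the evolution is monitored: when the number of high-curvature
contour points reaches a pre-set count, segmentation stops and the slice is
re-segmented with local thresholds — the head region is partitioned and the
leak-prone lower-lateral parts (I and II) receive a *higher* intensity
threshold, realized by a smaller Tc in t = (t2 - t1)/Tc + t1, which removes
the near-brain-intensity bridge from the evolution domain and reveals the
weak boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from . import gac
from .initialization import LevelSetField
from .intensity import IntensityRange

PART_REST = 0
PART_I = 1
PART_II = 2
PART_OUTSIDE = -1


@dataclass
class LeakageConfig:
    """Empirical constants of the leakage detector and local thresholds.

    ``curvature_threshold`` (voxel^-1) and ``preset_count`` define when a
    contour is declared leaking; both are data-determined constants, with
    defaults calibrated on the weak-boundary phantom so that detection fires
    on every leaking slice and never on clean ones.  Checks run every
    ``check_interval`` iterations starting at twice that, so the early
    transient contour cannot trigger a false stop.  ``part_tc`` maps the
    partition parts I and II to their (smaller, hence higher-threshold) Tc.
    """

    curvature_threshold: float = 0.5
    preset_count: int = 6
    check_interval: int = 5
    partition: str = "lower_lateral"
    part_tc: Dict[str, float] = field(default_factory=lambda: {"I": 2.0, "II": 2.0})

    def __post_init__(self) -> None:
        if self.curvature_threshold <= 0:
            raise ValueError("curvature_threshold must be positive")
        if self.preset_count < 1:
            raise ValueError("preset_count must be at least 1")
        if self.check_interval < 1:
            raise ValueError("check_interval must be at least 1")


def zero_level_points(phi: np.ndarray) -> np.ndarray:
    """Contour voxels: sign changes against any 4-neighbour.

    Returns an (n, 2) array of (row, col) indices.
    """
    phi = np.asarray(phi, dtype=np.float64)
    sign = phi >= 0
    edge = np.zeros_like(sign, dtype=bool)
    edge[:-1, :] |= sign[:-1, :] != sign[1:, :]
    edge[1:, :] |= sign[1:, :] != sign[:-1, :]
    edge[:, :-1] |= sign[:, :-1] != sign[:, 1:]
    edge[:, 1:] |= sign[:, 1:] != sign[:, :-1]
    return np.argwhere(edge)


def high_curvature_points(phi, curvature_threshold: float) -> np.ndarray:
    """Zero-level-set voxels whose |curvature| exceeds the threshold."""
    arr = phi.phi if isinstance(phi, LevelSetField) else np.asarray(phi, dtype=np.float64)
    points = zero_level_points(arr)
    if points.size == 0:
        return points.reshape(0, 2)
    k = gac.curvature(arr)
    keep = np.abs(k[points[:, 0], points[:, 1]]) > curvature_threshold
    return points[keep]


def leakage_detected(points: np.ndarray, preset_count: int) -> bool:
    """True iff the high-curvature point count reaches the pre-set value."""
    return len(points) >= preset_count


def make_stop_check(config: LeakageConfig):
    """Stop-check closure for :func:`braingac.gac.segment_slice`.

    Checks every ``check_interval`` iterations from iteration
    ``2 * check_interval`` onward (early transient contours are exempt), and
    unconditionally on the final call so that a leak that converges between
    periodic checks is still caught.
    """

    def check(psi: np.ndarray, iteration: int, final: bool = False) -> bool:
        if not final and (
            iteration < 2 * config.check_interval
            or iteration % config.check_interval
        ):
            return False
        pts = high_curvature_points(psi, config.curvature_threshold)
        return leakage_detected(pts, config.preset_count)

    return check


def partition_slice(
    slice_shape: Tuple[int, int], head_mask: np.ndarray, scheme: str = "lower_lateral"
) -> np.ndarray:
    """Label each head voxel with its local-threshold part.

    ``lower_lateral`` splits the head bounding box at its vertical midpoint
    and the lower half again at the horizontal midpoint: part I (label 1) is
    the lower-left quadrant, part II (label 2) the lower-right, everything
    else label 0.  Non-head voxels get label -1.  ``single`` puts every head
    voxel in part 0.
    """
    head_mask = np.asarray(head_mask, dtype=bool)
    if head_mask.shape != tuple(slice_shape):
        raise ValueError("head mask shape does not match the slice shape")
    if not head_mask.any():
        raise ValueError("head mask is empty")
    labels = np.full(slice_shape, PART_OUTSIDE, dtype=np.int8)
    labels[head_mask] = PART_REST
    if scheme == "single":
        return labels
    if scheme != "lower_lateral":
        raise ValueError(f"unknown partition scheme {scheme!r}")
    rows, cols = np.nonzero(head_mask)
    r_mid = (rows.min() + rows.max()) / 2.0
    c_mid = (cols.min() + cols.max()) / 2.0
    lower = rows > r_mid
    labels[rows[lower & (cols < c_mid)], cols[lower & (cols < c_mid)]] = PART_I
    labels[rows[lower & (cols >= c_mid)], cols[lower & (cols >= c_mid)]] = PART_II
    return labels


def local_threshold_domain(
    I: np.ndarray,
    parts: np.ndarray,
    intensity_range: IntensityRange,
    base_tc: float,
    part_tc: Dict[str, float],
) -> np.ndarray:
    """Evolution domain after per-part thresholding.

    Parts I and II use their own Tc; the rest of the head and everything
    outside it use the orientation's base Tc.
    """
    from .intensity import head_threshold  # local import avoids cycle at import time

    tc_map = np.full(parts.shape, base_tc, dtype=np.float64)
    tc_map[parts == PART_I] = part_tc.get("I", base_tc)
    tc_map[parts == PART_II] = part_tc.get("II", base_tc)
    t_map = np.empty_like(tc_map)
    for tc in np.unique(tc_map):
        t_map[tc_map == tc] = head_threshold(intensity_range, float(tc))
    return np.asarray(I, dtype=np.float64) > t_map


def resegment_with_local_thresholds(
    I: np.ndarray,
    phi0,
    parts: np.ndarray,
    intensity_range: IntensityRange,
    base_tc: float,
    params: "gac.EvolutionParams",
    part_tc: Optional[Dict[str, float]] = None,
    model: str = "spf",
) -> Tuple[np.ndarray, "gac.EvolutionTrace"]:
    """Re-segment a leaking slice with sub-threshold voxels masked out.

    Runs :func:`braingac.gac.segment_slice` again from the same initial
    level set, restricted to the per-part supra-threshold domain.  With
    identical Tc everywhere this reduces exactly to the single-threshold
    segmentation restricted to the head image.
    """
    if part_tc is None:
        part_tc = {"I": 2.0, "II": 2.0}
    domain = local_threshold_domain(I, parts, intensity_range, base_tc, part_tc)
    return gac.segment_slice(I, phi0, params, model=model, domain=domain)
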