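"""Effective intensity range, head threshold and head binarization.

The effective range [t1, t2] is taken at the 2% and 98% points of the
cumulative intensity histogram, ignoring voxels with unusual intensities at
both tails.  The head/background threshold is then

    t = (t2 - t1) / Tc + t1

with Tc an orientation-specific constant > 1, so t sits strictly between t1
and t2.  Thresholding the raw volume at t yields the binary head image used
for automatic contour initialization and for leakage correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .io import BinaryMask, Volume


@dataclass(frozen=True)
class IntensityRange:
    """Intensities at the 2% (t1) and 98% (t2) cumulative histogram points."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.t1 > self.t2:
            raise ValueError(f"t1 ({self.t1}) must not exceed t2 ({self.t2})")


@dataclass
class ThresholdConfig:
    """Per-orientation divisors Tc of the head-threshold formula.

    Tc is determined empirically; the defaults place t in the lower third of
    the effective range, separating background from skin/muscle without
    touching brain intensities.  All values must exceed 1 so t < t2.
    """

    tc_axial: float = 3.0
    tc_coronal: float = 3.5
    tc_sagittal: float = 3.5

    def __post_init__(self) -> None:
        for name in ("tc_axial", "tc_coronal", "tc_sagittal"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be > 1")

    def tc_for(self, orientation: str) -> float:
        try:
            return {
                "axial": self.tc_axial,
                "coronal": self.tc_coronal,
                "sagittal": self.tc_sagittal,
            }[orientation]
        except KeyError:
            raise ValueError(f"unknown orientation {orientation!r}") from None


ArrayOrVolume = Union[np.ndarray, Volume]


def _as_array(vol: ArrayOrVolume) -> np.ndarray:
    return vol.data if isinstance(vol, Volume) else np.asarray(vol)


def estimate_intensity_range(vol: ArrayOrVolume) -> IntensityRange:
    """Exact order-statistic estimate of the effective intensity range.

    t1 is the smallest intensity v such that the number of voxels with
    intensity <= v reaches 2% of all voxels; t2 analogously for 98%.  Ties at
    the percentile boundary resolve to the smaller intensity.
    """
    data = _as_array(vol)
    flat = np.sort(data, axis=None)
    n = flat.size
    if n == 0:
        raise ValueError("cannot estimate an intensity range on an empty volume")
    i1 = max(math.ceil(0.02 * n) - 1, 0)
    i2 = max(math.ceil(0.98 * n) - 1, 0)
    return IntensityRange(t1=float(flat[i1]), t2=float(flat[i2]))


def head_threshold(rng: IntensityRange, tc: float) -> float:
    """Head/background threshold t = (t2 - t1)/Tc + t1."""
    if tc <= 0:
        raise ValueError(f"Tc must be positive, got {tc}")
    return (rng.t2 - rng.t1) / tc + rng.t1


def binarize_head(vol: ArrayOrVolume, t: float):
    """Binary head image: in-voxels are exactly those with intensity > t.

    No morphological cleanup is applied.  Returns a :class:`BinaryMask` for
    a :class:`Volume` input, a boolean array for an array input.
    """
    data = _as_array(vol)
    mask = data > t
    if isinstance(vol, Volume):
        return BinaryMask(data=mask, spacing=vol.spacing, affine=vol.affine)
    return mask
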