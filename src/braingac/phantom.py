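"""Synthetic T1-like head phantom with known ground-truth brain mask.

The phantom is a stack of nested ellipsoidal shells — brain core, CSF layer,
skull, scalp, background — modulated by a smooth multiplicative bias field
(emulating MR intensity inhomogeneity) and additive Gaussian noise.  Optional
"weak boundary" arcs carve out the CSF/skull ring in narrow axial sectors and
replace it with muscle-like tissue at near-brain intensity connecting brain
to scalp: the configuration in which active contours leak out of the brain.

Every stage of the extraction pipeline is testable against the returned
ground-truth mask without downloading any data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .io import BinaryMask, Volume

#: Default weak-boundary sectors (degrees in the axial plane, 0 deg = +column
#: axis, 90 deg = +row axis i.e. the lower half of the image).  Both sit in
#: the lower-lateral quadrants targeted by the leakage-correction partition.
DEFAULT_WEAK_ARCS: Tuple[Tuple[float, float], ...] = ((57.5, 62.5), (117.5, 122.5))


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head.

    Defaults produce the standard test condition used throughout the suite:
    a 128x128x64 grid, noise at 5% of the brain intensity and a 20%
    multiplicative bias field.

    Attributes
    ----------
    shape:
        Grid dimensions (rows, columns, slices); slices = axial axis.
    brain_radius_frac:
        Brain ellipsoid semi-axes as a fraction of each grid dimension.  The
        default z fraction makes the brain span roughly the central 80% of
        the stack (as in a clinical axial acquisition), so every slice in
        the one-tenth..nine-tenths segmentation range contains brain; the
        outer shells may clip at the top/bottom faces of the grid.
    csf_thickness, skull_thickness, scalp_thickness:
        Shell thicknesses in voxels, added successively outside the brain.
    intensity_levels:
        Mean intensity per tissue; must satisfy the T1 ordering
        brain > CSF, skull < CSF, scalp > skull.
    bias_amplitude:
        Multiplicative inhomogeneity amplitude in [0, 1).
    noise_sd:
        Additive Gaussian noise standard deviation.
    weak_boundary_arcs:
        ``(start_deg, end_deg)`` axial sectors where the CSF+skull ring is
        replaced by a muscle bridge at ``weak_arc_intensity_frac`` times the
        brain intensity.  Narrow sectors (~5 deg) give the bridge dark side
        walls, which is what makes a local region-based contour leak.
    weak_arc_halfheight:
        Half-extent of the bridge along the slice axis, in voxels, centred
        on the brain equator.
    seed:
        Seed for bias field and noise; the ground truth never depends on it.
    """

    shape: Tuple[int, int, int] = (128, 128, 64)
    brain_radius_frac: Tuple[float, float, float] = (0.32, 0.36, 0.42)
    csf_thickness: float = 2.0
    skull_thickness: float = 3.0
    scalp_thickness: float = 4.0
    intensity_levels: Dict[str, float] = field(
        default_factory=lambda: {
            "background": 0.0,
            "scalp": 210.0,
            "skull": 25.0,
            "csf": 35.0,
            "brain": 110.0,
        }
    )
    bias_amplitude: float = 0.2
    noise_sd: float = 5.5
    weak_boundary_arcs: Tuple[Tuple[float, float], ...] = ()
    weak_arc_intensity_frac: float = 0.82
    weak_arc_halfheight: int = 12
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lv = self.intensity_levels
        if not (lv["brain"] > lv["csf"]):
            raise ValueError("T1 ordering violated: brain must be brighter than CSF")
        if not (lv["skull"] < lv["csf"]):
            raise ValueError("T1 ordering violated: skull must be darker than CSF")
        if not (lv["scalp"] > lv["skull"]):
            raise ValueError("T1 ordering violated: scalp must be brighter than skull")
        if not 0.0 <= self.bias_amplitude < 1.0:
            raise ValueError("bias_amplitude must be in [0, 1)")
        semis = self.brain_semis()
        shell = self.csf_thickness + self.skull_thickness + self.scalp_thickness
        # In-plane the whole head must fit; along the slice axis only brain+CSF
        # must — skull and scalp may clip at the top/bottom faces, as in a
        # clinical axial acquisition whose stack covers the brain.
        for dim, a in zip(self.shape[:2], semis[:2]):
            if a + shell >= dim / 2.0:
                raise GeometryError(
                    f"head (brain semi-axis {a:.1f} + shells {shell:.1f}) does not "
                    f"fit inside grid dimension {dim}"
                )
        if semis[2] + self.csf_thickness >= self.shape[2] / 2.0:
            raise GeometryError(
                f"brain+CSF (semi-axis {semis[2]:.1f} + {self.csf_thickness:.1f}) "
                f"does not fit inside the {self.shape[2]}-slice stack"
            )

    def brain_semis(self) -> Tuple[float, float, float]:
        return tuple(f * d for f, d in zip(self.brain_radius_frac, self.shape))


def generate_bias_field(shape: Sequence[int], amplitude: float, seed: int) -> np.ndarray:
    """Smooth multiplicative bias field with values in [1-amplitude, 1+amplitude].

    Built by trilinear upsampling of a small seeded random control grid, then
    centred and rescaled so the grid mean is exactly 1 and the range bound is
    exact.  The coarse control grid makes the field band-limited: adjacent
    voxels never jump by more than a small fraction of the amplitude.
    """
    if not 0.0 <= amplitude < 1.0:
        raise ValueError(f"amplitude must be in [0, 1), got {amplitude}")
    shape = tuple(int(s) for s in shape)
    if amplitude == 0.0:
        return np.ones(shape, dtype=np.float64)
    rng = np.random.default_rng(seed)
    # control-grid resolution scales with axis length so interpolation cells
    # stay >= ~16 voxels wide and neighbouring voxels never jump by more than
    # a small fraction of the amplitude
    ctrl = tuple(max(2, min(5, 1 + s // 16)) for s in shape)
    coarse = rng.uniform(-1.0, 1.0, size=ctrl)
    coords = np.meshgrid(
        *[np.linspace(0, c - 1, s) for c, s in zip(coarse.shape, shape)],
        indexing="ij",
    )
    up = ndimage.map_coordinates(coarse, np.array(coords), order=1, mode="nearest")
    up -= up.mean()
    peak = np.max(np.abs(up))
    if peak > 0:
        up /= peak
    return 1.0 + amplitude * up


def _ellipsoid(grids, center, semis) -> np.ndarray:
    q = np.zeros_like(grids[0], dtype=np.float64)
    for g, c, a in zip(grids, center, semis):
        q += ((g - c) / a) ** 2
    return q < 1.0


def generate_phantom(spec: PhantomSpec) -> Tuple[Volume, BinaryMask]:
    """Render the phantom volume and its ground-truth brain mask.

    Deterministic given ``spec.seed``; the truth mask marks exactly the brain
    ellipsoid and is independent of noise, bias and weak arcs.
    """
    shape = spec.shape
    center = tuple((d - 1) / 2.0 for d in shape)
    grids = np.meshgrid(*[np.arange(d, dtype=np.float64) for d in shape], indexing="ij")

    brain_semis = spec.brain_semis()
    csf_semis = tuple(a + spec.csf_thickness for a in brain_semis)
    skull_semis = tuple(a + spec.skull_thickness for a in csf_semis)
    scalp_semis = tuple(a + spec.scalp_thickness for a in skull_semis)

    lv = spec.intensity_levels
    tissue = np.full(shape, lv["background"], dtype=np.float64)
    tissue[_ellipsoid(grids, center, scalp_semis)] = lv["scalp"]
    tissue[_ellipsoid(grids, center, skull_semis)] = lv["skull"]
    tissue[_ellipsoid(grids, center, csf_semis)] = lv["csf"]
    brain = _ellipsoid(grids, center, brain_semis)
    tissue[brain] = lv["brain"]

    if spec.weak_boundary_arcs:
        # Ring between brain surface and scalp inner surface, sliced into
        # axial angular sectors near the brain equator.
        ring = _ellipsoid(grids, center, skull_semis) & ~brain
        angle = np.degrees(np.arctan2(grids[0] - center[0], grids[1] - center[1])) % 360.0
        band = np.abs(grids[2] - center[2]) <= spec.weak_arc_halfheight
        bridge_val = spec.weak_arc_intensity_frac * lv["brain"]
        for start, end in spec.weak_boundary_arcs:
            start, end = start % 360.0, end % 360.0
            if start <= end:
                in_arc = (angle >= start) & (angle <= end)
            else:
                in_arc = (angle >= start) | (angle <= end)
            tissue[ring & band & in_arc] = bridge_val

    bias = generate_bias_field(shape, spec.bias_amplitude, spec.seed)
    data = tissue * bias
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        data = data + rng.normal(0.0, spec.noise_sd, size=shape)

    vol = Volume(data=data, spacing=spec.spacing)
    truth = BinaryMask(data=brain, spacing=spec.spacing)
    return vol, truth


def weak_boundary_spec(**overrides) -> PhantomSpec:
    """Convenience constructor: the standard phantom with default weak arcs."""
    kwargs = dict(weak_boundary_arcs=DEFAULT_WEAK_ARCS)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)
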