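# Methods

## The extraction model

`braingac` segments each 2-D slice of an MR head volume with a geometric
active contour evolved as the zero level set of a scalar field φ:

    ∂φ/∂t = spf(x) · (k + v0) · |∇φ|                                  (evolution)
    spf(x) = ( Gσ*I(x) − (f1+f2)/2 ) / max_x | Gσ*I − (f1+f2)/2 |     (pressure)
    f1 = Σ Hε(φ)·I / Σ Hε(φ),   f2 = Σ (1−Hε(φ))·I / Σ (1−Hε(φ))      (region means)
    Hε(x) = ½ (1 + (2/π) arctan(x/ε))                                  (smoothed step)

`f1` and `f2` are two constants per iteration: the Heaviside-weighted means
of the intensity over the current inside and outside regions.  (In the
defining integrals a Gaussian window appears inside a domain integral; the
kernel integrates to one, so the windowing survives only in the smoothed
image term `Gσ*I` of the pressure.)  The normalization by the slice maximum
bounds `spf` in [−1, 1] and makes the force scale-free: the contour expands
wherever the smoothed intensity exceeds the midpoint of the two region
means, shrinks elsewhere, and therefore stops at statistical region
boundaries even where the image gradient is weak.  The classic edge-based
contour, `∂φ/∂t = c(k+v0)|∇φ|` with `c = 1/(1+|∇Gσ*I|)`, is implemented as
a baseline: its speed never reaches zero, so it creeps through weak edges —
the boundary-leakage failure the region model addresses.

### Sign and orientation conventions

Public level-set fields are binary with φ = −ρ inside the contour and +ρ
outside.  The evolution itself runs on the flipped field (positive inside):
in that orientation `Hε(φ)` weights the interior in the region means and the
literal update above moves the contour outward through bright tissue with
`v0 > 0`.  `segment_slice` flips once on entry; users never see the internal
orientation.

### Stability without re-initialization

φ is never a signed-distance function.  After every Euler step the field is
snapped to ±ρ by sign and convolved with a Gaussian of width `reg_sigma`
(selective binary + Gaussian regularization).  This keeps |∇φ| bounded,
regularizes the contour in place of explicit curvature-only smoothing, and
has a useful side effect: updates smaller than the smoothed field amplitude
cannot flip voxels, so the contour freezes where the driving force is weak
instead of drifting.  Curvature `k` is still kept inside the speed term (a
config switch `use_curvature` disables it); with the binary representation
its numerical role is small but it damps high-curvature transients.

### Convergence

A slice is converged when the per-iteration changed-voxel count stays below
`converge_tol` (5 voxels) for `converge_window` (3) consecutive iterations,
with a hard cap of `max_iters` (200).  The final mask is the largest
connected component of {φ < 0}; an empty mask marks the slice as failed
(the caller falls back or records an empty slice).

## Pipeline

1. **Intensity model.**  The effective range [t1, t2] is read off the exact
   sorted intensities at the 2% and 98% cumulative points (ties resolve to
   the smaller intensity), deliberately ignoring outlier tails.  The head
   threshold is `t = (t2−t1)/Tc + t1`; Tc is empirical and
   orientation-specific (defaults 3.0 axial, 3.5 coronal/sagittal, placing t
   between the dark tissues — background, skull, CSF — and the bright ones —
   brain, scalp).  Thresholding at t gives the binary head image.
2. **Automatic initialization.**  Per slice: find the left/right extreme
   head voxels (row ties resolve to the median row), take their distance
   d, approximate the brain as a square (axial) or a rectangle of
   width:height 8:7 (coronal) or 4:3 (sagittal) with width d, and place a
   circle of radius one third of the width at the shape's centre
   (horizontal centre = midpoint of the extremes, vertical centre = median
   head row — the placement is otherwise unspecified and this keeps the
   circle inside off-centre heads).  If the circle pokes out of the head
   mask it shrinks by 10% steps to a floor of 3 voxels.  φ0 is the binary
   field −ρ/+ρ of that circle.
3. **Slice sweep.**  Only slices from ⌊n/10⌋ to ⌊9n/10⌋ (1-based) are
   segmented — end slices contain little or no brain.  The middle slice is
   segmented first from the automatic circle; the sweep then moves outward
   in both directions, seeding each slice's φ0 with the neighbour's
   converged mask, which converges in a fraction of the iterations and
   tracks the shrinking brain cross-section.  Each slice's output is
   intersected with the binary head image and reduced to its largest
   component before being stored or propagated: sub-threshold tissue cannot
   be brain, and cleaning the seeds prevents the region statistics of small
   end slices from being dragged toward shell intensities.
4. **Leakage correction.**  Where CSF is locally absent, near-brain-intensity
   tissue (muscle, fat) bridges brain to scalp and the contour escapes.
   Escaping tongues carry clusters of high-curvature points on the zero
   level set, so during evolution the contour is checked every
   `check_interval` iterations (from twice that, so early transients are
   exempt, and once more at termination): if the number of zero-level-set
   voxels with |k| above `curvature_threshold` reaches `preset_count`, the
   slice is declared leaking, stopped, and re-segmented with local
   thresholds — the head bounding box is split at its vertical midpoint and
   the lower half again at the horizontal midpoint into parts I and II
   (the lower-lateral quadrants, where such bridges occur near the
   cerebellum), which receive a *higher* threshold via a smaller Tc
   (default 2.0 vs the orientation default), and sub-threshold voxels are
   clamped out of the evolution domain.  The corrected pass runs once,
   without further detection.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| sigma | 1.5 | voxels | Gaussian window of the smoothed image term |
| epsilon | 1.0 | — | Heaviside smoothing width (≈ one voxel) |
| v0 | 5 | voxel/iter | balloon force |
| dt | 1 | — | Euler time step |
| rho | 1 | — | binary level-set amplitude |
| reg_sigma | 1.0 | voxels | regularization smoothing |
| max_iters / converge_tol / converge_window | 200 / 5 / 3 | — | stopping rule |
| tc (axial/coronal/sagittal) | 3.0 / 3.5 / 3.5 | — | head-threshold divisors |
| leakage.curvature_threshold | 0.5 | voxel⁻¹ | high-curvature cutoff |
| leakage.preset_count | 6 | points | detection trigger |
| leakage.check_interval | 5 | iters | detection cadence |
| leakage.part_tc | I: 2.0, II: 2.0 | — | corrective thresholds |

σ, Δt, ρ and v0 are the published settings of the method; ε has no
published value and one voxel is the conventional choice.  The stopping
rule is ours (the method reports iteration counts but no rule).  The
leakage constants are declared data-empirical by the method; these defaults
were calibrated once on the weak-boundary phantom to make detection fire on
every leaking slice and never on clean ones, and are config-exposed.

## The synthetic phantom

The phantom emulates exactly the features the method responds to: nested
ellipsoidal shells (brain 110, CSF 35, skull 25, scalp 210, background 0 in
arbitrary units — the T1 ordering with bright subcutaneous fat and dark
CSF/bone), a smooth multiplicative bias field (trilinear upsampling of a
seeded coarse random grid, exactly mean-1 and range-bounded) emulating coil
inhomogeneity, additive Gaussian noise, and optional weak-boundary arcs:
narrow (~5°) axial sectors near the brain equator where the CSF/skull ring
is replaced by muscle-like tissue at 0.82× brain intensity connecting brain
to scalp.  Narrowness matters — the dark sector walls keep the bridge
statistically attached to the brain region, which is what lets the contour
escape, as it does near the cerebellum in real data.  The default geometry
puts the brain across the central ~84% of the stack, as in a clinical axial
acquisition, so every slice in the segmented range contains brain; the
outer shells may clip at the top/bottom faces of the field of view.
Defaults (128×128×64, noise 5% of brain intensity, bias amplitude 0.2) are
the standard condition used throughout the tests.

What the phantom does *not* model: anatomy (gyri, ventricles, eyes, neck),
partial-volume voxels, Rician noise statistics (at these contrasts the
Gaussian approximation does not change contour behaviour).  Passing tests
therefore validate the mechanics — initialization, evolution, stopping,
leak detection, thresholds, metrics — not clinical-grade accuracy on real
heads.

## Evaluation

Masks are scored against reference masks over the whole volume domain with
sensitivity TP/(TP+FN), specificity TN/(TN+FP), Jaccard TP/(TP+FP+FN),
Dice 2TP/(2TP+FP+FN) and FP_rate.  FP_rate is defined risk-style as
FP/(TP+FN) — false positives relative to the true brain volume — the
convention under which published specificity ≈ 0.99 and FP_rate ≈ 0.05 can
coexist (1−specificity would be ~0.007); `fp_rate_definition` switches to
1−specificity for sensitivity analyses.  Aggregation over volumes reports
"mean(sd)" with the sample (n−1) standard deviation.

## Numerical choices and degenerate inputs

Divisions are guarded at 10⁻⁸ (fitting-mean denominators fall back to the
global image mean; |∇φ| is floored in the curvature).  The SPF
normalization maximum is recomputed per slice per iteration; an identically
zero numerator yields a zero force field (constant images are fixed
points).  Convolutions use reflective boundaries.  Curvature uses central
differences with one-sided stencils at the image border.  Ratio-derived
lengths round half-up; slice-range indices use floor (forced by the
60-slice → 6..54 worked example).  Volumes with fewer than 10 slices fall
back to the full slice range with a warning.  A constant volume has an
empty head image on every slice and raises an extraction failure with
per-slice diagnostics.

## Design choices on genuinely open points

- **Region means as constants.**  The fitting means are global
  Heaviside-weighted means (constant per iteration), which is what the
  defining integrals reduce to and what gives the balloon force reach
  through homogeneous tissue; a voxel-wise local-window variant produces
  zero force away from intensity structure and cannot grow a contour from
  an interior seed at all.
- **Orientation handling.**  Orientation labels come from the image affine
  (nibabel axis codes); a config/CLI flag overrides them, since Analyze
  headers are often unreliable.  Each orientation is segmented
  independently; the method never fuses orientations.
- **Detection scope.**  The leak detector examines all zero-level-set
  voxels (4-neighbour sign changes), not only those near the head-mask
  boundary; on clean contours the count is zero, so the broader scope costs
  nothing and catches tongues anywhere.
- **Output cleanup.**  Intersecting each slice result with the binary head
  image is the volume-level counterpart of the domain clamp used in
  leakage correction; both follow from reading the head image as the
  universe of brain-candidate voxels.

## Known limitations

- The local-threshold correction trades false positives for false
  negatives: parts I and II are re-thresholded wholesale, so with strong
  bias fields some dark brain voxels in those quadrants fall below the
  corrective threshold (visible as a Dice gap between corrected
  weak-boundary runs ~0.97 and clean runs ~0.998).
- Bridges at *exactly* brain intensity cannot be separated by any
  threshold; the correction assumes the offending tissue is at least
  slightly darker than brain.
- Slices outside the ⌊n/10⌋..⌊9n/10⌋ range are never segmented; brain
  present there is a deliberate false negative.
- The classic edge-potential baseline is faithful to its published form
  and therefore performs poorly on full head volumes; it exists to
  demonstrate the leakage failure mode, not as a usable extractor.
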