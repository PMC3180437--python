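"""Core contour evolution: Heaviside, fitting means, SPF, curvature, steps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from braingac import (
    EvolutionParams,
    InitialContour,
    NumericalInstabilityError,
    curvature,
    edge_potential,
    evolve_step,
    init_level_set,
    local_fitting_means,
    segment_slice,
    smoothed_heaviside,
    spf_field,
)
from conftest import dice_of
from oracles import edge_potential_explicit, fitting_means_explicit, spf_explicit

PARAMS = EvolutionParams()


def circle_sdf(shape, center, radius):
    """Inside-positive signed distance to a circle."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return radius - np.hypot(rr - center[0], cc - center[1])


class TestHeaviside:
    def test_analytic_values(self):
        assert smoothed_heaviside(0.0, 1.0) == 0.5
        assert smoothed_heaviside(2.0, 2.0) == pytest.approx(0.75)
        assert smoothed_heaviside(1e12, 1.0) == pytest.approx(1.0, abs=1e-6)
        assert smoothed_heaviside(-1e12, 1.0) == pytest.approx(0.0, abs=1e-6)

    @given(st.floats(-1e6, 1e6), st.floats(0.01, 100))
    @settings(derandomize=True, max_examples=100)
    def test_symmetry_identity(self, x, eps):
        assert smoothed_heaviside(x, eps) + smoothed_heaviside(-x, eps) == pytest.approx(1.0)

    @given(st.floats(-100, 100), st.floats(0.01, 10), st.floats(0.001, 10))
    @settings(derandomize=True, max_examples=100)
    def test_strictly_increasing(self, x, step, eps):
        assert smoothed_heaviside(x + step, eps) > smoothed_heaviside(x, eps)


class TestFittingMeansAndSPF:
    def test_constant_image_means_equal_the_constant(self):
        I = np.full((20, 20), 42.0)
        phi = circle_sdf((20, 20), (10, 10), 5)
        f1, f2 = local_fitting_means(I, phi, PARAMS.sigma, PARAMS.epsilon)
        np.testing.assert_allclose(f1, 42.0)
        np.testing.assert_allclose(f2, 42.0)

    def test_two_region_means_with_sharp_indicator(self):
        # inside 100 / outside 20 with a near-binary Heaviside recovers the
        # per-region means
        phi = np.where(circle_sdf((32, 32), (16, 16), 9) > 0, 1.0, -1.0)
        I = np.where(phi > 0, 100.0, 20.0)
        f1, f2 = local_fitting_means(I, phi, sigma=1.5, epsilon=0.005)
        assert f1[0, 0] == pytest.approx(100.0, abs=2.0)
        assert f2[0, 0] == pytest.approx(20.0, abs=2.0)

    def test_means_match_explicit_summation_oracle(self):
        rng = np.random.default_rng(3)
        I = rng.uniform(0, 200, size=(24, 28))
        phi = rng.normal(size=(24, 28))
        f1, f2 = local_fitting_means(I, phi, sigma=2.0, epsilon=1.0)
        o1, o2 = fitting_means_explicit(I, phi, epsilon=1.0)
        assert f1[5, 7] == pytest.approx(o1, rel=1e-6)
        assert f2[5, 7] == pytest.approx(o2, rel=1e-6)

    def test_spf_matches_explicit_summation_oracle(self):
        rng = np.random.default_rng(4)
        I = rng.uniform(0, 200, size=(32, 32))
        phi = circle_sdf((32, 32), (16, 16), 8)
        f1, f2 = local_fitting_means(I, phi, sigma=1.5, epsilon=1.0)
        spf = spf_field(I, f1, f2, sigma=1.5)
        np.testing.assert_allclose(spf, spf_explicit(I, phi, 1.5, 1.0), rtol=1e-6, atol=1e-9)

    def test_constant_image_spf_identically_zero(self):
        I = np.full((16, 16), 3.0)
        phi = circle_sdf((16, 16), (8, 8), 4)
        f1, f2 = local_fitting_means(I, phi, 1.5, 1.0)
        assert np.all(spf_field(I, f1, f2, 1.5) == 0.0)

    def test_nonconstant_spf_max_abs_exactly_one(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            I = rng.uniform(0, 100, size=(20, 20))
            phi = rng.normal(size=(20, 20))
            f1, f2 = local_fitting_means(I, phi, 1.5, 1.0)
            spf = spf_field(I, f1, f2, 1.5)
            assert np.max(np.abs(spf)) == 1.0

    def test_spf_positive_in_bright_region_negative_in_dark(self):
        phi = circle_sdf((48, 48), (24, 24), 12)
        I = np.where(phi > 0, 100.0, 20.0)
        f1, f2 = local_fitting_means(I, phi, 1.5, 1.0)
        spf = spf_field(I, f1, f2, 1.5)
        assert spf[24, 24] > 0  # bright interior
        assert spf[2, 2] < 0  # dark exterior


class TestCurvature:
    def test_circle_curvature_one_over_radius(self):
        phi = -circle_sdf((64, 64), (32, 32), 20)  # outside-positive SDF
        k = curvature(phi)
        band = np.abs(phi) < 1.0
        assert np.median(k[band]) == pytest.approx(1 / 20.0, rel=0.10)

    def test_straight_edge_zero_curvature(self):
        rr = np.arange(32, dtype=float)
        phi = np.tile(rr[:, None], (1, 32)) - 16.0
        k = curvature(phi)
        assert np.abs(k[np.abs(phi) < 1.0]).max() < 1e-6

    def test_convergence_to_closed_form_with_radius(self):
        errors = []
        for radius in (8, 16, 32):
            phi = -circle_sdf((160, 160), (80, 80), radius)
            k = curvature(phi)
            band = np.abs(phi) < 1.0
            errors.append(abs(np.median(k[band]) - 1 / radius) * radius)
        assert errors[2] < errors[0]

    def test_minimum_grid_size(self):
        with pytest.raises(ValueError):
            curvature(np.zeros((2, 5)))


class TestEvolveStep:
    def test_zero_speed_is_stationary(self):
        phi = circle_sdf((32, 32), (16, 16), 8)
        out = evolve_step(phi, np.zeros_like(phi), curvature(phi), PARAMS)
        np.testing.assert_array_equal(out, phi)

    def test_balloon_growth_matches_radius_ode(self):
        # uniform unit pressure, v0 >> |k|: the zero level set of an
        # inside-positive SDF advances by ~ dt*v0 per step (r' = v0)
        radius = 20.0
        phi = circle_sdf((128, 128), (64, 64), radius)
        params = EvolutionParams(v0=5.0, dt=0.2, use_curvature=False)
        out = evolve_step(phi, np.ones_like(phi), 0.0, params)
        grown = (out > 0).sum()
        expected = np.pi * (radius + params.dt * params.v0) ** 2
        assert grown == pytest.approx(expected, rel=0.03)

    def test_non_finite_update_raises(self):
        phi = circle_sdf((16, 16), (8, 8), 4)
        spf = np.full_like(phi, np.inf)
        with pytest.raises(NumericalInstabilityError):
            evolve_step(phi, spf, 0.0, PARAMS)


class TestEdgePotential:
    def test_constant_image_has_unit_potential(self):
        np.testing.assert_allclose(edge_potential(np.full((16, 16), 9.0), 1.0), 1.0)

    def test_matches_explicit_oracle_and_bounds(self):
        I = np.zeros((21, 21))
        I[:, 11:] = 1.0
        c = edge_potential(I, 1.0)
        oracle = edge_potential_explicit(I, 1.0)
        np.testing.assert_allclose(c, oracle, rtol=1e-6)
        assert 0.0 < c.min() <= c.max() <= 1.0
        # unit contrast barely dents the potential; MR-scale contrast floors it
        assert c.min() == pytest.approx(0.757, abs=0.01)
        assert edge_potential(I * 200.0, 1.0).min() < 0.05


class TestSegmentSlice:
    def test_noiseless_disc_recovered_within_one_voxel_band(self):
        rr, cc = np.meshgrid(np.arange(96), np.arange(96), indexing="ij")
        disc = (rr - 48.0) ** 2 + (cc - 48.0) ** 2 < 30.0**2
        I = np.where(disc, 150.0, 10.0)
        phi0 = init_level_set(
            InitialContour((48, 48), 15.0, (45, 45), "axial"), I.shape, 1.0
        )
        mask, trace = segment_slice(I, phi0, PARAMS)
        assert trace.converged
        mismatch = mask ^ disc
        dist = ndimage.distance_transform_edt(~disc) + ndimage.distance_transform_edt(disc)
        assert not mismatch.any() or dist[mismatch].max() <= 1.5

    def test_constant_image_fixed_point_keeps_initialization(self):
        I = np.full((64, 64), 50.0)
        phi0 = init_level_set(
            InitialContour((32, 32), 10.0, (30, 30), "axial"), I.shape, 1.0
        )
        mask, trace = segment_slice(I, phi0, PARAMS)
        assert trace.converged
        np.testing.assert_array_equal(mask, phi0.phi < 0)

    def test_inhomogeneous_slice_dice(self, mid_slice):
        # 20% multiplicative bias: region-based pressure still finds the brain
        phi0 = init_level_set(
            InitialContour((64, 64), 20.0, (60, 60), "axial"),
            mid_slice["I"].shape,
            1.0,
        )
        mask, _ = segment_slice(mid_slice["I"], phi0, PARAMS)
        assert dice_of(mask, mid_slice["truth"]) >= 0.95

    def test_close_initialization_needs_fewer_iterations(self, mid_slice):
        from braingac import auto_initial_contour

        I = mid_slice["I"]
        close = auto_initial_contour(mid_slice["head"], "axial")
        far = InitialContour((63.5, 63.5), close.radius / 4, (20, 20), "axial")
        _, tr_close = segment_slice(I, init_level_set(close, I.shape, 1.0), PARAMS)
        _, tr_far = segment_slice(I, init_level_set(far, I.shape, 1.0), PARAMS)
        assert tr_close.iterations_run < tr_far.iterations_run


class TestClassicBaseline:
    def test_zero_potential_is_stationary(self):
        from braingac import classic_gac_step

        phi = circle_sdf((32, 32), (16, 16), 8)
        out = classic_gac_step(phi, np.zeros_like(phi), curvature(phi), PARAMS)
        np.testing.assert_array_equal(out, phi)

    def test_agreement_with_proposed_on_high_contrast_disc(self):
        rr, cc = np.meshgrid(np.arange(96), np.arange(96), indexing="ij")
        disc = (rr - 48.0) ** 2 + (cc - 48.0) ** 2 < 30.0**2
        I = np.where(disc, 200.0, 0.0)
        phi0 = init_level_set(
            InitialContour((48, 48), 15.0, (45, 45), "axial"), I.shape, 1.0
        )
        proposed, _ = segment_slice(I, phi0, PARAMS, model="spf")
        classic, _ = segment_slice(I, phi0, PARAMS, model="edge")
        diff = proposed ^ classic
        # dist is >= 1 everywhere (measured from the opposite region), so a
        # 2-voxel band around the zero-crossing corresponds to dist <= 3
        dist = ndimage.distance_transform_edt(~disc) + ndimage.distance_transform_edt(disc)
        assert not diff.any() or dist[diff].max() <= 3.0

    def test_classic_leaks_through_weak_bridge_on_phantom_slice(self, weak_phantom):
        from braingac import (
            binarize_head,
            estimate_intensity_range,
            head_threshold,
            partition_slice,
            resegment_with_local_thresholds,
            weak_boundary_spec,
        )

        vol, truth = weak_phantom
        data = vol.as_float()
        z = data.shape[2] // 2
        I, truth2d = data[:, :, z], truth.data[:, :, z]
        rng = estimate_intensity_range(data)
        head = binarize_head(I, head_threshold(rng, 3.0))
        phi0 = init_level_set(
            InitialContour((63.5, 63.5), 30.0, (90, 90), "axial"), I.shape, 1.0
        )
        params = EvolutionParams()
        classic, _ = segment_slice(I, phi0, params, model="edge")
        labels = partition_slice(I.shape, head, "lower_lateral")
        corrected, _ = resegment_with_local_thresholds(
            I, phi0, labels, rng, 3.0, params
        )
        spec = weak_boundary_spec()
        bridge_val = spec.weak_arc_intensity_frac * spec.intensity_levels["brain"]
        bridge = (~truth2d) & (np.abs(I - bridge_val) < 25) & head
        # the edge-potential model floods through the near-brain-intensity
        # bridge; the threshold-corrected region model keeps it out
        assert (classic & bridge).sum() > 0.5 * bridge.sum()
        assert (corrected & bridge).sum() <= 0.05 * bridge.sum()
        assert (classic & ~truth2d & ~corrected).any()
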