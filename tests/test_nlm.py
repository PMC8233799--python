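import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rnlmstar as rs
from oracles import naive_nlm_family


class TestExtractPatch:
    def test_constant_image_gives_constant_patch(self):
        img = np.full((10, 10), 0.3)
        patch = rs.extract_patch(img, (5, 5), 2)
        assert np.all(patch == 0.3)

    def test_interior_patch_is_direct_subgrid(self):
        img = np.arange(25, dtype=float).reshape(5, 5)
        patch = rs.extract_patch(img, (2, 2), 1)
        assert np.array_equal(patch, img[1:4, 1:4])

    def test_corner_patch_uses_symmetric_padding(self):
        img = np.arange(25, dtype=float).reshape(5, 5)
        patch = rs.extract_patch(img, (0, 0), 1)
        expected = np.pad(img, 1, mode="symmetric")[0:3, 0:3]
        assert np.array_equal(patch, expected)

    def test_stride2_dialect_samples_even_offsets(self):
        img = np.arange(81, dtype=float).reshape(9, 9)
        patch = rs.extract_patch(img, (4, 4), 1, dialect="stride2")
        assert np.array_equal(patch, img[2:7:2, 2:7:2])


class TestPatchSimilarity:
    def test_identical_patches_give_one(self, rng):
        p = rng.random((3, 3))
        assert rs.patch_similarity(p, p, h=0.5) == 1.0

    def test_doubling_distance_raises_to_fourth_power(self):
        p0 = np.zeros((3, 3))
        p1 = np.full((3, 3), 0.1)
        p2 = np.full((3, 3), 0.2)  # doubled pointwise difference
        phi1 = rs.patch_similarity(p0, p1, h=0.7)
        phi2 = rs.patch_similarity(p0, p2, h=0.7)
        assert phi2 == pytest.approx(phi1 ** 4, rel=1e-12)

    def test_hand_computed_value_uniform_kernel(self):
        p1 = np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]])
        p2 = np.array([[0.2, 0.2, 0.3], [0.4, 0.1, 0.6], [0.7, 0.8, 0.5]])
        # squared diffs: 0.01, 0.16, 0.16 -> mean = 0.33/9
        expected = math.exp(-(0.33 / 9) / 0.8 ** 2)
        assert rs.patch_similarity(p1, p2, h=0.8) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_h_rejected(self):
        p = np.zeros((3, 3))
        with pytest.raises(ValueError):
            rs.patch_similarity(p, p, h=0.0)


class TestPixelSimilarity:
    def test_equal_pixels_give_one(self):
        assert rs.pixel_similarity(0.4, 0.4, degc=0.2, omega=4) == 1.0

    def test_half_at_transition_position(self):
        for omega in (1, 2, 4, 8):
            assert rs.pixel_similarity(0.0, 0.2, degc=0.2, omega=omega) == pytest.approx(0.5)

    def test_double_transition_with_omega_four(self):
        assert rs.pixel_similarity(0.0, 0.4, degc=0.2, omega=4) == pytest.approx(1 / 17)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_decreasing_in_difference(self, y1, y2):
        rho_near = rs.pixel_similarity(0.0, min(y1, y2), degc=0.15, omega=3)
        rho_far = rs.pixel_similarity(0.0, max(y1, y2), degc=0.15, omega=3)
        assert rho_far <= rho_near + 1e-15

    def test_invalid_degc_rejected(self):
        with pytest.raises(ValueError):
            rs.pixel_similarity(0.1, 0.2, degc=0.0, omega=2)


class TestSelfWeightScale:
    def test_equal_intensities_limit_is_one(self):
        assert rs.self_weight_scale(0.5, 0.5, radp=3, degc=0.2, omega=4) == 1.0

    def test_large_difference_limit(self):
        val = rs.self_weight_scale(0.0, 1e9, radp=3, degc=0.2, omega=4)
        assert val == pytest.approx(1 + 49, rel=1e-9)

    def test_unit_ratio_value(self):
        # |yi - yk| = degc -> 1 + (2*3+1)^2 / 2 = 25.5
        assert rs.self_weight_scale(0.0, 0.2, radp=3, degc=0.2, omega=4) == pytest.approx(25.5)


@pytest.fixture
def random16(rng):
    return rng.random((16, 16))


class TestFiltersAgainstOracle:
    def test_constant_image_fixed_points(self, small_params):
        c = np.full((20, 20), 0.42)
        assert np.allclose(rs.nlm_filter(c, small_params), 0.42)
        assert np.allclose(rs.rnlm_filter(c, small_params, 0.0), 0.42)
        assert np.allclose(rs.rnlm_star_filter(c, small_params, 0.0), 0.42)

    def test_rnlm_bias_cancels_exactly_at_matching_sigma(self, small_params):
        sigma = 0.2
        c = np.full((20, 20), math.sqrt(2) * sigma)
        out = rs.rnlm_filter(c, small_params, sigma)
        # sqrt amplifies the ~1e-17 representation residue of 2*sigma^2
        assert np.allclose(out, 0.0, atol=1e-8)

    @pytest.mark.parametrize("variant", ["nlm", "rnlm", "rnlm_star"])
    def test_fast_path_matches_naive_loop(self, random16, small_params, variant):
        ref = naive_nlm_family(random16, small_params, sigma=0.05, variant=variant)
        if variant == "nlm":
            fast = rs.nlm_filter(random16, small_params)
        elif variant == "rnlm":
            fast = rs.rnlm_filter(random16, small_params, 0.05)
        else:
            fast = rs.rnlm_star_filter(random16, small_params, 0.05)
        assert np.max(np.abs(fast - ref)) <= 1e-8

    @pytest.mark.parametrize("dialect", ["contiguous", "stride2"])
    @pytest.mark.parametrize("a", [math.inf, 1.5])
    def test_fast_path_matches_oracle_across_kernels_and_dialects(
        self, random16, dialect, a
    ):
        p = rs.FilterParams(
            h=0.4, radp=2, rads=4, degc=0.2, omega=3, a=a, patch_dialect=dialect
        )
        ref = naive_nlm_family(random16, p, sigma=0.05, variant="rnlm_star")
        fast = rs.rnlm_star_filter(random16, p, 0.05)
        assert np.max(np.abs(fast - ref)) <= 1e-8

    def test_small_h_preserves_step_image(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        p = rs.FilterParams(h=1e-3, radp=2, rads=4, degc=0.5, omega=2)
        out = rs.nlm_filter(img, p)
        assert np.max(np.abs(out - img)) < 1e-6

    def test_no_sqrt_returns_squared_scale(self, random16, small_params):
        with_sqrt = rs.rnlm_filter(random16, small_params, 0.05)
        without = rs.rnlm_filter(random16, small_params, 0.05, no_sqrt=True)
        assert np.allclose(with_sqrt ** 2, without)

    def test_image_smaller_than_search_window_rejected(self, small_params):
        with pytest.raises(ValueError):
            rs.nlm_filter(np.zeros((5, 5)), small_params)

    def test_negative_sigma_rejected(self, random16, small_params):
        with pytest.raises(ValueError):
            rs.rnlm_filter(random16, small_params, -0.1)
        with pytest.raises(ValueError):
            rs.rnlm_star_filter(random16, small_params, -0.1)


class TestInvariants:
    def test_intensity_bounds(self, rng, small_params):
        img = rng.random((16, 16)) * 0.8 + 0.1
        nlm_out = rs.nlm_filter(img, small_params)
        assert nlm_out.min() >= img.min() - 1e-12
        assert nlm_out.max() <= img.max() + 1e-12
        for out in (
            rs.rnlm_filter(img, small_params, 0.1),
            rs.rnlm_star_filter(img, small_params, 0.1),
        ):
            assert out.min() >= 0
            assert out.max() <= img.max() + 1e-12

    def test_shift_equivariance_in_interior(self, rng, small_params):
        img = rng.random((24, 24))
        shift = 3
        out_then_shift = np.roll(rs.nlm_filter(img, small_params), shift, axis=1)
        shift_then_out = rs.nlm_filter(np.roll(img, shift, axis=1), small_params)
        margin = small_params.rads + small_params.patch_extent + shift
        inner = (slice(margin, -margin), slice(margin, -margin))
        assert np.max(np.abs(out_then_shift[inner] - shift_then_out[inner])) <= 1e-8

    def test_degc_to_infinity_recovers_rnlm(self, rng, small_params):
        # rho -> 1 and theta -> 1, so the starred weights collapse to the
        # plain max-self-weight scheme
        img = rng.random((16, 16))
        p_inf = small_params.with_(degc=1e9)
        star = rs.rnlm_star_filter(img, p_inf, 0.05)
        plain = rs.rnlm_filter(img, small_params, 0.05)
        assert np.max(np.abs(star - plain)) < 1e-8

    def test_rnlm_bias_correction_on_constant_phantom(self, small_params):
        # Monte-Carlo: E[M^2] = A^2 + 2 sigma^2 means the corrected mean
        # returns to A
        A, sigma = 0.6, 0.1
        means = []
        for seed in range(20):
            noisy = rs.add_rician(np.full((64, 64), A), sigma, seed=seed)
            out = rs.rnlm_filter(noisy, small_params, sigma)
            means.append(out.mean())
        hits = sum(abs(m - A) < 0.02 for m in means)
        assert hits >= 18


class TestWeightField:
    def test_uniform_weights_on_constant_image(self, small_params):
        img = np.full((16, 16), 0.5)
        wf = rs.compute_weight_field(img, (8, 8), small_params, "nlm")
        n = (2 * small_params.rads + 1) ** 2
        nz = wf.weights[wf.weights > 0]
        assert len(nz) == n
        assert np.allclose(nz, 1.0 / n)

    @pytest.mark.parametrize("variant", ["nlm", "rnlm_star"])
    def test_weights_sum_to_one(self, rng, small_params, variant):
        img = rng.random((14, 14))
        for center in [(0, 0), (6, 7), (13, 13)]:
            wf = rs.compute_weight_field(img, center, small_params, variant)
            assert wf.total() == pytest.approx(1.0, abs=1e-10)

    def test_field_reproduces_filter_output(self, rng, small_params):
        img = rng.random((14, 14))
        out = rs.nlm_filter(img, small_params)
        r, c = 6, 7
        wf = rs.compute_weight_field(img, (r, c), small_params, "nlm")
        rads = small_params.rads
        acc = 0.0
        for dy in range(-rads, rads + 1):
            for dx in range(-rads, rads + 1):
                w = wf.weights[rads + dy, rads + dx]
                if w:
                    acc += w * img[r + dy, c + dx]
        assert acc == pytest.approx(out[r, c], abs=1e-10)

    def test_star_self_weight_share_exceeds_nlm_share_at_particle(self):
        spec = rs.PhantomSpec(
            size=(32, 32), n_bands=1, n_particles=1, particle_radius_px=1,
            particle_contrast=0.5, edge_blur_sigma=0.0, seed=5, band_levels=(0.3,),
        )
        img = rs.make_phantom(spec)
        cy, cx = rs.phantoms._particle_centers(spec)[0]
        p = rs.FilterParams(h=0.4, radp=2, rads=5, degc=0.15, omega=4)
        share_star = rs.compute_weight_field(img, (cy, cx), p, "rnlm_star").self_weight_share
        share_nlm = rs.compute_weight_field(img, (cy, cx), p, "nlm").self_weight_share
        assert share_star > share_nlm
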