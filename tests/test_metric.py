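"""Tests for the 12-direction kernel bank and the DSS/MSS/GSS metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gradiq import (
    DistortionSpec,
    FixtureSpec,
    MetricParams,
    apply_distortion,
    build_kernel_bank,
    deviation_pool,
    direction_map,
    direction_responses,
    direction_similarity,
    joint_similarity,
    magnitude_similarity,
    make_oriented_edge,
    make_screen_fixture,
    quantized_direction,
    score_pair,
)
from gradiq.gradients import GradientField

from .oracles import argmax12_bruteforce, conv2d_bruteforce


class TestKernelBank:
    def test_exactly_twelve_kernels_at_quindecimal_angles(self, bank):
        assert bank.kernels.shape[0] == 12
        np.testing.assert_allclose(bank.angles, np.arange(12) * np.pi / 12)

    def test_quarter_turn_kernel_is_exact_grid_rotation(self, bank):
        np.testing.assert_array_equal(bank.kernels[6], np.rot90(bank.kernels[0]))

    def test_unit_absolute_sums(self, bank):
        sums = np.abs(bank.kernels).sum(axis=(1, 2))
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    @pytest.mark.parametrize("bad", [4, 1, -3])
    def test_invalid_base_size_rejected(self, bad):
        with pytest.raises(ValueError, match="base_size"):
            build_kernel_bank(bad)


class TestDirectionAssignment:
    def test_zero_magnitude_gives_zero_responses(self, bank):
        resp = direction_responses(np.zeros((10, 10)), bank)
        np.testing.assert_array_equal(resp, 0.0)

    def test_responses_match_bruteforce_convolution(self, bank, rng):
        mag = rng.uniform(0, 50, (8, 8))
        resp = direction_responses(mag, bank)
        for i in range(12):
            np.testing.assert_allclose(
                resp[i], conv2d_bruteforce(mag, bank.kernels[i]), atol=1e-9
            )

    @pytest.mark.parametrize("i", [0, 2, 3, 4, 6, 8, 9, 10])
    def test_oriented_edge_excites_matching_kernel(self, bank, i):
        # A step edge along i*pi/12 produces a magnitude ridge in that
        # orientation; the i-th line kernel must respond strongest there.
        # The default 5x5 bank cannot separate the 15-degree-from-axis
        # orientations from their neighbours, so those are tested with the
        # larger bank below.
        img = make_oriented_edge(64, 64, i * np.pi / 12, 100.0)
        field = GradientField.forward_l1(img)
        resp = direction_responses(field.magnitude, bank)
        on_edge = field.magnitude > 0.5 * field.magnitude.max()
        means = [resp[j][on_edge].mean() for j in range(12)]
        assert int(np.argmax(means)) == i

    @pytest.mark.parametrize("i", range(12))
    def test_seven_pixel_bank_resolves_all_twelve_orientations(self, i):
        bank7 = build_kernel_bank(7)
        img = make_oriented_edge(96, 96, i * np.pi / 12, 100.0)
        field = GradientField.forward_l1(img)
        resp = direction_responses(field.magnitude, bank7)
        on_edge = field.magnitude > 0.5 * field.magnitude.max()
        means = [resp[j][on_edge].mean() for j in range(12)]
        assert int(np.argmax(means)) == i

    def test_tie_breaks_toward_smallest_index(self):
        dm = direction_map(np.ones((12, 3, 3)))
        np.testing.assert_array_equal(dm.index, 0)
        np.testing.assert_array_equal(dm.direction, 0.0)

    def test_single_maximum_selects_its_angle(self):
        stack = np.zeros((12, 2, 2))
        stack[6] = 1.0
        dm = direction_map(stack)
        np.testing.assert_allclose(dm.direction, np.pi / 2)

    def test_argmax_matches_per_pixel_loop(self, rng):
        stack = rng.standard_normal((12, 4, 4))
        np.testing.assert_array_equal(direction_map(stack).index, argmax12_bruteforce(stack))

    def test_direction_values_lie_on_twelve_point_grid(self, screen_image, bank):
        dm = quantized_direction(screen_image, bank)
        assert np.all(np.isin(dm.direction, bank.angles))
        np.testing.assert_array_equal(dm.direction, dm.index * (np.pi / 12))

    def test_wrong_stack_shape_rejected(self):
        with pytest.raises(ValueError):
            direction_map(np.zeros((11, 4, 4)))


class TestSimilarityMaps:
    def test_direction_similarity_worked_value(self):
        d_r = np.array([[0.0]])
        d_d = np.array([[11 * np.pi / 12]])
        ds = direction_similarity(d_r, d_d, c_d=205.0)
        assert ds[0, 0] == pytest.approx(205.0 / (205.0 + (11 * np.pi / 12) ** 2), abs=1e-12)
        assert ds[0, 0] == pytest.approx(0.96112, abs=1e-5)

    def test_magnitude_similarity_worked_value(self):
        ms = magnitude_similarity(np.array([[10.0]]), np.array([[5.0]]), c_m=160.0)
        assert ms[0, 0] == pytest.approx(260.0 / 285.0, abs=1e-12)
        assert ms[0, 0] == pytest.approx(0.91228, abs=1e-5)

    def test_equal_inputs_give_unit_similarity(self, rng):
        d = rng.uniform(0, np.pi, (5, 5))
        np.testing.assert_allclose(direction_similarity(d, d), 1.0)
        m = rng.uniform(0, 300, (5, 5))
        np.testing.assert_allclose(magnitude_similarity(m, m), 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=arrays(np.float64, (4, 4), elements=st.floats(0, 500)),
        b=arrays(np.float64, (4, 4), elements=st.floats(0, 500)),
    )
    def test_similarity_symmetric_and_bounded(self, a, b):
        ms_ab = magnitude_similarity(a, b)
        np.testing.assert_allclose(ms_ab, magnitude_similarity(b, a))
        assert np.all(ms_ab > 0) and np.all(ms_ab <= 1 + 1e-12)

    def test_circular_variant_treats_near_pi_wrap_as_similar(self):
        d_r = np.array([[0.0]])
        d_d = np.array([[11 * np.pi / 12]])
        plain = direction_similarity(d_r, d_d)
        circ = direction_similarity(d_r, d_d, circular=True)
        assert circ[0, 0] > plain[0, 0]
        np.testing.assert_allclose(direction_similarity(d_r, d_r, circular=True), 1.0)

    def test_joint_similarity_product_and_reductions(self, rng):
        ds = np.array([[0.9]])
        ms = np.array([[0.8]])
        assert joint_similarity(ds, ms)[0, 0] == pytest.approx(0.72)
        ds_m = rng.uniform(0.1, 1.0, (4, 4))
        ms_m = rng.uniform(0.1, 1.0, (4, 4))
        np.testing.assert_array_equal(joint_similarity(ds_m, ms_m, alpha=0, beta=2), ms_m**2)
        np.testing.assert_array_equal(joint_similarity(ds_m, ms_m, alpha=1, beta=0), ds_m)

    def test_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            joint_similarity(np.ones((2, 2)), np.ones((2, 2)), alpha=-1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            magnitude_similarity(np.zeros((3, 3)), np.zeros((3, 4)))


class TestDeviationPool:
    def test_constant_map_pools_to_zero(self):
        assert deviation_pool(np.full((5, 5), 0.7)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_value(self):
        assert deviation_pool(np.array([1.0, 0.0, 1.0, 0.0])) == pytest.approx(0.5)

    def test_permutation_invariance(self, rng):
        vals = rng.uniform(0, 1, 36)
        assert deviation_pool(vals.reshape(6, 6)) == pytest.approx(
            deviation_pool(rng.permutation(vals).reshape(4, 9))
        )

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            deviation_pool(np.empty((0,)))


class TestScorePair:
    def test_identical_images_score_zero(self, screen_image):
        result = score_pair(screen_image, screen_image)
        assert result.dss == 0.0
        assert result.mss == 0.0
        assert result.gss == 0.0
        np.testing.assert_allclose(result.gs_map, 1.0)

    def test_symmetric_in_arguments(self, screen_image):
        dist = apply_distortion(screen_image, DistortionSpec("gaussian_noise", 15.0, seed=2))
        fwd = score_pair(screen_image, dist)
        rev = score_pair(dist, screen_image)
        assert fwd.gss == pytest.approx(rev.gss, abs=1e-12)
        assert fwd.dss == pytest.approx(rev.dss, abs=1e-12)

    def test_maps_bounded_and_result_consistent(self, screen_image):
        dist = apply_distortion(screen_image, DistortionSpec("gaussian_blur", 2.0))
        r = score_pair(screen_image, dist)
        for m in (r.ds_map, r.ms_map, r.gs_map):
            assert np.all(m > 0) and np.all(m <= 1 + 1e-12)
        assert r.n_pixels == screen_image.size
        assert r.m_ds == pytest.approx(r.ds_map.mean())
        assert 0 <= r.gss <= 0.5

    def test_noise_increases_score(self):
        ref = make_screen_fixture(FixtureSpec(96, 96, seed=1))
        gss = [
            np.mean(
                [
                    score_pair(
                        ref, apply_distortion(ref, DistortionSpec("gaussian_noise", lv, seed=s))
                    ).gss
                    for s in range(5)
                ]
            )
            for lv in (0.0, 10.0, 30.0)
        ]
        assert gss[0] < gss[1] < gss[2]

    def test_direction_only_metric_matches_dss_ranking(self, screen_image):
        # with alpha=1, beta=0 the joint map reduces to DS, so GSS == DSS
        params = MetricParams(alpha=1.0, beta=0.0)
        dist = apply_distortion(screen_image, DistortionSpec("gaussian_noise", 20.0, seed=4))
        r = score_pair(screen_image, dist, params)
        assert r.gss == pytest.approx(r.dss, abs=1e-12)

    def test_shape_mismatch_names_both_shapes(self, screen_image):
        with pytest.raises(ValueError, match=r"\(128, 128\).*\(64, 64\)"):
            score_pair(screen_image, screen_image[:64, :64])
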