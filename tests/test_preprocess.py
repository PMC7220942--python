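"""Binning, max-pool smoothing and Gaussian convolution against brute-force
oracles and their algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnnpeaks.preprocess import (
    DEFAULT_WINDOW_BINS,
    SmoothingConfig,
    bin_annotation,
    bin_to_fixed,
    convolve_same,
    gaussian_filter,
    max_pool_smooth,
    smooth,
)
from cnnpeaks.types import AnnotationTrack, DepthTrack, GenomicInterval


def naive_max_pool(v, w):
    half = w // 2
    return np.array(
        [v[max(0, n - half) : min(len(v), n + half + 1)].max() for n in range(len(v))]
    )


def naive_convolve(v, u):
    half = len(u) // 2
    out = np.zeros(len(v))
    for n in range(len(v)):
        for m in range(-half, half + 1):
            if 0 <= n - m < len(v):
                out[n] += v[n - m] * u[m + half]
    return out


class TestBinToFixed:
    def test_span_equal_L_is_identity(self):
        d = np.arange(10.0)
        track = DepthTrack(GenomicInterval("chr1", 0, 10), d)
        np.testing.assert_array_equal(bin_to_fixed(track, 10), d)

    def test_two_base_bins_average(self):
        span, L = 24_000, 12_000
        d = np.tile([0.0, 2.0], span // 2)
        track = DepthTrack(GenomicInterval("chr1", 0, span), d)
        np.testing.assert_allclose(bin_to_fixed(track, L), 1.0)

    def test_default_bin_count(self):
        track = DepthTrack(
            GenomicInterval("chr1", 0, DEFAULT_WINDOW_BINS), np.ones(DEFAULT_WINDOW_BINS)
        )
        assert bin_to_fixed(track).size == DEFAULT_WINDOW_BINS

    def test_small_window_tells_user_to_eliminate_it(self):
        track = DepthTrack(GenomicInterval("chr1", 0, 5), np.ones(5))
        with pytest.raises(ValueError, match="eliminate"):
            bin_to_fixed(track, 10)

    def test_uneven_partition_preserves_total_mass(self):
        rng = np.random.default_rng(0)
        d = rng.poisson(3, size=103).astype(float)
        track = DepthTrack(GenomicInterval("chr1", 0, 103), d)
        binned = bin_to_fixed(track, 10)
        # mean of bin means weighted by bin widths recovers the global mean
        edges = np.round(np.arange(11) * 103 / 10).astype(int)
        widths = np.diff(edges)
        assert np.isclose((binned * widths).sum(), d.sum())

    def test_annotation_binned_by_max(self):
        bits = np.zeros(20, dtype=np.int8)
        bits[3] = 1  # single annotated base -> its bin reads 1
        track = AnnotationTrack(GenomicInterval("chr1", 0, 20), bits)
        binned = bin_annotation(track, 10)
        assert binned[1] == 1.0
        assert binned.sum() == 1.0


class TestMaxPoolSmooth:
    def test_constant_vector_unchanged(self):
        v = np.full(17, 3.5)
        np.testing.assert_array_equal(max_pool_smooth(v, 4), v)

    def test_matches_naive_oracle_on_spec_example(self):
        v = np.array([0.0, 2, 1, 5, 3])
        np.testing.assert_array_equal(max_pool_smooth(v, 2), naive_max_pool(v, 2))

    @pytest.mark.parametrize("w", [1, 2, 3, 5, 8])
    def test_matches_naive_oracle_random(self, w):
        rng = np.random.default_rng(42)
        v = rng.normal(size=50)
        np.testing.assert_array_equal(max_pool_smooth(v, w), naive_max_pool(v, w))

    def test_length_preserved(self):
        assert max_pool_smooth(np.arange(9.0), 5).size == 9

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            max_pool_smooth(np.array([]), 3)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        st.integers(1, 9),
    )
    def test_monotone_in_input(self, v, w):
        v = np.array(v)
        bump = np.abs(v) * 0.1 + 1.0
        lo = max_pool_smooth(v, w)
        hi = max_pool_smooth(v + bump, w)
        assert (hi >= lo).all()


class TestGaussianFilter:
    def test_single_tap_is_identity_filter(self):
        np.testing.assert_array_equal(gaussian_filter(1, 2.0), [1.0])

    @pytest.mark.parametrize("M,sigma", [(3, 1.0), (11, 2.0), (21, 0.5)])
    def test_probability_vector_and_symmetry(self, M, sigma):
        u = gaussian_filter(M, sigma)
        assert u.size == M
        assert (u >= 0).all()
        assert abs(u.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(u, u[::-1])

    def test_closed_form_M3_sigma1(self):
        g = np.exp(-np.array([1.0, 0.0, 1.0]) / 2)
        np.testing.assert_allclose(gaussian_filter(3, 1.0), g / g.sum(), atol=1e-15)

    def test_even_M_rejected(self):
        with pytest.raises(ValueError):
            gaussian_filter(4, 1.0)


class TestConvolveSame:
    def test_identity_filter(self):
        v = np.array([1.0, 4, 2, 8])
        np.testing.assert_array_equal(convolve_same(v, np.array([1.0])), v)

    def test_impulse_response_recovers_filter(self):
        v = np.zeros(11)
        v[5] = 1.0
        u = np.array([0.25, 0.5, 0.25])
        np.testing.assert_allclose(convolve_same(v, u), naive_convolve(v, u))
        np.testing.assert_allclose(convolve_same(v, u)[4:7], u)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=20)
        u = rng.normal(size=5)
        np.testing.assert_allclose(convolve_same(v, u), naive_convolve(v, u), atol=1e-12)

    def test_filter_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            convolve_same(np.ones(3), np.ones(5))


class TestSmooth:
    CFG = SmoothingConfig(pool_width=3, filter_size=5, filter_sigma=1.0)

    def test_all_zero_depth_stays_zero(self):
        track = DepthTrack(GenomicInterval("chr1", 0, 40), np.zeros(40))
        assert not smooth(track, self.CFG, 20).x.any()

    def test_constant_depth_preserved_in_interior(self):
        track = DepthTrack(GenomicInterval("chr1", 0, 40), np.full(40, 4.0))
        x = smooth(track, self.CFG, 20).x
        pad = self.CFG.filter_size // 2
        np.testing.assert_allclose(x[pad:-pad], 4.0)

    def test_composite_equals_manual_pipeline(self):
        rng = np.random.default_rng(3)
        d = rng.poisson(5, size=60).astype(float)
        track = DepthTrack(GenomicInterval("chr1", 0, 60), d)
        got = smooth(track, self.CFG, 30).x
        binned = bin_to_fixed(track, 30)
        manual = naive_convolve(
            naive_max_pool(binned, self.CFG.pool_width),
            gaussian_filter(self.CFG.filter_size, self.CFG.filter_sigma),
        )
        np.testing.assert_allclose(got, np.clip(manual, 0, None), atol=1e-12)

    def test_never_negative_and_pooling_only_raises(self):
        rng = np.random.default_rng(11)
        d = rng.poisson(2, size=80).astype(float)
        track = DepthTrack(GenomicInterval("chr1", 0, 80), d)
        out = smooth(track, self.CFG, 40)
        assert (out.x >= 0).all()
        g = gaussian_filter(self.CFG.filter_size, self.CFG.filter_sigma)
        unpooled = convolve_same(bin_to_fixed(track, 40), g)
        pad = self.CFG.filter_size // 2
        assert (out.x[pad:-pad] >= unpooled[pad:-pad] - 1e-12).all()

    def test_annotation_binned_in_lockstep(self):
        bits = np.zeros(40, dtype=np.int8)
        bits[10:20] = 1
        iv = GenomicInterval("chr1", 0, 40)
        out = smooth(
            DepthTrack(iv, np.ones(40)),
            self.CFG,
            20,
            annotation=AnnotationTrack(iv, bits),
        )
        np.testing.assert_array_equal(out.lam[5:10], 1.0)
        assert out.lam.sum() == 5
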