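"""Loss functions against brute-force oracles, class weighting, label
rasterization, and the training loop's descent/reproducibility contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnnpeaks.model import build_model
from cnnpeaks.preprocess import ModelInput
from cnnpeaks.training import (
    LossConfig,
    TrainingExample,
    class_weight,
    rasterize_labels,
    topk_loss,
    train,
    weighted_ce,
)
from cnnpeaks.types import GenomicInterval, Label, LabeledRegion

from conftest import TINY_ARCH


def make_examples(rng, n, L=40, peaky=True):
    """Easy separable windows: background ~2, peaks ~20, fully labeled."""
    out = []
    for i in range(n):
        x = rng.gamma(4.0, 0.5, size=L) + 2.0
        y = np.zeros(L)
        if peaky:
            lo = int(rng.integers(5, L - 15))
            width = int(rng.integers(5, 10))
            x[lo : lo + width] += 18.0
            y[lo : lo + width] = 1.0
        lam = np.zeros(L)
        inp = ModelInput(
            x=x, lam=lam,
            anchor=GenomicInterval("chr1", i * L * 10, (i + 1) * L * 10),
            bin_width=10,
        )
        out.append(TrainingExample(input=inp, y=y, mask=np.ones(L, bool)))
    return out


class TestClassWeight:
    def test_direct_ratio(self):
        rng = np.random.default_rng(0)
        ex = make_examples(rng, 1, L=40, peaky=False)[0]
        ex.y[:10] = 1.0
        assert class_weight([ex]) == pytest.approx(3.0)

    def test_balanced_gives_one(self):
        rng = np.random.default_rng(0)
        ex = make_examples(rng, 1, L=40, peaky=False)[0]
        ex.y[:20] = 1.0
        assert class_weight([ex]) == pytest.approx(1.0)

    def test_all_negative_is_an_error(self):
        rng = np.random.default_rng(0)
        ex = make_examples(rng, 1, peaky=False)[0]
        with pytest.raises(ValueError, match="peak labels"):
            class_weight([ex])

    def test_masked_bins_do_not_count(self):
        rng = np.random.default_rng(0)
        ex = make_examples(rng, 1, L=40, peaky=False)[0]
        ex.y[:10] = 1.0
        ex.mask[20:] = False  # 10 pos, 10 neg visible
        assert class_weight([ex]) == pytest.approx(1.0)


class TestWeightedCE:
    def test_perfect_predictions_vanish(self):
        y = np.array([1.0, 0.0])
        h = np.array([1 - 1e-9, 1e-9])
        assert weighted_ce(y, h, 3.0).max() < 1e-8

    def test_spec_point_value(self):
        # y=1, h=0.5, w=2 -> 2 ln 2
        loss = weighted_ce(np.array([1.0]), np.array([0.5]), 2.0)
        assert loss[0] == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_w1_equals_unweighted_bce(self):
        rng = np.random.default_rng(1)
        y = (rng.random(200) < 0.4).astype(float)
        h = rng.uniform(0.01, 0.99, size=200)
        ours = weighted_ce(y, h, 1.0)
        bce = -(y * np.log(h) + (1 - y) * np.log(1 - h))
        np.testing.assert_allclose(ours, bce, atol=1e-10)

    def test_increasing_w_raises_positive_bin_loss(self):
        y = np.array([1.0])
        h = np.array([0.7])
        assert weighted_ce(y, h, 5.0)[0] > weighted_ce(y, h, 2.0)[0]

    def test_boundary_predictions_clamped_not_infinite(self):
        loss = weighted_ce(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 1.0)
        assert np.isfinite(loss).all()

    def test_masked_bins_zeroed(self):
        y = np.array([1.0, 1.0])
        h = np.array([0.5, 0.5])
        loss = weighted_ce(y, h, 1.0, mask=np.array([True, False]))
        assert loss[1] == 0.0 and loss[0] > 0.0


class TestTopKLoss:
    def test_full_kappa_is_mean(self):
        rng = np.random.default_rng(2)
        v = rng.exponential(size=50)
        assert topk_loss(v, 50) == pytest.approx(v.mean())

    def test_sort_and_average_oracle(self):
        v = np.array([0.1, 0.9, 0.4, 0.6])
        assert topk_loss(v, 2) == pytest.approx(0.75)

    def test_constant_losses_invariant_in_kappa(self):
        v = np.full(10, 0.3)
        for k in (1, 3, 10):
            assert topk_loss(v, k) == pytest.approx(0.3)

    def test_kappa_below_one_rejected(self):
        with pytest.raises(ValueError):
            topk_loss(np.ones(5), 0)

    def test_kappa_beyond_unmasked_rejected(self):
        with pytest.raises(ValueError, match="unmasked"):
            topk_loss(np.ones(5), 4, mask=np.array([1, 1, 0, 0, 0], bool))

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=40), st.data())
    def test_non_increasing_in_kappa(self, vals, data):
        v = np.array(vals)
        k1 = data.draw(st.integers(1, len(v)))
        k2 = data.draw(st.integers(k1, len(v)))
        assert topk_loss(v, k1) >= topk_loss(v, k2) - 1e-12


class TestRasterizeLabels:
    def test_majority_rule_and_mask(self):
        regions = [
            LabeledRegion(GenomicInterval("chr1", 0, 16), Label.PEAK),
            LabeledRegion(GenomicInterval("chr1", 20, 40), Label.NOPEAK),
        ]
        y, mask = rasterize_labels(regions, 0, 4, 10.0)
        # bins: [0,10) full peak; [10,20) 60% peak; [20,30),[30,40) nopeak
        np.testing.assert_array_equal(mask, [True, True, True, True])
        np.testing.assert_array_equal(y, [1.0, 1.0, 0.0, 0.0])

    def test_half_covered_bin_is_unlabeled(self):
        regions = [LabeledRegion(GenomicInterval("chr1", 0, 5), Label.PEAK)]
        y, mask = rasterize_labels(regions, 0, 2, 10.0)
        assert not mask[0] and not mask[1]

    def test_ambiguous_counts_as_nopeak(self):
        regions = [LabeledRegion(GenomicInterval("chr1", 0, 10), Label.AMBIGUOUS)]
        y, mask = rasterize_labels(regions, 0, 1, 10.0)
        assert mask[0] and y[0] == 0.0


class TestTrainLoop:
    def test_loss_descends_and_is_reproducible(self):
        rng = np.random.default_rng(3)
        examples = make_examples(rng, 12)
        cfg = LossConfig(epochs=5, batch_size=4, learning_rate=3e-3, seed=7)
        m1 = build_model(TINY_ARCH, seed=7)
        h1 = train(m1, examples, cfg)
        assert len(h1) == 5
        assert h1[-1] < h1[0]
        m2 = build_model(TINY_ARCH, seed=7)
        h2 = train(m2, examples, cfg)
        assert h1 == h2

    def test_no_labeled_windows_rejected(self):
        rng = np.random.default_rng(4)
        ex = make_examples(rng, 2)
        for e in ex:
            e.mask[:] = False
        with pytest.raises(ValueError, match="labeled"):
            train(build_model(TINY_ARCH, seed=0), ex, LossConfig(epochs=1))
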