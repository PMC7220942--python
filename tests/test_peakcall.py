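"""Interval extraction, Poisson scoring and the no-control contract."""

import inspect

import numpy as np
import pytest
from scipy import stats

import cnnpeaks.peakcall as pc
from cnnpeaks.peakcall import (
    CallingConfig,
    _runs_above_cutoff,
    call_window,
    estimate_lambda,
    poisson_pvalue,
    score_call,
)
from cnnpeaks.types import GenomicInterval


class TestPoissonPvalue:
    def test_observed_zero_gives_one(self):
        assert poisson_pvalue(0.0, 3.0) == 1.0

    def test_closed_form_lambda1_obs3(self):
        # P(N >= 3 | lam=1) = 1 - e^-1 (1 + 1 + 1/2)
        expected = 1.0 - np.exp(-1.0) * 2.5
        assert poisson_pvalue(3.0, 1.0) == pytest.approx(expected, abs=1e-12)
        assert poisson_pvalue(3.0, 1.0) == pytest.approx(0.080301, abs=1e-6)

    def test_non_increasing_in_observed(self):
        ps = [poisson_pvalue(k, 4.0) for k in range(15)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_rounding_of_fractional_observed(self):
        assert poisson_pvalue(2.4, 1.0) == pytest.approx(
            float(stats.poisson.sf(1, 1.0))
        )

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            poisson_pvalue(1.0, 0.0)


class TestScoreCall:
    IV = GenomicInterval("chr1", 100, 200)

    def test_p_equal_one_gives_zero_score(self):
        call = score_call(self.IV, activation=0.9, observed=0.0, lam=5.0)
        assert call.pvalue == 1.0
        assert call.score == 0.0

    def test_product_formula(self):
        # choose observed/lam with known p, then score = a * -log10 p
        call = score_call(self.IV, activation=0.8, observed=30.0, lam=5.0)
        assert call.score == pytest.approx(0.8 * -np.log10(call.pvalue))

    def test_linear_in_activation(self):
        c1 = score_call(self.IV, 0.4, 30.0, 5.0)
        c2 = score_call(self.IV, 0.8, 30.0, 5.0)
        assert c2.score == pytest.approx(2.0 * c1.score)


class TestEstimateLambda:
    def test_constant_depth_both_modes(self):
        ctx = np.full(100, 3.0)
        assert estimate_lambda(ctx, CallingConfig()) == 3.0
        local = CallingConfig(lambda_mode="local", local_flank_bins=5)
        assert estimate_lambda(ctx, local, peak_bins=(40, 60)) == 3.0

    def test_global_mean(self):
        assert estimate_lambda(np.array([0.0, 0, 4, 0, 0])) == pytest.approx(0.8)

    def test_local_floored_by_global(self):
        ctx = np.full(100, 5.0)
        ctx[40:60] = 50.0  # peak
        ctx[30:40] = 0.0  # sparse left flank
        ctx[60:70] = 0.0  # sparse right flank
        cfg = CallingConfig(lambda_mode="local", local_flank_bins=10)
        lam = estimate_lambda(ctx, cfg, peak_bins=(40, 60))
        assert lam == pytest.approx(ctx.mean())  # floored

    def test_all_zero_context_rejected(self):
        with pytest.raises(ValueError, match="background"):
            estimate_lambda(np.zeros(10))


class TestRunExtraction:
    def test_all_below_cutoff_empty(self):
        cfg = CallingConfig(min_peak_bins=1, merge_gap_bins=0)
        assert _runs_above_cutoff(np.full(10, 0.2), cfg) == []

    def test_run_length_oracle(self):
        probs = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        cfg = CallingConfig(min_peak_bins=1, merge_gap_bins=0)
        assert _runs_above_cutoff(probs, cfg) == [(1, 3), (4, 5)]

    def test_gap_merge(self):
        probs = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        cfg = CallingConfig(min_peak_bins=1, merge_gap_bins=1)
        assert _runs_above_cutoff(probs, cfg) == [(1, 5)]

    def test_min_length_filter(self):
        probs = np.array([0.9, 0.0, 0.9, 0.9, 0.0])
        cfg = CallingConfig(min_peak_bins=2, merge_gap_bins=0)
        assert _runs_above_cutoff(probs, cfg) == [(2, 4)]

    def test_every_constituent_bin_clears_cutoff(self):
        rng = np.random.default_rng(0)
        probs = rng.random(200)
        cfg = CallingConfig(min_peak_bins=1, merge_gap_bins=0, prob_cutoff=0.5)
        for lo, hi in _runs_above_cutoff(probs, cfg):
            assert (probs[lo:hi] >= cfg.prob_cutoff).all()


class _FixedThresholdNet:
    """Stand-in network emitting a constant threshold, for calling-logic tests."""

    def __init__(self, threshold, window_bins=40, segments=4):
        from cnnpeaks.model import ArchitectureConfig, ModelOutput, sigmoid

        self.cfg = ArchitectureConfig(
            window_bins=window_bins, threshold_segments=segments
        )
        self._t = threshold
        self._ModelOutput = ModelOutput
        self._sigmoid = sigmoid

    def forward(self, inputs):
        t = np.full(self.cfg.threshold_segments, self._t)
        probs = self._sigmoid(inputs.x - np.repeat(t, len(inputs.x) // t.size))
        return self._ModelOutput(thresholds=t, probabilities=probs)


class TestCallWindow:
    def _input(self):
        from cnnpeaks.preprocess import ModelInput

        x = np.full(40, 1.0)
        x[10:20] = 30.0  # clear enrichment over threshold 8
        return ModelInput(
            x=x, lam=np.zeros(40),
            anchor=GenomicInterval("chr1", 1000, 1400), bin_width=10,
        )

    def test_calls_map_to_genomic_coordinates(self):
        net = _FixedThresholdNet(threshold=8.0)
        cfg = CallingConfig(min_peak_bins=1, merge_gap_bins=0)
        (call,) = call_window(net, self._input(), cfg)
        # bins [10, 20) at bin width 10 from anchor 1000 -> [1100, 1200)
        assert call.interval == GenomicInterval("chr1", 1100, 1200)
        assert 0 < call.activation < 1
        assert 0 < call.pvalue <= 1
        assert np.isfinite(call.score) and call.score >= 0

    def test_everything_below_threshold_gives_no_calls(self):
        net = _FixedThresholdNet(threshold=100.0)
        assert call_window(net, self._input(), CallingConfig()) == []

    def test_no_control_track_anywhere_in_calling_path(self):
        for fn in (pc.call_window, pc.call_track, pc.call_genome):
            params = inspect.signature(fn).parameters
            assert not any(
                "control" in name or "input_track" in name or "igg" in name.lower()
                for name in params
            ), f"{fn.__name__} must not accept a control track"
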