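"""Single-neuron response statistics: dF/F_std, tuning, Z_diff."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearcortex.responses import (
    DegenerateResponseError,
    FluorescenceTrace,
    TrialResponseMatrix,
    bf_distance_octaves,
    dff_zscore,
    frequency_response_function,
    frf_percent_change,
    interpolate_at_frequency,
    is_responsive,
    normalize_frf,
    resample_by_bf_bin,
    sparseness,
    trial_response,
    zdiff,
    zdiff_significance,
)


def matrix(responses, freqs=None):
    responses = np.asarray(responses, dtype=float)
    if freqs is None:
        freqs = 1000.0 * 2.0 ** np.arange(responses.shape[0])
    return TrialResponseMatrix(responses=responses, frequencies=freqs)


class TestDffZscore:
    def test_hand_example(self):
        # baseline frames mean 10, sd 2; a post frame at 14 scores z = 2
        base = np.array([8.0, 12.0, 8.0, 12.0])  # mean 10, sd (ddof=1) ~2.31
        base = np.array([10 - 2, 10 + 2, 10 - 2, 10 + 2])
        sd = base.std(ddof=1)
        F = np.concatenate([base, [14.0] * 8])
        tr = FluorescenceTrace(F=F, frame_rate=4.0)
        z = dff_zscore(tr, onset_s=1.0)
        assert z[-1] == pytest.approx((14 - 10) / sd)

    def test_shift_invariance(self, rng):
        F = rng.normal(5.0, 1.0, size=40)
        tr0 = FluorescenceTrace(F=F, frame_rate=10.0)
        tr1 = FluorescenceTrace(F=F + 100.0, frame_rate=10.0)
        assert np.allclose(dff_zscore(tr0, 2.0), dff_zscore(tr1, 2.0))

    def test_zero_baseline_sd_flagged(self):
        tr = FluorescenceTrace(F=np.ones(40), frame_rate=10.0)
        with pytest.raises(DegenerateResponseError):
            dff_zscore(tr, 2.0)


class TestTrialResponse:
    def test_zero_segment(self):
        assert trial_response(np.zeros(10)) == 0.0

    def test_hand_mean(self):
        assert trial_response([1.0, 2.0, 3.0]) == pytest.approx(2.0)


class TestResponsiveness:
    def test_single_frequency_reduces_to_t_test(self, rng):
        from scipy import stats

        vals = rng.normal(0.4, 1.0, size=(1, 25))
        m = matrix(vals)
        p = stats.ttest_1samp(vals[0], 0.0).pvalue
        assert is_responsive(m) == (p < 0.05)

    def test_strong_single_peak_detected(self, rng):
        vals = rng.normal(0.0, 1.0, size=(12, 25))
        vals[4] += 5.0 / math.sqrt(25) * 5  # 5 sigma/sqrt(n) margin
        assert is_responsive(matrix(vals))

    def test_null_calibration_near_alpha(self):
        # silent neurons should be flagged at roughly the nominal rate
        rng = np.random.default_rng(99)
        hits = sum(
            is_responsive(matrix(rng.normal(0, 1, size=(12, 25))))
            for _ in range(400)
        )
        assert hits / 400 <= 0.08

    def test_matches_statsmodels_holm(self, rng):
        # cross-check the decision against the reference implementation
        from scipy import stats
        from statsmodels.stats.multitest import multipletests

        vals = rng.normal(0.15, 1.0, size=(8, 20))
        p = np.array([stats.ttest_1samp(row, 0.0).pvalue for row in vals])
        expected = bool(multipletests(p, 0.05, method="holm")[0].any())
        assert is_responsive(matrix(vals)) == expected


class TestFrequencyResponseFunction:
    def test_one_hot_peak(self):
        vals = np.zeros((5, 3))
        vals[2] = 4.0
        frf = frequency_response_function(matrix(vals))
        assert frf.best_frequency == matrix(vals).frequencies[2]

    def test_tie_breaks_to_lowest_frequency(self):
        vals = np.ones((4, 3))
        frf = frequency_response_function(matrix(vals))
        assert frf.best_frequency == matrix(vals).frequencies[0]

    def test_argmax_matches_brute_force(self, rng):
        for _ in range(20):
            vals = rng.normal(size=(10, 5))
            m = matrix(vals)
            frf = frequency_response_function(m)
            means = [np.mean(row) for row in vals]
            assert frf.best_frequency == m.frequencies[int(np.argmax(means))]


class TestSparseness:
    def test_flat_positive_gives_zero(self):
        assert sparseness(np.full(8, 2.5)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("c", [1.0, 0.3, -2.0])
    def test_one_hot_gives_one(self, c):
        r = np.zeros(12)
        r[0] = c
        assert sparseness(r) == pytest.approx(1.0, abs=1e-12)

    def test_hand_arithmetic(self):
        assert sparseness(np.array([2.0, 1.0, 1.0])) == pytest.approx(1 / 6, abs=1e-12)

    def test_all_zero_flagged_missing(self):
        assert sparseness(np.zeros(5)) is None

    @given(st.permutations(list(range(6))))
    @settings(deadline=None, max_examples=30)
    def test_permutation_invariance(self, perm):
        r = np.array([0.5, 1.0, 2.0, 0.1, 3.0, 0.7])
        assert sparseness(r[list(perm)]) == pytest.approx(sparseness(r), abs=1e-12)


class TestZdiff:
    def test_identical_samples(self):
        assert zdiff([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_arithmetic(self):
        assert zdiff([2.0, 4.0], [1.0, 3.0]) == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 50),
    )
    @settings(deadline=None, max_examples=40)
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(3)
        rp, rm = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        z0 = zdiff(rp, rm)
        z1 = zdiff(scale * rp + shift, scale * rm + shift)
        assert z1 == pytest.approx(z0, rel=1e-9)

    def test_zero_sd_flagged(self):
        with pytest.raises(DegenerateResponseError):
            zdiff([1.0, 1.0], [0.0, 2.0])


class TestZdiffSignificance:
    def test_deterministic_under_seed(self, rng):
        rp, rm = rng.normal(1, 1, 25), rng.normal(0, 1, 25)
        a = zdiff_significance(rp, rm, seed=11)
        b = zdiff_significance(rp, rm, seed=11)
        assert a.significant == b.significant
        assert np.allclose(a.null_scores, b.null_scores)

    def test_strong_separation_always_significant(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            rp = rng.normal(3.0, 1.0, 25)
            rm = rng.normal(0.0, 1.0, 25)
            hits += zdiff_significance(rp, rm, seed=seed).significant
        assert hits >= 50 * 0.99

    def test_significance_iff_above_null_95th(self, rng):
        rp, rm = rng.normal(0.6, 1, 25), rng.normal(0, 1, 25)
        res = zdiff_significance(rp, rm, seed=5)
        assert res.significant == (res.zdiff > res.null_95th)


class TestInterpolation:
    def test_exact_at_tested_frequency(self):
        vals = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        frf = frequency_response_function(matrix(vals))
        assert interpolate_at_frequency(frf, frf.frequencies[1]) == pytest.approx(2.0)

    def test_log2_midpoint_is_arithmetic_mean(self):
        vals = np.array([[1.0, 1.0], [3.0, 3.0]])
        m = matrix(vals, freqs=np.array([1000.0, 4000.0]))
        frf = frequency_response_function(m)
        assert interpolate_at_frequency(frf, 2000.0) == pytest.approx(2.0, abs=1e-12)

    def test_against_dense_grid_oracle(self, rng):
        freqs = 1000.0 * 2.0 ** np.arange(8)
        means = rng.normal(size=8)
        frf = frequency_response_function(
            matrix(np.repeat(means[:, None], 2, axis=1), freqs=freqs)
        )
        target = 3000.0
        # oracle: dense piecewise-linear reconstruction in log2 space
        grid = np.linspace(np.log2(freqs[0]), np.log2(freqs[-1]), 200001)
        dense = np.interp(grid, np.log2(freqs), means)
        oracle = dense[np.argmin(np.abs(grid - np.log2(target)))]
        assert interpolate_at_frequency(frf, target) == pytest.approx(oracle, abs=1e-4)

    def test_out_of_range_rejected(self):
        frf = frequency_response_function(matrix(np.ones((3, 2))))
        with pytest.raises(ValueError):
            interpolate_at_frequency(frf, 100.0)


class TestNormalizeAndPercentChange:
    def test_peak_becomes_one_and_scale_invariance(self, rng):
        vals = np.abs(rng.normal(1, 0.5, size=(6, 4)))
        frf = frequency_response_function(matrix(vals))
        n1 = normalize_frf(frf)
        assert n1.mean_response.max() == pytest.approx(1.0)
        scaled = frequency_response_function(matrix(3.7 * vals))
        n2 = normalize_frf(scaled)
        assert np.allclose(n1.mean_response, n2.mean_response)

    def test_percent_change_zero_for_identical(self):
        frf = frequency_response_function(matrix(np.ones((4, 2))))
        assert np.allclose(frf_percent_change(frf, frf), 0.0)

    def test_percent_change_hand_value(self):
        pre = frequency_response_function(
            matrix(np.array([[0.5, 0.5], [1.0, 1.0]]))
        )
        post = frequency_response_function(
            matrix(np.array([[0.75, 0.75], [1.0, 1.0]]))
        )
        change = frf_percent_change(pre, post)
        assert change[0] == pytest.approx(50.0)

    def test_near_zero_pre_flagged(self):
        pre = frequency_response_function(matrix(np.array([[0.0, 0.0], [1.0, 1.0]])))
        post = frequency_response_function(matrix(np.array([[0.5, 0.5], [1.0, 1.0]])))
        assert np.isnan(frf_percent_change(pre, post)[0])


class TestBfDistance:
    def test_reference_itself(self):
        assert bf_distance_octaves(15000.0) == 0.0

    def test_one_octave(self):
        assert bf_distance_octaves(30000.0) == pytest.approx(1.0)

    def test_cs_separation_is_0p4_octaves(self):
        assert bf_distance_octaves(11400.0) == pytest.approx(0.396, abs=5e-3)


class TestBfBinResampling:
    def test_flat_histogram_and_determinism(self, rng):
        bfs = rng.uniform(5000, 32000, size=300)
        neurons = list(range(300))
        out1 = resample_by_bf_bin(neurons, bfs, n_bins=6, seed=4, freq_range=(4999, 32001))
        out2 = resample_by_bf_bin(neurons, bfs, n_bins=6, seed=4, freq_range=(4999, 32001))
        assert out1 == out2
        edges = np.logspace(np.log2(4999), np.log2(32001), 7, base=2.0)
        counts = np.histogram([bfs[i] for i in out1], bins=edges)[0]
        assert counts.min() == counts.max()

    def test_empty_bin_warns(self, rng):
        bfs = np.concatenate([rng.uniform(5000, 6000, 20), rng.uniform(30000, 32000, 20)])
        with pytest.warns(UserWarning, match="empty"):
            resample_by_bf_bin(list(range(40)), bfs, n_bins=12, seed=0)
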