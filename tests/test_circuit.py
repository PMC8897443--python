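"""Rate-based MGB -> AC -> BLA model."""

from dataclasses import replace

import numpy as np
import pytest

from fearcortex.circuit import (
    CircuitParams,
    CircuitState,
    Stimulus,
    circular_distance,
    delta_update,
    drift_step,
    forward,
    freezing_response,
    model_learning_specificity,
    run_experiment,
    sweep_tuning,
    tuning_ls_correlation_over_time,
    tuning_matrix,
)

P = CircuitParams()


class TestCircularDistance:
    def test_ring_neighbors(self):
        assert circular_distance(1, 10, 10) == 1

    def test_self_distance(self):
        assert circular_distance(4, 4, 10) == 0

    def test_hand_value(self):
        assert circular_distance(3, 8, 10) == 5

    def test_symmetry(self):
        for i in range(1, 11):
            for j in range(1, 11):
                assert circular_distance(i, j, 10) == circular_distance(j, i, 10)


class TestTuningMatrix:
    def test_mgb_diagonal_is_one(self):
        T = tuning_matrix(P.sigma_mgb, 0.0, 1.0)
        assert np.allclose(np.diag(T), 1.0)

    def test_cortex_diagonal_constant(self):
        T = tuning_matrix(3.0, 0.9, 1 / 1.8)
        assert T[0, 0] == pytest.approx(0.1 / 1.8, abs=1e-12)

    def test_full_inhibition_silences_cortex(self):
        T = tuning_matrix(3.0, 1.0, 1 / 1.8)
        assert np.allclose(T, 0.0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            tuning_matrix(0.0)

    def test_circulant_symmetry(self):
        T = tuning_matrix(5.0, 0.3, 1.0)
        assert np.allclose(T, np.roll(np.roll(T, 1, 0), 1, 1))


class TestForward:
    def test_cortex_off_leaves_pure_thalamic_drive(self):
        state = CircuitState.initial(P, 0)
        stim = Stimulus.tone(3)
        x_mgb, x_ctx = forward(P, state, stim, ac_off=True)
        T = tuning_matrix(P.sigma_mgb, 0.0, 1.0)
        assert np.allclose(x_mgb, T @ stim.s)
        assert np.allclose(x_ctx, 0.0)

    def test_narrow_mgb_limit_is_one_hot(self):
        p = replace(P, sigma_mgb=1e-4)
        state = CircuitState.initial(p, 0)
        x_mgb, _ = forward(p, state, Stimulus.tone(4), ac_off=True)
        expect = np.zeros(10)
        expect[3] = 1.0
        assert np.allclose(x_mgb, expect, atol=1e-8)

    def test_broad_cortex_spreads_to_cs_minus(self):
        stim = Stimulus.tone(P.cs_plus_channel)
        narrow = CircuitState.initial(replace(P, sigma_ctx_init=3.0), 0)
        broad = CircuitState.initial(replace(P, sigma_ctx_init=10.0), 0)
        _, xc_narrow = forward(P, narrow, stim)
        _, xc_broad = forward(P, broad, stim)
        k = P.cs_minus_channel - 1
        assert xc_broad[k] > xc_narrow[k]


class TestDeltaUpdate:
    def test_no_shock_no_update(self):
        state = CircuitState.initial(P, 0)
        w0 = state.w_mgb.copy()
        delta_update(P, state, np.ones(10), np.ones(10), shock=0)
        assert np.array_equal(state.w_mgb, w0)

    def test_single_pairing_increment(self):
        state = CircuitState.initial(P, 0)
        delta_update(P, state, np.ones(10), np.zeros(10), shock=1)
        assert np.allclose(state.w_mgb, 0.2)

    def test_ten_pairings_saturate(self):
        state = CircuitState.initial(P, 0)
        for _ in range(10):
            delta_update(P, state, np.ones(10), np.zeros(10), shock=1)
        assert np.allclose(state.w_mgb, 1.0)

    def test_weights_always_bounded(self, rng):
        state = CircuitState.initial(P, 0)
        for _ in range(200):
            x = rng.normal(0, 5, size=10)
            delta_update(P, state, x, x, shock=1)
            assert np.all(state.w_mgb >= 0) and np.all(state.w_mgb <= 1)


class TestFreezingResponse:
    def test_all_weights_one_self_normalizes(self):
        state = CircuitState.initial(P, 0)
        state.w_mgb[:] = 1.0
        state.w_ctx[:] = 1.0
        f = freezing_response(P, state, Stimulus.tone(3))
        assert f == pytest.approx(1.0)

    def test_all_weights_zero(self):
        state = CircuitState.initial(P, 0)
        state.w_mgb[:] = 0.0
        state.w_ctx[:] = 0.0
        assert freezing_response(P, state, Stimulus.tone(3)) == 0.0

    def test_monotone_in_weights(self, rng):
        state = CircuitState.initial(P, 0)
        f0 = freezing_response(P, state, Stimulus.tone(3))
        state.w_mgb[2] += 0.5
        assert freezing_response(P, state, Stimulus.tone(3)) > f0

    def test_untrained_symmetric_weights_give_zero_ls(self):
        state = CircuitState.initial(P, 0)
        assert model_learning_specificity(P, state) == pytest.approx(0.0, abs=1e-12)

    def test_global_weight_scaling_degree_zero(self):
        # freezing is a ratio: scaling numerator and normalizer weights
        # together leaves it unchanged (checked via the all-ones case)
        state = CircuitState.initial(P, 0)
        state.w_mgb[:] = 0.4
        state.w_ctx[:] = 0.4
        f = freezing_response(P, state, Stimulus.tone(3))
        assert f == pytest.approx(0.4)


class TestDrift:
    def test_sigma_stays_within_bounds(self):
        state = CircuitState.initial(replace(P, sigma_ctx_init=20.0), 0)
        for _ in range(1000):
            drift_step(P, state)
            assert 4.0 <= state.sigma_ctx <= 20.0

    def test_interior_steps_unbiased(self):
        state = CircuitState.initial(replace(P, sigma_ctx_init=12.0), 5)
        moves = []
        for _ in range(10000):
            before = state.sigma_ctx
            drift_step(P, state)
            moves.append(state.sigma_ctx - before)
            state.sigma_ctx = 12.0  # stay in the interior
        assert abs(np.mean(moves)) < 0.01

    def test_weights_untouched(self):
        state = CircuitState.initial(P, 0)
        w = state.w_mgb.copy()
        drift_step(P, state)
        assert np.array_equal(state.w_mgb, w)


class TestExperiments:
    def test_narrow_beats_broad_deterministically(self):
        narrow = run_experiment(replace(P, sigma_ctx_init=3.0), "control", seed=0)
        broad = run_experiment(replace(P, sigma_ctx_init=10.0), "control", seed=0)
        assert narrow.ls_at_conditioning > broad.ls_at_conditioning

    def test_unknown_manipulation_rejected(self):
        with pytest.raises(ValueError):
            run_experiment(P, "lesion_everything", seed=0)

    def test_cortex_silent_params_make_ac_off_equal_control(self):
        # with I_ctx >= 1 the cortex is silent and the ac_off manipulations
        # coincide exactly with control
        p = replace(P, inhibition_ctx=1.0)
        ctl = run_experiment(p, "control", seed=3)
        off_cond = run_experiment(p, "ac_off_conditioning", seed=3)
        off_recall = run_experiment(p, "ac_off_recall", seed=3)
        assert ctl.ls_at_conditioning == pytest.approx(off_cond.ls_at_conditioning, abs=1e-12)
        assert ctl.ls_at_conditioning == pytest.approx(off_recall.ls_at_conditioning, abs=1e-12)

    def test_ac_off_conditioning_reduces_specificity(self):
        ctl = run_experiment(P, "control", seed=0)
        off = run_experiment(P, "ac_off_conditioning", seed=0)
        assert off.ls_at_conditioning < ctl.ls_at_conditioning

    def test_freezing_bounded(self):
        for manip in ("control", "reduced_inhibition", "ac_off_conditioning", "ac_off_recall"):
            res = run_experiment(P, manip, seed=1)
            for v in res.freezing.values():
                assert 0.0 <= v <= 1.0

    def test_determinism_under_seed(self):
        a = run_experiment(P, "control", seed=42)
        b = run_experiment(P, "control", seed=42)
        assert a.ls_after_drift == b.ls_after_drift

    def test_linear_exponent_mode_runs(self):
        p = replace(P, exponent="linear")
        res = run_experiment(p, "control", seed=0)
        assert res.ls_at_conditioning > 0


class TestTuningSweep:
    def test_ls_decreases_with_tuning_width(self):
        out = sweep_tuning(P, np.array([3.0, 6.0, 10.0, 15.0]), seed=0, normalize=False)
        ls = out["ls_post_conditioning"]
        assert np.all(np.diff(ls) < 0)

    def test_normalized_sweep_peaks_at_one(self):
        out = sweep_tuning(P, np.array([3.0, 10.0]), seed=0, normalize=True)
        peak = max(out["ls_post_conditioning"].max(), out["ls_post_drift"].max())
        assert peak == pytest.approx(1.0)

    def test_drift_decorrelates_tuning_and_ls(self):
        r0, r1 = tuning_ls_correlation_over_time(P, n_model_mice=12, seed=0)
        assert abs(r0) >= 0.8
        assert abs(r1) < abs(r0)

    def test_zero_drift_keeps_correlation(self):
        p = replace(P, drift_amplitude=0.0, sigma_ctx_bounds=(0.1, 50.0), n_drift_steps=100)
        r0, r1 = tuning_ls_correlation_over_time(p, n_model_mice=10, seed=0)
        assert r0 == pytest.approx(r1, abs=1e-9)
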