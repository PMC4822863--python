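"""STDP window, pair-rule arithmetic, schedules, and homeostatic training."""
import numpy as np
import pytest
from scipy.integrate import quad

from pitchstdp import stimuli
from pitchstdp.network import WeightMatrix
from pitchstdp.plasticity import (
    STDPParams,
    TrainedModel,
    mixed_type_average,
    mixed_type_schedule,
    presentations_for,
    rate_based_delta,
    single_type_schedule,
    stdp_delta,
    stdp_delta_row,
    stdp_window,
    train,
)

P = STDPParams()


class TestWindow:
    def test_potentiation_amplitude_at_zero_plus(self):
        assert stdp_window(1e-9) == pytest.approx(15.0, rel=1e-5)

    def test_depression_value_at_minus_5ms(self):
        assert stdp_window(-5e-3) == pytest.approx(-10.0 * np.exp(-1.0))

    def test_zero_lag_is_zero(self):
        assert stdp_window(0.0) == 0.0

    def test_integral_closed_form_and_numeric(self):
        assert P.window_integral == pytest.approx(-0.035)
        numeric = quad(stdp_window, -0.5, 0.5, points=[0.0], limit=200)[0]
        assert numeric == pytest.approx(-0.035, abs=1e-6)

    def test_wider_extent_toward_depression(self):
        dep = -quad(stdp_window, -0.5, 0.0, limit=200)[0]
        pot = quad(stdp_window, 0.0, 0.5, limit=200)[0]
        assert dep == pytest.approx(0.050, abs=1e-6)
        assert pot == pytest.approx(0.015, abs=1e-6)

    def test_homeostatic_coefficient(self):
        assert P.b_j == pytest.approx(-1.05)

    def test_net_potentiating_window_rejected(self):
        with pytest.raises(ValueError):
            STDPParams(a_p=100.0)


class TestPairRule:
    def test_no_spikes_no_change(self):
        assert stdp_delta(np.empty(0), np.empty(0)) == 0.0

    def test_lone_pre_spike_gives_homeostatic_term(self):
        # one pre spike, silent post: delta = -eta * b_j = +1.05e-7
        assert stdp_delta(np.array([0.1]), np.empty(0)) == pytest.approx(1.05e-7)

    def test_single_causal_pair(self):
        # s = +1 ms: eta * (15 e^-1 - b_j)
        got = stdp_delta(np.array([0.100]), np.array([0.101]))
        assert got == pytest.approx(1e-7 * (15 * np.exp(-1.0) + 1.05), rel=1e-6)

    def test_eta_scale_is_multiplicative(self):
        base = stdp_delta(np.array([0.1]), np.array([0.1012]))
        assert stdp_delta(np.array([0.1]), np.array([0.1012]), eta_scale=100.0) == pytest.approx(
            100.0 * base
        )

    def test_pairs_beyond_cutoff_ignored(self):
        far = stdp_delta(np.array([0.0]), np.array([0.2]))
        assert far == pytest.approx(1.05e-7)  # only the homeostatic term

    def test_row_version_matches_scalar(self):
        rng = np.random.default_rng(7)
        pre = [np.sort(rng.uniform(0, 1, rng.integers(0, 40))) for _ in range(5)]
        post = np.sort(rng.uniform(0, 1, 30))
        row = stdp_delta_row(pre, post, P)
        for j in range(5):
            assert row[j] == pytest.approx(stdp_delta(pre[j], post, P), rel=1e-12)


class TestRateBasedRule:
    def test_fixed_point_at_target_rate(self):
        assert rate_based_delta(30.0, 123.0, alpha=-1e-5) == 0.0

    def test_sign_above_target(self):
        alpha = P.eta * 100.0 * P.window_integral
        assert rate_based_delta(80.0, 100.0, alpha) < 0.0

    def test_silent_presynaptic_is_neutral(self):
        assert rate_based_delta(80.0, 0.0, alpha=-1e-5) == 0.0

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            rate_based_delta(-1.0, 10.0, alpha=-1e-5)


class TestSchedules:
    def test_presentation_count_from_learning_time(self):
        assert presentations_for(P, eta_scale=100.0) == 100
        assert presentations_for(P, eta_scale=1.0) == 10_000

    def test_missing_category_rejected(self):
        sched = single_type_schedule("tone", [110.0, 220.0], 5)
        sched.pools.pop(220.0)
        with pytest.raises(ValueError):
            type(sched)(sched.mode, [110.0, 220.0], sched.pools, 5, 0)

    def test_mixed_schedule_covers_all_categories(self):
        cats = [110.0, 220.0, 440.0]
        sched = mixed_type_schedule(cats, 5, seed=1)
        assert set(sched.pools) == set(cats)
        assert all(len(v) >= 1 for v in sched.pools.values())

    def test_vowel_pool_alternates_both_vowels(self):
        sched = single_type_schedule("vowel", [110.0], 4)
        assert len(sched.pools[110.0]) == 2


class TestTraining:
    def test_initial_rate_high_then_homeostatic(self, trained_110):
        trace = trained_110.trace
        first = trace["output_rate_hz"].iloc[0]
        last = trace["output_rate_hz"].tail(10).mean()
        assert first > 45.0  # high initial regime (learning already bites within it)
        assert abs(last - 30.0) < abs(first - 30.0)

    def test_homeostasis_from_below(self):
        # starting from weak weights (subthreshold drive), the homeostatic
        # term must pull the rate UP toward the target
        p_low = STDPParams(w_0=0.003)
        sched = single_type_schedule("tone", [220.0], n_presentations=60, seed=5)
        res = train(sched, p=p_low, eta_scale=100.0)
        trace = res.trace
        first = trace["output_rate_hz"].iloc[:3].mean()
        last = trace["output_rate_hz"].tail(10).mean()
        assert first < 20.0
        assert last > first
        assert last == pytest.approx(30.0, rel=0.25)

    def test_weights_stay_in_bounds(self, trained_110):
        w = trained_110.model.weights.w
        assert w.min() >= -0.2 - 1e-12 and w.max() <= 0.2 + 1e-12

    def test_trace_and_snapshots(self, trained_110):
        trace = trained_110.trace
        assert len(trace) == 100
        assert {"category_hz", "presentation", "output_rate_hz", "mean_abs_dw", "n_clipped"} <= set(
            trace.columns
        )
        assert set(trained_110.snapshots) == {0.1, 1.0}
        assert np.array_equal(trained_110.snapshots[1.0], trained_110.model.weights.w)

    def test_reproducible_under_seed(self):
        runs = []
        for _ in range(2):
            sched = single_type_schedule("tone", [196.0], n_presentations=5, seed=9)
            runs.append(train(sched, eta_scale=100.0).model.weights.w.copy())
        assert np.array_equal(runs[0], runs[1])

    def test_eta_times_t_invariance(self):
        # halving eta while doubling the presentation count lands in the
        # same homeostatic regime (same final rate ballpark)
        finals = []
        for eta, n in ((200.0, 30), (100.0, 60)):
            sched = single_type_schedule("tone", [147.0], n_presentations=n, seed=13)
            res = train(sched, eta_scale=eta)
            finals.append(res.trace["output_rate_hz"].tail(8).mean())
        assert finals[0] == pytest.approx(finals[1], abs=10.0)

    def test_trained_vector_strength_exceeds_untrained(self, trained_110, tone110):
        from pitchstdp import analysis

        untrained = TrainedModel.untrained([110.0], trained_110.model.cmap)
        vs = {}
        for name, model in (("trained", trained_110.model), ("untrained", untrained)):
            reps = analysis.present_repeated(model, tone110, 6, seed=3)
            vs[name] = analysis.vector_strength(np.concatenate([r[0] for r in reps]), 110.0)
        assert vs["trained"] > vs["untrained"] + 0.2


class TestMixedTypeAverage:
    def _wm(self, val):
        return WeightMatrix(np.full((2, 3), val), [100.0, 200.0], [1.0, 2.0, 3.0])

    def test_identity(self):
        m = self._wm(0.01)
        assert np.array_equal(mixed_type_average([m, m]).w, m.w)

    def test_midpoint(self):
        avg = mixed_type_average([self._wm(0.00), self._wm(0.02)])
        assert np.allclose(avg.w, 0.01)

    def test_shape_mismatch_rejected(self):
        other = WeightMatrix(np.zeros((1, 3)), [100.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            mixed_type_average([self._wm(0.0), other])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mixed_type_average([])
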