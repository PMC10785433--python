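import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meioflow import (
    ClassCounts,
    ExperimentSeries,
    MisclassParams,
    OptimizerConfig,
    SampleRole,
    category_probs,
    fit_experiment,
    log_likelihood,
    proportion_wald_test,
    simulate_series,
    wald_test,
)
from meioflow.errors import ConvergenceError
from oracles import grid_search_s


def _series(counts_rows, roles, ids=None):
    ids = ids or [f"s{i}" for i in range(len(counts_rows))]
    entries = tuple(
        (ClassCounts(ids[i], *map(int, row)), roles[i]) for i, row in enumerate(counts_rows)
    )
    return ExperimentSeries("exp", entries)


ROLES_CPU = [SampleRole.CONTROL_ZERO, SampleRole.PURE_ONE, SampleRole.UNKNOWN]


class TestCategoryProbs:
    def test_endpoints_reproduce_q_and_p(self, example_params):
        np.testing.assert_array_equal(category_probs(example_params, 0.0),
                                      example_params.q_arr)
        np.testing.assert_array_equal(category_probs(example_params, 1.0),
                                      example_params.p_arr)

    def test_hand_evaluated_midpoint(self, example_params):
        np.testing.assert_allclose(
            category_probs(example_params, 0.5), [0.455, 0.475, 0.070], atol=1e-12
        )

    def test_domain_error(self, example_params):
        with pytest.raises(ValueError):
            category_probs(example_params, 1.2)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            MisclassParams(p=(0.9, 0.2, 0.05), q=(0.01, 0.90, 0.09))


class TestLogLikelihood:
    def test_all_zero_counts_is_zero(self, example_params):
        series = _series([(0, 0, 0), (0, 0, 0), (0, 0, 0)], ROLES_CPU)
        assert log_likelihood(series, example_params, [0.5]) == 0.0

    def test_hand_summed_single_sample(self, example_params):
        series = _series([(0, 0, 0), (0, 0, 0), (3, 5, 2)], ROLES_CPU)
        expected = 3 * np.log(0.455) + 5 * np.log(0.475) + 2 * np.log(0.070)
        assert log_likelihood(series, example_params, [0.5]) == pytest.approx(expected, rel=1e-12)

    def test_empty_sample_leaves_value_unchanged(self, example_params):
        base = _series([(10, 80, 10), (90, 5, 5), (3, 5, 2)], ROLES_CPU)
        padded = _series([(10, 80, 10), (90, 5, 5), (3, 5, 2), (0, 0, 0)],
                         ROLES_CPU + [SampleRole.UNKNOWN])
        assert log_likelihood(base, example_params, [0.5]) == log_likelihood(
            padded, example_params, [0.5, 0.3]
        )

    def test_zero_probability_with_positive_count_is_neg_inf(self):
        params = MisclassParams(p=(1.0, 0.0, 0.0), q=(1.0, 0.0, 0.0))
        series = _series([(5, 1, 0), (5, 0, 0), (5, 0, 0)], ROLES_CPU)
        assert log_likelihood(series, params, [0.5]) == -np.inf


class TestFit:
    def test_control_and_pure_only_gives_empirical_proportions(self):
        """With s fixed at 0/1 the likelihood separates into two multinomials
        whose MLEs are the observed proportions."""
        series = _series([(2, 90, 8), (95, 1, 4)],
                         [SampleRole.CONTROL_ZERO, SampleRole.PURE_ONE])
        fit = fit_experiment(series)
        np.testing.assert_allclose(fit.params.q_arr, [0.02, 0.90, 0.08], atol=1e-5)
        np.testing.assert_allclose(fit.params.p_arr, [0.95, 0.01, 0.04], atol=1e-5)
        assert fit.converged
        assert fit.s_hat.size == 0

    def test_matches_grid_search_oracle_small_instance(self, example_params):
        series = simulate_series(example_params, [0.0, 1.0, 0.12], n=400, seed=11)
        fit = fit_experiment(series)
        s_grid = grid_search_s(series.counts, np.array([0.0, 1.0, 0.0]), unknown_index=2)
        assert abs(fit.s_hat[0] - s_grid) <= 1.5e-4

    def test_likelihood_at_optimum_beats_truth(self, example_params):
        for seed in range(5):
            series = simulate_series(example_params, [0.0, 1.0, 0.05], n=2_000, seed=seed)
            fit = fit_experiment(series)
            assert fit.loglik >= log_likelihood(series, example_params, [0.05]) - 1e-6

    def test_simulation_recovery_within_3se(self, example_params):
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            series = simulate_series(example_params, [0.0, 1.0, 0.05], n=10_000, seed=seed)
            fit = fit_experiment(series, OptimizerConfig(n_starts=4, seed=seed))
            if abs(fit.s_hat[0] - 0.05) <= 3 * fit.se_s[0]:
                hits += 1
        assert hits >= n_rep - 1

    def test_se_tracks_sampling_spread(self, example_params):
        """Reported SE approximates the empirical spread of s_hat, and the
        bias shrinks, as per-sample n grows."""
        prev_spread = None
        for n in (1_000, 10_000, 100_000):
            ests, ses = [], []
            for seed in range(40):
                series = simulate_series(example_params, [0.0, 1.0, 0.05], n=n, seed=100 + seed)
                fit = fit_experiment(series, OptimizerConfig(n_starts=2, seed=seed))
                ests.append(fit.s_hat[0])
                ses.append(fit.se_s[0])
            spread = np.std(ests, ddof=1)
            assert np.nanmedian(ses) == pytest.approx(spread, rel=0.6)
            assert abs(np.mean(ests) - 0.05) < 5 * spread / np.sqrt(40) + 1e-4
            if prev_spread is not None:
                assert spread < prev_spread
            prev_spread = spread

    def test_boundary_optimum_flagged(self):
        """A spiked sample indistinguishable from the control pins s at 0."""
        series = _series([(0, 9_800, 200), (9_500, 300, 200), (0, 9_790, 210)], ROLES_CPU)
        fit = fit_experiment(series)
        if fit.boundary[0]:
            assert np.isnan(fit.se_s[0])
            assert fit.s_hat[0] < 1e-6

    def test_requires_control_and_pure(self):
        with pytest.raises(ValueError):
            _series([(1, 1, 1), (1, 1, 1)], [SampleRole.CONTROL_ZERO, SampleRole.UNKNOWN])

    def test_empty_sample_rejected(self):
        series = _series([(0, 0, 0), (9, 0, 1)],
                         [SampleRole.CONTROL_ZERO, SampleRole.PURE_ONE])
        with pytest.raises(ValueError):
            fit_experiment(series)


class TestWald:
    def test_degenerate_zero_estimate(self):
        series = _series([(0, 9_800, 200), (9_500, 300, 200), (0, 9_790, 210)], ROLES_CPU)
        fit = fit_experiment(series)
        if fit.s_hat[0] < 1e-6:
            res = wald_test(fit, 0)
            assert res.statistic == 0.0
            assert res.p_value == pytest.approx(0.5)

    def test_z_of_4_tail_probability(self, example_params):
        """z = 0.02/0.005 = 4 gives one-sided p ~ 3.17e-5."""
        series = simulate_series(example_params, [0.0, 1.0, 0.05], n=5_000, seed=2)
        fit = fit_experiment(series)
        fit.s_hat[0], fit.se_s[0] = 0.02, 0.005
        res = wald_test(fit, 0)
        assert res.statistic == pytest.approx(4.0)
        assert res.p_value == pytest.approx(3.167e-5, rel=1e-3)
        two = wald_test(fit, 0, alternative="two-sided")
        assert two.p_value == pytest.approx(2 * res.p_value)

    def test_proportion_mode_cross_check(self):
        spiked = ClassCounts("sp", 120, 9_000, 880)
        control = ClassCounts("ct", 30, 9_200, 770)
        res = proportion_wald_test(spiked, control)
        f1, f0 = 120 / 10_000, 30 / 10_000
        z = (f1 - f0) / np.sqrt(f1 * (1 - f1) / 10_000 + f0 * (1 - f0) / 10_000)
        assert res.statistic == pytest.approx(z)
        assert 0 < res.p_value < 0.001


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    a=st.tuples(*[st.floats(0.01, 10)] * 3),
    b=st.tuples(*[st.floats(0.01, 10)] * 3),
    s=st.floats(0.0, 1.0),
)
def test_category_probs_stay_on_simplex(a, b, s):
    """Mixture probabilities sum to one and are nonnegative for any valid
    parameter triples and any s in [0, 1]."""
    p = np.array(a) / np.sum(a)
    q = np.array(b) / np.sum(b)
    probs = category_probs(MisclassParams(tuple(p), tuple(q)), s)
    assert np.all(probs >= 0)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(s1=st.floats(0.0, 0.99), ds=st.floats(0.001, 0.5))
def test_rfp_probability_increasing_in_s(s1, ds):
    """When p1 > q1 the RFP category probability strictly increases with s."""
    params = MisclassParams(p=(0.9, 0.05, 0.05), q=(0.01, 0.90, 0.09))
    s2 = min(1.0, s1 + ds)
    assert category_probs(params, s2)[0] > category_probs(params, s1)[0]
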