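"""Cost model, DP threshold synthesis, and the online QD detector."""

import itertools
import math

import numpy as np
import pytest

import seizureqd as sq
from seizureqd.qd_policy import ThresholdPolicy, policy_from_pmfs

from conftest import StoppingOracle, poisson_model


def random_instance(rng):
    alphabet = int(rng.integers(2, 4))
    cost = sq.CostSpec(gamma=float(rng.uniform(0.05, 0.95)),
                       horizon_M=int(rng.integers(3, 7)),
                       rho=float(rng.uniform(0.02, 0.4)))
    return (rng.dirichlet(np.ones(alphabet)), rng.dirichlet(np.ones(alphabet)),
            cost, float(rng.uniform(0.01, 0.5)))


class TestCostPrimitives:
    def test_delay_at_first_stage_is_zero(self):
        assert sq.expected_delay_given_past(1, 0.3) == pytest.approx(0.0)

    def test_delay_hand_sum(self):
        # k=2, rho=0.5: (1*0.5 + 0*0.25) / 0.75
        assert sq.expected_delay_given_past(2, 0.5) == pytest.approx(2 / 3)

    def test_delay_long_horizon_asymptote(self):
        # for k >> 1/rho the change has almost surely happened near the start,
        # so the conditional age approaches k - E[T] = k - 1/rho
        rho = 0.3
        assert sq.expected_delay_given_past(10_000, rho) == \
            pytest.approx(10_000 - 1.0 / rho, rel=1e-9)

    def test_delay_is_increasing_in_stage(self):
        d = [sq.expected_delay_given_past(k, 0.05) for k in range(1, 200)]
        assert np.all(np.diff(d) > 0)

    def test_delay_undefined_for_degenerate_prior(self):
        with pytest.raises(ValueError):
            sq.expected_delay_given_past(5, 0.0)

    @pytest.mark.parametrize("rho,expected", [(0.1, 10.0), (1.0, 1.0),
                                              (0.5, 2.0)])
    def test_expected_time_to_change(self, rho, expected):
        assert sq.expected_time_to_change(rho) == pytest.approx(expected)

    def test_expected_time_to_change_monte_carlo(self):
        rng = np.random.default_rng(0)
        draws = rng.geometric(0.1, size=200_000)
        assert sq.expected_time_to_change(0.1) == \
            pytest.approx(draws.mean(), rel=0.02)

    def test_stage_cost_corners(self):
        cost = sq.CostSpec(gamma=0.5, horizon_M=10, rho=0.1)
        assert sq.stage_cost(0.0, 0, 5, cost) == 0.0
        assert sq.stage_cost(1.0, 1, 5, cost) == 0.0
        assert sq.stage_cost(0.4, 1, 5, cost) == pytest.approx(3.0)

    def test_invalid_cost_spec(self):
        with pytest.raises(ValueError):
            sq.CostSpec(gamma=1.5, horizon_M=10, rho=0.1)
        with pytest.raises(ValueError):
            sq.CostSpec(gamma=0.5, horizon_M=1, rho=0.1)
        with pytest.raises(ValueError):
            sq.CostSpec(gamma=0.5, horizon_M=10, rho=0.0)


class TestMarginalEmissions:
    def test_pmfs_normalize(self, corpus_bundle):
        q0, q1 = sq.marginal_emission_pmfs(
            corpus_bundle.model, corpus_bundle.training_codes)
        assert q0.sum() == pytest.approx(1.0, abs=1e-12)
        assert q1.sum() == pytest.approx(1.0, abs=1e-12)
        # ictal pmf concentrates on larger codes
        support = np.arange(len(q0))
        assert q1 @ support > q0 @ support

    def test_history_free_model_is_exact_poisson(self):
        model = poisson_model(2.0, 5.0, n_codes=40)
        q0, _ = sq.marginal_emission_pmfs(model)
        from scipy.stats import poisson
        np.testing.assert_allclose(q0[:-1], poisson.pmf(np.arange(39), 2.0),
                                   atol=1e-12)


class TestBackwardInduction:
    def test_exact_backend_matches_enumeration(self):
        rng = np.random.default_rng(2024)
        for _ in range(5):
            q0, q1, cost, pi0 = random_instance(rng)
            oracle = StoppingOracle(q0, q1, cost.rho, cost)
            policy = policy_from_pmfs(q0, q1, cost, method="exact",
                                      pi_start=pi0)
            assert policy.j0 == pytest.approx(oracle.value(0, pi0),
                                              abs=1e-9)

    def test_grid_backend_tracks_exact_backend(self):
        rng = np.random.default_rng(7)
        q0, q1, cost, pi0 = random_instance(rng)
        exact = policy_from_pmfs(q0, q1, cost, method="exact", pi_start=pi0)
        grid = policy_from_pmfs(q0, q1, cost, method="grid", pi_start=pi0,
                                pi_grid_size=2001)
        assert grid.j0 == pytest.approx(exact.j0, abs=1e-4)
        np.testing.assert_allclose(grid.F[1:], exact.F[1:], atol=2e-3)

    def test_gamma_one_thresholds_at_grid_minimum(self):
        q0 = np.array([0.5, 0.3, 0.2])
        q1 = np.array([0.2, 0.3, 0.5])
        cost = sq.CostSpec(gamma=1.0, horizon_M=8, rho=0.1)
        for method in ("grid", "exact"):
            policy = policy_from_pmfs(q0, q1, cost, method=method)
            np.testing.assert_allclose(policy.F[1:], 0.0, atol=1e-12)

    def test_gamma_zero_thresholds_at_one(self):
        q0 = np.array([0.5, 0.3, 0.2])
        q1 = np.array([0.2, 0.3, 0.5])
        cost = sq.CostSpec(gamma=0.0, horizon_M=8, rho=0.1)
        for method in ("grid", "exact"):
            policy = policy_from_pmfs(q0, q1, cost, method=method)
            assert np.all(policy.F[1:] >= 1.0 - 1e-12)

    def test_value_function_sandwich(self):
        rng = np.random.default_rng(11)
        q0, q1, cost, _ = random_instance(rng)
        policy = policy_from_pmfs(q0, q1, cost, method="grid",
                                  keep_values=True)
        grid = policy.pi_grid
        stop = (1 - cost.gamma) / cost.rho * (1 - grid)
        values = policy.value_table
        assert np.all(values >= -1e-12)
        for k in range(1, cost.horizon_M):
            assert np.all(values[k] <= stop + 1e-9)

    def test_threshold_decreases_toward_horizon(self, corpus_bundle):
        policy = sq.synthesize_policy(
            corpus_bundle.model, corpus_bundle.default_cost(),
            training_codes=corpus_bundle.training_codes)
        f = policy.F[1:]
        assert f[-1] < f[0]                       # overall decline
        assert np.any(np.diff(f) > 0) or np.all(np.diff(f) <= 0)

    def test_policy_json_round_trip(self):
        q0 = np.array([0.6, 0.4])
        q1 = np.array([0.3, 0.7])
        cost = sq.CostSpec(gamma=0.4, horizon_M=6, rho=0.2)
        policy = policy_from_pmfs(q0, q1, cost, method="exact")
        back = ThresholdPolicy.from_json(policy.to_json())
        np.testing.assert_allclose(back.F, policy.F)
        assert back.cost == policy.cost
        assert back.j0 == pytest.approx(policy.j0)


class TestRunQd:
    def test_unreachable_threshold_never_fires(self, corpus_bundle):
        cost = corpus_bundle.default_cost()
        policy = ThresholdPolicy(F=np.ones(cost.horizon_M), cost=cost)
        events, _ = sq.run_qd(corpus_bundle.model, policy,
                              corpus_bundle.obs_runs[0])
        assert events == []

    def test_gamma_one_fires_at_stage_one(self, corpus_bundle):
        policy = sq.synthesize_policy(
            corpus_bundle.model, corpus_bundle.default_cost(gamma=1.0),
            training_codes=corpus_bundle.training_codes)
        events, _ = sq.run_qd(corpus_bundle.model, policy,
                              corpus_bundle.obs_runs[0][:200],
                              refractory_s=1e9)
        assert events and events[0].stage == 1

    def test_detection_never_precedes_minimum_threshold_crossing(
            self, corpus_bundle):
        policy = sq.synthesize_policy(
            corpus_bundle.model, corpus_bundle.default_cost(),
            training_codes=corpus_bundle.training_codes)
        events, traj = sq.run_qd(corpus_bundle.model, policy,
                                 corpus_bundle.obs_runs[0])
        f_min = policy.F[1:].min()
        first_possible = np.flatnonzero(traj.pi > f_min)
        for e in events:
            assert e.stage >= first_possible[0]

    def test_detection_restarts_filter_and_clock(self, corpus_bundle):
        policy = sq.synthesize_policy(
            corpus_bundle.model, corpus_bundle.default_cost(),
            training_codes=corpus_bundle.training_codes)
        events, traj = sq.run_qd(corpus_bundle.model, policy,
                                 corpus_bundle.obs_runs[0])
        assert len(events) >= 1
        assert traj.restart_indices == [e.stage + 1 for e in events
                                        if e.stage + 1 < len(traj.pi)]

    def test_refractory_suppresses_immediate_redetection(self):
        model = poisson_model(1.0, 8.0, rho=0.05, n_codes=30, p0=0.95)
        cost = sq.CostSpec(gamma=0.9, horizon_M=50, rho=model.rho)
        policy = sq.synthesize_policy(model, cost)
        z = np.full(40, 8.0)   # persistently ictal-looking
        few, _ = sq.run_qd(model, policy, z, refractory_s=100.0)
        many, _ = sq.run_qd(model, policy, z, refractory_s=0.0)
        assert len(few) == 1
        assert len(many) > len(few)

    def test_horizon_too_small_rejected(self, corpus_bundle):
        cost = corpus_bundle.default_cost()
        policy = ThresholdPolicy(F=np.ones(1), cost=cost)
        with pytest.raises(ValueError):
            sq.run_qd(corpus_bundle.model, policy, corpus_bundle.obs_runs[0])


class TestStoppingBehavior:
    def test_induced_stopping_matches_oracle_on_all_sequences(self):
        rng = np.random.default_rng(31)
        for _ in range(3):
            q0, q1, cost, pi0 = random_instance(rng)
            oracle = StoppingOracle(q0, q1, cost.rho, cost)
            policy = policy_from_pmfs(q0, q1, cost, method="exact",
                                      pi_start=pi0)
            alphabet = range(len(q0))
            for seq in itertools.product(alphabet,
                                         repeat=cost.horizon_M - 1):
                pi = pi0
                mine = None
                for k, symbol in enumerate(seq, start=1):
                    pi, _ = oracle.step(pi, symbol)
                    if pi > policy.F[k]:
                        mine = k
                        break
                assert mine == oracle.stop_stage(pi0, seq)
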