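"""Inference engine: policy prediction, KL values, precision fixed points."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from limitedoffer import (
    AgentParams,
    BeliefState,
    Policy,
    State,
    TaskConfig,
    action_probability,
    build_desired_outcome,
    build_hazard_schedule,
    build_transitions,
    policy_posterior,
    policy_set,
    policy_value,
    precision_update,
    predict_terminal,
    variational_fixed_point,
)

from conftest import enumerate_terminal, fixed_point_oracle, kl_oracle


class TestPolicySet:
    def test_size_and_uniqueness(self):
        pols = policy_set(trial=3, horizon=8)
        assert len(pols) == 8 - 3 + 2
        assert len({p.accept_trial for p in pols}) == len(pols)

    def test_out_of_range_trial(self):
        with pytest.raises(ValueError):
            policy_set(trial=0, horizon=8)
        with pytest.raises(ValueError):
            policy_set(trial=9, horizon=8)


class TestPredictTerminal:
    def test_matches_exhaustive_enumeration(self, tiny_config):
        sched = build_hazard_schedule(tiny_config)
        P = build_transitions(sched)
        for start in range(1, tiny_config.horizon + 1):
            belief = BeliefState.point_mass(State.LOW_PENDING, start)
            for pol in policy_set(start, tiny_config.horizon):
                expected = enumerate_terminal(
                    sched.withdrawal,
                    sched.high_offer,
                    tiny_config.horizon,
                    pol.accept_trial,
                    start_trial=start,
                )
                np.testing.assert_allclose(
                    predict_terminal(belief, pol, P), expected, atol=1e-12
                )

    def test_absorbing_state_is_fixed(self, tiny_config):
        P = build_transitions(build_hazard_schedule(tiny_config))
        for s in (State.HIGH_OBTAINED, State.WITHDRAWN, State.ACCEPTED_LOW):
            belief = BeliefState.point_mass(s, 1)
            for pol in policy_set(1, tiny_config.horizon):
                out = predict_terminal(belief, pol, P)
                assert out[s] == pytest.approx(1.0)

    def test_accept_now_is_certain(self, tiny_config):
        P = build_transitions(build_hazard_schedule(tiny_config))
        belief = BeliefState.point_mass(State.LOW_PENDING, 2)
        out = predict_terminal(belief, Policy(2), P)
        np.testing.assert_allclose(out, [0, 0, 0, 1], atol=1e-15)

    def test_stale_policy_rejected(self, tiny_config):
        P = build_transitions(build_hazard_schedule(tiny_config))
        belief = BeliefState.point_mass(State.LOW_PENDING, 3)
        with pytest.raises(ValueError):
            predict_terminal(belief, Policy(2), P)


class TestPolicyValue:
    def test_zero_iff_terminal_equals_goal(self, default_config):
        d = build_desired_outcome(default_config, 2.0)
        assert policy_value(d.probs.copy(), d) == pytest.approx(0.0, abs=1e-14)

    def test_point_mass_on_withdrawn(self):
        cfg = TaskConfig(low_offer=35, high_offer=80)
        d = build_desired_outcome(cfg, 2.0)
        terminal = np.array([0.0, 0.0, 1.0, 0.0])
        assert policy_value(terminal, d) == pytest.approx(
            np.log(d.probs[State.WITHDRAWN])
        )

    def test_accept_value_constant_without_hazards(self):
        # with (near-)zero event probabilities every accept time is equivalent
        cfg = TaskConfig(
            base_withdrawal_hazard=1e-12, base_offer_prob=1e-12
        )
        view = AgentParams(8.0, 1.0, 4.0).view(cfg)
        _, Q = view.policy_values(1)
        accept_vals = Q[:-1]  # last entry is never-accept
        np.testing.assert_allclose(accept_vals, accept_vals[0], atol=1e-9)

    def test_matches_kl_oracle_and_nonpositive(self, tiny_config):
        view = AgentParams(8.0, 1.3, 5.0).view(tiny_config)
        pols, Q = view.policy_values(1)
        sched = view.schedule
        for pol, q in zip(pols, Q):
            terminal = enumerate_terminal(
                sched.withdrawal, sched.high_offer, tiny_config.horizon, pol.accept_trial
            )
            assert q == pytest.approx(-kl_oracle(terminal, view.desired.probs), abs=1e-10)
            assert q <= 0


class TestPolicyPosterior:
    def test_direct_evaluation(self):
        post = policy_posterior(np.array([-0.1, -0.5]), 4.0)
        raw = np.array([np.exp(-0.4), np.exp(-2.0)])
        np.testing.assert_allclose(post, raw / raw.sum(), atol=1e-12)

    def test_zero_precision_limit_is_uniform(self):
        post = policy_posterior(np.array([-0.1, -2.0, -5.0]), 0.0)
        np.testing.assert_allclose(post, 1 / 3)

    def test_infinite_precision_argmax_with_ties(self):
        post = policy_posterior(np.array([-0.5, -0.1, -0.1]), np.inf)
        np.testing.assert_allclose(post, [0.0, 0.5, 0.5])


class TestPrecisionUpdate:
    @pytest.mark.parametrize("alpha", [4.0, 8.0, 16.0])
    def test_zero_cost_recovers_prior(self, alpha):
        Q = np.zeros(3)
        belief = precision_update(Q, np.ones(3) / 3, alpha, 1.0)
        assert belief.expected_precision == pytest.approx(alpha)

    def test_worked_example(self):
        # alpha=8, b0=1, posterior-weighted Q = -1  ->  gamma = 8/2
        Q = np.array([-1.0, -1.0])
        belief = precision_update(Q, np.array([0.5, 0.5]), 8.0, 1.0)
        assert belief.shape == pytest.approx(8.0)
        assert belief.rate == pytest.approx(2.0)
        assert belief.expected_precision == pytest.approx(4.0)

    @given(cost=st.floats(0.01, 20.0), extra=st.floats(0.01, 20.0))
    def test_monotone_in_expected_cost(self, cost, extra):
        post = np.array([1.0])
        g1 = precision_update(np.array([-cost]), post, 8.0).expected_precision
        g2 = precision_update(np.array([-cost - extra]), post, 8.0).expected_precision
        assert g2 < g1 <= 8.0


class TestVariationalFixedPoint:
    def test_single_policy_closed_form(self):
        vs = variational_fixed_point(np.array([-0.7]), prior_precision=8.0, prior_rate=1.0)
        assert vs.converged
        np.testing.assert_allclose(vs.posterior, [1.0])
        assert vs.precision.expected_precision == pytest.approx(8.0 / 1.7, abs=1e-6)

    @pytest.mark.parametrize(
        "Q,alpha",
        [
            ([-0.1, -2.0], 8.0),
            ([-0.5, -0.4, -1.5], 4.0),
            ([-1.0, -0.2, -0.05, -3.0, -0.6], 16.0),
        ],
    )
    def test_matches_scalar_root_oracle(self, Q, alpha):
        vs = variational_fixed_point(
            np.array(Q), prior_precision=alpha, tol=1e-12, max_iter=500
        )
        gamma_star = fixed_point_oracle(Q, alpha)
        assert vs.converged
        assert vs.precision.expected_precision == pytest.approx(gamma_star, abs=1e-8)

    def test_self_consistency_at_convergence(self):
        Q = np.array([-0.3, -1.2, -0.05])
        vs = variational_fixed_point(Q, prior_precision=8.0, tol=1e-10, max_iter=500)
        gamma = vs.precision.expected_precision
        np.testing.assert_allclose(
            vs.posterior, policy_posterior(Q, gamma), atol=1e-8
        )
        again = precision_update(Q, vs.posterior, 8.0, 1.0)
        assert again.expected_precision == pytest.approx(gamma, abs=1e-8)

    def test_permutation_invariance(self):
        Q = np.array([-0.1, -0.9, -0.4, -2.5])
        perm = [2, 0, 3, 1]
        a = variational_fixed_point(Q, prior_precision=8.0, tol=1e-10, max_iter=500)
        b = variational_fixed_point(Q[perm], prior_precision=8.0, tol=1e-10, max_iter=500)
        assert a.precision.expected_precision == pytest.approx(
            b.precision.expected_precision, abs=1e-8
        )
        np.testing.assert_allclose(a.posterior[perm], b.posterior, atol=1e-8)

    @given(alpha=st.floats(0.5, 32.0))
    def test_precision_never_exceeds_prior(self, alpha):
        Q = np.array([-0.2, -1.5, -0.7])
        vs = variational_fixed_point(Q, prior_precision=alpha, max_iter=500)
        assert vs.precision.expected_precision <= alpha + 1e-9

    def test_nonconvergence_flagged(self):
        with pytest.warns(RuntimeWarning, match="did not converge"):
            vs = variational_fixed_point(
                np.array([-0.1, -2.0]), prior_precision=8.0, tol=1e-12, max_iter=1
            )
        assert not vs.converged


class TestActionProbability:
    def test_masses_sum_to_one(self, default_config):
        view = AgentParams(8.0).view(default_config)
        for t in (1, 4, 8):
            vs = view.evaluate(t)
            p_acc, p_wait = action_probability(vs, t)
            assert p_acc + p_wait == pytest.approx(1.0)

    def test_uniform_posterior_gives_one_over_k(self):
        # with zero sensitivity AND vanishing hazards every policy predicts
        # a point-mass terminal at the same KL from the uniform goal, so the
        # posterior is uniform; note that under nonzero hazards a uniform
        # goal still discriminates policies via outcome entropy
        cfg = TaskConfig(base_withdrawal_hazard=1e-12, base_offer_prob=1e-12)
        view = AgentParams(8.0, 1.0, 0.0).view(cfg)
        for t in (1, 5, 8):
            k = len(policy_set(t, 8))
            assert view.accept_probability(t) == pytest.approx(1 / k, abs=1e-6)

    def test_last_trial_acceptance_dominates(self, default_config):
        # at trial T only accept-now and never-accept remain; the low offer
        # beats a near-certain zero payoff, so acceptance dominates
        view = AgentParams(16.0).view(default_config)
        assert view.accept_probability(default_config.horizon) > 0.9


class TestPrecisionDynamics:
    @pytest.mark.parametrize("alpha", [4.0, 8.0, 16.0])
    def test_high_offer_raises_precision(self, default_config, alpha):
        view = AgentParams(alpha).view(default_config)
        before = view.expected_precision(5, State.LOW_PENDING)
        after = view.expected_precision(6, State.HIGH_OBTAINED)
        assert after > before

    def test_withdrawal_drop_grows_with_prior_precision(self, default_config):
        drops = []
        for alpha in (4.0, 8.0, 16.0):
            view = AgentParams(alpha).view(default_config)
            before = view.expected_precision(3, State.LOW_PENDING)
            after = view.expected_precision(4, State.WITHDRAWN)
            assert after < before
            drops.append(before - after)
        assert drops[0] < drops[1] < drops[2]
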