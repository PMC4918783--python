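"""Belief updating, expected-free-energy components and action sampling.

Oracles used here are written independently of the implementation paths:
Bayes updates are checked against an explicit enumeration of the joint
(previous state, next state, outcome) table, and epistemic value against
the literal expected-KL definition.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epistemaze import (
    BeliefState,
    ZeroLikelihoodError,
    bayes_update,
    belief_from_context,
    build_task,
    epistemic_value,
    evaluate_policy_set,
    extrinsic_value,
    free_energy,
    normalize_preferences,
    outcome_prediction,
    policy_posterior,
    policy_quality,
    propagate_belief,
    select_action,
)
from epistemaze.core_model import Policy

from conftest import make_random_model, random_belief


def brute_force_posterior(belief, action, observation, model):
    """Oracle: enumerate the joint over (s, s', o) and condition on o."""
    n = model.n_states
    joint = np.zeros((n, n))  # (s, s') given the observation
    for s in range(n):
        for s2 in range(n):
            joint[s, s2] = (
                belief[s] * model.B[action][s2, s] * model.A[observation, s2]
            )
    marginal = joint.sum()
    return joint.sum(axis=0) / marginal


def kl(p, q):
    p = np.clip(p, 1e-300, None)
    q = np.clip(q, 1e-300, None)
    return float((p * (np.log(p) - np.log(q))).sum())


class TestBayesUpdate:
    def test_identity_likelihood_collapses_to_observed_state(self):
        rng = np.random.default_rng(0)
        model = make_random_model(4, 4, 1, rng, identity_likelihood=True)
        # stay-in-place dynamics so the observation pins the state exactly
        model.trans.per_control[0][:] = np.eye(4)
        belief = BeliefState(np.full(4, 0.25), 4, 1)
        post = bayes_update(belief, 0, 2, model)
        assert np.allclose(post.state_belief, np.eye(4)[2])

    def test_reward_cue_updates_context_by_hand_bayes(self, sim1):
        # 50/50 context, move left, observe (left, red) with 75/25
        # reliabilities: posterior = 0.5*0.75 / (0.5*0.75 + 0.5*0.25) = 0.75
        task, model, _ = sim1
        belief = belief_from_context(np.array([0.5, 0.5]), 0, task.n_locations)
        red_left = model.obs.outcome_index(location=1, cue=0)
        post = bayes_update(belief, 1, red_left, model)
        assert np.allclose(post.context_marginal, [0.75, 0.25], atol=1e-12)

    def test_uninformative_likelihood_keeps_predicted_belief(self):
        rng = np.random.default_rng(1)
        model = make_random_model(5, 3, 2, rng)
        A = np.tile(model.A[:, :1], (1, 5))  # all columns equal
        model.obs.likelihood[:] = A
        q = random_belief(5, rng)
        belief = BeliefState(q, 5, 1)
        predicted = model.B[1] @ q
        post = bayes_update(belief, 1, 0, model)
        assert np.allclose(post.state_belief, predicted, atol=1e-12)

    def test_impossible_observation_raises(self, sim1):
        task, model, _ = sim1
        belief = belief_from_context(np.array([1.0, 0.0]), 0, task.n_locations)
        # move left but claim to observe a cue at the right arm
        red_right = model.obs.outcome_index(location=2, cue=0)
        with pytest.raises(ZeroLikelihoodError, match="impossible"):
            bayes_update(belief, 1, red_right, model)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("n_states", [2, 7, 23, 50])
    def test_matches_joint_enumeration_oracle(self, seed, n_states):
        rng = np.random.default_rng(seed)
        model = make_random_model(n_states, n_states + 3, 2, rng)
        q = random_belief(n_states, rng)
        belief = BeliefState(q, n_states, 1)
        action = int(rng.integers(2))
        obs = int(rng.integers(n_states + 3))
        post = bayes_update(belief, action, obs, model)
        oracle = brute_force_posterior(q, action, obs, model)
        assert np.allclose(post.state_belief, oracle, atol=1e-10)


class TestPropagation:
    def test_tau_zero_is_identity(self, sim1):
        task, model, policies = sim1
        belief = belief_from_context(np.array([0.4, 0.6]), 0, task.n_locations)
        out = propagate_belief(belief, policies[0], 0, model)
        assert np.allclose(out, belief.state_belief)

    def test_deterministic_move_preserves_context(self, sim1):
        task, model, _ = sim1
        policy = Policy((1, 1, 1), (False, False, False))
        belief = belief_from_context(np.array([0.3, 0.7]), 0, task.n_locations)
        out = propagate_belief(belief, policy, 1, model)
        reshaped = out.reshape(task.n_contexts, task.n_locations)
        assert np.allclose(reshaped[:, 1], [0.3, 0.7])  # mass at left arm
        assert np.allclose(reshaped[:, [0, 2, 3, 4]], 0.0)

    def test_absorbing_state_is_idempotent(self, sim1):
        task, model, _ = sim1
        policy = Policy((1, 1, 1), (False, False, False))
        belief = belief_from_context(np.array([0.5, 0.5]), 0, task.n_locations)
        one = propagate_belief(belief, policy, 1, model)
        two = propagate_belief(belief, policy, 2, model)
        assert np.allclose(one, two)

    def test_tau_out_of_range(self, sim1):
        task, model, policies = sim1
        belief = belief_from_context(np.array([0.5, 0.5]), 0, task.n_locations)
        with pytest.raises(ValueError):
            propagate_belief(belief, policies[0], 4, model)


class TestOutcomePrediction:
    def test_reward_reliability_shows_in_prediction(self, sim1):
        task, model, _ = sim1
        q = np.zeros(model.n_states)
        q[1] = 1.0  # left arm, context reward-left
        p = outcome_prediction(q, model.obs)
        red_left = model.obs.outcome_index(1, 0)
        white_left = model.obs.outcome_index(1, 1)
        assert math.isclose(p[red_left], 0.75)
        assert math.isclose(p[white_left], 0.25)
        assert math.isclose(p.sum(), 1.0, abs_tol=1e-12)

    def test_normalization_on_random_inputs(self):
        rng = np.random.default_rng(3)
        model = make_random_model(8, 5, 1, rng)
        for _ in range(10):
            p = outcome_prediction(random_belief(8, rng), model.obs)
            assert math.isclose(p.sum(), 1.0, abs_tol=1e-12)


class TestValues:
    def test_extrinsic_point_mass_and_uniform(self):
        prefs = normalize_preferences([1.0, 0.0, -1.0])
        assert math.isclose(
            extrinsic_value(np.array([0.0, 1.0, 0.0]), prefs),
            prefs.log_preferences[1],
        )
        assert math.isclose(
            extrinsic_value(np.full(3, 1 / 3), prefs),
            prefs.log_preferences.mean(),
        )

    def test_extrinsic_closed_form_two_outcomes(self):
        prefs = normalize_preferences([2.0, -2.0])
        dist = np.array([0.75, 0.25])
        expected = 0.75 * (-math.log1p(math.exp(-4))) + 0.25 * (
            -4 - math.log1p(math.exp(-4))
        )
        assert math.isclose(extrinsic_value(dist, prefs), expected, abs_tol=1e-12)

    def test_extrinsic_never_positive(self):
        rng = np.random.default_rng(4)
        prefs = normalize_preferences(rng.normal(size=6))
        for _ in range(20):
            assert extrinsic_value(random_belief(6, rng), prefs) <= 0.0

    def test_epistemic_zero_for_point_mass(self, sim1):
        _, model, _ = sim1
        q = np.zeros(model.n_states)
        q[3] = 1.0
        assert epistemic_value(q, model.obs) == 0.0

    def test_epistemic_zero_for_uninformative_likelihood(self):
        rng = np.random.default_rng(5)
        model = make_random_model(6, 4, 1, rng)
        model.obs.likelihood[:] = np.tile(model.A[:, :1], (1, 6))
        assert epistemic_value(random_belief(6, rng), model.obs) == 0.0

    def test_epistemic_identity_likelihood_equals_entropy(self):
        rng = np.random.default_rng(6)
        model = make_random_model(2, 2, 1, rng, identity_likelihood=True)
        assert math.isclose(
            epistemic_value(np.array([0.5, 0.5]), model.obs), math.log(2)
        )

    def test_epistemic_matches_expected_kl_definition(self):
        # oracle: E_{Q(o)}[ KL(Q(s|o) || Q(s)) ] by explicit enumeration
        rng = np.random.default_rng(7)
        model = make_random_model(9, 6, 1, rng)
        q = random_belief(9, rng)
        qo = model.A @ q
        expected = 0.0
        for o in range(6):
            post = model.A[o] * q / qo[o]
            expected += qo[o] * kl(post, q)
        assert math.isclose(epistemic_value(q, model.obs), expected, abs_tol=1e-10)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_epistemic_nonnegative_and_relabel_invariant(self, seed):
        rng = np.random.default_rng(seed)
        model = make_random_model(7, 5, 1, rng)
        q = random_belief(7, rng)
        value = epistemic_value(q, model.obs)
        assert value >= 0.0
        perm_s = rng.permutation(7)
        perm_o = rng.permutation(5)
        shuffled = make_random_model(7, 5, 1, rng)
        shuffled.obs.likelihood[:] = model.A[np.ix_(perm_o, perm_s)]
        assert math.isclose(
            epistemic_value(q[perm_s], shuffled.obs), value, abs_tol=1e-10
        )


class TestPolicyQuality:
    def test_components_sum_to_quality(self, sim1):
        task, model, policies = sim1
        belief = belief_from_context(np.array([0.6, 0.4]), 0, task.n_locations)
        ev = policy_quality(belief, policies[5], model)
        assert np.allclose(
            ev.per_tau_quality,
            ev.extrinsic_component + ev.epistemic_component,
            atol=1e-10,
        )
        assert math.isclose(ev.total_quality, ev.per_tau_quality.sum(), abs_tol=1e-10)
        assert np.all(ev.epistemic_component >= 0.0)

    def test_certain_context_prefers_direct_policy_to_reward(self, sim1):
        task, model, policies = sim1
        belief = belief_from_context(np.array([1.0, 0.0]), 0, task.n_locations)
        totals = [policy_quality(belief, p, model).total_quality for p in policies]
        best = policies[int(np.argmax(totals))]
        assert best.controls == (1, 1, 1)  # straight to the baited left arm
        assert best.n_sweeps == 0

    def test_point_mass_belief_has_zero_epistemic_everywhere(self, sim1):
        task, model, policies = sim1
        belief = belief_from_context(np.array([0.0, 1.0]), 0, task.n_locations)
        for p in policies:
            ev = policy_quality(belief, p, model)
            assert np.allclose(ev.epistemic_component, 0.0, atol=1e-12)

    def test_vectorized_evaluation_matches_scalar(self, sim3):
        task, model, policies = sim3
        rng = np.random.default_rng(8)
        prior = random_belief(task.n_contexts, rng)
        belief = belief_from_context(prior, 0, task.n_locations)
        for start in range(task.horizon):
            ext, epi, totals = evaluate_policy_set(belief, policies, model, start)
            for i, p in enumerate(policies):
                ev = policy_quality(belief, p, model, start=start)
                assert np.allclose(ext[i], ev.extrinsic_component, atol=1e-10)
                assert np.allclose(epi[i], ev.epistemic_component, atol=1e-10)
                assert math.isclose(totals[i], ev.total_quality, abs_tol=1e-10)

    def test_kl_limit_with_identity_likelihood(self):
        # observed states: Q_tau reduces to -KL(Q(o)||P(o)) exactly
        rng = np.random.default_rng(9)
        for trial in range(100):
            n = int(rng.integers(2, 8))
            model = make_random_model(n, n, 2, rng, identity_likelihood=True)
            q = random_belief(n, rng)
            belief = BeliefState(q, n, 1)
            policy = Policy((0, 1), (False, False))
            ev = policy_quality(belief, policy, model)
            for tau in (1, 2):
                qs = propagate_belief(belief, policy, tau, model)
                qo = model.A @ qs
                expected = -kl(qo, np.exp(model.C))
                assert math.isclose(
                    ev.per_tau_quality[tau - 1], expected, abs_tol=1e-10
                )

    def test_utility_scaling_touches_only_extrinsic(self, default_params):
        # expected free energy is a linear mixture: rescaling utility
        # differences leaves every epistemic component unchanged
        from epistemaze import AgentParams

        strong = AgentParams(reward_utility=4.0, loss_utility=-4.0,
                             imaginary_cost=-0.5)
        t1, m1, p1 = build_task("sim1", default_params)
        t2, m2, p2 = build_task("sim1", strong)
        belief = belief_from_context(np.array([0.5, 0.5]), 0, t1.n_locations)
        ext1, epi1, _ = evaluate_policy_set(belief, p1, m1)
        ext2, epi2, _ = evaluate_policy_set(belief, p2, m2)
        assert np.allclose(epi1, epi2, atol=1e-10)
        assert not np.allclose(ext1, ext2)


class TestPolicyPosterior:
    def test_zero_gamma_is_uniform(self):
        post = policy_posterior(np.array([3.0, -1.0, 0.5]), 0.0)
        assert np.allclose(post, 1 / 3)

    def test_unit_gap_closed_form(self):
        post = policy_posterior(np.array([1.0, 0.0]), 1.0)
        e = math.e
        assert np.allclose(post, [e / (1 + e), 1 / (1 + e)], atol=1e-12)

    def test_large_gamma_concentrates_on_argmax(self):
        post = policy_posterior(np.array([0.3, 0.31, 0.1]), 1e4)
        assert post[1] > 0.999

    def test_normalized_and_monotone(self):
        rng = np.random.default_rng(10)
        q = rng.normal(size=12)
        post = policy_posterior(q, 2.5)
        assert math.isclose(post.sum(), 1.0, abs_tol=1e-12)
        order = np.argsort(q)
        assert np.all(np.diff(post[order]) >= -1e-15)

    def test_nonfinite_quality_rejected(self):
        with pytest.raises(ValueError):
            policy_posterior(np.array([np.nan, 1.0]), 1.0)


class TestSelectAction:
    def test_point_mass_posterior_returns_its_control(self, sim1):
        _, _, policies = sim1
        post = np.zeros(len(policies))
        post[3] = 1.0
        rng = np.random.default_rng(0)
        action = select_action(post, policies, 0, set(range(5)), rng)
        assert action == policies[3].controls[0]

    def test_agreeing_policies_yield_common_control(self, sim1):
        _, _, policies = sim1
        # policies 0 and 1 are the two direct policies: (1,1,1) and (2,2,2)
        idx = [i for i, p in enumerate(policies) if p.controls == (1, 1, 1)]
        jdx = [i for i, p in enumerate(policies) if p.controls[0] == 1 and p.n_sweeps == 0]
        assert idx == jdx
        post = np.zeros(len(policies))
        post[idx[0]] = 0.5
        # give the other half to a sweep policy sharing step-2 control
        other = next(i for i, p in enumerate(policies) if p.controls[1:] == (1, 1))
        post[other] = 0.5
        rng = np.random.default_rng(1)
        action = select_action(post, policies, 1, set(range(5)), rng)
        assert action == 1

    def test_absorbing_arm_forces_matching_control(self, sim1):
        _, _, policies = sim1
        post = np.full(len(policies), 1.0 / len(policies))
        rng = np.random.default_rng(2)
        for _ in range(10):
            assert select_action(post, policies, 2, {2}, rng) == 2

    def test_no_feasible_mass_raises(self, sim1):
        _, _, policies = sim1
        post = np.zeros(len(policies))
        post[0] = 1.0  # policy (1,1,1)
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="feasible"):
            select_action(post, policies, 0, {3}, rng)


class TestFreeEnergy:
    def _exact_posterior_and_evidence(self, model, actions, observations):
        alpha = model.D.copy()
        for a, o in zip(actions, observations):
            alpha = model.A[o] * (model.B[a] @ alpha)
        return alpha / alpha.sum(), alpha.sum()

    def test_exact_posterior_attains_negative_log_evidence(self):
        rng = np.random.default_rng(11)
        model = make_random_model(6, 4, 2, rng)
        actions, observations = [0, 1, 0], [2, 0, 3]
        post, evidence = self._exact_posterior_and_evidence(
            model, actions, observations
        )
        belief = BeliefState(post, 6, 1)
        f = free_energy(belief, observations, actions, model)
        assert math.isclose(f, -math.log(evidence), abs_tol=1e-10)

    def test_any_other_belief_exceeds_the_bound(self):
        rng = np.random.default_rng(12)
        model = make_random_model(5, 4, 2, rng)
        actions, observations = [1, 0], [1, 2]
        post, evidence = self._exact_posterior_and_evidence(
            model, actions, observations
        )
        bound = -math.log(evidence)
        for _ in range(20):
            q = random_belief(5, rng)
            f = free_energy(BeliefState(q, 5, 1), observations, actions, model)
            assert f >= bound - 1e-12

    def test_perturbing_exact_posterior_strictly_increases(self):
        rng = np.random.default_rng(13)
        model = make_random_model(2, 3, 1, rng)
        actions, observations = [0], [1]
        post, evidence = self._exact_posterior_and_evidence(
            model, actions, observations
        )
        f_star = free_energy(BeliefState(post, 2, 1), observations, actions, model)
        eps = 0.05
        perturbed = post + np.array([eps, -eps])
        f = free_energy(BeliefState(perturbed, 2, 1), observations, actions, model)
        assert f > f_star + 1e-6


class TestBeliefConvergence:
    def test_repeated_consistent_rewards_converge_monotonically(self, sim1):
        # volatility 0: each trial's reward evidence can only sharpen the
        # context belief toward the true context
        task, model, _ = sim1
        red_left = model.obs.outcome_index(1, 0)
        prior = np.array([0.5, 0.5])
        history = []
        for _ in range(12):
            belief = belief_from_context(prior, 0, task.n_locations)
            post = bayes_update(belief, 1, red_left, model)
            prior = post.context_marginal  # carryover with volatility 0
            history.append(prior[0])
        assert all(b - a > 0 for a, b in zip(history, history[1:] ))
        assert history[-1] > 0.999
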