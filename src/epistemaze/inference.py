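"""Belief updating and expected-free-energy policy evaluation.

The quality of a policy at a future step tau decomposes as

    Q_tau(pi) = E_{Q(o_tau|pi)}[ ln P(o_tau|m) ]           (extrinsic value)
              + E_{Q(o_tau|pi)}[ KL( Q(s|o_tau,pi) || Q(s|pi) ) ]  (epistemic)

and the total quality Q(pi) sums Q_tau over the remaining steps of the
policy.  The policy posterior is a precision-weighted softmax
``P(pi) ∝ exp(gamma * Q(pi))`` and actions are sampled from the marginal
over the current step's control state.

Beliefs are propagated by exact recursive Bayesian filtering: for this
small discrete model family the exact filtering posterior is the fixed
point of the variational scheme, and :func:`free_energy` is kept as an
oracle to verify the bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import (
    LOG_FLOOR,
    PROB_TOL,
    GenerativeModel,
    ObservationModel,
    Policy,
    PolicySet,
    Preferences,
)


class ZeroLikelihoodError(ValueError):
    """Raised when an observation is impossible under the predicted state."""


@dataclass(frozen=True)
class BeliefState:
    """Categorical posterior over hidden (location x context) states."""

    state_belief: np.ndarray
    n_locations: int
    n_contexts: int

    def __post_init__(self) -> None:
        q = self.state_belief
        if q.ndim != 1 or q.size != self.n_locations * self.n_contexts:
            raise ValueError("state_belief has wrong shape")
        if np.any(q < -PROB_TOL) or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("state_belief is not a probability distribution")

    @property
    def context_marginal(self) -> np.ndarray:
        """Marginal over contexts (sum of the state belief over locations)."""
        return self.state_belief.reshape(self.n_contexts, self.n_locations).sum(axis=1)

    @property
    def location_marginal(self) -> np.ndarray:
        return self.state_belief.reshape(self.n_contexts, self.n_locations).sum(axis=0)

    def context_entropy(self) -> float:
        """Shannon entropy (nats) of the context marginal."""
        p = np.clip(self.context_marginal, LOG_FLOOR, None)
        return float(-(p * np.log(p)).sum())


@dataclass(frozen=True)
class PolicyEvaluation:
    """Per-step quality decomposition of a single policy."""

    per_tau_quality: np.ndarray
    extrinsic_component: np.ndarray
    epistemic_component: np.ndarray

    @property
    def total_quality(self) -> float:
        return float(self.per_tau_quality.sum())


def belief_from_context(
    context_prior: np.ndarray, location: int, n_locations: int
) -> BeliefState:
    """Joint belief with the given context marginal and a known location."""
    context_prior = np.asarray(context_prior, dtype=float)
    n_contexts = context_prior.size
    q = np.zeros(n_locations * n_contexts)
    for k in range(n_contexts):
        q[location + n_locations * k] = context_prior[k]
    return BeliefState(q, n_locations=n_locations, n_contexts=n_contexts)


def bayes_update(
    belief: BeliefState,
    action: int,
    observation: int,
    model: GenerativeModel,
) -> BeliefState:
    """Exact filtering step: predict through ``B[action]``, condition on ``o``.

    Returns the posterior ``∝ P(o|s') * sum_s P(s'|s,a) * belief(s)``.
    Raises :class:`ZeroLikelihoodError` when the observation has zero
    marginal likelihood under the predicted state distribution.
    """
    predicted = model.B[action] @ belief.state_belief
    post = model.A[observation] * predicted
    z = post.sum()
    if z <= 0.0:
        s_pred = int(np.argmax(predicted))
        raise ZeroLikelihoodError(
            f"observation {observation} is impossible: zero likelihood under "
            f"predicted states (most likely predicted state {s_pred})"
        )
    return BeliefState(post / z, belief.n_locations, belief.n_contexts)


def propagate_belief(
    belief: BeliefState, policy: Policy, tau: int, model: GenerativeModel
) -> np.ndarray:
    """Push the state belief ``tau`` steps forward along a policy.

    Returns ``B[u_tau] ... B[u_1] @ state_belief``; ``tau = 0`` is the
    identity.  ``tau`` must not exceed the policy horizon.
    """
    if not 0 <= tau <= policy.horizon:
        raise ValueError(f"tau={tau} outside policy horizon {policy.horizon}")
    q = belief.state_belief
    for t in range(tau):
        q = model.B[policy.controls[t]] @ q
    return q


def outcome_prediction(state_dist: np.ndarray, obs: ObservationModel) -> np.ndarray:
    """Posterior predictive distribution over outcomes, ``A @ q``."""
    return obs.likelihood @ state_dist


def extrinsic_value(outcome_dist: np.ndarray, prefs: Preferences) -> float:
    """Expected log prior preference of predicted outcomes (always <= 0)."""
    return float(outcome_dist @ prefs.log_preferences)


def epistemic_value(state_dist: np.ndarray, obs: ObservationModel) -> float:
    """Expected information gain about the state under predicted outcomes.

    Equals the mutual information between states and outcomes under the
    joint ``A[o,s] q[s]``, computed in the numerically friendly form
    ``H[Q(o)] - E_q H[A(:,s)]``; clipped at zero against round-off.
    """
    A = obs.likelihood
    qo = A @ state_dist
    h_cols = (A * np.log(np.clip(A, LOG_FLOOR, None))).sum(axis=0)
    h_qo = -(qo * np.log(np.clip(qo, LOG_FLOOR, None))).sum()
    value = float(h_qo + state_dist @ h_cols)
    # cancellation noise: an exact zero (point mass, uninformative
    # likelihood) may come out as +-1e-16
    return value if value > 1e-12 else 0.0


def policy_quality(
    belief: BeliefState,
    policy: Policy,
    model: GenerativeModel,
    start: int = 0,
) -> PolicyEvaluation:
    """Evaluate one policy's remaining steps from the current belief.

    ``start`` indexes the first control still to be executed, so the
    evaluation covers steps ``start .. horizon-1`` (the whole policy by
    default).  Each step contributes extrinsic plus epistemic value of
    the belief propagated to that step.
    """
    steps = range(start, policy.horizon)
    ext = np.empty(len(steps))
    epi = np.empty(len(steps))
    q = belief.state_belief
    for i, t in enumerate(steps):
        q = model.B[policy.controls[t]] @ q
        ext[i] = extrinsic_value(outcome_prediction(q, model.obs), model.prefs)
        epi[i] = epistemic_value(q, model.obs)
    return PolicyEvaluation(
        per_tau_quality=ext + epi,
        extrinsic_component=ext,
        epistemic_component=epi,
    )


def evaluate_policy_set(
    belief: BeliefState,
    policies: PolicySet,
    model: GenerativeModel,
    start: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`policy_quality` over a whole policy set.

    Returns ``(extrinsic, epistemic, totals)`` where the first two have
    shape ``(n_policies, horizon - start)`` and ``totals`` is their
    summed per-policy quality.  Policies sharing a control at a step are
    propagated together, which keeps the per-trial cost low enough for
    thousand-run experiments.
    """
    A = model.A
    C = model.C
    controls = policies.controls_array()[:, start:]
    n_pol, n_steps = controls.shape
    qs = np.tile(belief.state_belief, (n_pol, 1))
    h_cols = (A * np.log(np.clip(A, LOG_FLOOR, None))).sum(axis=0)

    ext = np.empty((n_pol, n_steps))
    epi = np.empty((n_pol, n_steps))
    for t in range(n_steps):
        for u in np.unique(controls[:, t]):
            idx = controls[:, t] == u
            qs[idx] = qs[idx] @ model.B[u].T
        qo = qs @ A.T
        ext[:, t] = qo @ C
        h_qo = -(qo * np.log(np.clip(qo, LOG_FLOOR, None))).sum(axis=1)
        e = h_qo + qs @ h_cols
        epi[:, t] = np.where(e > 1e-12, e, 0.0)
    return ext, epi, (ext + epi).sum(axis=1)


def policy_posterior(qualities: np.ndarray, gamma: float) -> np.ndarray:
    """Precision-weighted softmax over policy qualities."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    q = np.asarray(qualities, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("policy qualities must be finite")
    z = gamma * q
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def select_action(
    policy_post: np.ndarray,
    policies: PolicySet,
    step: int,
    feasible: set[int] | frozenset[int],
    rng: np.random.Generator,
) -> int:
    """Sample an action from the step marginal of the policy posterior.

    The marginal over the ``step``-th control of every policy is formed,
    restricted to the feasible controls (e.g. only the matching arm
    control in an absorbing arm) and renormalized before sampling.
    """
    controls = policies.controls_array()[:, step]
    n_controls = policies.n_controls
    marginal = np.zeros(n_controls)
    np.add.at(marginal, controls, policy_post)
    mask = np.zeros(n_controls, dtype=bool)
    mask[list(feasible)] = True
    marginal[~mask] = 0.0
    z = marginal.sum()
    if z <= 0.0:
        raise ValueError("no feasible control has positive posterior mass")
    return int(rng.choice(n_controls, p=marginal / z))


def free_energy(
    belief: BeliefState,
    observation_history: list[int],
    action_history: list[int],
    model: GenerativeModel,
) -> float:
    """Variational free energy of a belief given full trial histories.

    ``F(q) = E_q[ ln q(s_T) - ln P(o_1..o_T, s_T) ]`` with the joint
    computed by the forward (filtering) recursion.  For the exact
    posterior this equals the negative log evidence; for any other
    distribution it exceeds it by ``KL(q || posterior)``.
    """
    if len(observation_history) != len(action_history):
        raise ValueError("histories must have equal length")
    alpha = model.D.copy()
    for a, o in zip(action_history, observation_history):
        alpha = model.A[o] * (model.B[a] @ alpha)
    evidence = alpha.sum()
    if evidence <= 0.0:
        raise ZeroLikelihoodError("observation history has zero probability")
    q = belief.state_belief
    log_alpha = np.log(np.clip(alpha, LOG_FLOOR, None))
    log_q = np.log(np.clip(q, LOG_FLOOR, None))
    return float(q @ (log_q - log_alpha))
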