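"""Building blocks of the discrete generative model.

A maze-foraging agent is described by a categorical partially observed
Markov decision process whose hidden state factorizes into a *location*
(where the animal is, including covert "imaginary" locations that stand
for episodic recall of an arm) and a *context* (the hidden reward
contingency).  The generative model consists of

* a likelihood matrix ``A`` mapping hidden states to outcomes, where an
  outcome is a (location, cue) pair — the location component is observed
  noiselessly, the cue (reward / neutral / mnemonic) is stochastic;
* one column-stochastic transition matrix ``B[u]`` per control state
  ``u``, which moves the location component and never the context;
* log prior preferences ``C`` over outcomes, the softmax of utilities;
* an initial state prior ``D``.

Indexing conventions used throughout the package::

    state   = location + n_locations * context
    outcome = location + n_locations * cue

Policies are fixed-horizon sequences of control states; steps that visit
imaginary locations are flagged as covert (sweep) steps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

#: absolute tolerance for probability-vector normalization checks
PROB_TOL = 1e-12

#: floor used inside logarithms to guard against log(0)
LOG_FLOOR = 1e-16


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationModel:
    """Likelihood ``P(outcome | hidden state)`` plus cue bookkeeping.

    Parameters
    ----------
    likelihood
        Array of shape ``(n_outcomes, n_states)``; every column is a
        probability distribution over outcomes.
    cue_labels
        Ordered cue identities (e.g. ``("red", "white", "blue", "green")``).
    n_locations
        Number of locations; fixes the (location, cue) factorization of
        the outcome index and the (location, context) factorization of
        the state index.
    """

    likelihood: np.ndarray
    cue_labels: tuple[str, ...]
    n_locations: int

    @property
    def n_outcomes(self) -> int:
        return self.likelihood.shape[0]

    @property
    def n_states(self) -> int:
        return self.likelihood.shape[1]

    @property
    def n_cues(self) -> int:
        return len(self.cue_labels)

    def outcome_index(self, location: int, cue: int) -> int:
        return location + self.n_locations * cue

    def outcome_location(self, outcome: int) -> int:
        return outcome % self.n_locations

    def outcome_cue(self, outcome: int) -> int:
        return outcome // self.n_locations


@dataclass(frozen=True)
class TransitionModel:
    """Per-control transition matrices ``P(next state | state, u)``.

    ``per_control[u]`` has shape ``(n_states, n_states)`` with
    column-stochastic convention: ``per_control[u][s_next, s]``.
    Absorbing states self-transition with probability one under every
    control, and no control changes the context component of a state.
    """

    per_control: tuple[np.ndarray, ...]
    absorbing_states: frozenset[int]
    n_locations: int
    n_contexts: int

    @property
    def n_controls(self) -> int:
        return len(self.per_control)

    @property
    def n_states(self) -> int:
        return self.per_control[0].shape[0]


@dataclass(frozen=True)
class Preferences:
    """Prior preferences over outcomes: ``C(o) = ln P(o | m)``.

    The log preferences are the log-softmax of the utilities, so only
    utility *differences* carry meaning — shifting every utility by a
    constant leaves behaviour unchanged.
    """

    utilities: np.ndarray
    log_preferences: np.ndarray


@dataclass(frozen=True)
class Policy:
    """A fixed-horizon sequence of control states.

    ``imaginary_mask[t]`` is True where the control at step ``t`` visits
    an imaginary (episodic-retrieval) location, i.e. a covert sweep.
    """

    controls: tuple[int, ...]
    imaginary_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.controls) != len(self.imaginary_mask):
            raise ValueError("controls and imaginary_mask must have equal length")

    @property
    def horizon(self) -> int:
        return len(self.controls)

    @property
    def n_sweeps(self) -> int:
        return int(sum(self.imaginary_mask))


@dataclass(frozen=True)
class PolicySet:
    """Ordered, deterministic collection of the policies of a task."""

    policies: tuple[Policy, ...]
    horizon: int
    n_controls: int

    def __len__(self) -> int:
        return len(self.policies)

    def __iter__(self):
        return iter(self.policies)

    def __getitem__(self, i: int) -> Policy:
        return self.policies[i]

    def controls_array(self) -> np.ndarray:
        """Controls as an ``(n_policies, horizon)`` integer array."""
        return np.array([p.controls for p in self.policies], dtype=np.intp)


@dataclass(frozen=True)
class AgentParams:
    """Agent-level parameters shared by all four maze tasks.

    Attributes
    ----------
    gamma
        Policy precision (inverse temperature) of the softmax over
        policy qualities; dimensionless, >= 0.
    volatility
        Prior per-trial probability that the context changes; mixes the
        between-trial context carry-over toward the other contexts.
    reward_reliability
        Probability that the baited arm delivers the reward cue.
    context_cue_reliability
        Probability that an imaginary location delivers the
        context-congruent mnemonic cue.
    reward_utility, loss_utility
        Utilities of the reward cue and of the neutral cue at a real
        arm (the "wrong arm" experience).
    imaginary_cost
        Utility of any mnemonic cue at an imaginary location; the small
        cost of performing a forward sweep.
    horizon
        Optional override of the task's policy length.
    """

    gamma: float = 10.0
    volatility: float = 0.02
    reward_reliability: float = 0.75
    context_cue_reliability: float = 0.85
    reward_utility: float = 2.0
    loss_utility: float = -2.0
    imaginary_cost: float = -0.25
    horizon: int | None = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        for name in ("volatility", "reward_reliability", "context_cue_reliability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.horizon is not None and self.horizon < 1:
            raise ValueError("horizon must be a positive integer")


@dataclass(frozen=True)
class GenerativeModel:
    """Bundle of likelihood, transitions, preferences and initial prior."""

    obs: ObservationModel
    trans: TransitionModel
    prefs: Preferences
    init_prior: np.ndarray

    @property
    def A(self) -> np.ndarray:
        return self.obs.likelihood

    @property
    def B(self) -> tuple[np.ndarray, ...]:
        return self.trans.per_control

    @property
    def C(self) -> np.ndarray:
        return self.prefs.log_preferences

    @property
    def D(self) -> np.ndarray:
        return self.init_prior

    @property
    def n_states(self) -> int:
        return self.obs.n_states

    @property
    def n_outcomes(self) -> int:
        return self.obs.n_outcomes

    @property
    def n_controls(self) -> int:
        return self.trans.n_controls

    @property
    def n_locations(self) -> int:
        return self.obs.n_locations

    @property
    def n_contexts(self) -> int:
        return self.trans.n_contexts


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def normalize_preferences(utilities: np.ndarray | list[float]) -> Preferences:
    """Turn raw outcome utilities into normalized log preferences.

    ``log_preferences[i] = utilities[i] - log(sum_j exp(utilities[j]))``,
    i.e. the log of a softmax distribution over outcomes.  Invariant to
    adding a constant to all utilities.
    """
    u = np.asarray(utilities, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("utilities must be a non-empty 1-D vector")
    m = u.max()
    log_z = m + np.log(np.exp(u - m).sum())
    return Preferences(utilities=u, log_preferences=u - log_z)


def validate_model(
    obs: ObservationModel,
    trans: TransitionModel,
    prefs: Preferences | None = None,
) -> list[str]:
    """Check the structural invariants of a generative model.

    Returns a list of human-readable violation messages; the empty list
    means the model is well formed.  Checks performed:

    * every likelihood column is a probability distribution;
    * outcomes are deterministic in location (an outcome whose location
      component differs from the state's location has probability 0);
    * every transition column, for every control, is a distribution;
    * absorbing states self-transition with probability 1;
    * no control moves probability mass across contexts;
    * preference ordering matches utility ordering (when given).
    """
    report: list[str] = []
    A = obs.likelihood
    n_loc = obs.n_locations

    if np.any(A < -PROB_TOL):
        report.append("likelihood contains negative entries")
    col_sums = A.sum(axis=0)
    for s in np.nonzero(np.abs(col_sums - 1.0) > 1e-9)[0]:
        report.append(
            f"likelihood column for state {s} sums to {col_sums[s]:.6g}, not 1"
        )
    for o in range(obs.n_outcomes):
        for s in range(obs.n_states):
            if A[o, s] > PROB_TOL and (o % n_loc) != (s % n_loc):
                report.append(
                    f"outcome {o} (location {o % n_loc}) has probability "
                    f"{A[o, s]:.3g} in state {s} (location {s % n_loc})"
                )

    for u, B in enumerate(trans.per_control):
        sums = B.sum(axis=0)
        for s in np.nonzero(np.abs(sums - 1.0) > 1e-9)[0]:
            report.append(
                f"transition column (control {u}, state {s}) sums to "
                f"{sums[s]:.6g}, not 1"
            )
        if np.any(B < -PROB_TOL):
            report.append(f"transition matrix for control {u} has negative entries")
        for s in trans.absorbing_states:
            if abs(B[s, s] - 1.0) > 1e-9:
                report.append(
                    f"absorbing state {s} leaks under control {u}: "
                    f"self-transition {B[s, s]:.6g}"
                )
        # context preservation: mass starting in context k must stay there
        for s in range(trans.n_states):
            ctx = s // trans.n_locations
            mass_out = B[:, s].reshape(trans.n_contexts, trans.n_locations)
            leak = mass_out.sum(axis=1)
            for k in np.nonzero(leak > PROB_TOL)[0]:
                if k != ctx:
                    report.append(
                        f"control {u} moves state {s} from context {ctx} "
                        f"to context {k}"
                    )

    if prefs is not None:
        order_u = np.argsort(prefs.utilities, kind="stable")
        order_c = np.argsort(prefs.log_preferences, kind="stable")
        if not np.array_equal(order_u, order_c):
            report.append("log-preference ordering does not match utility ordering")
        total = np.exp(prefs.log_preferences).sum()
        if abs(total - 1.0) > 1e-9:
            report.append(f"exp(log_preferences) sums to {total:.6g}, not 1")

    return report


def _sweep_then_arm_policies(
    arm_controls: tuple[int, ...],
    sweep_controls: tuple[int, ...],
    horizon: int,
    max_sweeps: int,
    distinct_sweeps: bool,
) -> list[tuple[int, ...]]:
    """Sweep prefixes of length 0..max_sweeps followed by a repeated arm.

    With repetition allowed this yields the 14-policy set of the two-arm
    maze (2 + 4 + 8); with ordered distinct sweeps and three arms it
    yields the 48-policy set of the radial maze (3 + 9 + 18 + 18).
    """
    out: list[tuple[int, ...]] = []
    for k in range(max_sweeps + 1):
        if k >= horizon:
            break
        if distinct_sweeps:
            prefixes = itertools.permutations(sweep_controls, k)
        else:
            prefixes = itertools.product(sweep_controls, repeat=k)
        for prefix in prefixes:
            for arm in arm_controls:
                out.append(tuple(prefix) + (arm,) * (horizon - k))
    return out


def _double_tmaze_policies(task) -> list[tuple[int, ...]]:
    """Policies of the double T-maze: at most one sweep per policy.

    Policies either go straight through both decision points, or insert
    a single VTE event at one of them (policies with one and with two
    sweeps are not compared).  Forms, with e an easy move, c a costly
    (final) move, se an easy-point sweep and sc a sweep of the costly
    point reached by e::

        [e, c, c, c]   [se, e, c, c]   [e, sc, c, c]
    """
    out: list[tuple[int, ...]] = []
    for e in task.easy_controls:
        costly_sweeps = task.costly_sweeps_by_easy[e]
        for c in task.final_controls:
            out.append((e, c, c, c))
            for se in task.easy_sweep_controls:
                out.append((se, e, c, c))
            for sc in costly_sweeps:
                out.append((e, sc, c, c))
    return out


def enumerate_policies(task) -> PolicySet:
    """Enumerate the policy set of a task, deterministically ordered.

    The enumeration rule is selected by ``task.policy_rule``:

    ``"sweeps_then_arm"``
        Sweep prefixes (repeats allowed) followed by a repeated arm
        control; used by the two-arm mazes (14 policies at horizon 3).
    ``"sweeps_then_arm_distinct"``
        Same but with ordered distinct sweep prefixes; used by the
        three-arm radial maze (48 policies at horizon 4).
    ``"double_tmaze"``
        Easy choice then costly choice with at most one sweep per
        decision point (36 policies at horizon 4).
    """
    rule = getattr(task, "policy_rule", None)
    horizon = task.horizon
    if rule in ("sweeps_then_arm", "sweeps_then_arm_distinct"):
        seqs = _sweep_then_arm_policies(
            tuple(task.arm_controls),
            tuple(task.sweep_controls),
            horizon,
            max_sweeps=task.max_sweeps,
            distinct_sweeps=(rule == "sweeps_then_arm_distinct"),
        )
    elif rule == "double_tmaze":
        seqs = _double_tmaze_policies(task)
    else:
        raise ValueError(f"unknown task policy rule: {rule!r}")

    imaginary = frozenset(task.sweep_controls)
    policies = tuple(
        Policy(controls=s, imaginary_mask=tuple(c in imaginary for c in s))
        for s in seqs
    )
    n_controls = task.n_controls
    for p in policies:
        for c in p.controls:
            if not 0 <= c < n_controls:
                raise ValueError(f"policy control {c} out of range for task")
    return PolicySet(policies=policies, horizon=horizon, n_controls=n_controls)
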