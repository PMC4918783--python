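"""The generative process: true context, true location, cue sampling.

The environment shares the agent's likelihood and transition structure
but holds the *true* context, which the agent can only infer through
sampled cues.  Covert (imaginary) actions never move the animal: the
body stays where it is while the cue for that step is sampled from the
imaginary location's likelihood column — the mnemonic retrieval.
Between trials the context posterior is blended toward the remaining
contexts under the volatility prior before becoming the next prior.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_model import GenerativeModel
from .tasks import TaskSpec


@dataclass(frozen=True)
class EnvState:
    """True state of the generative process at one within-trial step.

    ``true_location`` is always a real location.  ``outcome_location``
    is the location whose cue is sampled this step; it differs from
    ``true_location`` only during a covert sweep, when it points at the
    imaginary location being "visited".
    """

    true_context: int
    true_location: int
    trial: int = 1
    step: int = 0
    outcome_location: int | None = None
    swept: bool = False

    @property
    def sampling_location(self) -> int:
        return self.true_location if self.outcome_location is None else self.outcome_location


@dataclass(frozen=True)
class ContextSchedule:
    """Initial context plus an ordered list of (trial, new context) changes."""

    initial_context: int
    changes: tuple[tuple[int, int], ...]
    n_trials: int

    def __post_init__(self) -> None:
        last = 1
        for trial, ctx in self.changes:
            if trial <= last:
                raise ValueError("change trials must be strictly increasing and > 1")
            if not 1 <= trial <= self.n_trials:
                raise ValueError(f"change trial {trial} outside 1..{self.n_trials}")
            last = trial

    def context_at(self, trial: int) -> int:
        """True context in force during ``trial`` (1-based)."""
        ctx = self.initial_context
        for t, c in self.changes:
            if trial >= t:
                ctx = c
        return ctx


def env_step(env: EnvState, action: int, task: TaskSpec, model: GenerativeModel) -> EnvState:
    """Advance the generative process by one action.

    The true context's (deterministic) transition model decides what the
    action achieves — absorbing arms, barrier blocks and the reach of
    covert sweeps included.  When the transition lands on an imaginary
    location the body stays put and the step is marked as a sweep whose
    cue is sampled there; otherwise the true location moves (possibly
    failing in place, e.g. at a barrier).
    """
    n_loc = task.n_locations
    state = env.true_location + n_loc * env.true_context
    col = model.B[action][:, state]
    next_state = int(np.argmax(col))
    if col[next_state] < 1.0 - 1e-9:
        raise ValueError("generative process requires deterministic transitions")
    next_loc = next_state % n_loc
    if task.location_kinds[next_loc] == "imaginary":
        return replace(env, step=env.step + 1, outcome_location=next_loc, swept=True)
    return replace(
        env,
        step=env.step + 1,
        true_location=next_loc,
        outcome_location=None,
        swept=False,
    )


def sample_outcome(env: EnvState, model: GenerativeModel, rng: np.random.Generator) -> int:
    """Draw one outcome from the likelihood column of the sampled state."""
    state = env.sampling_location + model.n_locations * env.true_context
    p = model.A[:, state]
    return int(rng.choice(model.n_outcomes, p=p))


def carryover_prior(context_posterior: np.ndarray, volatility: float) -> np.ndarray:
    """Between-trial context carry-over under the volatility prior.

    ``prior(c) = (1-v) post(c) + v * sum_{c' != c} post(c') / (K-1)``:
    with probability ``v`` the context is believed to have switched,
    uniformly over the other contexts.
    """
    if not 0.0 <= volatility <= 1.0:
        raise ValueError("volatility must lie in [0, 1]")
    p = np.asarray(context_posterior, dtype=float)
    k = p.size
    if k == 1:
        return p.copy()
    return (1.0 - volatility) * p + volatility * (p.sum() - p) / (k - 1)


def advance_context(schedule: ContextSchedule, trial: int, env: EnvState) -> EnvState:
    """Apply the context schedule at the start of ``trial``.

    The true context changes exactly on the scheduled trials; the agent
    is never told and must infer the change from cues.
    """
    return replace(env, trial=trial, true_context=schedule.context_at(trial))
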