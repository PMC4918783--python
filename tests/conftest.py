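"""Shared fixtures: built tasks and random-model factories."""

import numpy as np
import pytest

from epistemaze import (
    AgentParams,
    GenerativeModel,
    ObservationModel,
    Preferences,
    TransitionModel,
    build_task,
    normalize_preferences,
)


@pytest.fixture(scope="session")
def default_params():
    return AgentParams()


@pytest.fixture(scope="session")
def sim1():
    """(task, model, policies) of the two-arm T-maze with defaults."""
    return build_task("sim1")


@pytest.fixture(scope="session")
def sim2():
    return build_task("sim2")


@pytest.fixture(scope="session")
def sim3():
    return build_task("sim3")


@pytest.fixture(scope="session")
def sim4():
    return build_task("sim4")


def make_random_model(
    n_states: int,
    n_outcomes: int,
    n_controls: int,
    rng: np.random.Generator,
    identity_likelihood: bool = False,
) -> GenerativeModel:
    """Random categorical model for engine tests (flat location structure).

    States are treated as a single 'context' row of locations so that
    belief containers work without maze structure; likelihood and
    transitions are arbitrary column-stochastic matrices.
    """
    if identity_likelihood:
        assert n_outcomes == n_states
        A = np.eye(n_states)
    else:
        A = rng.random((n_outcomes, n_states)) + 0.05
        A /= A.sum(axis=0, keepdims=True)
    B = []
    for _ in range(n_controls):
        M = rng.random((n_states, n_states)) + 0.05
        M /= M.sum(axis=0, keepdims=True)
        B.append(M)
    D = rng.random(n_states) + 0.05
    D /= D.sum()
    obs = ObservationModel(A, cue_labels=("cue",), n_locations=n_states)
    trans = TransitionModel(
        per_control=tuple(B),
        absorbing_states=frozenset(),
        n_locations=n_states,
        n_contexts=1,
    )
    prefs = normalize_preferences(rng.normal(size=n_outcomes))
    return GenerativeModel(obs=obs, trans=trans, prefs=prefs, init_prior=D)


def random_belief(n_states: int, rng: np.random.Generator) -> np.ndarray:
    q = rng.random(n_states) + 0.02
    return q / q.sum()
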