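"""The four built-in maze tasks as validated generative models.

Each builder returns ``(TaskSpec, GenerativeModel, PolicySet)``:

``two_arm_tmaze`` (``sim1``)
    T-maze with a left and a right arm, one baited per context.  Five
    locations (center, two arms, two imaginary arm locations) times two
    contexts give 10 hidden states and 20 outcomes; horizon 3; 14
    policies.
``three_arm_radial`` (``sim2``)
    Radial maze with three arms and three contexts: 21 hidden states,
    28 outcomes, horizon 4, 48 policies.
``double_tmaze`` (``sim3``)
    Two consecutive decision points, an "easy" one (recoverable, and
    with a context-dependent barrier blocking one path) followed by a
    "costly" one (absorbing): 11 locations x 4 contexts = 44 hidden
    states, 11 control states, 36 policies with at most one sweep per
    decision point.
``plentiful_tmaze`` (``sim4``)
    The two-arm maze with four contexts: the first two as in ``sim1``
    (gain +2 vs loss -2), the last two bait both arms with a "usual"
    and a "high" reward signalled by dark cues.

Cue semantics: ``red`` = reward, ``white`` = neutral, ``blue``/``green``
= episodic recall of a rewarding / neutral arm visit, ``yellow``/
``black`` = recall cues at the easy decision point partitioning the
contexts by their first letter, ``dark_red``/``dark_blue`` = presence /
recall of the high reward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    AgentParams,
    GenerativeModel,
    ObservationModel,
    PolicySet,
    Preferences,
    TransitionModel,
    enumerate_policies,
    normalize_preferences,
)


@dataclass(frozen=True)
class TaskSpec:
    """Static description of a maze task.

    ``locations`` are ordered with the center/home first, real arms
    next and imaginary locations last; ``location_kinds`` tags each as
    ``"real"`` or ``"imaginary"``.  Control state ``u`` targets location
    ``u``.  ``sweep_tags`` labels each imaginary control as belonging to
    an easy or costly decision point (double T-maze only).
    """

    name: str
    locations: tuple[str, ...]
    location_kinds: tuple[str, ...]
    contexts: tuple[str, ...]
    cues: tuple[str, ...]
    absorbing_locations: frozenset[int]
    horizon: int
    home_location: int
    arm_controls: tuple[int, ...]
    sweep_controls: tuple[int, ...]
    reward_cues: tuple[int, ...]
    policy_rule: str
    max_sweeps: int = 2
    imaginary_cost: float = -0.25
    sweep_tags: dict[int, str] = field(default_factory=dict)
    # double T-maze structure (unused elsewhere)
    easy_controls: tuple[int, ...] = ()
    easy_sweep_controls: tuple[int, ...] = ()
    final_controls: tuple[int, ...] = ()
    costly_sweeps_by_easy: dict[int, tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def n_contexts(self) -> int:
        return len(self.contexts)

    @property
    def n_controls(self) -> int:
        return self.n_locations

    @property
    def n_cues(self) -> int:
        return len(self.cues)

    def is_imaginary_control(self, u: int) -> bool:
        return u in self.sweep_controls

    def feasible_controls(self, location: int) -> frozenset[int]:
        """Controls available from a (real) location.

        In an absorbing arm only the matching arm control remains; from
        any other location every control may be attempted (moves that
        the maze geometry or a barrier forbids simply fail in place).
        """
        if location in self.absorbing_locations:
            return frozenset({location})
        return frozenset(range(self.n_controls))


def _state(loc: int, ctx: int, n_loc: int) -> int:
    return loc + n_loc * ctx


def _build_model(
    task: TaskSpec,
    emissions: dict[tuple[int, int], list[tuple[int, float]]],
    move: "callable",
    utilities: np.ndarray,
) -> GenerativeModel:
    """Assemble A, B, C, D from per-state emissions and a movement rule.

    ``emissions[(loc, ctx)]`` lists ``(cue, prob)`` pairs; ``move(loc,
    ctx, u)`` gives the deterministic next location under control ``u``.
    """
    n_loc, n_ctx, n_cue = task.n_locations, task.n_contexts, task.n_cues
    n_states = n_loc * n_ctx
    n_out = n_loc * n_cue

    A = np.zeros((n_out, n_states))
    for (loc, ctx), pairs in emissions.items():
        s = _state(loc, ctx, n_loc)
        for cue, p in pairs:
            A[loc + n_loc * cue, s] += p

    B = []
    for u in range(task.n_controls):
        Bu = np.zeros((n_states, n_states))
        for ctx in range(n_ctx):
            for loc in range(n_loc):
                nxt = loc if loc in task.absorbing_locations else move(loc, ctx, u)
                Bu[_state(nxt, ctx, n_loc), _state(loc, ctx, n_loc)] = 1.0
        B.append(Bu)

    D = np.zeros(n_states)
    for ctx in range(n_ctx):
        D[_state(task.home_location, ctx, n_loc)] = 1.0 / n_ctx

    obs = ObservationModel(A, task.cues, n_locations=n_loc)
    trans = TransitionModel(
        per_control=tuple(B),
        absorbing_states=frozenset(
            _state(loc, ctx, n_loc)
            for loc in task.absorbing_locations
            for ctx in range(n_ctx)
        ),
        n_locations=n_loc,
        n_contexts=n_ctx,
    )
    prefs = normalize_preferences(utilities)
    return GenerativeModel(obs=obs, trans=trans, prefs=prefs, init_prior=D)


def _arm_emission(rewarded: bool, r: float, reward_cue: int, neutral_cue: int):
    """Reward cue with reliability ``r`` at the baited arm; the wrong arm
    shows the complementary structure (neutral with probability ``r``)."""
    if rewarded:
        return [(reward_cue, r), (neutral_cue, 1.0 - r)]
    return [(neutral_cue, r), (reward_cue, 1.0 - r)]


def _sweep_emission(match_cue: int, miss_cue: int, r: float):
    return [(match_cue, r), (miss_cue, 1.0 - r)]


# ---------------------------------------------------------------------------
# sim1: two-arm T-maze
# ---------------------------------------------------------------------------

RED, WHITE, BLUE, GREEN = 0, 1, 2, 3


def build_two_arm_tmaze(
    params: AgentParams | None = None,
) -> tuple[TaskSpec, GenerativeModel, PolicySet]:
    """Two-arm T-maze: 10 hidden states, 20 outcomes, 14 policies."""
    params = params or AgentParams()
    task = TaskSpec(
        name="two_arm_tmaze",
        locations=("center", "left", "right", "imag_left", "imag_right"),
        location_kinds=("real", "real", "real", "imaginary", "imaginary"),
        contexts=("reward_left", "reward_right"),
        cues=("red", "white", "blue", "green"),
        absorbing_locations=frozenset({1, 2}),
        horizon=params.horizon or 3,
        home_location=0,
        arm_controls=(1, 2),
        sweep_controls=(3, 4),
        reward_cues=(RED,),
        policy_rule="sweeps_then_arm",
        max_sweeps=2,
        imaginary_cost=params.imaginary_cost,
    )

    r = params.reward_reliability
    rc = params.context_cue_reliability
    arm_of_imag = {3: 1, 4: 2}
    rewarded_arm = {0: 1, 1: 2}  # context -> baited arm location

    emissions: dict[tuple[int, int], list[tuple[int, float]]] = {}
    for ctx in range(2):
        emissions[(0, ctx)] = [(WHITE, 1.0)]
        for arm in (1, 2):
            emissions[(arm, ctx)] = _arm_emission(
                rewarded_arm[ctx] == arm, r, RED, WHITE
            )
        for imag in (3, 4):
            match = rewarded_arm[ctx] == arm_of_imag[imag]
            emissions[(imag, ctx)] = (
                _sweep_emission(BLUE, GREEN, rc)
                if match
                else _sweep_emission(GREEN, BLUE, rc)
            )

    utilities = np.zeros(task.n_locations * task.n_cues)
    for arm in (1, 2):
        utilities[arm + 5 * RED] = params.reward_utility
        utilities[arm + 5 * WHITE] = params.loss_utility
    for imag in (3, 4):
        utilities[imag + 5 * BLUE] = params.imaginary_cost
        utilities[imag + 5 * GREEN] = params.imaginary_cost

    model = _build_model(task, emissions, lambda loc, ctx, u: u, utilities)
    return task, model, enumerate_policies(task)


# ---------------------------------------------------------------------------
# sim2: three-arm radial maze
# ---------------------------------------------------------------------------


def build_three_arm_radial(
    params: AgentParams | None = None,
) -> tuple[TaskSpec, GenerativeModel, PolicySet]:
    """Three-arm radial maze: 21 hidden states, 28 outcomes, 48 policies."""
    params = params or AgentParams()
    task = TaskSpec(
        name="three_arm_radial",
        locations=(
            "center",
            "left",
            "middle",
            "right",
            "imag_left",
            "imag_middle",
            "imag_right",
        ),
        location_kinds=("real",) * 4 + ("imaginary",) * 3,
        contexts=("reward_left", "reward_middle", "reward_right"),
        cues=("red", "white", "blue", "green"),
        absorbing_locations=frozenset({1, 2, 3}),
        horizon=params.horizon or 4,
        home_location=0,
        arm_controls=(1, 2, 3),
        sweep_controls=(4, 5, 6),
        reward_cues=(RED,),
        policy_rule="sweeps_then_arm_distinct",
        max_sweeps=3,
        imaginary_cost=params.imaginary_cost,
    )

    r = params.reward_reliability
    rc = params.context_cue_reliability
    arm_of_imag = {4: 1, 5: 2, 6: 3}
    rewarded_arm = {0: 1, 1: 2, 2: 3}
    n_loc = task.n_locations

    emissions: dict[tuple[int, int], list[tuple[int, float]]] = {}
    for ctx in range(3):
        emissions[(0, ctx)] = [(WHITE, 1.0)]
        for arm in (1, 2, 3):
            emissions[(arm, ctx)] = _arm_emission(
                rewarded_arm[ctx] == arm, r, RED, WHITE
            )
        for imag in (4, 5, 6):
            match = rewarded_arm[ctx] == arm_of_imag[imag]
            emissions[(imag, ctx)] = (
                _sweep_emission(BLUE, GREEN, rc)
                if match
                else _sweep_emission(GREEN, BLUE, rc)
            )

    utilities = np.zeros(n_loc * task.n_cues)
    for arm in (1, 2, 3):
        utilities[arm + n_loc * RED] = params.reward_utility
        utilities[arm + n_loc * WHITE] = params.loss_utility
    for imag in (4, 5, 6):
        utilities[imag + n_loc * BLUE] = params.imaginary_cost
        utilities[imag + n_loc * GREEN] = params.imaginary_cost

    model = _build_model(task, emissions, lambda loc, ctx, u: u, utilities)
    return task, model, enumerate_policies(task)


# ---------------------------------------------------------------------------
# sim3: double T-maze with easy and costly decision points
# ---------------------------------------------------------------------------

# cue indices for the six-cue tasks
S3_RED, S3_WHITE, S3_BLUE, S3_GREEN, S3_YELLOW, S3_BLACK = range(6)


def build_double_tmaze(
    params: AgentParams | None = None,
) -> tuple[TaskSpec, GenerativeModel, PolicySet]:
    """Double T-maze: 44 hidden states, 11 control states, 36 policies.

    Contexts are the four path labels LL, LR, RL, RR: the first letter
    is the open easy-side path (the other is blocked by a barrier), the
    second letter the baited final arm.  Easy-point sweeps emit yellow
    (contexts L*) or black (R*); costly-point sweeps emit blue/green as
    in the simple T-maze.  Only the final arms are absorbing, so a wrong
    easy choice can be undone while a wrong costly choice cannot.
    """
    params = params or AgentParams()
    locations = (
        "home",
        "costly_dp_left",
        "costly_dp_right",
        "final_left",
        "final_right",
        "imag_easy_left",
        "imag_easy_right",
        "imag_costlyL_left",
        "imag_costlyL_right",
        "imag_costlyR_left",
        "imag_costlyR_right",
    )
    task = TaskSpec(
        name="double_tmaze",
        locations=locations,
        location_kinds=("real",) * 5 + ("imaginary",) * 6,
        contexts=("LL", "LR", "RL", "RR"),
        cues=("red", "white", "blue", "green", "yellow", "black"),
        absorbing_locations=frozenset({3, 4}),
        horizon=params.horizon or 4,
        home_location=0,
        arm_controls=(3, 4),
        sweep_controls=(5, 6, 7, 8, 9, 10),
        reward_cues=(S3_RED,),
        policy_rule="double_tmaze",
        imaginary_cost=params.imaginary_cost,
        sweep_tags={5: "easy", 6: "easy", 7: "costly", 8: "costly",
                    9: "costly", 10: "costly"},
        easy_controls=(1, 2),
        easy_sweep_controls=(5, 6),
        final_controls=(3, 4),
        costly_sweeps_by_easy={1: (7, 8), 2: (9, 10)},
    )

    n_loc = task.n_locations
    r = params.reward_reliability
    rc = params.context_cue_reliability
    first_letter = {0: "L", 1: "L", 2: "R", 3: "R"}
    second_letter = {0: "L", 1: "R", 2: "L", 3: "R"}
    rewarded_final = {ctx: (3 if second_letter[ctx] == "L" else 4) for ctx in range(4)}
    # which final arm each costly-point sweep imagines visiting
    imagined_final = {7: 3, 8: 4, 9: 3, 10: 4}
    # anchor: the real location an imaginary location's moves depart from
    anchor = {0: 0, 1: 1, 2: 2, 3: 3, 4: 4, 5: 0, 6: 0, 7: 1, 8: 1, 9: 2, 10: 2}

    def move(loc: int, ctx: int, u: int) -> int:
        a = anchor[loc]
        if a == 0:  # easy zone: home + easy-point sweeps
            open_dp = 1 if first_letter[ctx] == "L" else 2
            if u in (5, 6, 0):
                return u
            if u in (1, 2):
                return u if u == open_dp else a  # barrier: blocked move fails
            return a
        if a in (1, 2):  # a costly decision point and its sweeps
            own_sweeps = task.costly_sweeps_by_easy[a]
            if u in (3, 4, 0, a) or u in own_sweeps:
                return u
            return a
        return a  # final arms handled by the absorbing rule

    emissions: dict[tuple[int, int], list[tuple[int, float]]] = {}
    for ctx in range(4):
        for loc in (0, 1, 2):
            emissions[(loc, ctx)] = [(S3_WHITE, 1.0)]
        for final in (3, 4):
            emissions[(final, ctx)] = _arm_emission(
                rewarded_final[ctx] == final, r, S3_RED, S3_WHITE
            )
        easy_cue = S3_YELLOW if first_letter[ctx] == "L" else S3_BLACK
        easy_miss = S3_BLACK if easy_cue == S3_YELLOW else S3_YELLOW
        for imag in (5, 6):
            emissions[(imag, ctx)] = _sweep_emission(easy_cue, easy_miss, rc)
        for imag in (7, 8, 9, 10):
            match = rewarded_final[ctx] == imagined_final[imag]
            emissions[(imag, ctx)] = (
                _sweep_emission(S3_BLUE, S3_GREEN, rc)
                if match
                else _sweep_emission(S3_GREEN, S3_BLUE, rc)
            )

    utilities = np.zeros(n_loc * task.n_cues)
    for final in (3, 4):
        utilities[final + n_loc * S3_RED] = params.reward_utility
        utilities[final + n_loc * S3_WHITE] = params.loss_utility
    for imag in (5, 6):
        utilities[imag + n_loc * S3_YELLOW] = params.imaginary_cost
        utilities[imag + n_loc * S3_BLACK] = params.imaginary_cost
    for imag in (7, 8, 9, 10):
        utilities[imag + n_loc * S3_BLUE] = params.imaginary_cost
        utilities[imag + n_loc * S3_GREEN] = params.imaginary_cost

    model = _build_model(task, emissions, move, utilities)
    return task, model, enumerate_policies(task)


# ---------------------------------------------------------------------------
# sim4: plentiful-reward T-maze
# ---------------------------------------------------------------------------

S4_RED, S4_WHITE, S4_BLUE, S4_GREEN, S4_DARK_RED, S4_DARK_BLUE = range(6)


def build_plentiful_tmaze(
    params: AgentParams | None = None,
    usual_reward: float = 2.0,
    diff: float = 2.0,
) -> tuple[TaskSpec, GenerativeModel, PolicySet]:
    """Two-arm maze with four contexts and a high-reward option.

    Contexts 1-2 replicate the simple T-maze (one arm baited, utilities
    +-2).  Contexts 3-4 bait both arms: one delivers the usual reward
    (red cue, utility ``usual_reward``), the other the high reward
    (dark-red cue, utility ``usual_reward + diff``); the default
    ``diff = usual_reward`` makes the high reward twice the usual one.
    Imaginary visits recall the corresponding cue (dark-blue for the
    high-reward arm).
    """
    params = params or AgentParams()
    if diff < 0:
        raise ValueError(f"diff must be >= 0, got {diff}")
    task = TaskSpec(
        name="plentiful_tmaze",
        locations=("center", "left", "right", "imag_left", "imag_right"),
        location_kinds=("real", "real", "real", "imaginary", "imaginary"),
        contexts=(
            "reward_left",
            "reward_right",
            "usual_left_high_right",
            "high_left_usual_right",
        ),
        cues=("red", "white", "blue", "green", "dark_red", "dark_blue"),
        absorbing_locations=frozenset({1, 2}),
        horizon=params.horizon or 3,
        home_location=0,
        arm_controls=(1, 2),
        sweep_controls=(3, 4),
        reward_cues=(S4_RED, S4_DARK_RED),
        policy_rule="sweeps_then_arm",
        max_sweeps=2,
        imaginary_cost=params.imaginary_cost,
    )

    n_loc = task.n_locations
    r = params.reward_reliability
    rc = params.context_cue_reliability
    arm_of_imag = {3: 1, 4: 2}
    # per context: arm -> "usual" | "high" | None
    arm_reward = {
        0: {1: "usual", 2: None},
        1: {1: None, 2: "usual"},
        2: {1: "usual", 2: "high"},
        3: {1: "high", 2: "usual"},
    }
    arm_cue = {"usual": S4_RED, "high": S4_DARK_RED}
    sweep_cue = {"usual": S4_BLUE, "high": S4_DARK_BLUE}

    emissions: dict[tuple[int, int], list[tuple[int, float]]] = {}
    for ctx in range(4):
        emissions[(0, ctx)] = [(S4_WHITE, 1.0)]
        for arm in (1, 2):
            kind = arm_reward[ctx][arm]
            if kind is None:
                emissions[(arm, ctx)] = [(S4_WHITE, r), (S4_RED, 1.0 - r)]
            else:
                emissions[(arm, ctx)] = [(arm_cue[kind], r), (S4_WHITE, 1.0 - r)]
        for imag in (3, 4):
            kind = arm_reward[ctx][arm_of_imag[imag]]
            if kind is None:
                emissions[(imag, ctx)] = _sweep_emission(S4_GREEN, S4_BLUE, rc)
            else:
                emissions[(imag, ctx)] = _sweep_emission(sweep_cue[kind], S4_GREEN, rc)

    utilities = np.zeros(n_loc * task.n_cues)
    for arm in (1, 2):
        utilities[arm + n_loc * S4_RED] = usual_reward
        utilities[arm + n_loc * S4_DARK_RED] = usual_reward + diff
        utilities[arm + n_loc * S4_WHITE] = params.loss_utility
    for imag in (3, 4):
        for cue in (S4_BLUE, S4_GREEN, S4_DARK_BLUE):
            utilities[imag + n_loc * cue] = params.imaginary_cost

    model = _build_model(task, emissions, lambda loc, ctx, u: u, utilities)
    return task, model, enumerate_policies(task)


#: task builders addressable by simulation name
TASK_BUILDERS = {
    "sim1": build_two_arm_tmaze,
    "sim2": build_three_arm_radial,
    "sim3": build_double_tmaze,
    "sim4": build_plentiful_tmaze,
}


def build_task(name: str, params: AgentParams | None = None, **kwargs):
    """Build a task by its simulation name (``sim1`` .. ``sim4``)."""
    try:
        builder = TASK_BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown simulation {name!r}; expected one of {sorted(TASK_BUILDERS)}"
        ) from None
    return builder(params, **kwargs)
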