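"""Multi-trial, multi-run experiments and their summary metrics.

A *trial* is one pass through the maze (``horizon`` actions) starting
from the center with the carried-over context prior; a *run* is an
independent agent living through the full trial schedule.  Metrics
mirror the standard read-outs of VTE experiments: per-trial performance
(fraction of runs whose trial ends with a reward cue), normalized
context uncertainty at trial start, the fraction of runs executing at
least one covert sweep (the VTE fraction, split by decision point for
the double T-maze), the 0/1/2+ sweep histogram, and the mean context
belief trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_model import AgentParams, GenerativeModel, PolicySet
from .environment import (
    ContextSchedule,
    EnvState,
    advance_context,
    carryover_prior,
    env_step,
    sample_outcome,
)
from .inference import (
    BeliefState,
    bayes_update,
    belief_from_context,
    evaluate_policy_set,
    policy_posterior,
    select_action,
)
from .tasks import TaskSpec, build_task

#: default trial schedules of the four simulations (1-based change trials)
DEFAULT_SCHEDULES: dict[str, ContextSchedule] = {
    "sim1": ContextSchedule(0, ((11, 1),), n_trials=20),
    "sim2": ContextSchedule(0, ((11, 1), (21, 2)), n_trials=30),
    "sim3": ContextSchedule(0, ((11, 1), (21, 2), (31, 3)), n_trials=40),
    "sim4": ContextSchedule(0, ((10, 1), (20, 2), (30, 3)), n_trials=40),
}

DEFAULT_N_RUNS = 1000


@dataclass(frozen=True)
class TrialRecord:
    """Everything observed in one trial of one run."""

    actions: tuple[int, ...]
    outcomes: tuple[int, ...]
    sweeps: int
    sweeps_by_tag: dict[str, int]
    reward_collected: bool
    reward_magnitude: float
    context_prior_start: np.ndarray
    context_posterior_end: np.ndarray
    chosen_policy_trace: tuple[int, ...]


@dataclass(frozen=True)
class ExperimentResult:
    """Per-trial across-run averages of one simulated experiment."""

    simulation: str
    n_runs: int
    seed: int
    n_trials: int
    performance: np.ndarray
    uncertainty: np.ndarray
    vte_fraction: np.ndarray
    mean_sweeps: np.ndarray
    sweep_hist: np.ndarray  # (n_trials, 3): fraction with 0 / 1 / >=2 sweeps
    context_belief: np.ndarray  # (n_trials, n_contexts), trial-start means
    vte_fraction_easy: np.ndarray | None = None
    vte_fraction_costly: np.ndarray | None = None
    utility_performance: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (trial, metric)."""
        rows = []

        def add(metric: str, values: np.ndarray) -> None:
            for t, v in enumerate(values, start=1):
                rows.append(
                    {
                        "simulation": self.simulation,
                        "trial": t,
                        "metric": metric,
                        "value": float(v),
                        "n_runs": self.n_runs,
                        "seed": self.seed,
                    }
                )

        add("performance", self.performance)
        add("uncertainty", self.uncertainty)
        add("vte_fraction", self.vte_fraction)
        add("mean_sweeps", self.mean_sweeps)
        for k in range(3):
            add(f"sweep_hist_{k}", self.sweep_hist[:, k])
        for k in range(self.context_belief.shape[1]):
            add(f"context_belief_{k}", self.context_belief[:, k])
        if self.vte_fraction_easy is not None:
            add("vte_fraction_easy", self.vte_fraction_easy)
        if self.vte_fraction_costly is not None:
            add("vte_fraction_costly", self.vte_fraction_costly)
        if self.utility_performance is not None:
            add("utility_performance", self.utility_performance)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {
            "simulation": self.simulation,
            "n_runs": self.n_runs,
            "seed": self.seed,
            "n_trials": self.n_trials,
            "performance": self.performance.tolist(),
            "uncertainty": self.uncertainty.tolist(),
            "vte_fraction": self.vte_fraction.tolist(),
            "mean_sweeps": self.mean_sweeps.tolist(),
            "sweep_hist": self.sweep_hist.tolist(),
            "context_belief": self.context_belief.tolist(),
            "config": self.config,
        }
        for name in ("vte_fraction_easy", "vte_fraction_costly", "utility_performance"):
            v = getattr(self, name)
            out[name] = None if v is None else v.tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentResult":
        def arr(x):
            return None if x is None else np.asarray(x, dtype=float)

        return cls(
            simulation=d["simulation"],
            n_runs=d["n_runs"],
            seed=d["seed"],
            n_trials=d["n_trials"],
            performance=arr(d["performance"]),
            uncertainty=arr(d["uncertainty"]),
            vte_fraction=arr(d["vte_fraction"]),
            mean_sweeps=arr(d["mean_sweeps"]),
            sweep_hist=arr(d["sweep_hist"]),
            context_belief=arr(d["context_belief"]),
            vte_fraction_easy=arr(d.get("vte_fraction_easy")),
            vte_fraction_costly=arr(d.get("vte_fraction_costly")),
            utility_performance=arr(d.get("utility_performance")),
            config=d.get("config", {}),
        )


@dataclass(frozen=True)
class GridResult:
    """Mean executed sweeps at a fixed trial over a (c, diff) reward grid."""

    c_values: tuple[float, ...]
    diff_values: tuple[float, ...]
    mean_sweeps: np.ndarray  # (len(c_values), len(diff_values))
    trial_index: int
    n_runs: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "c": c,
                "diff": d,
                "mean_sweeps": float(self.mean_sweeps[i, j]),
                "trial": self.trial_index,
                "n_runs": self.n_runs,
                "seed": self.seed,
            }
            for i, c in enumerate(self.c_values)
            for j, d in enumerate(self.diff_values)
        ]
        return pd.DataFrame(rows)


def run_trial(
    model: GenerativeModel,
    task: TaskSpec,
    policies: PolicySet,
    env: EnvState,
    context_prior: np.ndarray,
    params: AgentParams,
    rng: np.random.Generator,
) -> tuple[TrialRecord, BeliefState, EnvState]:
    """Run one trial: plan, act, observe and update for ``horizon`` steps.

    All policies are re-evaluated from the current belief at every step
    (their already-executed prefix is dropped), the posterior over
    policies is formed with precision ``gamma``, and the action is
    sampled from the step marginal restricted to feasible controls.
    """
    belief = belief_from_context(context_prior, task.home_location, task.n_locations)
    actions: list[int] = []
    outcomes: list[int] = []
    trace: list[int] = []
    sweeps_by_tag: dict[str, int] = {}
    n_sweeps = 0

    for step in range(task.horizon):
        _, _, totals = evaluate_policy_set(belief, policies, model, start=step)
        post = policy_posterior(totals, params.gamma)
        trace.append(int(np.argmax(post)))
        feasible = task.feasible_controls(env.true_location)
        action = select_action(post, policies, step, feasible, rng)
        env = env_step(env, action, task, model)
        outcome = sample_outcome(env, model, rng)
        belief = bayes_update(belief, action, outcome, model)
        actions.append(action)
        outcomes.append(outcome)
        if env.swept:
            n_sweeps += 1
            tag = task.sweep_tags.get(env.outcome_location, "sweep")
            sweeps_by_tag[tag] = sweeps_by_tag.get(tag, 0) + 1

    final_cue = model.obs.outcome_cue(outcomes[-1])
    reward_collected = final_cue in task.reward_cues
    record = TrialRecord(
        actions=tuple(actions),
        outcomes=tuple(outcomes),
        sweeps=n_sweeps,
        sweeps_by_tag=sweeps_by_tag,
        reward_collected=reward_collected,
        reward_magnitude=float(model.prefs.utilities[outcomes[-1]]),
        context_prior_start=np.asarray(context_prior, dtype=float),
        context_posterior_end=belief.context_marginal,
        chosen_policy_trace=tuple(trace),
    )
    return record, belief, env


def _run_records(
    task: TaskSpec,
    model: GenerativeModel,
    policies: PolicySet,
    schedule: ContextSchedule,
    params: AgentParams,
    n_runs: int,
    seed: int,
    n_trials: int | None = None,
) -> list[list[TrialRecord]]:
    """Independent runs of the full trial schedule; run r uses seed+r."""
    n_trials = n_trials or schedule.n_trials
    all_records: list[list[TrialRecord]] = []
    for r in range(n_runs):
        rng = np.random.default_rng((seed + r) % 2**31)
        context_prior = np.full(task.n_contexts, 1.0 / task.n_contexts)
        env = EnvState(true_context=schedule.initial_context,
                       true_location=task.home_location)
        run_records: list[TrialRecord] = []
        for trial in range(1, n_trials + 1):
            env = advance_context(schedule, trial, env)
            env = replace(env, true_location=task.home_location, step=0,
                          outcome_location=None, swept=False)
            record, belief, env = run_trial(
                model, task, policies, env, context_prior, params, rng
            )
            run_records.append(record)
            context_prior = carryover_prior(belief.context_marginal, params.volatility)
        all_records.append(run_records)
    return all_records


def compute_metrics(
    records: list[list[TrialRecord]],
    task: TaskSpec,
    model: GenerativeModel | None = None,
    schedule: ContextSchedule | None = None,
) -> dict[str, np.ndarray]:
    """Across-run per-trial averages of the standard read-outs."""
    if not records or not records[0]:
        raise ValueError("records must be non-empty")
    n_runs = len(records)
    n_trials = len(records[0])
    k = task.n_contexts
    log_k = np.log(k) if k > 1 else 1.0

    performance = np.zeros(n_trials)
    uncertainty = np.zeros(n_trials)
    vte = np.zeros(n_trials)
    mean_sweeps = np.zeros(n_trials)
    hist = np.zeros((n_trials, 3))
    belief = np.zeros((n_trials, k))
    tagged = bool(task.sweep_tags) and any(
        t in ("easy", "costly") for t in task.sweep_tags.values()
    )
    vte_easy = np.zeros(n_trials) if tagged else None
    vte_costly = np.zeros(n_trials) if tagged else None

    for run in records:
        for t, rec in enumerate(run):
            performance[t] += rec.reward_collected
            p = np.clip(rec.context_prior_start, 1e-16, None)
            uncertainty[t] += -(p * np.log(p)).sum() / log_k
            vte[t] += rec.sweeps > 0
            mean_sweeps[t] += rec.sweeps
            hist[t, min(rec.sweeps, 2)] += 1
            belief[t] += rec.context_prior_start
            if tagged:
                vte_easy[t] += rec.sweeps_by_tag.get("easy", 0) > 0
                vte_costly[t] += rec.sweeps_by_tag.get("costly", 0) > 0

    out = {
        "performance": performance / n_runs,
        "uncertainty": uncertainty / n_runs,
        "vte_fraction": vte / n_runs,
        "mean_sweeps": mean_sweeps / n_runs,
        "sweep_hist": hist / n_runs,
        "context_belief": belief / n_runs,
    }
    if tagged:
        out["vte_fraction_easy"] = vte_easy / n_runs
        out["vte_fraction_costly"] = vte_costly / n_runs

    if model is not None and schedule is not None and len(task.reward_cues) > 1:
        # plentiful task: mean collected utility over the per-phase ceiling,
        # the expected final-step utility of the best arm in the true context
        util = np.zeros(n_trials)
        for run in records:
            for t, rec in enumerate(run):
                util[t] += rec.reward_magnitude
        util /= n_runs
        ceiling = np.empty(n_trials)
        n_loc = task.n_locations
        for t in range(n_trials):
            ctx = schedule.context_at(t + 1)
            best = -np.inf
            for arm in task.absorbing_locations:
                s = arm + n_loc * ctx
                exp_u = float(model.A[:, s] @ model.prefs.utilities)
                best = max(best, exp_u)
            ceiling[t] = best
        out["utility_performance"] = util / ceiling
    return out


def run_simulation(
    sim_name: str,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
    params: AgentParams | None = None,
    schedule: ContextSchedule | None = None,
    n_trials: int | None = None,
    **task_kwargs,
) -> ExperimentResult:
    """Run one of the four built-in experiments and aggregate its metrics.

    ``task_kwargs`` are forwarded to the task builder (e.g.
    ``usual_reward`` and ``diff`` for ``sim4``).
    """
    if sim_name not in DEFAULT_SCHEDULES:
        raise ValueError(
            f"unknown simulation {sim_name!r}; expected one of "
            f"{sorted(DEFAULT_SCHEDULES)}"
        )
    params = params or AgentParams()
    schedule = schedule or DEFAULT_SCHEDULES[sim_name]
    task, model, policies = build_task(sim_name, params, **task_kwargs)
    records = _run_records(
        task, model, policies, schedule, params, n_runs, seed, n_trials
    )
    metrics = compute_metrics(records, task, model=model, schedule=schedule)
    return ExperimentResult(
        simulation=sim_name,
        n_runs=n_runs,
        seed=seed,
        n_trials=len(records[0]),
        performance=metrics["performance"],
        uncertainty=metrics["uncertainty"],
        vte_fraction=metrics["vte_fraction"],
        mean_sweeps=metrics["mean_sweeps"],
        sweep_hist=metrics["sweep_hist"],
        context_belief=metrics["context_belief"],
        vte_fraction_easy=metrics.get("vte_fraction_easy"),
        vte_fraction_costly=metrics.get("vte_fraction_costly"),
        utility_performance=metrics.get("utility_performance"),
        config={
            "params": vars(params).copy(),
            "schedule": {
                "initial_context": schedule.initial_context,
                "changes": list(map(list, schedule.changes)),
                "n_trials": schedule.n_trials,
            },
            "task_kwargs": task_kwargs,
        },
    )


def sweep_reward_grid(
    c_values=(0.0, 0.5, 1.0, 1.5, 2.0),
    diff_values=(0.0, 1.0, 2.0, 3.0, 4.0),
    n_runs: int = 10_000,
    trial_index: int = 31,
    seed: int = 0,
    params: AgentParams | None = None,
) -> GridResult:
    """Mean executed sweeps at ``trial_index`` of the plentiful-reward
    protocol, as a function of the usual reward ``c`` and the high-low
    differential ``diff``.

    Each grid cell reruns the full ``sim4`` schedule up to the probe
    trial with arm utilities ``c`` and ``c + diff``.
    """
    if any(d < 0 for d in diff_values):
        raise ValueError("diff values must be nonnegative")
    params = params or AgentParams()
    schedule = DEFAULT_SCHEDULES["sim4"]
    if trial_index > schedule.n_trials:
        raise ValueError("trial_index outside the sim4 schedule")
    grid = np.zeros((len(c_values), len(diff_values)))
    for i, c in enumerate(c_values):
        for j, d in enumerate(diff_values):
            task, model, policies = build_task(
                "sim4", params, usual_reward=float(c), diff=float(d)
            )
            records = _run_records(
                task, model, policies, schedule, params,
                n_runs=n_runs, seed=seed, n_trials=trial_index,
            )
            grid[i, j] = float(
                np.mean([run[trial_index - 1].sweeps for run in records])
            )
    return GridResult(
        c_values=tuple(float(c) for c in c_values),
        diff_values=tuple(float(d) for d in diff_values),
        mean_sweeps=grid,
        trial_index=trial_index,
        n_runs=n_runs,
        seed=seed,
    )
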