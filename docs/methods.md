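# Methods

## Model

The agent is a finite categorical POMDP with hidden states
`s = (location, context)` and outcomes `o = (location, cue)`. The
likelihood `A[o, s]` is deterministic in the location component (the
animal always knows where its body — or its covert focus — is) and
stochastic in the cue; transitions `B[u]` are deterministic per control
state `u`, never change the context within a trial, and make arm states
absorbing. Preferences are log-softmax utilities over outcomes,
`C(o) = u(o) − log Σ exp(u)`, so only utility differences matter.

Imaginary locations implement episodic retrieval: "visiting" one does
not move the body but samples a mnemonic cue (the recalled outcome of
going down that arm) with its own reliability, at a small utility cost.
Policies are fixed-horizon control sequences; steps through imaginary
locations are covert (VTE) steps.

Policy quality is the per-step sum of extrinsic value (expected log
preference of predicted outcomes) and epistemic value (expected
information gain about hidden states), evaluated by propagating the
*current* belief forward through the policy without conditioning on
intermediate outcomes — the standard expected-free-energy form. All
policies are re-evaluated from the current belief at every within-trial
step, so an agent can abandon a policy mid-trial; actions are sampled
from the softmax posterior's current-step control marginal, restricted
to feasible controls (in an absorbing arm only the matching arm control
remains).

Belief updating is exact recursive Bayesian filtering. For this model
family the exact filtering posterior is the fixed point of the
variational scheme; a `free_energy` functional is retained and tested as
an oracle (equality with negative log evidence at the exact posterior,
strict increase under perturbation). Between trials the context
posterior is carried over after volatility mixing
`prior(c) = (1−v)·post(c) + v · Σ_{c'≠c} post(c') / (K−1)`,
the location belief is reset to the home location, and the first trial
starts from a flat context prior.

## Tasks

* **Two-arm T-maze** (`sim1`): 5 locations × 2 contexts, 4 cues,
  horizon 3, 14 policies (2 direct, 4 one-sweep, 8 two-sweep; repeated
  sweeps allowed). 20 trials, contingency reversal at trial 11.
* **Three-arm radial maze** (`sim2`): 7 locations × 3 contexts,
  horizon 4, 48 policies (3 direct, 9 one-sweep, 18 ordered distinct
  two-sweep, 18 three-sweep permutations — unlike the two-arm maze,
  sweep prefixes here are distinct; both enumerations reproduce their
  tasks' policy counts). 30 trials, changes at 11 and 21.
* **Double T-maze** (`sim3`): an easy decision point (recoverable;
  one path blocked by a context-dependent barrier) followed by a costly
  one (absorbing). 11 locations × 4 contexts (path labels LL, LR, RL,
  RR), 6 cues: yellow/black at the easy point partition contexts by
  their first letter, blue/green at the costly points recall the reward
  identity of a final arm. Blocked moves fail in place, so the location
  component of the next outcome reveals the barrier — this is how the
  agent detects a context change mid-trial. Policies (horizon 4) carry
  at most one sweep each, at either decision point: `[e,c,c,c]`,
  `[se,e,c,c]`, `[e,sc,c,c]` → 20 policies. Allowing a second sweep
  per policy would double the covert-policy multiplicity and, under the
  softmax, produce easy-point sweeps at rates comparable to costly-point
  ones, which contradicts the behaviour the task is meant to capture.
  40 trials, contexts LL→LR→RL→RR in blocks of ten.
* **Plentiful T-maze** (`sim4`): the two-arm maze with four contexts —
  two single-reward contexts coded as gain/loss (+2/−2) and two
  both-arms-baited contexts with a usual reward `c` (red cue, default
  2) and a high reward `c + diff` (dark-red cue, default twice the
  usual). Dark-blue is the mnemonic recall of the high reward. 40
  trials, changes at trials 10, 20 and 30. The reward-grid analysis
  reruns this protocol per `(c, diff)` cell and records the mean number
  of executed sweeps at probe trial 31.

Cue conventions shared by all tasks: the baited arm emits the reward
cue with reliability `r = 0.75`, otherwise the neutral cue; unbaited
arms mirror this (neutral with probability `r`). Imaginary locations
emit the context-congruent mnemonic cue with reliability 0.85. The
center and decision-point locations emit the neutral cue
deterministically.

## Parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| `gamma` | 10.0 | — | policy precision (softmax inverse temperature) |
| `volatility` | 0.02 | probability/trial | prior context-change rate |
| `reward_reliability` | 0.75 | probability | reward cue at the baited arm |
| `context_cue_reliability` | 0.85 | probability | mnemonic cue congruence |
| `reward_utility` / `loss_utility` | +2 / −2 | log-preference units | gain/loss coding of arm outcomes |
| `imaginary_cost` | −0.25 | log-preference units | cost of one covert sweep |

Reliabilities and the ±2 utilities are fixed by the task definitions.
The sweep cost is set intermediate between the gain and the loss, which
is the regime in which deliberation is worth paying for. Volatility is
"small" by assumption; 0.02 keeps between-trial confidence high enough
for habitization while leaving beliefs revisable after a reversal.

`gamma` has no externally fixed value and was **calibrated once**, over
a coarse grid, against the joint set of qualitative patterns the four
experiments must show (VTE extinction and post-reversal reinstatement;
single-sweep preference in the radial maze; costly-point specificity
and the larger burst at the LR→RL reversal; suppression under plentiful
reward; grid threshold near usual-reward ≈ 1). Low precision (γ ≈ 2)
leaves a persistent ~20% VTE floor — the softmax spreads mass over the
twelve sweep-containing policies even when they are clearly inferior —
while γ = 10 yields near-complete extinction with prompt reinstatement
and was frozen as the default. All parameters are config-overridable.

## Metrics

Per trial, averaged over independent runs (default 1000; run *r* uses
seed `base_seed + r`): **performance** is the fraction of runs whose
final within-trial outcome is a reward cue, which puts the ceiling at
the reward reliability (0.75); **uncertainty** is the Shannon entropy
of the trial-start context belief normalized by `ln K`; the **VTE
fraction** is the fraction of runs that executed at least one covert
sweep (split by decision point in the double T-maze), counting only
realized covert visits — a sweep attempt the maze geometry blocks moves
nothing and counts nothing; the sweep histogram bins runs by 0 / 1 / ≥2
executed sweeps; the context-belief heatmap is the mean trial-start
posterior. The plentiful task additionally reports mean collected
utility normalized by the per-phase ceiling (the best arm's expected
final-step utility under the true context).

## Numerical choices

Probabilities are floored at 1e-16 inside logarithms; epistemic values
in [−1e-12, 1e-12] are snapped to exactly zero (they are analytic
zeros suffering cancellation). Policy evaluation is vectorized across
the policy set by grouping policies that share a control at each step;
a scalar per-policy path is kept and the two are cross-checked in the
tests. The policy softmax subtracts the maximum before exponentiating.
Ties in action sampling are resolved by the seeded generator; policy
enumeration order is deterministic.

## What the simulations do and do not show

All data are self-generated by the built-in generative processes: cue
stochasticity is the only noise source, contexts change on a fixed
schedule, and the agent's model matches the process exactly (no
learning of contingencies, no precision dynamics, no model mismatch).
Passing tests therefore show that the *policy-selection principle*
produces the documented VTE phenomenology under matched generative
assumptions — not that real rodents implement this computation, and not
how the behaviour degrades when cue reliabilities or context structure
must be learned. Quantitative trial-by-trial traces also depend on the
precision calibration above; only the qualitative patterns are asserted.

Test-suite experiment sizes are 150–200 runs (and a reduced reward
grid at 100 runs per cell), chosen so the asserted patterns are far
outside sampling noise while the whole suite stays fast; the library
default remains 1000 runs (10,000 for the grid).

## Known limitations

* Expected free energy is evaluated without conditioning on
  intermediate predicted outcomes, so information that two steps of a
  policy both deliver is counted twice; this is the standard form but
  it inflates the epistemic value of redundant step combinations.
* Reward re-consumption at absorbing arms (one outcome per remaining
  step) implicitly discounts late arrivals but also lets repeated arm
  observations accrue epistemic value each step.
* γ is fixed per experiment; precision dynamics, contingency learning,
  and the question of *where* sweeps are directed are out of scope.
* The double T-maze compresses the two costly decision points' four
  endpoints into two shared final arms; context is then the (open path,
  baited arm) pair.
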