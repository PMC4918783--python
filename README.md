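# epistemaze

Discrete active-inference agents foraging in T-mazes, built to study
**vicarious trial and error (VTE)**: the pause-and-deliberate behaviour
rodents show at maze choice points, whose neural correlate is the
hippocampal "forward sweep". The package models forward sweeps as
*covert epistemic actions* — visits to imaginary maze locations that
retrieve a mnemonic cue at a small utility cost — and lets policies that
contain them compete with direct reward-seeking policies on a single
currency: expected free energy.

## Who this is for

Computational neuroscientists and cognitive modellers who want a small,
fully seeded, pure-Python sandbox for the exploration–exploitation
trade-off between deliberative (epistemic) and habitual (extrinsic)
policies in discrete POMDPs, with the four classic maze experiments
built in.

## The model

The agent is a categorical POMDP. Hidden states factor into a *location*
(center, arms, and imaginary arm locations) and a *context* (which arm
is baited). Outcomes are (location, cue) pairs; the reward cue appears
at the baited arm with reliability 0.75, and imaginary locations emit a
context-congruent mnemonic cue with reliability 0.85. Preferences are
the log-softmax of outcome utilities (reward +2, wrong-arm experience
−2, mnemonic cue −0.25 — the cost of a sweep).

The quality of a policy π at future step τ is

```
Q_τ(π) = E_{Q(o_τ|π)}[ ln P(o_τ|m) ]  +  E_{Q(o_τ|π)}[ KL( Q(s_τ|o_τ,π) ‖ Q(s_τ|π) ) ]
         └────── extrinsic value ──────┘  └──────────── epistemic value ────────────┘
```

summed over the remaining steps, and policies are selected through a
precision-weighted softmax `P(π) ∝ exp(γ · Q(π))` with the action
sampled from the current-step marginal. Beliefs follow exact Bayesian
filtering; between trials the context posterior becomes the next prior
after mixing with a small volatility term (the prior belief that the
world may have changed).

Four tasks ship as named builders: `sim1` (two-arm T-maze, 10 states /
20 outcomes / 14 policies), `sim2` (three-arm radial maze, 21 / 28 / 48),
`sim3` (double T-maze with an easy and a costly decision point, 44
states, 11 controls), and `sim4` (two-arm maze with plentiful-reward
contexts, 14 policies).

## Worked example

```python
import epistemaze as em

result = em.run_simulation("sim1", n_runs=200, seed=7)
for t in (1, 2, 10, 11, 12, 20):
    print(t, round(result.performance[t-1], 3),
          round(result.uncertainty[t-1], 3),
          round(result.vte_fraction[t-1], 3))
```

prints (trial, performance, context uncertainty, VTE fraction):

```
1 0.59 1.0 0.63
2 0.66 0.528 0.0
10 0.68 0.238 0.005
11 0.275 0.25 0.01
12 0.35 0.646 0.045
20 0.75 0.26 0.005
```

Read: on trial 1 the context is unknown (uncertainty 1.0) and 63% of
runs execute at least one covert sweep; after one trial of evidence the
sweeps all but vanish and performance sits near its 0.75 ceiling (the
reward-cue reliability). The baited arm switches on trial 11:
performance collapses, uncertainty spikes, and VTE transiently
reappears before the agent re-habituates.

The same experiments are available from the shell:

```bash
epistemaze sim1 --runs 200 --seed 7 --out sim1.csv --json-out sim1.json --plot sim1.png
epistemaze validate sim3
epistemaze sweep --runs 100 --seed 7 --out grid.csv   # sweeps vs (c, diff)
```

CSV output is tidy (`simulation, trial, metric, value, n_runs, seed,
config_hash`); experiments are bit-reproducible given the same seed and
configuration.

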