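# resdec

Models of **choice-based learning (CBL)** — the phenomenon where making a
decision raises the probability of making the same decision again — built
around the *local reservoir* idea: every decision dissipates energy into a
finite local environment, and the environment's occupancy feeds back on
the next decision.  A small reservoir gets imbalanced by a single choice
and drives repetition; a large one absorbs choices without a trace.

The package is for computational-neuroscience and physics-of-decision
researchers who want to simulate, solve and fit this model family:

* `resdec.reservoir` — stochastic simulator of the discrete reservoir: `N`
  lower and `N+1` upper fermionic energy levels; Decision L excites lower
  level *i* to upper *i+1*, Decision R to upper *i*; consumed levels
  recover after a `lifetime` of τ cycles (deterministic or memoryless).
  Decision-consistency curves, random-walk views, active-portion
  statistics.
* `resdec.rate_model` — the exact continuous-time Markov chain over all
  2^(2N+1) occupation micro-states with rates (γ_in, γ_up, γ_out):
  generator construction, steady state, and the decision-transition
  probabilities P(L→L), P(L→R) via an embedded-jump-chain first-passage
  solve, with the CBL imbalance P(L→L) − P(L→R); an exact Gillespie
  simulator serves as an independent cross-check.
* `resdec.photon` — a single-photon decision maker: Malus-law detection
  (cos²θ at the horizontal port), waveplate update ±π/R after each
  detection, strict termination outside [0, π/2].  The resolution R plays
  the reservoir-size role.
* `resdec.behavior` — repetition-consistency scoring for paired-preference
  experiments (28 items × 8 appearances, 112 trials), the learning score
  `max(c_2..c_7) − c_1 + 0.5`, a synthetic participant with
  choice-induced preference change, and reservoir-size estimation by
  inverting the model's consistency-versus-N curve.
* `resdec.cli` — the `resdec` command line (`simulate-reservoir`,
  `analytic`, `simulate-photon`, `behavior-score`, `estimate-n`,
  `fixtures`, `run`), with reproducibility sidecars for every output.

## Worked example

How consistent is a small reservoir (N=4, lifetime 10) with its earlier
decisions?

```python
from resdec.reservoir import ReservoirConfig, decision_consistency_curve

curve = decision_consistency_curve(
    ReservoirConfig(n_levels=4, lifetime=10),
    t0=2000, lags=[1, 2, 5, 10, 20, 50], n_runs=10_000, seed=42,
)
for lag, m in zip(curve.lags, curve.mean_consistency):
    print(f"lag {lag:3d}  consistency {m:.3f}")
```

```
lag   1  consistency 0.666
lag   2  consistency 0.675
lag   5  consistency 0.809
lag  10  consistency 0.809
lag  20  consistency 0.731
lag  50  consistency 0.634
```

Two-thirds of runs repeat their reference decision one cycle later — far
above the 0.5 chance level — and the correlation persists for tens of
cycles.  (The hump at lags 5–10 is the burst/stall phase-locking this
small, deterministic-recovery reservoir exhibits; see `docs/methods.md`.)
With `n_levels=100` the same curve sits at 0.5 everywhere: a large
environment shows no CBL.

The analytic counterpart, from the shell:

```bash
$ resdec analytic --n-levels 2 --gamma-in 1 --gamma-up 1 --gamma-out 10
{
  ...
  "n_states": 32,
  "p_LL": 0.5051,
  "p_LR": 0.4949,
  "imbalance": 0.0102
}
```

A clogged reservoir (slow γ_out) repeats itself: P(L→L) exceeds P(L→R) by
0.0102.  With `--gamma-up 10 --gamma-out 1` the imbalance flips to −0.065:
fast cycling erases CBL.

Scoring behavioral data and mapping it back to a reservoir size:

```bash
resdec behavior-score --in choices.csv --curve curve.json --out score.json
resdec estimate-n --consistency 0.66 --runs 10000 --seed 7 --out est.json
```

`behavior-score` expects a CSV with columns `trial,item_a,item_b,chosen`
and reports the per-repetition consistencies `c_1..c_7`, the learning
score, and (given a model curve) the estimated reservoir size `n_hat`.

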