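# chaseambush

Game-theoretic analysis of predator–prey attack and defense behaviors.

Predators attack by **chasing** (speeding up) or **ambushing** (stopping and
waiting); prey defend by **escaping** or **freezing**. This package asks which
of these behaviors are Nash equilibria when both sides can only sense the
*presence* of the opponent within a detection distance — no directional
information — and respond by changing speed. It provides:

- **`grid_world`** — exact enumeration of single-step encounter probabilities
  between one predator ("wolf") and one prey ("sheep") on a 5×5 lattice.
  Each agent has a detection radius `D ∈ {0, 1, 2}` (Chebyshev cells) and a
  speed delta `S ∈ {−1, 0, 1}`: on detecting the opponent it moves at speed
  `1 + S` instead of the default 1. The encounter probability
  `p = encounters / total cases` is an exact rational; the 3×3 bimatrix with
  prey payoff `1 − p` and predator payoff `p` is a constant-sum game.
- **`nash`** — a bimatrix Nash solver by exhaustive support enumeration with a
  best-response certificate, handling degenerate games (ties, extinct-player
  conditions) and classifying equilibria as pure, mixed, partially mixed or
  indeterminate.
- **`abm`** — a continuous-space torus individual-based model (a wolf–sheep
  predation ecology): sheep graze, wolves eat co-located sheep, both reproduce
  by energy-halving splits and pay per-tick costs
  `c_e + (d + |S|)·c_b + speed·c_m`. Two behavioral algorithms are supported:
  *sensory–motor* (speed changes to `1 + S` on detection within `D = d·f`,
  `f = 10`) and *non-sensory motor* (speed changes with fixed probability `K`,
  no sensing).
- **`payoffs`** — per-tick payoffs from encounter counts,
  `P_w = E/N_w`, `P_s = 1 − E/(E + N_s)`, window averaging, and assembly of
  11×11 payoff bimatrices over the speed-delta grid (empirical
  game-theoretic analysis of the simulated population as a pool of players).
- **`experiments`** — assignment of solved equilibria back into the simulator
  (mixed strategies realized as per-event behavioral switching), switching
  reports, and sensory vs non-sensory algorithm comparisons.

## Worked example

Both agents detecting at the outer edge of a radius-2 range (adjacent starts
excluded) produces a fully mixed equilibrium — behavioral switching:

```python
import numpy as np
from chaseambush import grid_bimatrix, find_equilibria

game = grid_bimatrix(D_w=2, D_s=2)      # exact rational 3x3 bimatrix
eq = find_equilibria(game)[0]
print(dict(zip(game.row_labels, np.round(eq.prey_mixture, 3))))
print(dict(zip(game.col_labels, np.round(eq.predator_mixture, 3))))
print(round(eq.prey_value, 4), round(eq.predator_value, 4), eq.classification)
```

prints

```
{-1: 0.139, 0: 0.499, 1: 0.363}
{-1: 0.139, 0: 0.499, 1: 0.363}
0.9773 0.0227 mixed_both
```

i.e. the prey escapes (`S_s = +1`) with probability 0.363, keeps its speed
with 0.499 and freezes with 0.139; by the game's role-swap symmetry the
predator's chase/no-change/ambush mixture is identical. The equilibrium
payoffs sum to 1 exactly (a constant-sum contest). At other detection
combinations the equilibria are pure: e.g. at `(D_w, D_s) = (1, 0)` the
predator ambushes (`S̄_w = −1`), at `(1, 1)` the predator keeps speed while
the prey escapes, and a prey that senses at radius 2 freezes under the
single-step rule but escapes once adjacent starts (two-step interactions)
are allowed.

The same pipeline runs at population scale:

```bash
chaseambush fixture --profile fast --out plan.yaml
chaseambush abm-sweep --config plan.yaml --out sweep.csv
chaseambush grid-probs --variant single --out landscape.csv
chaseambush grid-nash --variant single --out equilibria.json
```

`abm-sweep` simulates every (S_s, S_w) cell of the plan, from which payoff
bimatrices, equilibria (`nash-solve`), equilibrium-assignment measurements
(`eq-run`) and landscape heatmaps (`plot`) follow. In the multi-agent
setting the payoff sum `P_s + P_w` exceeds 1 whenever `E + N_s > N_w`, so
these games are typically positive-sum rather than constant-sum.

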