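# Methods

## The single-pair grid world

One predator is anchored at the centre `(2, 2)` of a 5×5 lattice and one prey
is placed at every other admissible cell. Detection is evaluated once, on the
initial positions, using Chebyshev distance (the Moore-neighborhood metric):
agent *i* with radius `D_i` detects the opponent iff the distance is `≤ D_i`,
and then moves at speed `1 + S_i` instead of the default 1. Both agents then
take one synchronous step and an encounter is scored iff they occupy the same
cell at the end of the step (no pass-through or swap captures).

**Movement.** An agent moving at speed `s` lands on a uniformly chosen cell of
the Chebyshev ring of radius `s` around its start — its set of possible next
positions: 1 case for speed 0 (a stationary agent contributes a single case,
not eight), the 8 Moore neighbours for speed 1, the 16 ring-2 cells for
speed 2. The lattice bounds only constrain the initial placement; the step is
taken on an unbounded plane, so only the relative displacement matters and
the predator/prey role-swap symmetry `p(D, D, a, b) = p(D, D, b, a)` holds
exactly. This ring convention was selected by validating candidate movement
rules against the known mixed-equilibrium solution of the radius-2 game; the
alternative "two cells along one Moore heading" rule (8 endpoints at speed 2)
produces a different, incorrect mixture.

**Variants.** Under `single_step_exclusive`, initial placements at Chebyshev
distance 1 from the anchor are dropped whenever either radius is 2 — at the
outer edge of a radius-2 range the agents would already have detected each
other before becoming adjacent. `adjacent_inclusive` keeps those placements,
which is equivalent to admitting a two-step interaction; it flips the prey's
long-range equilibrium from freeze to escape when the prey out-senses the
predator.

**Exactness.** Encounter probabilities are `fractions.Fraction` ratios; the
3×3 bimatrix (prey `1 − p`, predator `p`) is constant-sum exactly, cell by
cell. Decimal rendering (3 decimals, round-half-even) happens only at
serialization.

## The Nash solver

Games are small (3×3 and 11×11), so equilibria are found by exhaustive
support enumeration: for each candidate support pair the opponent mixtures
are solved from the indifference conditions (pairwise payoff-difference
equations plus normalization; a square solve when support sizes match, least
squares otherwise) and kept only if they are valid probability vectors and
pass the best-response certificate — no pure strategy may exceed the
equilibrium value by more than `tol` (1e−9 for rational inputs, 1e−7 for
simulation-derived payoffs). Mixture entries below 1e−12 are snapped to zero
and renormalized. Duplicates within tolerance are merged and the output is
ordered lexicographically by support then mixture, making the solver
deterministic.

For games up to 6 strategies per side all support pairs (including
unequal-size pairs, needed for degenerate games) are enumerated; for larger
games the default restricts to supports of size ≤ 4, which covers the
small-support equilibria these payoff landscapes produce while keeping the
11×11 case tractable.

**Classification.** `pure` (two singleton supports), `mixed_both` (both ≥ 2),
`mixed_partial` (exactly one ≥ 2), and `indeterminate` when a player's payoff
does not depend on its own strategy at all — each column (row) of its table
constant within tolerance, as for an extinct predator whose payoffs are
identically zero. Note that flatness *given the equilibrium mixture* would be
the wrong test: indifference across the support is the defining property of
any mixed equilibrium.

**Selection.** All equilibria are reported. Where a downstream consumer needs
one representative, the rule is: a unique equilibrium as-is; otherwise the
equilibrium whose two-point supports sit on the extreme speed deltas (the
chase/ambush × escape/freeze corners); otherwise the first both-side-mixed
one; otherwise the first in deterministic order.

## The individual-based model

A torus of `width × height` integer patches, agents at real-valued
coordinates. Each tick runs three phases:

1. **Prey phase.** Every sheep senses (Euclidean distance with torus wrap,
   on pre-move positions), chooses its speed, turns uniformly within ±45° and
   advances; on a green patch one uniformly chosen co-located sheep eats
   (gains `sheep_gain_from_food`, patch turns brown); each sheep pays its
   tick cost, reproduces with probability `sheep_reproduce`% (parent energy
   halves, offspring inherits traits and position), and dies if energy ≤ 0.
2. **Predator phase.** Same sense→choose→move; each wolf, in a fresh random
   order, eats exactly one uniformly chosen sheep on its patch (if any),
   incrementing the encounter count `E` and gaining `wolf_gain_from_food`;
   costs, reproduction with probability `r`%, death as above.
3. **Grass phase.** Brown patches count down `grass_regrowth_time` ticks and
   regrow.

`E`, `N_w`, `N_s` are recorded after all interactions; `N_s` excludes sheep
eaten that tick, so `E + N_s` is the pre-interaction prey count. Offspring do
not act in their birth tick. Speed is clamped at 0 (`S = −1` is a full stop;
stationary agents still turn).

**Costs.** Per tick, `c_e + (t + |S|)·c_b + speed_factor·c_m` with
`speed_factor = 1 + S` on speed-change ticks and 1 otherwise; `t` is the
sensory investment `d` (sensory algorithm) or the switch probability `K`
(non-sensory). The detection distance is `D = d·f` with sensitivity factor
`f = 10`; the cost is charged on the investment `d`, not the realized
distance. For a mixed strategy the realized draw of `S` enters the cost on
change ticks; on unchanged ticks the mixture's mean `|S|` stands in (for the
two-point `{+1, −1}` mixtures that occur in practice, `|S| = 1` either way).

**Defaults.** 51×51 patches, 100 sheep, 50 wolves, gains 4 (sheep) / 20
(wolf), 30-tick regrowth, 4% sheep reproduction, `c_e = c_m = 0.5` (one
energy unit per unchanged tick at `c_b = 0`), initial energy uniform on
(0, 2·gain), half the patches initially green. `r` and `c_b` are the swept
condition variables. Horizon 11,000 ticks with measurement window
[10,000, 11,000). Every run derives its generator from
`SeedSequence(master_seed, (condition, cell, repeat))`, so sweeps are
reproducible cell-by-cell regardless of execution order.

## Payoffs and empirical games

Per tick, `p_w = E/N_w` and `p_s = E/(E + N_s)`; payoffs `P_w = p_w`,
`P_s = 1 − p_s`, `P_diff = P_s − P_w`. Ratios are computed per tick and then
averaged over the window — not the ratio of window means, which differs
whenever the denominators fluctuate. An empty predator roster contributes
`p_w = 0` (mass at `P_w = 0` marks predator extinction); an empty
pre-interaction prey roster contributes `p_s = 0` and flags prey extinction.
The game sum classifies as constant (`|P_s + P_w − 1| ≤ 1e−9`), positive or
negative; with live predators the sign of `P_s + P_w − 1` equals the sign of
`(E + N_s) − N_w`.

The population is treated as a pool of players: the window-mean `P_s` and
`P_w` of the run with fixed `(S_s, S_w)` fill one cell of an 11×11 (or
smaller) bimatrix per condition `(d or K values, c_b, r)`. Both the
across-repeat mean matrix (the default solver input) and the per-repeat
matrices are emitted, since switching statistics are also of interest per
repeat.

**Equilibrium assignment.** A solved mixture is realized per triggered event:
on each tick where the speed change fires, the agent redraws `S` from the
equilibrium mixture — this is what makes individuals visibly switch between
chase and ambush (or escape and freeze). Per-birth assignment (each agent
fixes one `S` at birth) is available as a sensitivity option. Runs grouped by
window-mean `E` use a closed boundary: `E = 4` exactly falls in the `≤ 4`
group. Algorithm comparisons use Mann–Whitney rank tests reported
descriptively (statistic, p-value and a probability-of-superiority effect
size) alongside binned proportions.

## Desk-scale problem sizes

The test suite runs everything at desk scale, as the package's own choice of
test geometry:

- grid world: full 81-combination enumerations per variant (exact, instant);
- solver checks: 50 random games (3×3 and 11×11) against an independently
  coded exhaustive 3×3 oracle and the best-response certificate;
- IBM: a 15×15 "tiny" world (30 sheep, 8 wolves, 150 ticks) for bookkeeping
  audits, and a 25×25 "fast" world (80 sheep, 20 wolves, 800 ticks, window
  [500, 800)) for distributional checks and the sweep → solve → assign →
  measure pipeline. The fast world is the smallest scanned configuration
  that sustains predator–prey coexistence; an 11×11 world with ≤ 10 agents
  per side collapses to extinction before the window and measures nothing.

What desk scale does *not* show: the full-scale switching probabilities at
the mutual radius-2 condition. At 25×25 the mutual-detection game is
dominated by predator extinction (`P_w ≈ 0` across cells), and its
equilibrium bears no resemblance to the near-even chase/ambush mixture that
emerges at full scale; reproducing that number requires the 51×51 world,
the 11-point speed grid and multi-repeat 11,000-tick runs (hours on one
CPU), and is exposed through the `full_paper` fixture profile rather than
the test suite. The corresponding test documents this gap and fails at desk
scale rather than asserting a weakened claim.

## Known limitations

- The simulator is synchronous-by-phase (all sheep act, then all wolves);
  within-phase conflicts (grass, predation) are resolved by uniform random
  choice, which matches sequential random-order semantics distributionally
  but not trace-by-trace.
- Energy-ledger event logging is exact but memory-heavy; it is intended for
  short audit runs, not full sweeps.
- Support enumeration is complete only up to the configured support-size cap
  for games larger than 6×6; equilibria of an 11×11 game with support ≥ 5 on
  both sides would be missed (none of the empirical payoff landscapes
  examined produce them).
- Evolutionary stability (invasion analysis of the equilibria) is out of
  scope; equilibria are computed for fixed trait pairs only.
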