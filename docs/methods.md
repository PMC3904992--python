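# Methods

## Model

The Social Honesty game couples a stochastic two-player game to
imitation dynamics on an interaction graph. Strategies are binary
(honest `H`, dishonest `D`); payoffs of a single interaction are random
variables:

* `H–H`: both players receive the constant reward `R`.
* `H–D`: the honest player receives 0. The dishonest player is punished
  with probability `p_hd` (payoff `−s`), otherwise receives the
  advantage `b`.
* `D–D`: each player is caught independently with probability `p_dd`
  (payoff `−s`). Only when **neither** is caught does a fair coin award
  `b` to one player and 0 to the other; if exactly one is caught, the
  uncaught partner receives 0.

Every unordered adjacent pair interacts exactly once per round and both
players see the same realization — an interaction is a single joint
transaction, not two independent experiences. A player's round gain is
the raw (not degree-normalized) sum over her interactions. Punishment
*replaces* the would-be gain with `−s` rather than subtracting `s` from
it, so `s = 0` still bites: it strips the dishonest gain.

The expected payoffs implied by the rule are `R` (H in H–H),
`b(1−p_hd) − s·p_hd` (D against H), and `b(1−p_dd)²/2 − s·p_dd` per
player in D–D. The quadratic factor is the point where the rule's two
readings diverge: awarding the coin win to an uncaught player even when
the partner was caught would give `b(1−p_dd)/2 − s·p_dd` instead. We
use the strict no-punishment-win reading. It follows the rule's literal
"if no player is punished" clause, and it is the completion whose
collective behavior matches the published reference points: with it,
the smallest full-fixation punishment probability at severity 8 lands
at ≈0.28–0.29 (reference 0.295), and the severity-2 transition interval
contains stable mixed equilibria near 60% honest; with the permissive
reading, the critical probability shifts to ≈0.315 and the mixed
plateau at the interval midpoint disappears.

### Update rules

Strategy revision is synchronous; all players decide from the same
payoff snapshot. Homogeneous populations are absorbing under every
rule (there is no mutation).

* **best** — copy the strategy of the maximum-payoff candidate among
  self and neighbors. If the player herself attains the maximum she
  keeps her strategy; otherwise ties are broken uniformly among the
  maximal neighbors. Including the player's own payoff in the
  comparison is the standard spatial-evolutionary-game convention; the
  self-excluded literal variant (always adopt the best neighbor) is
  available via `include_self=False` for sensitivity runs — it deepens
  the early crash of honesty but destroys cluster-driven recovery.
* **best_myopic** — with probability `q` (default 0.9) apply the best
  decision, otherwise copy a uniformly random neighbor.
* **best_fermi** — adopt the best neighbor's strategy with probability
  `1/(1 + exp((π_self − π_best)/K))`, else keep one's own. `K`
  (default 0.1) is the selection temperature; `π_best` is the maximum
  payoff among neighbors, self excluded, of raw payoff totals (not
  per-interaction averages).

A uniform choice among tied maximal neighbors is realized as a single
Bernoulli draw with success probability (#honest maximal)/(#maximal);
this is exactly equivalent and keeps the random-number budget at one
draw per player per decision.

### Topologies

Lattices are periodic (toroidal) in both axes; Moore (Chebyshev ball)
and von Neumann (Manhattan ball) neighborhoods with radius ≥ 1.
`well_mixed` is the complete graph. `scale_free` is a Barabási–Albert
preferential-attachment graph with attachment parameter `m` (default 4,
chosen so the mean degree ≈ 8 matches Moore radius 1, making
neighborhood comparisons degree-fair), mapped onto the lattice cells by
a seeded random permutation; the mapping affects visualization only.
The attachment is non-spatial — nothing constrains edges by lattice
distance.

## Parameter defaults

| parameter | default | meaning |
|-----------|---------|---------|
| `R`       | 1       | H–H reward (payoff units; sets the scale) |
| `b`       | 3       | dishonest advantage when unpunished |
| `s`       | 2       | punishment severity (punished payoff −s) |
| `p_hd`, `p_dd` | 0.45 | punishment probabilities (shared `p` unless split) |
| lattice   | 100×100, Moore r=1 | study-scale world |
| rounds    | 500     | measurement horizon for sweeps |
| `q`       | 0.9     | myopic mixing weight |
| `K`       | 0.1     | Fermi temperature |

`R = 1` is the conventional normalization; all other payoffs are
interpreted relative to it. The default `p = 0.45` sits inside the
severity-2 transition interval measured by this implementation
(lower ≈ 0.42, upper ≈ 0.46 with the full-fixation criterion), which is
where the scientifically interesting mixed dynamics live.

## Initial states and what they emulate

* `random_state` places an **exact** count `round(f·n)` of honest cells
  uniformly at random — "50% honest" is literal, which removes
  initial-rate variance from small-lattice experiments (an i.i.d.
  Bernoulli field would not).
* `single_dissident_state` puts one deviant in the middle of a uniform
  field.
* `evolved_cluster_state` produces naturally clustered worlds by
  evolving a 50% random start under caller-chosen `(p, s)` and
  capturing the first state whose honest rate enters a tolerance band
  around the target. The capture-on-first-hit rule means a `min_rounds`
  burn-in (default 0) is advisable for low targets, because the crash
  phase of the dynamics can cross a low band before clusters have
  formed.

These generators emulate the study conditions, not empirical data: real
social networks have degree heterogeneity, community structure and
noisy, asynchronous decision-making that the synchronous lattice model
deliberately abstracts away. Passing tests therefore validate the
model's internal dynamics, not its calibration to any real population.

## Summary statistics

* **Honest rate** — fraction of H cells.
* **Granularity** — `1 − mean_rows(#adjacent within-row strategy
  changes)/(cols−1)`, scanned along rows without wrap-around. Random
  50% mixtures score ≈0.5, few large clusters score →1, a checkerboard
  scores 0. The scan is deliberately row-only; adding a column scan
  would change the baseline values.
* **Transition interval** — from a sweep of final rates (measured at
  round 500, averaged over replicates): the lower bound is the largest
  grid value whose mean final honest rate is ≤ `eps_low` (default
  0.01); the upper bound is the smallest value where *every* replicate
  fixates at 1.0 (`full_fixation`; a mean-threshold criterion is
  available). If the sweep never shows dishonest domination the lower
  bound is reported as `−inf`.
* **Critical probability** — smallest `p` on a scan grid with full
  fixation across replicates, refined once at a fifth of the step.

## Numerical choices

* One RNG stream per simulation (`numpy` PCG64 via `SeedSequence`);
  sweeps derive child seeds from the master seed and the (scaled)
  parameter value plus run index, so enlarging `n_runs` never perturbs
  existing runs.
* The lattice backend draws uniforms in a fixed layout (per half-offset:
  focal punishment draw, partner punishment draw, winner coin) and is
  implemented twice — numba-compiled loops and a numpy roll-based
  fallback — consuming identical streams; the test suite asserts
  bit-identical trajectories. Arbitrary graphs use an edge-list backend
  with the same payoff rule but a different draw order, so lattice and
  graph backends agree in distribution, not draw for draw.
* Homogeneous states are absorbing, so simulations early-stop on
  fixation and pad the trajectory with the constant rate.
* The Fermi exponent is clipped to ±700 before exponentiation.
* Degenerate inputs: lattices must satisfy `rows, cols ≥ 2·radius+1`
  (otherwise wrap-around would duplicate pairs); scale-free graphs
  require `1 ≤ m ≤ n−2`; granularity needs ≥ 2 columns.

## Scales used in the shipped checks

The test suite and `scripts/acceptance.py` rerun the study protocol at
desk scale, as this package's own choice of replication: transition
sweeps with 8–16 replicates per grid value (the study protocol uses
100), the severity-8 critical-probability pilot with 25 replicates at
0.005 resolution on a targeted window, plateau estimates from 15–40
replicates of 400 rounds, and evolved-state granularity over 3–10
seeds per case. Interval bounds from the coarse 0.02-step sweep are
refined at 0.005 resolution (`refine_interval_bounds`) before the
midpoint is used, so the midpoint is not quantized to the coarse grid;
the reported statistics are means over replicates.

## Known limitations

* The round-3 collapse depth at the severity-2 interval midpoint is
  ≈20% honest in this implementation; reference accounts of the same
  experiment report ≈2% together with the ≈60% recovery plateau. No
  payoff completion consistent with replacement punishment and a
  meaningful `s = 0` severity row reproduces both simultaneously (an
  additive `b−s` punishment reproduces the 2%→60% trajectory shape but
  makes `s = 0` punishment a no-op and shifts the critical
  probabilities upward); we keep the completion that matches the
  critical-probability and plateau references and report the collapse
  depth as computed.
* No mutation/exploration noise, no asynchronous updating, no memory or
  reputation; dishonesty cannot re-invade an all-honest population.
* Payoffs on heterogeneous-degree graphs are raw sums, which favors
  hubs; this is intentional but means scale-free results are not
  degree-normalized.
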