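# Methods

## Model

A gene regulatory network over `N` genes is a directed signed graph with a
nested canalyzing function (NCF) per gene. An NCF is an ordered list of
tuples `(v, I, O)` — regulator, canalyzing value, canalyzed value — with
pairwise-distinct regulators, no self-loops, and at least one tuple; the
default output is pinned to the complement of the last tuple's canalyzed
value, so a rule's behaviour is fully determined by its tuple sequence.
Updates are synchronous and deterministic; every trajectory reaches a fixed
point or a limit cycle. Perturbations are modelled as clamps: a knocked-out
gene is held at 0 and an overexpressed gene at 1 for the entire trajectory,
initial state included. The sign of a regulation is `+1` when `I = O` and
`−1` otherwise; flipping both bits of a tuple changes the logical role of
the regulator (conjunctive vs. disjunctive position) without changing the
interaction sign, which is what the sign-preserving mutation exploits.

Self-loops are forbidden globally, not just at insertion: allowing them
anywhere would let a rule trivially memorize its own state and would
complicate the constraint semantics for no modelling gain.

## Experiment replay and scoring

Every dataset row is replayed on a candidate network: the initial state is
the Boolean expression of the row's base wild-type experiment (the row
itself for wild-type rows), the row's clamp is applied, and the trajectory
is followed to its attractor. Per-gene similarity is the fraction of
attractor states agreeing with the observed value; the row score is the
mean over genes, the dynamics accuracy the mean over rows, and the per-gene
average over rows (`s̄_i`) feeds the mutation heuristic. When several
wild-type rows exist each perturbation row uses exactly the wild-type row
it names — never an average.

Structural metrics count signed ordered pairs: the universe has
`2·N·(N−1)` candidate interactions, an edge inferred with the wrong sign
costs both a false positive and a false negative, and precision is defined
as 0 for an empty prediction. An unsigned mode (flag) supports comparing
against tools that do not predict signs.

## Attractor search

`find_attractor` hashes visited states, so memory is linear in transient
plus period, and stops at the first revisit (minimal transient τ by
construction). Trajectories that exceed the step budget (`max_steps`,
default 2000 — far beyond any cycle observed at the benchmark sizes) return
the final state as a period-1 pseudo-attractor flagged `truncated`; such
rows are scored against that single state and surfaced in the report. The
GA's inner loop uses a numba-compiled batch kernel with uint64
state encoding (networks ≤ 64 genes; wider networks fall back to the pure
Python path). The kernel is a pure function of its arguments; a property
test asserts bit-identical agreement with the reference implementation, and
threaded fitness evaluation is therefore identical to sequential
evaluation.

## Constraints

Coherency is aggregated conservatively over multiple perturbation rows of
the same gene: a pair contributes only if all nonzero coherencies share one
sign — mixed evidence yields no constraint rather than a contradictory
hard one. Boundary conventions: `|r| ≥ β` is direct, `α < |r| < β`
indirect, `|r| = α` nothing. Zero-variance columns have correlation 0 by
definition here, preventing constraints on constant genes. Indirect
constraints are checked by signed-parity reachability — walks, not simple
paths, since the (node, parity) product graph is what a hard "some path of
this sign exists" condition naturally lives on — and a direct edge of the
right sign satisfies an indirect constraint (a weak correlation is not
evidence *against* directness). Overexpression rows use the same coherency
formula; it is sign-symmetric in the perturbation direction.

The directness test is a heuristic and misfires knowingly: with a dozen
Boolean steady-state rows, strong correlations arise along indirect chains,
so some derived "direct" constraints force edges the true network realizes
only as paths. Measured on noiseless 10-gene benchmarks, every such
violation still corresponds to a true signed influence (the signed path
exists); the cost is false-positive edges, visible in the precision of the
worked example.

## Genetic algorithm

Defaults follow the standard study conditions: population 200, 2 elites,
stop after 200 generations without strict improvement of the best fitness
(ties do not reset the counter), per-gene convergence window 100
generations with a 2 % tolerance, roulette-wheel selection proportional to
fitness (uniform fallback when all fitnesses are zero), no crossover.
Each generation keeps the elites and rebuilds the rest: every offspring
comes from an independently selected parent and exactly one successful
mutation; offspring violating any constraint are discarded and re-mutated
(up to `mutation_retry_cap = 100` violations, then the parent passes
through unchanged and the give-up is counted). Inapplicable mutation kinds
are resampled without consuming the retry budget, which makes the kind
choice uniform over the applicable kinds.

Mutation-gene choice is tiered: first genes with `s̄_i < 1` whose history
over the window still moves beyond the tolerance; then any imperfect gene;
then any gene. Histories are tracked per lineage (offspring inherit a copy
of the parent's buffer); tracking the generation best instead is available
by flag, as the better choice is genuinely open.

Initialization seeds every topology with the direct-constraint edges,
grows to the scale-free edge count `2N − 3` by degree-preferential
attachment, rewires (never deletes) edges so every gene keeps at least one
regulator, and greedily repairs unmet indirect constraints (direct edge if
the slot is free, otherwise a two-hop path); canalyzing orders and
unconstrained bits are uniform. `structure_fixed` mode — the
regulatory-function search used to give rule-less structure predictions a
dynamics score — takes an explicit input network, randomizes only rule
internals, and restricts mutations to the sign-preserving kinds (combined
flip and swap), conserving the signed edge set exactly; a flag relaxes this
to the looser reading that only forbids removal and insertion.

One pragmatic addition: when the best fitness reaches 1.0 the run stops
immediately (`stop_on_perfect`, on by default). No strict improvement is
possible beyond the ceiling, so the stagnation stop would fire 200
generations later with an unchanged result; stopping early only removes
dead compute.

Determinism: all stochastic decisions draw from one seeded generator in the
sequential breeding phase; fitness evaluation consumes no randomness.
Identical seed and config give byte-identical outputs at any worker count.

## Synthetic benchmarks

The generator emulates the standard artificial-data protocol: undirected
Barabási–Albert growth (two seed nodes, one edge; each new node attaches to
two distinct nodes degree-preferentially) gives exactly `2N − 3` edges and
a connected graph; edges are oriented uniformly at random and rewired
minimally so every gene has a regulator; rules get uniform random
canalyzing values and orders. Wild-type rows are the distinct attractors
reached from 10000 uniform random initial states (most frequent first,
capped at 10 rows); knockouts start from the dominant wild-type attractor's
representative state (its lexicographically minimal cycle state) with the
gene clamped. Limit-cycle attractors collapse to per-gene majority vectors
(ties to 1). The real-valued export maps bits to Gaussians at 2.0 (off) and
8.0 (on) arbitrary units, noise σ 0.5 by default — separable by 2-means up
to roughly σ 1.5.

What this does not emulate: measurement noise structure of microarrays,
ODE-based steady states, asynchronous updates, or dropout-like artifacts.
Passing tests show the pipeline is correct and self-consistent under its
own model class, not that the heuristics transfer to any particular
real-data regime.

## Discretization

Per-gene 1-D 2-means: Lloyd's algorithm from 10 seeded random centroid
pairs, best within-cluster SSE kept, equal-SSE ties broken toward the lower
split threshold; the higher-mean cluster maps to 1. The result is invariant
to shifting and positive rescaling of a column. Zero-variance columns map
to all 0 with a warning (no evidence of activity); missing values are
rejected. As with any k-means, a local SSE minimum can win on unimodal
columns; on two-level columns — the regime the export produces — the
restarts recover the global optimum (property-tested against an exhaustive
split oracle).

## Problem sizes used in tests

The suite runs the full protocol at 6–10 genes with populations 24–200 and
the acceptance checks at the standard 10-gene, 17-edge, per-gene-knockout
conditions; exhaustive oracles (all `2^N` states, all `2^k` rule inputs)
back the core primitives at those sizes. These sizes are the package's own
test design: they exercise every regime (multiple attractors, limit
cycles, constraint misfires, stagnation and perfect-fitness stops) while
keeping the suite quick to run.

## Known limitations

- Eleven steady-state rows underdetermine 17 signed edges: dynamics
  accuracy near 1.0 coexists with precision around 0.3, and structural
  accuracy does not beat the all-negative baseline (that would require
  signed precision above 0.5). The constraints bias, but cannot fix, this.
- Direct constraints derived from strong indirect correlations force
  false-positive edges by construction; they are hard constraints, so the
  GA cannot drop them.
- Wild-type limit cycles are summarized by majority vectors, so even the
  generating network may score below 1.0 on its own dataset; exact
  self-consistency holds in the all-fixed-point regime.
- Synchronous updates only; asynchronous semantics are out of scope.
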