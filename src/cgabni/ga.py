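"""Constrained genetic algorithm for Boolean network inference.

The algorithm evolves a population of candidate Boolean networks (one NCF
rule per gene) under hard path-consistency constraints.  Fitness is the
dynamics accuracy of a candidate on the observed steady-state dataset.
Each generation carries the best ``n_elites`` networks unchanged and fills
the rest with offspring: a parent is drawn by roulette-wheel selection
(probability proportional to fitness) and modified by exactly one rule
mutation — there is no crossover.  Offspring violating any constraint are
discarded and re-mutated; the population is therefore feasible at every
generation.  The run stops once the best fitness has not strictly improved
for ``stop_stagnant_generations`` generations.

Mutations act on one gene's rule, chosen heuristically: genes whose average
per-experiment similarity is already perfect, or has been flat (range within
``gene_convergence_tolerance``) over the last ``gene_convergence_window``
generations, are deprioritized.  Tuples required by direct constraints form
the fixed-path subgroup (FPS) and are protected from mutations that would
change their edge or sign; the remaining tuples form the variable-path
subgroup (VPS).  Six mutation kinds are implemented: canalyzing-value flip,
canalyzed-value flip (both switch the interaction sign), the combined flip
(sign-preserving, toggles conjunction/disjunction semantics), order swap
within a subgroup, tuple removal, and tuple insertion at the VPS head
(allowed only for regulators correlated with the target beyond ``alpha``).

``structure_fixed`` mode turns the GA into a regulatory-function search for
a given topology: removal and insertion are disabled and, by default, so
are the sign-flipping kinds, conserving the signed edge set exactly.

Fitness evaluation is read-only per chromosome and consumes no random
numbers, so it can be spread over threads with results identical to
sequential evaluation; all stochastic choices happen in the sequential
breeding phase against a single seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from . import _kernel
from .constraints import ConstraintParams, ConstraintSet, correlation_matrix, satisfies
from .core import (
    BooleanNetwork,
    DEFAULT_MAX_STEPS,
    NCFRule,
    edges_of,
    tuple_sign,
)
from .io import ExpressionDataset
from .scoring import dynamics_accuracy

__all__ = [
    "GAConfig",
    "Chromosome",
    "GAResult",
    "KindInapplicable",
    "InitializationError",
    "MUTATION_KINDS",
    "initialize_population",
    "roulette_select",
    "choose_mutation_gene",
    "mutate_rule",
    "propose_offspring",
    "evolve",
    "write_generation_log",
]

MUTATION_KINDS = (
    "canalyzing_flip",
    "canalyzed_flip",
    "both_flip",
    "swap",
    "removal",
    "insertion",
)
#: Sign-preserving kinds used by the structure-fixed (function-search) mode.
STRUCTURE_SAFE_KINDS = ("both_flip", "swap")


class KindInapplicable(Exception):
    """The requested mutation kind has no eligible tuple/regulator."""


class InitializationError(RuntimeError):
    """The constraint set could not be embedded in a feasible topology."""


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 200
    n_elites: int = 2
    stop_stagnant_generations: int = 200
    gene_convergence_window: int = 100
    gene_convergence_tolerance: float = 0.02
    max_generations: int = 5000
    mutation_retry_cap: int = 100
    structure_fixed: bool = False
    #: Literal reading of the function-search routine: allow sign-flipping
    #: kinds (the edge set is still conserved, signs are not).
    structure_fixed_allow_sign_flips: bool = False
    #: "lineage": each chromosome tracks its own per-gene similarity history;
    #: "best": one shared history of the generation-best chromosome.
    convergence_tracking: str = "lineage"
    stop_on_perfect: bool = True
    max_steps: int = DEFAULT_MAX_STEPS
    seed: int = 0
    n_workers: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.n_elites < self.population_size:
            raise ValueError("need 0 <= n_elites < population_size")
        if not 0.0 <= self.gene_convergence_tolerance <= 1.0:
            raise ValueError("gene_convergence_tolerance must be in [0, 1]")
        if self.convergence_tracking not in ("lineage", "best"):
            raise ValueError("convergence_tracking must be 'lineage' or 'best'")

    def mutation_kinds(self) -> tuple[str, ...]:
        if not self.structure_fixed:
            return MUTATION_KINDS
        if self.structure_fixed_allow_sign_flips:
            return tuple(k for k in MUTATION_KINDS if k not in ("removal", "insertion"))
        return STRUCTURE_SAFE_KINDS


class GeneHistory:
    """Ring buffer of recent per-gene average similarities."""

    __slots__ = ("window", "values", "count", "pos")

    def __init__(self, window: int, n_genes: int):
        self.window = window
        self.values = np.zeros((window, n_genes))
        self.count = 0
        self.pos = 0

    def push(self, sims: np.ndarray) -> None:
        self.values[self.pos] = sims
        self.pos = (self.pos + 1) % self.window
        self.count = min(self.count + 1, self.window)

    def not_converged(self, tolerance: float) -> np.ndarray:
        """True for genes whose history is short or still moving beyond
        the tolerance."""
        if self.count < self.window:
            return np.ones(self.values.shape[1], dtype=bool)
        return (self.values.max(axis=0) - self.values.min(axis=0)) > tolerance

    def copy(self) -> "GeneHistory":
        out = GeneHistory(self.window, self.values.shape[1])
        out.values = self.values.copy()
        out.count = self.count
        out.pos = self.pos
        return out


@dataclass
class Chromosome:
    """A candidate network with cached fitness and similarity history."""

    network: BooleanNetwork
    history: GeneHistory
    fitness: float | None = None
    gene_sim: np.ndarray | None = None

    def clone(self) -> "Chromosome":
        return Chromosome(self.network, self.history.copy(), self.fitness, self.gene_sim)

    def fps_indices(self, gene: int, constraint_set: ConstraintSet) -> list[int]:
        """Tuple positions of gene's rule required by direct constraints."""
        required = constraint_set.direct_for_target(gene)
        rule = self.network.rules[gene]
        return [
            j
            for j, (v, i, o) in enumerate(rule.tuples)
            if required.get(v) == tuple_sign(i, o)
        ]


@dataclass
class GAResult:
    best: Chromosome
    generations: list[dict]
    stop_reason: str
    retry_giveups: int = 0

    @property
    def n_generations(self) -> int:
        return len(self.generations)


# ---------------------------------------------------------------------------
# population initialization


def _edge_walk_ok(edges: dict[tuple[int, int], int], c) -> bool:
    adj: dict[int, list[tuple[int, int]]] = {}
    for (s, t), sign in edges.items():
        adj.setdefault(s, []).append((t, sign))
    seen: set[tuple[int, int]] = set()
    frontier = [(c.source, 1)]
    while frontier:
        nxt = []
        for node, par in frontier:
            for t, sign in adj.get(node, ()):
                key = (t, par * sign)
                if key not in seen:
                    seen.add(key)
                    nxt.append(key)
        frontier = nxt
    return (c.target, c.sign) in seen


def _random_feasible_edges(
    constraint_set: ConstraintSet, n: int, rng: np.random.Generator
) -> dict[tuple[int, int], int]:
    edges: dict[tuple[int, int], int] = {}
    for c in constraint_set.direct:
        edges[(c.source, c.target)] = c.sign
    protected = set(edges)
    target_count = max(2 * n - 3, len(edges))
    degree = np.zeros(n)
    for s, t in edges:
        degree[s] += 1
        degree[t] += 1
    # degree-preferential fill up to the BA edge count
    while len(edges) < target_count:
        w = degree + 1.0
        s = int(rng.choice(n, p=w / w.sum()))
        t = int(rng.choice(n, p=w / w.sum()))
        if s == t or (s, t) in edges:
            continue
        edges[(s, t)] = 1 if rng.random() < 0.5 else -1
        degree[s] += 1
        degree[t] += 1
    # every gene needs >= 1 regulator: rewire unprotected edges
    def in_deg() -> np.ndarray:
        d = np.zeros(n, dtype=np.int64)
        for _, t in edges:
            d[t] += 1
        return d

    d = in_deg()
    while (d == 0).any():
        g = int(np.flatnonzero(d == 0)[0])
        movable = [
            (s, t)
            for (s, t) in edges
            if (s, t) not in protected and d[t] >= 2 and s != g and (s, g) not in edges
        ]
        if movable:
            s, t = movable[int(rng.integers(len(movable)))]
            edges[(s, g)] = edges.pop((s, t))
        else:
            sources = [s for s in range(n) if s != g and (s, g) not in edges]
            s = int(rng.choice(sources))
            edges[(s, g)] = 1 if rng.random() < 0.5 else -1
        d = in_deg()
    # greedy repair until indirect constraints hold
    for _ in range(20):
        violated = [c for c in constraint_set.indirect if not _edge_walk_ok(edges, c)]
        if not violated:
            return edges
        for c in violated:
            if (c.source, c.target) not in edges:
                edges[(c.source, c.target)] = c.sign
                continue
            placed = False
            for m in rng.permutation(n):
                m = int(m)
                if m in (c.source, c.target):
                    continue
                e1 = edges.get((c.source, m))
                e2 = edges.get((m, c.target))
                if (e1 is None or e1 == 1) and (e2 is None or e2 == c.sign):
                    edges[(c.source, m)] = 1
                    edges[(m, c.target)] = c.sign
                    placed = True
                    break
            if not placed:
                raise InitializationError(f"cannot satisfy indirect constraint {c}")
    violated = [c for c in constraint_set.indirect if not _edge_walk_ok(edges, c)]
    raise InitializationError(f"constraints unsatisfiable after repair: {violated}")


def _rules_from_edges(
    edges: dict[tuple[int, int], int], n: int, rng: np.random.Generator
) -> tuple[NCFRule, ...]:
    incoming: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for (s, t), sign in edges.items():
        incoming[t].append((s, sign))
    rules = []
    for i in range(n):
        regs = incoming[i]
        order = rng.permutation(len(regs))
        tuples = []
        for j in order:
            v, sign = regs[int(j)]
            bit = int(rng.integers(2))
            tuples.append((v, bit, bit if sign > 0 else 1 - bit))
        rules.append(NCFRule(i, tuple(tuples)))
    return tuple(rules)


def initialize_population(
    constraint_set: ConstraintSet,
    n_genes: int,
    config: GAConfig,
    rng: np.random.Generator,
    gene_names: tuple[str, ...] | None = None,
    initial_network: BooleanNetwork | None = None,
) -> list[Chromosome]:
    """Feasible starting population.

    Free-structure mode seeds every topology with the direct-constraint
    edges, grows it to the scale-free edge count ``2N - 3`` by preferential
    attachment and greedily repairs indirect constraints.  Structure-fixed
    mode clones the given network's signed edge set and randomizes only the
    canalyzing orders and the sign-free bit of each tuple.
    """
    names = gene_names or tuple(f"v{i + 1}" for i in range(n_genes))
    pop: list[Chromosome] = []
    if config.structure_fixed:
        if initial_network is None:
            raise ValueError("structure_fixed mode needs an initial network")
        fixed_edges = {(s, t): sign for s, t, sign in edges_of(initial_network)}
        for _ in range(config.population_size):
            rules = _rules_from_edges(fixed_edges, n_genes, rng)
            net = BooleanNetwork(initial_network.gene_names, rules)
            pop.append(Chromosome(net, GeneHistory(config.gene_convergence_window, n_genes)))
    else:
        for _ in range(config.population_size):
            edges = _random_feasible_edges(constraint_set, n_genes, rng)
            net = BooleanNetwork(names, _rules_from_edges(edges, n_genes, rng))
            ok, violated = satisfies(net, constraint_set)
            if not ok:  # defensive: construction guarantees feasibility
                raise InitializationError(f"infeasible initial network: {violated}")
            pop.append(Chromosome(net, GeneHistory(config.gene_convergence_window, n_genes)))
    return pop


# ---------------------------------------------------------------------------
# selection and mutation


def roulette_select(population: list[Chromosome], rng: np.random.Generator) -> Chromosome:
    """Fitness-proportional selection; uniform when all fitnesses are 0."""
    fitness = np.array([c.fitness for c in population], dtype=np.float64)
    total = fitness.sum()
    if total <= 0.0:
        return population[int(rng.integers(len(population)))]
    return population[int(rng.choice(len(population), p=fitness / total))]


def choose_mutation_gene(
    chromosome: Chromosome,
    config: GAConfig,
    rng: np.random.Generator,
    history: GeneHistory | None = None,
) -> int:
    """Pick the rule to mutate.

    First tier: genes with imperfect average similarity that are still
    moving (range over the convergence window above the tolerance); second
    tier: any imperfect gene; last resort: any gene.
    """
    n = chromosome.network.n_genes
    sims = chromosome.gene_sim
    if sims is None:
        return int(rng.integers(n))
    hist = history if history is not None else chromosome.history
    imperfect = sims < 1.0 - 1e-12
    tier1 = np.flatnonzero(imperfect & hist.not_converged(config.gene_convergence_tolerance))
    if tier1.size:
        return int(rng.choice(tier1))
    tier2 = np.flatnonzero(imperfect)
    if tier2.size:
        return int(rng.choice(tier2))
    return int(rng.integers(n))


def _replace_rule(net: BooleanNetwork, gene: int, tuples: tuple) -> BooleanNetwork:
    rules = list(net.rules)
    rules[gene] = NCFRule(gene, tuple(tuples))
    return BooleanNetwork(net.gene_names, tuple(rules))


def mutate_rule(
    chromosome: Chromosome,
    gene: int,
    kind: str,
    correlations: np.ndarray,
    params: ConstraintParams,
    constraint_set: ConstraintSet,
    rng: np.random.Generator,
) -> BooleanNetwork:
    """Apply one mutation kind to one gene's rule (feasibility unchecked).

    Raises :class:`KindInapplicable` when the kind has no eligible target:
    flips and removal need a VPS tuple, removal additionally a rule with at
    least two tuples, swap needs two tuples in one subgroup, insertion an
    unused regulator correlated with the target beyond ``alpha``.
    """
    net = chromosome.network
    rule = net.rules[gene]
    tuples = list(rule.tuples)
    fps = set(chromosome.fps_indices(gene, constraint_set))
    vps = [j for j in range(len(tuples)) if j not in fps]

    if kind in ("canalyzing_flip", "canalyzed_flip"):
        if not vps:
            raise KindInapplicable(kind)
        j = vps[int(rng.integers(len(vps)))]
        v, i, o = tuples[j]
        tuples[j] = (v, 1 - i, o) if kind == "canalyzing_flip" else (v, i, 1 - o)
    elif kind == "both_flip":
        j = int(rng.integers(len(tuples)))
        v, i, o = tuples[j]
        tuples[j] = (v, 1 - i, 1 - o)
    elif kind == "swap":
        pairs = [
            (a, b)
            for group in (sorted(fps), vps)
            for ai, a in enumerate(group)
            for b in group[ai + 1 :]
        ]
        if not pairs:
            raise KindInapplicable(kind)
        a, b = pairs[int(rng.integers(len(pairs)))]
        tuples[a], tuples[b] = tuples[b], tuples[a]
    elif kind == "removal":
        if not vps or len(tuples) < 2:
            raise KindInapplicable(kind)
        del tuples[vps[int(rng.integers(len(vps)))]]
    elif kind == "insertion":
        present = set(rule.regulators)
        candidates = [
            v
            for v in range(net.n_genes)
            if v != gene and v not in present and abs(correlations[v, gene]) > params.alpha
        ]
        if not candidates:
            raise KindInapplicable(kind)
        v = candidates[int(rng.integers(len(candidates)))]
        new = (v, int(rng.integers(2)), int(rng.integers(2)))
        head = vps[0] if vps else len(tuples)
        tuples.insert(head, new)
    else:
        raise ValueError(f"unknown mutation kind {kind!r}")
    return _replace_rule(net, gene, tuple(tuples))


def propose_offspring(
    parent: Chromosome,
    constraint_set: ConstraintSet,
    correlations: np.ndarray,
    config: GAConfig,
    params: ConstraintParams,
    rng: np.random.Generator,
    history: GeneHistory | None = None,
) -> tuple[Chromosome, bool]:
    """One feasible offspring of ``parent``.

    The mutation kind is drawn uniformly among the applicable kinds
    (inapplicable draws are resampled without consuming the retry budget);
    constraint-violating offspring are discarded and the loop retries.
    After ``mutation_retry_cap`` rejections the parent is returned
    unmodified; the second return value reports that give-up.
    """
    kinds = config.mutation_kinds()
    retries = 0
    while retries < config.mutation_retry_cap:
        gene = choose_mutation_gene(parent, config, rng, history)
        child_net = None
        for idx in rng.permutation(len(kinds)):
            try:
                child_net = mutate_rule(
                    parent, gene, kinds[int(idx)], correlations, params, constraint_set, rng
                )
                break
            except KindInapplicable:
                continue
        if child_net is not None and satisfies(child_net, constraint_set)[0]:
            return Chromosome(child_net, parent.history.copy()), False
        retries += 1
    return parent.clone(), True


# ---------------------------------------------------------------------------
# fitness evaluation


class _FitnessEvaluator:
    """Precompiled experiment protocol; maps a network to (fitness, s_bar)."""

    def __init__(self, dataset: ExpressionDataset, max_steps: int):
        if dataset.boolean is None:
            raise ValueError("the GA needs a binarized dataset")
        self.dataset = dataset
        self.max_steps = max_steps
        self.use_kernel = dataset.n_genes <= _kernel.MAX_KERNEL_GENES
        r = dataset.n_experiments
        self.init = np.stack(
            [dataset.boolean[dataset.base_row_index(j)] for j in range(r)]
        ).astype(np.int8)
        self.clamp_gene = np.full(r, -1, dtype=np.int64)
        self.clamp_val = np.zeros(r, dtype=np.int8)
        for j in range(r):
            clamp = dataset.clamps_for_row(j)
            if clamp:
                ((g, b),) = clamp.items()
                self.clamp_gene[j] = g
                self.clamp_val[j] = b
        self.obs = dataset.boolean.astype(np.int8)

    def __call__(self, net: BooleanNetwork) -> tuple[float, np.ndarray]:
        if self.use_kernel:
            sims, _ = _kernel.dynamics_scores(
                _kernel.compile_network(net),
                self.init,
                self.clamp_gene,
                self.clamp_val,
                self.obs,
                self.max_steps,
            )
            return float(sims.mean(axis=1).mean()), sims.mean(axis=0)
        report = dynamics_accuracy(net, self.dataset, max_steps=self.max_steps)
        return report.dynamics_accuracy, report.per_gene


def _evaluate_population(
    population: list[Chromosome], evaluator: _FitnessEvaluator, n_workers: int
) -> None:
    todo = [c for c in population if c.fitness is None]
    if not todo:
        return
    if n_workers > 1:
        results = Parallel(n_jobs=n_workers, backend="threading")(
            delayed(evaluator)(c.network) for c in todo
        )
    else:
        results = [evaluator(c.network) for c in todo]
    for chrom, (fit, sims) in zip(todo, results):
        chrom.fitness = fit
        chrom.gene_sim = sims


# ---------------------------------------------------------------------------
# the generational loop


def evolve(
    dataset: ExpressionDataset,
    constraint_set: ConstraintSet,
    config: GAConfig,
    params: ConstraintParams = ConstraintParams(),
    initial_network: BooleanNetwork | None = None,
) -> GAResult:
    """Run the constrained GA and return the best network ever seen.

    Stops on ``stop_stagnant_generations`` generations without strict
    improvement of the best fitness, on the generation cap, or (by default)
    as soon as the fitness ceiling 1.0 is reached, after which no strict
    improvement is possible.
    """
    rng = np.random.default_rng(config.seed)
    n = dataset.n_genes
    evaluator = _FitnessEvaluator(dataset, config.max_steps)
    correlations = correlation_matrix(dataset.boolean)
    population = initialize_population(
        constraint_set, n, config, rng,
        gene_names=dataset.gene_names, initial_network=initial_network,
    )
    _evaluate_population(population, evaluator, config.n_workers)
    shared_history = (
        GeneHistory(config.gene_convergence_window, n)
        if config.convergence_tracking == "best"
        else None
    )

    def push_histories() -> None:
        if shared_history is not None:
            best = max(population, key=lambda c: c.fitness)
            shared_history.push(best.gene_sim)
        else:
            for c in population:
                c.history.push(c.gene_sim)

    def feasibility_rate() -> float:
        return float(
            np.mean([satisfies(c.network, constraint_set)[0] for c in population])
        )

    push_histories()
    best_ever = max(population, key=lambda c: c.fitness).clone()
    stagnant = 0
    giveups = 0
    log: list[dict] = []
    stop_reason = "max_generations"
    for gen in range(1, config.max_generations + 1):
        order = sorted(range(len(population)), key=lambda i: (-population[i].fitness, i))
        elites = [population[i].clone() for i in order[: config.n_elites]]
        children = []
        for _ in range(config.population_size - config.n_elites):
            parent = roulette_select(population, rng)
            child, gave_up = propose_offspring(
                parent, constraint_set, correlations, config, params, rng,
                history=shared_history,
            )
            giveups += gave_up
            children.append(child)
        population = elites + children
        _evaluate_population(population, evaluator, config.n_workers)
        push_histories()
        gen_best = max(population, key=lambda c: c.fitness)
        if gen_best.fitness > best_ever.fitness:
            best_ever = gen_best.clone()
            stagnant = 0
        else:
            stagnant += 1
        log.append(
            {
                "generation": gen,
                "best_fitness": float(gen_best.fitness),
                "mean_fitness": float(np.mean([c.fitness for c in population])),
                "feasibility_rate": feasibility_rate(),
            }
        )
        if config.stop_on_perfect and best_ever.fitness >= 1.0:
            stop_reason = "perfect_fitness"
            break
        if stagnant >= config.stop_stagnant_generations:
            stop_reason = "stagnation"
            break
    return GAResult(best=best_ever, generations=log, stop_reason=stop_reason,
                    retry_giveups=giveups)


def write_generation_log(result: GAResult, path: str | Path, header: dict | None = None) -> None:
    """Per-generation TSV log with an optional reproducibility header."""
    lines = []
    for key, val in (header or {}).items():
        lines.append(f"# {key}: {val}")
    lines.append("generation\tbest_fitness\tmean_fitness\tfeasibility_rate")
    for rec in result.generations:
        lines.append(
            f"{rec['generation']}\t{rec['best_fitness']:.6f}"
            f"\t{rec['mean_fitness']:.6f}\t{rec['feasibility_rate']:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
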