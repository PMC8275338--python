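"""Gold-standard benchmark networks and steady-state datasets.

The benchmark protocol mirrors the artificial-data study conditions: scale-
free topologies from Barabási–Albert growth (two seed nodes joined by one
edge, every new node attaching to two distinct existing nodes by degree-
preferential sampling, hence exactly ``2N - 3`` edges), random edge
orientation, uniformly random canalyzing values and orders, wild-type
attractors sampled from 10000 random initial states, and one knockout
experiment per gene simulated from the dominant wild-type attractor.

Attractor-to-expression collapse uses the per-gene majority over the cycle
states (ties break to 1); fixed points are reported verbatim.  The optional
real-valued export maps a bit ``b`` to a Gaussian with mean
``b * high + (1 - b) * low``, chosen so that per-gene 2-means separates the
two levels reliably at moderate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .core import BooleanNetwork, DEFAULT_MAX_STEPS, NCFRule, find_attractor
from .io import ExpressionDataset

__all__ = ["BenchmarkSpec", "generate_ba_network", "generate_dataset", "generate_benchmark"]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Study conditions for one synthetic benchmark.

    ``n_edges`` defaults to ``2N - 3`` and ``n_initial_states`` to 10000 to
    match the benchmark protocol; ``include_oe`` adds per-gene
    overexpression rows on top of the default per-gene knockouts.
    """

    n_genes: int
    n_edges: int | None = None
    n_initial_states: int = 10000
    include_ko: bool = True
    include_oe: bool = False
    noise_sd: float = 0.5
    low: float = 2.0
    high: float = 8.0
    max_wt_rows: int = 10
    max_steps: int = DEFAULT_MAX_STEPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("benchmark networks need at least 3 genes")
        if self.edge_count < self.n_genes - 1:
            raise ValueError("n_edges must be at least N - 1")
        if self.n_initial_states < 1:
            raise ValueError("n_initial_states must be >= 1")

    @property
    def edge_count(self) -> int:
        return 2 * self.n_genes - 3 if self.n_edges is None else self.n_edges


def _ba_edge_list(n: int, n_edges: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Undirected BA growth (m0=2, m=2), then uniform extra edges if asked."""
    degree = np.zeros(n, dtype=np.int64)
    edges: set[frozenset] = set()

    def add(u: int, v: int) -> None:
        edges.add(frozenset((u, v)))
        degree[u] += 1
        degree[v] += 1

    add(0, 1)
    for v in range(2, n):
        targets: set[int] = set()
        while len(targets) < min(2, v):
            w = degree[:v].astype(np.float64)
            w[list(targets)] = 0.0
            probs = w / w.sum()
            targets.add(int(rng.choice(v, p=probs)))
        for t in targets:
            add(v, t)
    while len(edges) < n_edges:  # beyond 2N-3 only when explicitly requested
        u, v = rng.choice(n, size=2, replace=False)
        if frozenset((int(u), int(v))) not in edges:
            add(int(u), int(v))
    return [tuple(sorted(e)) for e in sorted(edges, key=lambda e: tuple(sorted(e)))]


def _orient_and_fix(
    undirected: list[tuple[int, int]], n: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Random orientation, then rewire so every gene has a regulator."""
    directed = []
    for u, v in undirected:
        directed.append((u, v) if rng.random() < 0.5 else (v, u))
    in_deg = np.zeros(n, dtype=np.int64)
    for _, t in directed:
        in_deg[t] += 1
    existing = set(directed)
    while (in_deg == 0).any():
        g = int(np.flatnonzero(in_deg == 0)[0])
        donors = np.flatnonzero(in_deg == in_deg.max())
        donor = int(rng.choice(donors))
        candidates = [
            i for i, (s, t) in enumerate(directed)
            if t == donor and s != g and (s, g) not in existing
        ]
        if not candidates:  # fall back to any rewirable edge into a multi-input gene
            candidates = [
                i for i, (s, t) in enumerate(directed)
                if in_deg[t] >= 2 and s != g and (s, g) not in existing
            ]
        idx = int(rng.choice(candidates))
        s, t = directed[idx]
        existing.discard((s, t))
        directed[idx] = (s, g)
        existing.add((s, g))
        in_deg[t] -= 1
        in_deg[g] += 1
    return directed


def _random_rules(
    directed: list[tuple[int, int]], n: int, rng: np.random.Generator
) -> tuple[NCFRule, ...]:
    incoming: dict[int, list[int]] = {i: [] for i in range(n)}
    for s, t in directed:
        incoming[t].append(s)
    rules = []
    for i in range(n):
        regs = list(incoming[i])
        rng.shuffle(regs)
        tuples = tuple((v, int(rng.integers(2)), int(rng.integers(2))) for v in regs)
        rules.append(NCFRule(i, tuples))
    return tuple(rules)


def generate_ba_network(spec: BenchmarkSpec, rng: np.random.Generator) -> BooleanNetwork:
    """Random scale-free Boolean network with NCF rules.

    The underlying undirected graph is connected by construction; rewiring
    guarantees every gene at least one regulator while conserving the edge
    count.
    """
    n = spec.n_genes
    undirected = _ba_edge_list(n, spec.edge_count, rng)
    directed = _orient_and_fix(undirected, n, rng)
    names = tuple(f"v{i + 1}" for i in range(n))
    return BooleanNetwork(names, _random_rules(directed, n, rng))


def _attractors_python(net, init_states, clamp, max_steps):
    """Fallback attractor summary for networks beyond the kernel's width."""
    canon, majority = [], []
    for state in init_states:
        att = find_attractor(net, state, clamp, max_steps=max_steps)
        states = np.asarray(att.states, dtype=np.int8)
        canon.append(min(tuple(s) for s in att.states))
        majority.append((states.mean(axis=0) >= 0.5).astype(np.int8))
    return canon, majority


def generate_dataset(
    net: BooleanNetwork, spec: BenchmarkSpec, rng: np.random.Generator
) -> ExpressionDataset:
    """Steady-state dataset of a network under the benchmark protocol.

    Wild-type rows: one per distinct attractor reached from
    ``n_initial_states`` random initial states, most frequent first, capped
    at ``max_wt_rows``.  Perturbation rows: each gene clamped (KO and/or OE)
    starting from the dominant wild-type attractor's representative state
    (its lexicographically minimal cycle state), based on that wild-type
    row.  Rows are the per-gene majority vectors of the reached attractors.
    """
    n = net.n_genes
    init = rng.integers(0, 2, size=(spec.n_initial_states, n)).astype(np.int8)
    use_kernel = n <= _kernel.MAX_KERNEL_GENES
    no_clamp = np.full(spec.n_initial_states, -1, dtype=np.int64)
    zeros = np.zeros(spec.n_initial_states, dtype=np.int8)
    if use_kernel:
        canon, majority, _, _ = _kernel.attractor_summary(
            net, init, no_clamp, zeros, spec.max_steps
        )
        canon = [int(c) for c in canon]
    else:
        canon, majority = _attractors_python(net, init, None, spec.max_steps)

    # distinct attractors, most frequent first (ties by canonical code)
    counts: dict = {}
    first_row: dict = {}
    for idx, c in enumerate(canon):
        counts[c] = counts.get(c, 0) + 1
        first_row.setdefault(c, idx)
    order = sorted(counts, key=lambda c: (-counts[c], c))[: spec.max_wt_rows]

    ids, mgs, ets, wts, rows = [], [], [], [], []
    for j, c in enumerate(order):
        ids.append(f"WT{j + 1:02d}")
        mgs.append(None)
        ets.append("WT")
        wts.append(None)
        rows.append(np.asarray(majority[first_row[c]], dtype=np.int8))

    dominant = order[0]
    if net.n_genes <= _kernel.MAX_KERNEL_GENES:
        rep = _kernel.decode_state(dominant, n)
    else:
        rep = np.asarray(dominant, dtype=np.int8)
    perturbations = []
    if spec.include_ko:
        perturbations.append(("KO", 0))
    if spec.include_oe:
        perturbations.append(("OE", 1))
    for et, bit in perturbations:
        for g in range(n):
            if use_kernel:
                _, maj, _, _ = _kernel.attractor_summary(
                    net,
                    rep[None, :],
                    np.array([g], dtype=np.int64),
                    np.array([bit], dtype=np.int8),
                    spec.max_steps,
                )
                row = np.asarray(maj[0], dtype=np.int8)
            else:
                att = find_attractor(net, rep, {g: bit}, max_steps=spec.max_steps)
                states = np.asarray(att.states, dtype=np.int8)
                row = (states.mean(axis=0) >= 0.5).astype(np.int8)
            ids.append(f"{et}{(g + 1):02d}")
            mgs.append(net.gene_names[g])
            ets.append(et)
            wts.append("WT01")
            rows.append(row)

    boolean = np.vstack(rows).astype(np.int8)
    real = boolean * spec.high + (1 - boolean) * spec.low
    if spec.noise_sd > 0:
        real = real + rng.normal(0.0, spec.noise_sd, size=real.shape)
    return ExpressionDataset(
        gene_names=net.gene_names,
        ids=tuple(ids),
        mutated_gene=tuple(mgs),
        experiment_type=tuple(ets),
        base_wt=tuple(wts),
        boolean=boolean,
        real=real.astype(np.float64),
    )


def generate_benchmark(spec: BenchmarkSpec) -> tuple[BooleanNetwork, ExpressionDataset]:
    """Convenience wrapper: network and dataset from the spec's own seed."""
    rng = np.random.default_rng(spec.seed)
    net = generate_ba_network(spec, rng)
    return net, generate_dataset(net, spec, rng)
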