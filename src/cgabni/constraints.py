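"""Path-consistency constraints from wild-type vs. perturbation expression.

Comparing a perturbation row ``e`` (mutated gene ``k``) with its base
wild-type row ``w`` gives the gene-gene coherency
``delta(k,l) = (e_k - w_k) * (e_l - w_l)``: a positive value means genes
``k`` and ``l`` moved together, a negative one that they moved oppositely.
Combined with the Pearson correlation ``r(k,l)`` of the two genes over the
whole Boolean dataset, each ordered pair is assigned at most one of four
constraint classes:

=====================  =========================
condition              constraint
=====================  =========================
delta>0, r >= beta     direct, positive
delta>0, alpha<r<beta  indirect, positive
delta<0, r <= -beta    direct, negative
delta<0, -beta<r<-alpha indirect, negative
=====================  =========================

with ``alpha = 0.1`` and ``beta = 0.5`` by default.  A direct constraint
requires the signed edge itself; an indirect constraint requires a directed
path (length >= 1, a direct edge qualifies) whose edge-sign product matches,
decided by signed-parity reachability.  Constraints are hard: the genetic
algorithm never accepts a network violating one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import BooleanNetwork, Edge, edges_of
from .io import ExpressionDataset

__all__ = [
    "PathConstraint",
    "ConstraintParams",
    "ConstraintSet",
    "coherency",
    "correlation",
    "correlation_matrix",
    "derive_constraints",
    "satisfies",
]

DIRECT = "direct"
INDIRECT = "indirect"


@dataclass(frozen=True)
class PathConstraint:
    source: int
    target: int
    sign: int  # +1 or -1
    directness: str  # "direct" | "indirect"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("constraint source and target must differ")
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if self.directness not in (DIRECT, INDIRECT):
            raise ValueError(f"directness must be direct/indirect, got {self.directness!r}")


@dataclass(frozen=True)
class ConstraintParams:
    """Correlation thresholds: ``alpha`` is the floor below which no
    constraint is emitted, ``beta`` separates indirect from direct."""

    alpha: float = 0.1
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < self.beta <= 1.0:
            raise ValueError(f"need 0 <= alpha < beta <= 1, got {self.alpha}, {self.beta}")


@dataclass(frozen=True)
class ConstraintSet:
    constraints: tuple[PathConstraint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "constraints", tuple(self.constraints))
        seen: dict[tuple[int, int], PathConstraint] = {}
        for c in self.constraints:
            prev = seen.get((c.source, c.target))
            if prev is not None:
                raise ValueError(
                    f"conflicting constraints on pair ({c.source}, {c.target}): {prev} vs {c}"
                )
            seen[(c.source, c.target)] = c

    def __len__(self) -> int:
        return len(self.constraints)

    def __iter__(self):
        return iter(self.constraints)

    @property
    def direct(self) -> tuple[PathConstraint, ...]:
        return tuple(c for c in self.constraints if c.directness == DIRECT)

    @property
    def indirect(self) -> tuple[PathConstraint, ...]:
        return tuple(c for c in self.constraints if c.directness == INDIRECT)

    def direct_for_target(self, gene: int) -> dict[int, int]:
        """source -> required sign, over direct constraints targeting ``gene``."""
        return {c.source: c.sign for c in self.direct if c.target == gene}

    def to_tsv(self, path: str | Path, gene_names: list[str] | None = None) -> None:
        name = (lambda i: gene_names[i]) if gene_names else (lambda i: str(i))
        lines = ["source\ttarget\tsign\tdirectness"]
        for c in self.constraints:
            sgn = "+1" if c.sign > 0 else "-1"
            lines.append(f"{name(c.source)}\t{name(c.target)}\t{sgn}\t{c.directness}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, gene_names: list[str] | None = None) -> "ConstraintSet":
        index = {g: i for i, g in enumerate(gene_names)} if gene_names else None
        out = []
        lines = Path(path).read_text().splitlines()
        for raw in lines[1:]:
            if not raw.strip():
                continue
            s, t, sgn, d = raw.split("\t")
            si = index[s] if index else int(s)
            ti = index[t] if index else int(t)
            out.append(PathConstraint(si, ti, 1 if sgn in ("+1", "1") else -1, d))
        return cls(tuple(out))


def coherency(e: np.ndarray, w: np.ndarray, k: int, l: int) -> int:
    """Gene-gene coherency between a perturbation row and its base wild-type row."""
    if l == k:
        raise ValueError("coherency is undefined for the mutated gene itself")
    return int((int(e[k]) - int(w[k])) * (int(e[l]) - int(w[l])))


def correlation(E: np.ndarray, k: int, l: int) -> float:
    """Pearson correlation of genes ``k`` and ``l`` over all experiments;
    0 if either column has zero variance."""
    E = np.asarray(E, dtype=np.float64)
    if E.ndim != 2 or E.shape[0] < 2:
        raise ValueError("correlation needs a matrix with at least 2 rows")
    xk, xl = E[:, k], E[:, l]
    if np.ptp(xk) == 0.0 or np.ptp(xl) == 0.0:
        return 0.0
    return float(np.corrcoef(xk, xl)[0, 1])


def correlation_matrix(E: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlations, zero-variance columns mapped to 0."""
    E = np.asarray(E, dtype=np.float64)
    sd = E.std(axis=0)
    ok = sd > 0.0
    r = np.zeros((E.shape[1], E.shape[1]))
    if ok.sum() >= 2:
        sub = np.corrcoef(E[:, ok], rowvar=False)
        r[np.ix_(ok, ok)] = sub
    np.fill_diagonal(r, 1.0)
    r[~ok, :] = 0.0
    r[:, ~ok] = 0.0
    return r


def _classify(delta: int, r: float, params: ConstraintParams) -> tuple[int, str] | None:
    a, b = params.alpha, params.beta
    if delta > 0 and r > 0:
        if r >= b:
            return 1, DIRECT
        if a < r < b:
            return 1, INDIRECT
    elif delta < 0 and r < 0:
        if r <= -b:
            return -1, DIRECT
        if -b < r < -a:
            return -1, INDIRECT
    return None


def derive_constraints(
    dataset: ExpressionDataset, params: ConstraintParams = ConstraintParams()
) -> ConstraintSet:
    """Derive the constraint set from a binarized, annotated dataset.

    Coherencies of a mutated gene ``k`` are aggregated over all of its
    perturbation rows conservatively: a pair ``(k, l)`` yields a constraint
    only if every nonzero coherency shares one sign; mixed signs or all-zero
    coherencies yield none.
    """
    if dataset.boolean is None:
        raise ValueError("constraint derivation needs a binarized dataset")
    E = dataset.boolean
    pert_rows = [j for j, et in enumerate(dataset.experiment_type) if et != "WT"]
    if not pert_rows:
        raise ValueError("constraint derivation needs at least one perturbation row")
    n = dataset.n_genes
    r_mat = correlation_matrix(E)
    by_gene: dict[int, list[int]] = {}
    for j in pert_rows:
        by_gene.setdefault(dataset.gene_index(dataset.mutated_gene[j]), []).append(j)
    out: list[PathConstraint] = []
    for k in sorted(by_gene):
        rows = by_gene[k]
        for l in range(n):
            if l == k:
                continue
            deltas = [
                coherency(E[j], E[dataset.base_row_index(j)], k, l) for j in rows
            ]
            nonzero = {d for d in deltas if d != 0}
            if len(nonzero) != 1:
                continue
            delta = nonzero.pop()
            cls = _classify(delta, r_mat[k, l], params)
            if cls is not None:
                out.append(PathConstraint(k, l, cls[0], cls[1]))
    return ConstraintSet(tuple(out))


def _signed_reachable(edges: list[Edge], n: int, source: int) -> set[tuple[int, int]]:
    """(node, parity) pairs reachable from ``source`` by walks of length >= 1."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for s, t, sign in edges:
        adj.setdefault(s, []).append((t, sign))
    seen: set[tuple[int, int]] = set()
    frontier = [(source, 1)]
    while frontier:
        nxt = []
        for node, par in frontier:
            for t, sign in adj.get(node, ()):
                key = (t, par * sign)
                if key not in seen:
                    seen.add(key)
                    nxt.append(key)
        frontier = nxt
    return seen


def satisfies(
    net: BooleanNetwork, constraint_set: ConstraintSet
) -> tuple[bool, list[PathConstraint]]:
    """Check a network against a constraint set.

    Returns ``(ok, violated)``.  Direct constraints require the signed edge
    itself; indirect constraints require any signed walk of the right parity
    (which a direct edge of the right sign also provides).
    """
    edges = edges_of(net)
    edge_set = set(edges)
    reach_cache: dict[int, set[tuple[int, int]]] = {}
    violated = []
    for c in constraint_set:
        if c.directness == DIRECT:
            ok = (c.source, c.target, c.sign) in edge_set
        else:
            if c.source not in reach_cache:
                reach_cache[c.source] = _signed_reachable(edges, net.n_genes, c.source)
            ok = (c.target, c.sign) in reach_cache[c.source]
        if not ok:
            violated.append(c)
    return not violated, violated
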