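"""Synchronous Boolean networks with nested canalyzing update rules.

A gene regulatory network is modelled as a directed graph over ``N`` genes,
each carrying a binary state.  The update rule of every gene is a *nested
canalyzing function* (NCF): an ordered cascade of ``(regulator, I, O)``
tuples, evaluated top to bottom.  The first tuple whose regulator currently
equals its canalyzing value ``I`` forces the gene to the canalyzed value
``O``; if no tuple fires, the gene takes the default output, which is the
complement of the last tuple's ``O``.  All genes update synchronously, so
every trajectory is deterministic and eventually falls into a fixed point or
a limit cycle (an attractor).

Perturbation experiments are expressed as *clamps*: a knocked-out gene is
pinned at 0 and an overexpressed gene at 1 for the whole trajectory,
including the initial state.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NCFRule",
    "BooleanNetwork",
    "Attractor",
    "evaluate_rule",
    "synchronous_step",
    "find_attractor",
    "edges_of",
    "tuple_sign",
    "DEFAULT_MAX_STEPS",
]

#: Step budget for attractor search before a trajectory is truncated.
DEFAULT_MAX_STEPS = 2000

Clamps = Mapping[int, int]
Edge = tuple[int, int, int]  # (source, target, sign) with sign in {+1, -1}


def _check_bit(value: int, what: str) -> int:
    if value not in (0, 1):
        raise ValueError(f"{what} must be 0 or 1, got {value!r}")
    return int(value)


def tuple_sign(canalyzing: int, canalyzed: int) -> int:
    """Sign of the regulation encoded by one canalyzing tuple.

    ``I == O`` means the regulator's presence drives the target the same
    way (activation, +1); ``I != O`` means it drives it oppositely
    (inhibition, -1).  Flipping both bits leaves the sign unchanged.
    """
    return 1 if canalyzing == canalyzed else -1


@dataclass(frozen=True)
class NCFRule:
    """Nested canalyzing update rule for one target gene.

    Parameters
    ----------
    target
        Index of the regulated gene.
    tuples
        Ordered ``(regulator, I, O)`` canalyzing tuples.  Regulators are
        pairwise distinct and never equal the target (no self-loops).
    default_out
        Output when no tuple fires.  Derived as ``1 - O`` of the last tuple
        when omitted; an explicit inconsistent value is rejected unless the
        rule is built with ``permissive=True`` (used when reading foreign
        rule files).
    """

    target: int
    tuples: tuple[tuple[int, int, int], ...]
    default_out: int | None = None
    permissive: InitVar[bool] = False

    def __post_init__(self, permissive: bool) -> None:
        tup = tuple(
            (int(v), _check_bit(i, "canalyzing value I"), _check_bit(o, "canalyzed value O"))
            for v, i, o in self.tuples
        )
        object.__setattr__(self, "tuples", tup)
        if not tup:
            raise ValueError(f"rule for gene {self.target} needs at least one canalyzing tuple")
        regs = [v for v, _, _ in tup]
        if len(set(regs)) != len(regs):
            raise ValueError(f"rule for gene {self.target} lists a regulator twice: {regs}")
        if self.target in regs:
            raise ValueError(f"rule for gene {self.target} contains a self-loop")
        derived = 1 - tup[-1][2]
        if self.default_out is None:
            object.__setattr__(self, "default_out", derived)
        else:
            _check_bit(self.default_out, "default output")
            if self.default_out != derived and not permissive:
                raise ValueError(
                    f"rule for gene {self.target}: default output {self.default_out} "
                    f"must equal 1 - O of the last tuple ({derived})"
                )

    @property
    def regulators(self) -> tuple[int, ...]:
        return tuple(v for v, _, _ in self.tuples)

    @property
    def k(self) -> int:
        """Number of regulatory inputs."""
        return len(self.tuples)


@dataclass(frozen=True)
class BooleanNetwork:
    """A set of genes with one NCF rule per gene."""

    gene_names: tuple[str, ...]
    rules: tuple[NCFRule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "rules", tuple(self.rules))
        n = len(self.gene_names)
        if len(set(self.gene_names)) != n:
            raise ValueError("gene names must be unique")
        if len(self.rules) != n:
            raise ValueError(f"expected {n} rules, got {len(self.rules)}")
        for i, rule in enumerate(self.rules):
            if rule.target != i:
                raise ValueError(f"rule at position {i} targets gene {rule.target}")
            for v in rule.regulators:
                if not 0 <= v < n:
                    raise ValueError(f"rule for gene {i} references unknown gene {v}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"unknown gene {name!r}") from None

    def edges(self) -> list[Edge]:
        return edges_of(self)


@dataclass(frozen=True)
class Attractor:
    """The cyclic state set a deterministic trajectory converges to.

    ``states[j+1 mod p]`` is the synchronous successor of ``states[j]``;
    ``tau`` is the transient length (the minimal ``t`` with
    ``v_t = v_{t+p}``).  When the step budget is exhausted before a state
    repeats, the final state alone is returned as a period-1 pseudo-attractor
    with ``truncated=True``.
    """

    states: tuple[tuple[int, ...], ...]
    tau: int
    truncated: bool = False

    @property
    def period(self) -> int:
        return len(self.states)


def _as_state(state: Sequence[int], n: int) -> np.ndarray:
    arr = np.asarray(state, dtype=np.int8)
    if arr.shape != (n,):
        raise ValueError(f"state must have length {n}, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("state values must be 0 or 1")
    return arr


def _check_clamps(clamps: Clamps | None, n: int) -> dict[int, int]:
    if not clamps:
        return {}
    out = {}
    for g, b in clamps.items():
        if not 0 <= g < n:
            raise IndexError(f"clamped gene index {g} out of range for {n} genes")
        out[int(g)] = _check_bit(b, f"clamp value for gene {g}")
    return out


def evaluate_rule(rule: NCFRule, state: Sequence[int]) -> int:
    """Evaluate one NCF: output of the first firing tuple, else the default."""
    n = len(state)
    for v, canalyzing, canalyzed in rule.tuples:
        if not 0 <= v < n:
            raise IndexError(f"regulator index {v} out of range for state of length {n}")
        if state[v] == canalyzing:
            return canalyzed
    return rule.default_out


def synchronous_step(
    net: BooleanNetwork, state: Sequence[int], clamps: Clamps | None = None
) -> np.ndarray:
    """One synchronous update: every gene reads the *current* state.

    Clamped genes take their clamp value regardless of their rule.
    """
    n = net.n_genes
    cur = _as_state(state, n)
    clamp = _check_clamps(clamps, n)
    nxt = np.empty(n, dtype=np.int8)
    for i, rule in enumerate(net.rules):
        nxt[i] = evaluate_rule(rule, cur)
    for g, b in clamp.items():
        nxt[g] = b
    return nxt


def find_attractor(
    net: BooleanNetwork,
    initial: Sequence[int],
    clamps: Clamps | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Attractor:
    """Follow the trajectory from ``initial`` until a state repeats.

    Clamps are applied to the initial state as well, so a knocked-out gene is
    0 from time 0 onward.  Cycle detection uses a visited-state hash index,
    so memory is linear in the transient plus the period.  If no state
    repeats within ``max_steps`` updates the final state is returned as a
    truncated period-1 pseudo-attractor.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    n = net.n_genes
    clamp = _check_clamps(clamps, n)
    state = _as_state(initial, n).copy()  # never mutate the caller's state
    for g, b in clamp.items():
        state[g] = b

    seen: dict[tuple[int, ...], int] = {}
    trajectory: list[tuple[int, ...]] = []
    for t in range(max_steps + 1):
        key = tuple(int(b) for b in state)
        first = seen.get(key)
        if first is not None:
            return Attractor(states=tuple(trajectory[first:t]), tau=first)
        seen[key] = t
        trajectory.append(key)
        if t == max_steps:
            break
        state = synchronous_step(net, state, clamp)
    return Attractor(states=(trajectory[-1],), tau=max_steps, truncated=True)


def edges_of(net: BooleanNetwork) -> list[Edge]:
    """Signed directed edge set induced by the rules, one edge per tuple."""
    edges: list[Edge] = []
    for rule in net.rules:
        for v, canalyzing, canalyzed in rule.tuples:
            edges.append((v, rule.target, tuple_sign(canalyzing, canalyzed)))
    return edges
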