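"""Structural and dynamics accuracy of an inferred network.

Structural metrics compare the inferred signed directed edge set against the
gold standard over all ``2 * N * (N - 1)`` possible signed ordered gene
pairs: precision ``TP / (TP + FP)``, recall ``TP / (TP + FN)`` and
structural accuracy ``(TP + TN) / (TP + FP + FN + TN)``.  An edge inferred
with the wrong sign counts as a false positive and its true counterpart as a
false negative (an unsigned comparison is available for cross-tool scoring).

Dynamics metrics replay the experimental protocol: for every experiment row
the candidate network is initialized at the Boolean expression of the row's
base wild-type experiment, the mutated gene (if any) is clamped (KO -> 0,
OE -> 1), and the trajectory is simulated to its attractor.  The per-gene
similarity ``s_i`` is the fraction of attractor states agreeing with the
observed value, the per-experiment similarity ``s`` the mean over genes, and
the dynamics accuracy the mean of ``s`` over experiments.  The per-gene
average similarity over experiments (``s_bar_i``) guides the mutation-gene
choice of the genetic algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Attractor, BooleanNetwork, DEFAULT_MAX_STEPS, Edge, find_attractor
from .io import ExpressionDataset

__all__ = [
    "StructuralReport",
    "DynamicsReport",
    "simulate_experiment",
    "state_similarity",
    "dynamics_accuracy",
    "structural_metrics",
]


@dataclass(frozen=True)
class StructuralReport:
    """Signed-pair confusion counts; the ratio metrics recompute from them."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def structural_accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "structural_accuracy": self.structural_accuracy,
        }


@dataclass(frozen=True)
class DynamicsReport:
    per_experiment: np.ndarray  # s(e, attractor) per dataset row
    per_gene: np.ndarray  # s_bar_i, mean of s_i over experiments
    truncated_rows: tuple[int, ...] = ()

    @property
    def dynamics_accuracy(self) -> float:
        return float(self.per_experiment.mean())

    def as_dict(self) -> dict[str, float]:
        return {"dynamics_accuracy": self.dynamics_accuracy}


def simulate_experiment(
    net: BooleanNetwork,
    row: int,
    dataset: ExpressionDataset,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Attractor:
    """Attractor the network reaches under one experiment's protocol.

    The initial state is the Boolean expression of the row's base wild-type
    experiment (the row itself for wild-type rows); KO/OE rows clamp the
    mutated gene for the whole trajectory.
    """
    if dataset.boolean is None:
        raise ValueError("dynamics scoring needs a binarized dataset")
    base = dataset.base_row_index(row)
    return find_attractor(
        net, dataset.boolean[base], dataset.clamps_for_row(row), max_steps=max_steps
    )


def state_similarity(e: np.ndarray, attractor: Attractor) -> tuple[float, np.ndarray]:
    """Similarity of an observed Boolean expression to an attractor.

    Returns ``(s, s_i)`` where ``s_i`` is, per gene, the fraction of
    attractor states whose value matches the observation, and ``s`` is the
    mean of ``s_i`` over genes.
    """
    e = np.asarray(e, dtype=np.int8)
    states = np.asarray(attractor.states, dtype=np.int8)
    if states.shape[1] != e.shape[0]:
        raise ValueError("attractor and expression dimensions differ")
    s_i = (states == e[None, :]).mean(axis=0)
    return float(s_i.mean()), s_i


def dynamics_accuracy(
    net: BooleanNetwork,
    dataset: ExpressionDataset,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> DynamicsReport:
    """Dynamics accuracy of a network on a dataset (also the GA fitness)."""
    if dataset.n_experiments == 0:
        raise ValueError("dataset is empty")
    n = dataset.n_genes
    per_exp = np.empty(dataset.n_experiments)
    per_gene = np.zeros((dataset.n_experiments, n))
    truncated = []
    for row in range(dataset.n_experiments):
        att = simulate_experiment(net, row, dataset, max_steps=max_steps)
        if att.truncated:
            truncated.append(row)
        s, s_i = state_similarity(dataset.boolean[row], att)
        per_exp[row] = s
        per_gene[row] = s_i
    return DynamicsReport(
        per_experiment=per_exp,
        per_gene=per_gene.mean(axis=0),
        truncated_rows=tuple(truncated),
    )


def _unsign(edges: set[Edge]) -> set[tuple[int, int]]:
    return {(s, t) for s, t, _ in edges}


def structural_metrics(
    inferred: list[Edge] | set[Edge],
    truth: list[Edge] | set[Edge],
    n_genes: int,
    signed: bool = True,
) -> StructuralReport:
    """Confusion counts of an inferred signed edge set against the gold one.

    The universe has ``2 * N * (N-1)`` signed ordered pairs (or
    ``N * (N-1)`` unsigned pairs with ``signed=False``).
    """
    inf_s: set = set(inferred)
    tru_s: set = set(truth)
    for s, t, _ in inf_s | tru_s:
        if s == t:
            raise ValueError("edge sets must be self-loop-free")
        if not (0 <= s < n_genes and 0 <= t < n_genes):
            raise ValueError(f"edge ({s}, {t}) outside gene range")
    if not signed:
        inf_s, tru_s = _unsign(inf_s), _unsign(tru_s)
    universe = (2 if signed else 1) * n_genes * (n_genes - 1)
    tp = len(inf_s & tru_s)
    fp = len(inf_s - tru_s)
    fn = len(tru_s - inf_s)
    return StructuralReport(tp=tp, fp=fp, fn=fn, tn=universe - tp - fp - fn)


def write_report(
    structural: StructuralReport | None,
    dynamics: DynamicsReport | None,
    gene_names: list[str],
    tsv_path: str | Path,
) -> dict:
    """Flat key-value TSV report; returns the same content as a dict."""
    flat: dict = {}
    if structural is not None:
        flat.update(structural.as_dict())
    if dynamics is not None:
        flat.update(dynamics.as_dict())
        for g, v in zip(gene_names, dynamics.per_gene):
            flat[f"s_bar[{g}]"] = float(v)
        flat["n_truncated_rows"] = len(dynamics.truncated_rows)
    lines = [f"{k}\t{v:.6g}" if isinstance(v, float) else f"{k}\t{v}" for k, v in flat.items()]
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    return flat
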