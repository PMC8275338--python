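"""Readers and writers for datasets, networks, constraints and reports.

File dialects
-------------
Expression dataset (TSV)
    Header ``id  MG  ET  WT  <gene> ...`` (the ``id`` column is optional;
    ids are auto-generated as ``WT01``/``KO01``/``OE01`` when absent).
    ``ET`` is one of ``WT``, ``KO``, ``OE``; for perturbation rows ``MG``
    names the mutated gene and ``WT`` the id of the base wild-type row.
NCF rule file
    One rule per line: ``gene = (regulator,I,O)(regulator,I,O)...:Odef``.
    Line order defines the gene index order.
Signed edge list (SIF-like TSV)
    ``source  +1|-1  target``.
Constraint set (TSV)
    ``source  target  sign  directness`` with a header row.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BooleanNetwork, Edge, NCFRule

__all__ = [
    "ExpressionDataset",
    "ParseError",
    "read_dataset",
    "write_dataset",
    "read_network",
    "write_network",
    "write_edges",
]

ET_TOKENS = ("WT", "KO", "OE")


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line."""


@dataclass
class ExpressionDataset:
    """Steady-state expression matrix with per-experiment annotations.

    Rows are experiments, columns are genes.  ``boolean`` and/or ``real``
    hold the binarized and raw matrices; every non-wild-type row names the
    mutated gene and the wild-type row it perturbs.
    """

    gene_names: tuple[str, ...]
    ids: tuple[str, ...]
    mutated_gene: tuple[str | None, ...]
    experiment_type: tuple[str, ...]
    base_wt: tuple[str | None, ...]
    boolean: np.ndarray | None = None
    real: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_names = tuple(self.gene_names)
        self.ids = tuple(self.ids)
        self.mutated_gene = tuple(self.mutated_gene)
        self.experiment_type = tuple(self.experiment_type)
        self.base_wt = tuple(self.base_wt)
        r, n = self.n_experiments, self.n_genes
        if len(set(self.gene_names)) != n:
            raise ValueError("gene names must be unique")
        if len(set(self.ids)) != r:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate experiment ids: {dupes}")
        for name, ann in (
            ("mutated_gene", self.mutated_gene),
            ("experiment_type", self.experiment_type),
            ("base_wt", self.base_wt),
        ):
            if len(ann) != r:
                raise ValueError(f"{name} must have one entry per experiment")
        if self.boolean is None and self.real is None:
            raise ValueError("dataset needs a boolean or a real matrix")
        for label, mat in (("boolean", self.boolean), ("real", self.real)):
            if mat is None:
                continue
            mat = np.asarray(mat)
            if mat.shape != (r, n):
                raise ValueError(f"{label} matrix shape {mat.shape} != ({r}, {n})")
            if label == "boolean":
                if not np.isin(mat, (0, 1)).all():
                    raise ValueError("boolean matrix must contain only 0/1")
                self.boolean = mat.astype(np.int8)
            else:
                if not np.isfinite(mat).all():
                    raise ValueError("real matrix contains missing or non-finite values")
                self.real = mat.astype(np.float64)
        id_index = {eid: j for j, eid in enumerate(self.ids)}
        for j in range(r):
            et = self.experiment_type[j]
            if et not in ET_TOKENS:
                raise ValueError(f"row {self.ids[j]!r}: unknown experiment type {et!r}")
            mg, wt = self.mutated_gene[j], self.base_wt[j]
            if et == "WT":
                if mg:
                    raise ValueError(f"row {self.ids[j]!r}: wild-type row must not name a mutated gene")
            else:
                if not mg or mg not in self.gene_names:
                    raise ValueError(f"row {self.ids[j]!r}: mutated gene {mg!r} is not a known gene")
                if not wt or wt not in id_index:
                    raise ValueError(f"row {self.ids[j]!r}: base wild-type row {wt!r} not found")
                if self.experiment_type[id_index[wt]] != "WT":
                    raise ValueError(f"row {self.ids[j]!r}: base row {wt!r} is not a wild-type row")

    @property
    def n_experiments(self) -> int:
        return len(self.ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"unknown gene {name!r}") from None

    def base_row_index(self, row: int) -> int:
        """Index of the base wild-type row (the row itself if wild-type)."""
        if self.experiment_type[row] == "WT":
            return row
        return self.ids.index(self.base_wt[row])

    def clamps_for_row(self, row: int) -> dict[int, int]:
        """Perturbation clamps of a row: KO pins the gene at 0, OE at 1."""
        et = self.experiment_type[row]
        if et == "WT":
            return {}
        g = self.gene_index(self.mutated_gene[row])
        return {g: 0 if et == "KO" else 1}

    def with_boolean(self, matrix: np.ndarray) -> "ExpressionDataset":
        return replace(self, boolean=np.asarray(matrix, dtype=np.int8))


def _auto_ids(ets: list[str]) -> list[str]:
    counters = {t: 0 for t in ET_TOKENS}
    ids = []
    for et in ets:
        counters.setdefault(et, 0)
        counters[et] += 1
        ids.append(f"{et}{counters[et]:02d}")
    return ids


def read_dataset(path: str | Path, mode: str = "boolean") -> ExpressionDataset:
    """Read an expression dataset TSV; see the module docstring for the dialect."""
    if mode not in ("boolean", "real"):
        raise ValueError("mode must be 'boolean' or 'real'")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    cols = list(df.columns)
    has_id = bool(cols) and cols[0].lower() == "id"
    meta = cols[1:4] if has_id else cols[0:3]
    if [c.upper() for c in meta] != ["MG", "ET", "WT"]:
        raise ParseError(f"{path}: expected columns [id] MG ET WT <genes...>, got {cols[:4]}")
    genes = cols[4:] if has_id else cols[3:]
    if not genes:
        raise ParseError(f"{path}: no gene columns found")
    ets = [v.strip() for v in df[meta[1]]]
    for j, et in enumerate(ets):
        if et not in ET_TOKENS:
            raise ParseError(f"{path}, line {j + 2}: unknown experiment type {et!r}")
    ids = [v.strip() for v in df[cols[0]]] if has_id else _auto_ids(ets)
    mgs = [v.strip() or None for v in df[meta[0]]]
    wts = [v.strip() or None for v in df[meta[2]]]
    raw = df[genes].to_numpy()
    try:
        values = raw.astype(np.float64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    kwargs: dict = {"boolean": None, "real": None}
    if mode == "boolean":
        if not np.isin(values, (0.0, 1.0)).all():
            bad = int(np.argmax(~np.isin(values, (0.0, 1.0)).all(axis=1))) + 2
            raise ParseError(f"{path}, line {bad}: boolean dataset contains non-0/1 values")
        kwargs["boolean"] = values.astype(np.int8)
    else:
        kwargs["real"] = values
    try:
        return ExpressionDataset(
            gene_names=tuple(genes),
            ids=tuple(ids),
            mutated_gene=tuple(mgs),
            experiment_type=tuple(ets),
            base_wt=tuple(wts),
            **kwargs,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_dataset(ds: ExpressionDataset, path: str | Path, mode: str = "boolean") -> None:
    """Write a dataset TSV (deterministic for identical inputs)."""
    if mode == "boolean":
        mat = ds.boolean
    elif mode == "real":
        mat = ds.real
    else:
        raise ValueError("mode must be 'boolean' or 'real'")
    if mat is None:
        raise ValueError(f"dataset holds no {mode} matrix")
    df = pd.DataFrame(mat, columns=list(ds.gene_names))
    if mode == "real":
        df = df.map(lambda x: format(x, ".6g"))
    df.insert(0, "WT", [v or "" for v in ds.base_wt])
    df.insert(0, "ET", list(ds.experiment_type))
    df.insert(0, "MG", [v or "" for v in ds.mutated_gene])
    df.insert(0, "id", list(ds.ids))
    df.to_csv(path, sep="\t", index=False)


_TUPLE_RE = re.compile(r"\(\s*([^,()\s]+)\s*,\s*([01])\s*,\s*([01])\s*\)")
_RULE_RE = re.compile(r"^(?P<gene>\S+)\s*=\s*(?P<body>(?:\([^)]*\))+)\s*:\s*(?P<dflt>[01])\s*$")


def read_network(path: str | Path, strict: bool = True) -> BooleanNetwork:
    """Read an NCF rule file.

    Line order defines the gene order.  With ``strict=True`` a default
    output inconsistent with ``1 - O`` of the last tuple is an error;
    otherwise it is kept as written and a warning is emitted.
    """
    path = Path(path)
    lines = [
        (ln, raw.strip())
        for ln, raw in enumerate(path.read_text().splitlines(), start=1)
        if raw.strip() and not raw.lstrip().startswith("#")
    ]
    genes: list[str] = []
    parsed: list[tuple[int, str, list[tuple[str, int, int]], int]] = []
    for ln, line in lines:
        m = _RULE_RE.match(line)
        if not m:
            raise ParseError(f"{path}, line {ln}: malformed rule {line!r}")
        gene = m.group("gene")
        if gene in genes:
            raise ParseError(f"{path}, line {ln}: gene {gene!r} has more than one rule")
        body = m.group("body")
        tuples = [(t[0], int(t[1]), int(t[2])) for t in _TUPLE_RE.findall(body)]
        if len(tuples) != body.count("("):
            raise ParseError(f"{path}, line {ln}: malformed tuple in {body!r}")
        genes.append(gene)
        parsed.append((ln, gene, tuples, int(m.group("dflt"))))
    if not parsed:
        raise ParseError(f"{path}: empty rule file")
    index = {g: i for i, g in enumerate(genes)}
    rules = []
    for ln, gene, tuples, dflt in parsed:
        idx_tuples = []
        for reg, i, o in tuples:
            if reg not in index:
                raise ParseError(f"{path}, line {ln}: unknown regulator {reg!r}")
            idx_tuples.append((index[reg], i, o))
        derived = 1 - idx_tuples[-1][2]
        if dflt != derived:
            msg = f"{path}, line {ln}: default output {dflt} != 1 - O of last tuple ({derived})"
            if strict:
                raise ParseError(msg)
            warnings.warn(msg, stacklevel=2)
        try:
            rules.append(NCFRule(index[gene], tuple(idx_tuples), dflt, permissive=not strict))
        except ValueError as exc:
            raise ParseError(f"{path}, line {ln}: {exc}") from exc
    return BooleanNetwork(tuple(genes), tuple(rules))


def write_network(
    net: BooleanNetwork, rule_path: str | Path, sif_path: str | Path | None = None
) -> None:
    """Write a network in the rule format, optionally also as a signed edge list."""
    lines = []
    for rule in net.rules:
        body = "".join(
            f"({net.gene_names[v]},{i},{o})" for v, i, o in rule.tuples
        )
        lines.append(f"{net.gene_names[rule.target]} = {body}:{rule.default_out}")
    Path(rule_path).write_text("\n".join(lines) + "\n")
    if sif_path is not None:
        write_edges(net.edges(), [str(g) for g in net.gene_names], sif_path)


def write_edges(edges: list[Edge], gene_names: list[str], path: str | Path) -> None:
    """Write a SIF-like signed edge list: ``source  +1|-1  target``."""
    lines = [
        f"{gene_names[s]}\t{'+1' if sign > 0 else '-1'}\t{gene_names[t]}"
        for s, t, sign in edges
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_edges(path: str | Path, gene_names: list[str]) -> list[Edge]:
    """Read a SIF-like signed edge list using a known gene order."""
    index = {g: i for i, g in enumerate(gene_names)}
    edges: list[Edge] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3 or parts[1] not in ("+1", "-1", "1"):
            raise ParseError(f"{path}, line {ln}: malformed edge line {line!r}")
        src, sign, tgt = parts
        if src not in index or tgt not in index:
            raise ParseError(f"{path}, line {ln}: unknown gene in edge {line!r}")
        edges.append((index[src], index[tgt], 1 if sign in ("+1", "1") else -1))
    return edges
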