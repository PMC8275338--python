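"""Boolean discretization of real-valued steady-state expression.

Each gene (column) is clustered into two groups by 1-D 2-means; rows in the
cluster with the higher mean become 1 ("on"), the others 0.  Per column the
clustering runs Lloyd's algorithm from 10 seeded random centroid pairs and
keeps the lowest within-cluster SSE; among equal-SSE partitions the one with
the lower split threshold wins, which makes the result deterministic up to
the seed while still letting different seeds resolve genuine SSE ties
differently (the protocol used to probe binarization stability re-runs the
clustering under many seeds).

Zero-variance columns carry no evidence of activity and map to all 0 (with a
warning).  Missing values are rejected.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import ExpressionDataset

__all__ = ["binarize", "binarize_matrix"]

_N_RESTARTS = 10


def _kmeans2_column(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """1-D 2-means labels for one column, higher-mean cluster -> 1."""
    best_sse = np.inf
    best_threshold = np.inf
    best_labels: np.ndarray | None = None
    for _ in range(_N_RESTARTS):
        c = rng.choice(x, size=2, replace=False)
        lo, hi = (c[0], c[1]) if c[0] <= c[1] else (c[1], c[0])
        if lo == hi:  # degenerate draw; nudge apart
            hi = lo + 1.0
        for _ in range(100):
            labels = (np.abs(x - hi) < np.abs(x - lo)).astype(np.int8)
            new_lo = x[labels == 0].mean() if (labels == 0).any() else lo
            new_hi = x[labels == 1].mean() if (labels == 1).any() else hi
            if new_lo == lo and new_hi == hi:
                break
            lo, hi = new_lo, new_hi
        sse = float(((x[labels == 0] - lo) ** 2).sum() + ((x[labels == 1] - hi) ** 2).sum())
        on = x[labels == 1]
        threshold = float(on.min()) if on.size else np.inf
        if sse < best_sse - 1e-12 or (
            abs(sse - best_sse) <= 1e-12 and threshold < best_threshold
        ):
            best_sse, best_threshold, best_labels = sse, threshold, labels
    assert best_labels is not None
    if not best_labels.any():  # both centroids collapsed below all points
        return np.zeros_like(best_labels)
    return best_labels


def binarize_matrix(values: np.ndarray, seed: int = 0) -> np.ndarray:
    """Binarize an experiments x genes real matrix column by column."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    if values.shape[0] < 2:
        raise ValueError("binarization needs at least 2 experiments")
    if not np.isfinite(values).all():
        raise ValueError("matrix contains missing or non-finite values")
    rng = np.random.default_rng(seed)
    out = np.empty(values.shape, dtype=np.int8)
    for j in range(values.shape[1]):
        col = values[:, j]
        if np.ptp(col) == 0.0:
            warnings.warn(f"column {j} has zero variance; mapped to all 0", stacklevel=2)
            out[:, j] = 0
        else:
            out[:, j] = _kmeans2_column(col, rng)
    return out


def binarize(dataset: ExpressionDataset, seed: int = 0) -> ExpressionDataset:
    """Return a copy of the dataset with its boolean matrix recomputed
    from the real matrix by per-gene 2-means."""
    if dataset.real is None:
        raise ValueError("dataset holds no real-valued matrix to binarize")
    return dataset.with_boolean(binarize_matrix(dataset.real, seed))
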