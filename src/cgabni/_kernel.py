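"""Jit-compiled batch attractor simulation.

The genetic algorithm scores hundreds of candidate networks per generation
and the benchmark generator samples attractors from thousands of initial
states, so the inner simulation loop is compiled with numba.  Networks are
flattened to arrays: ``reg``/``cin``/``cout`` hold the concatenated
canalyzing tuples of all rules, ``ptr[i]:ptr[i+1]`` delimits gene ``i``'s
tuples and ``dflt[i]`` is its default output.  States are encoded as uint64
bit masks, so the fast path is limited to networks of at most 64 genes;
callers fall back to :func:`cgabni.core.find_attractor` beyond that.

The compiled routines are pure functions of their arguments (no global
state, no RNG), which is what makes threaded fitness evaluation bit-identical
to sequential evaluation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import BooleanNetwork

__all__ = ["compile_network", "dynamics_scores", "attractor_summary", "MAX_KERNEL_GENES"]

MAX_KERNEL_GENES = 64


def compile_network(net: BooleanNetwork):
    """Flatten a network into the kernel's array representation."""
    reg, cin, cout, ptr = [], [], [], [0]
    dflt = []
    for rule in net.rules:
        for v, i, o in rule.tuples:
            reg.append(v)
            cin.append(i)
            cout.append(o)
        ptr.append(len(reg))
        dflt.append(rule.default_out)
    return (
        np.asarray(reg, dtype=np.int64),
        np.asarray(cin, dtype=np.int8),
        np.asarray(cout, dtype=np.int8),
        np.asarray(ptr, dtype=np.int64),
        np.asarray(dflt, dtype=np.int8),
    )


@njit(cache=False, nogil=True)
def _simulate_row(reg, cin, cout, ptr, dflt, state, clamp_gene, clamp_val,
                  max_steps, codes, traj):  # pragma: no cover - exercised via wrappers
    """Run one trajectory; returns (tau, period, truncated)."""
    n = state.shape[0]
    if clamp_gene >= 0:
        state[clamp_gene] = clamp_val
    t = 0
    while True:
        code = np.uint64(0)
        for i in range(n):
            if state[i]:
                code |= np.uint64(1) << np.uint64(i)
        for u in range(t):
            if codes[u] == code:
                return u, t - u, False
        codes[t] = code
        for i in range(n):
            traj[t, i] = state[i]
        if t == max_steps:
            return t, 1, True
        for i in range(n):
            val = dflt[i]
            for j in range(ptr[i], ptr[i + 1]):
                if state[reg[j]] == cin[j]:
                    val = cout[j]
                    break
            traj[t + 1, i] = val  # scratch row reused as the next state
        for i in range(n):
            state[i] = traj[t + 1, i]
        if clamp_gene >= 0:
            state[clamp_gene] = clamp_val
        t += 1


@njit(cache=False, nogil=True)
def _dynamics_scores(reg, cin, cout, ptr, dflt, init, clamp_gene, clamp_val,
                     obs, max_steps):  # pragma: no cover - exercised via wrappers
    n_rows, n = init.shape
    sims = np.zeros((n_rows, n))
    truncated = np.zeros(n_rows, dtype=np.uint8)
    codes = np.empty(max_steps + 1, dtype=np.uint64)
    traj = np.empty((max_steps + 2, n), dtype=np.int8)
    state = np.empty(n, dtype=np.int8)
    for r in range(n_rows):
        for i in range(n):
            state[i] = init[r, i]
        tau, p, trunc = _simulate_row(
            reg, cin, cout, ptr, dflt, state, clamp_gene[r], clamp_val[r],
            max_steps, codes, traj,
        )
        if trunc:
            truncated[r] = 1
        for i in range(n):
            m = 0
            for u in range(tau, tau + p):
                if traj[u, i] == obs[r, i]:
                    m += 1
            sims[r, i] = m / p
    return sims, truncated


@njit(cache=False, nogil=True)
def _attractor_summary(reg, cin, cout, ptr, dflt, init, clamp_gene, clamp_val,
                       max_steps):  # pragma: no cover - exercised via wrappers
    n_rows, n = init.shape
    canon = np.empty(n_rows, dtype=np.uint64)
    majority = np.empty((n_rows, n), dtype=np.int8)
    periods = np.empty(n_rows, dtype=np.int64)
    truncated = np.zeros(n_rows, dtype=np.uint8)
    codes = np.empty(max_steps + 1, dtype=np.uint64)
    traj = np.empty((max_steps + 2, n), dtype=np.int8)
    state = np.empty(n, dtype=np.int8)
    for r in range(n_rows):
        for i in range(n):
            state[i] = init[r, i]
        tau, p, trunc = _simulate_row(
            reg, cin, cout, ptr, dflt, state, clamp_gene[r], clamp_val[r],
            max_steps, codes, traj,
        )
        if trunc:
            truncated[r] = 1
        cmin = codes[tau]
        for u in range(tau, tau + p):
            if codes[u] < cmin:
                cmin = codes[u]
        canon[r] = cmin
        periods[r] = p
        for i in range(n):
            ones = 0
            for u in range(tau, tau + p):
                ones += traj[u, i]
            majority[r, i] = 1 if 2 * ones >= p else 0
    return canon, majority, periods, truncated


def _check_size(net: BooleanNetwork) -> None:
    if net.n_genes > MAX_KERNEL_GENES:
        raise ValueError(
            f"kernel supports at most {MAX_KERNEL_GENES} genes, got {net.n_genes}"
        )


def dynamics_scores(
    compiled,
    init: np.ndarray,
    clamp_gene: np.ndarray,
    clamp_val: np.ndarray,
    obs: np.ndarray,
    max_steps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row, per-gene similarities of a compiled network against
    observations; mirrors :func:`cgabni.scoring.dynamics_accuracy`.

    ``clamp_gene[r] = -1`` means no clamp for row ``r``.
    """
    reg, cin, cout, ptr, dflt = compiled
    return _dynamics_scores(
        reg, cin, cout, ptr, dflt,
        np.ascontiguousarray(init, dtype=np.int8),
        np.ascontiguousarray(clamp_gene, dtype=np.int64),
        np.ascontiguousarray(clamp_val, dtype=np.int8),
        np.ascontiguousarray(obs, dtype=np.int8),
        int(max_steps),
    )


def attractor_summary(
    net: BooleanNetwork,
    init: np.ndarray,
    clamp_gene: np.ndarray,
    clamp_val: np.ndarray,
    max_steps: int,
):
    """Canonical attractor code (minimal state bit mask over the cycle),
    per-gene majority vector (ties -> 1), period and truncation flag for
    every initial state."""
    _check_size(net)
    reg, cin, cout, ptr, dflt = compile_network(net)
    return _attractor_summary(
        reg, cin, cout, ptr, dflt,
        np.ascontiguousarray(init, dtype=np.int8),
        np.ascontiguousarray(clamp_gene, dtype=np.int64),
        np.ascontiguousarray(clamp_val, dtype=np.int8),
        int(max_steps),
    )


def decode_state(code: int, n_genes: int) -> np.ndarray:
    """Inverse of the kernel's bit-mask state encoding."""
    code = int(code)
    return np.array([(code >> i) & 1 for i in range(n_genes)], dtype=np.int8)
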