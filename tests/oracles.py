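"""Independent reference implementations used to check the package.

These deliberately avoid the package's own code paths: the NCF oracle
evaluates the quantified piecewise definition instead of a short-circuit
scan, the attractor oracle walks a fully enumerated transition graph, the
2-means oracle enumerates every contiguous split of the sorted column, and
the signed-path oracle enumerates walks explicitly.
"""

from __future__ import annotations

import numpy as np


def ncf_eval(tuples, default_out, state):
    """Piecewise NCF definition: output O_m for the minimal m such that all
    earlier regulators miss their canalyzing value and regulator m hits."""
    k = len(tuples)
    for m in range(k):
        earlier_miss = all(state[tuples[j][0]] != tuples[j][1] for j in range(m))
        if earlier_miss and state[tuples[m][0]] == tuples[m][1]:
            return tuples[m][2]
    return default_out


def transition_map(net):
    """Successor of every one of the 2^N states, via the NCF oracle."""
    n = net.n_genes
    succ = np.empty(2**n, dtype=np.int64)
    for code in range(2**n):
        state = [(code >> i) & 1 for i in range(n)]
        nxt = 0
        for i, rule in enumerate(net.rules):
            if ncf_eval(rule.tuples, rule.default_out, state):
                nxt |= 1 << i
        succ[code] = nxt
    return succ


def brute_attractor(succ, initial_code):
    """(tau, cycle codes in trajectory order) by walking the enumerated map."""
    seen = {}
    code = initial_code
    t = 0
    while code not in seen:
        seen[code] = t
        code = int(succ[code])
        t += 1
    tau = seen[code]
    cycle = [c for c, time in sorted(seen.items(), key=lambda kv: kv[1]) if time >= tau]
    return tau, cycle


def best_two_means_split(col):
    """Exhaustive optimal 1-D 2-means: minimal-SSE contiguous split of the
    sorted values; ties toward the lower split threshold; labels by value."""
    order = np.sort(np.asarray(col, dtype=float))
    best = (np.inf, np.inf, None)  # (sse, threshold, labels)
    for cut in range(1, len(order)):
        lo, hi = order[:cut], order[cut:]
        if lo[-1] == hi[0]:
            continue  # equal values cannot be split by a distance rule
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        threshold = hi[0]
        if sse < best[0] - 1e-12 or (abs(sse - best[0]) <= 1e-12 and threshold < best[1]):
            best = (sse, threshold, (np.asarray(col) >= threshold).astype(np.int8))
    return best[2]


def signed_walks_reach(edges, source, target, sign, max_len):
    """Does a directed walk source -> target of edge-sign product ``sign``
    exist, with length in [1, max_len]?  Explicit breadth enumeration."""
    frontier = {(source, 1)}
    for _ in range(max_len):
        nxt = set()
        for node, par in frontier:
            for s, t, sg in edges:
                if s == node:
                    nxt.add((t, par * sg))
        if (target, sign) in nxt:
            return True
        frontier = frontier | nxt
    return False


def random_rule(rng, n_genes, target, k):
    """Uniform random NCF tuples for a target gene with k distinct regulators."""
    pool = [g for g in range(n_genes) if g != target]
    regs = rng.choice(pool, size=k, replace=False)
    return tuple((int(v), int(rng.integers(2)), int(rng.integers(2))) for v in regs)
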