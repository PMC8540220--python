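"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: reachability is
computed by boolean adjacency-matrix powers, t-tests by scipy, and BH
adjustment by statsmodels / a naive min-over-tail loop.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def random_graph(rng, n_nodes=None, directed=False, p=None):
    """A random edge list over string node names, seeded by ``rng``."""
    n = n_nodes or int(rng.integers(4, 30))
    p = p if p is not None else float(rng.uniform(0.05, 0.3))
    nodes = [f"N{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and (directed or i < j) and rng.random() < p:
                edges.append((nodes[i], nodes[j]))
    return nodes, edges


def reach_within(nodes, edges, directed, k, mode):
    """Boolean reachability within k hops via adjacency powers.

    Returns an (n, n) boolean matrix R where R[s, t] answers "is there a
    path of length <= k from s to t under ``mode``" (diagonal False).
    """
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        if u == v:
            continue
        A[idx[u], idx[v]] = True
        if not directed:
            A[idx[v], idx[u]] = True
    if directed and mode == "ignore":
        A = A | A.T
    power = A.copy()
    reach = A.copy()
    for _ in range(k - 1):
        power = power @ A
        reach |= power
    if directed and mode == "either":
        reach = reach | reach.T
    np.fill_diagonal(reach, False)
    return reach, idx


def welch_or_student(case, control, variant):
    """Two-sided two-sample t-test via scipy (the independent route)."""
    res = stats.ttest_ind(case, control, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def bh_naive(p, m=None):
    """Direct min-over-tail BH formula, O(n^2); for small vectors only."""
    p = np.asarray(p, dtype=float)
    m = m if m is not None else p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    out = np.empty_like(p)
    for i in range(p.size):
        tail = [sorted_p[j] * m / (j + 1) for j in range(i, p.size)]
        out[order[i]] = min(1.0, min(tail))
    return out
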