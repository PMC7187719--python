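"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: enumeration, direct formulas and scipy.sparse.csgraph
(not networkx) so every oracle follows a different code path than the
functions it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse.csgraph import shortest_path
from sympy.utilities.iterables import multiset_partitions


def adjacency(g) -> np.ndarray:
    n = g.number_of_nodes()
    a = np.zeros((n, n))
    for i, j in g.edges():
        a[i, j] = a[j, i] = 1.0
    return a


def brute_clustering(g) -> float:
    """Mean nodal clustering by explicit neighbor-pair counting."""
    a = adjacency(g)
    n = a.shape[0]
    coeffs = []
    for v in range(n):
        nbrs = np.flatnonzero(a[v])
        k = nbrs.size
        if k < 2:
            coeffs.append(0.0)
            continue
        links = sum(a[x, y] for x, y in itertools.combinations(nbrs, 2))
        coeffs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(coeffs))


def brute_path_length(g) -> float:
    """Mean shortest-path length over unordered pairs via csgraph."""
    d = shortest_path(adjacency(g), method="FW", unweighted=True)
    iu = np.triu_indices(d.shape[0], k=1)
    return float(d[iu].mean())


def partition_quality(g, partition) -> float:
    """Newman-Girvan Q by direct e_c / d_c arithmetic."""
    m = g.number_of_edges()
    q = 0.0
    for c in partition:
        c = set(c)
        e_c = sum(1 for i, j in g.edges() if i in c and j in c)
        d_c = sum(deg for node, deg in g.degree() if node in c)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def exhaustive_modularity(g) -> float:
    """Max Q over every partition of the node set (Bell-number search)."""
    nodes = list(g.nodes())
    return max(partition_quality(g, part) for part in multiset_partitions(nodes))


def bh_stepup(p_values, q_level=0.05):
    """Reference Benjamini-Hochberg step-up, written from the definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, m * p[idx] / rank)
        adjusted[idx] = running_min
    reject = adjusted <= q_level
    return adjusted, reject
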