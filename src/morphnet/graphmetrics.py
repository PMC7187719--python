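"""Graph-topology metrics and their null-normalized (small-world) forms.

For each density on the grid the binarized covariance network yields
modularity Q, mean clustering coefficient Cp and characteristic path
length Lp. Cp and Lp are normalized by their averages over N matching
null networks — random covariance matrices whose off-diagonal mean and
variance match the observed matrix (the Hirschberger-Qi-Steuer
construction), thresholded at the same density — giving

    gamma = Cp / Crand_p,   lambda = Lp / Lrand_p,   sigma = gamma / lambda.

A small-world topology satisfies gamma > 1, lambda ~ 1 and sigma > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import (CovarianceNetwork, DensityGrid, n_edges_at_density,
                       ranked_pairs, threshold_to_density)

METRIC_COLUMNS = ["density", "Q", "Cp", "Lp", "Crand_p", "Lrand_p",
                  "gamma", "lambda", "sigma", "n_null", "n_null_disconnected"]

#: Cap on the HQS factor count (reached only for a near-constant matrix,
#: whose off-diagonal variance target is ~0).
_MAX_FACTORS = 10_000


def clustering_coefficient(g: nx.Graph) -> float:
    """Mean nodal clustering coefficient Cp.

    Nodal value = 2 * (edges among neighbors) / (k (k-1)); nodes with
    degree < 2 contribute 0; Cp is the unweighted mean over all nodes.
    """
    return float(nx.average_clustering(g, count_zeros=True))


def characteristic_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length Lp over all unordered node pairs."""
    if g.number_of_nodes() < 2:
        raise ValueError("path length needs >= 2 nodes")
    if not nx.is_connected(g):
        raise ValueError(
            "graph is disconnected: characteristic path length is infinite "
            "(raise the density; see min_connected_density)")
    return float(nx.average_shortest_path_length(g))


def _largest_component_path_length(g: nx.Graph) -> tuple[float, bool]:
    """Lp on the largest connected component; flags whether g was disconnected."""
    if nx.is_connected(g):
        return float(nx.average_shortest_path_length(g)), False
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    if sub.number_of_nodes() < 2:
        return float("nan"), True
    return float(nx.average_shortest_path_length(sub)), True


def modularity_quality(g: nx.Graph, partition) -> float:
    """Newman-Girvan quality Q = sum_c [e_c/m - (d_c/2m)^2] of a partition."""
    return float(nx.community.modularity(g, partition))


def _refine_partition(g: nx.Graph, partition):
    """Greedy single-node moves to a local modularity optimum.

    Standard first-phase Louvain sweep applied at the finest level to a
    finished partition; moves a node to the neighboring (or a fresh
    singleton) community whenever the move strictly increases Q.
    """
    m = g.number_of_edges()
    comms = [set(c) for c in partition]
    comm_of = {v: ci for ci, c in enumerate(comms) for v in c}
    deg = dict(g.degree())
    sigma = [float(sum(deg[v] for v in c)) for c in comms]
    improved = True
    while improved:
        improved = False
        for v in g.nodes():
            a = comm_of[v]
            k_vc: dict[int, int] = {}
            for nb in g[v]:
                cb = comm_of[nb]
                k_vc[cb] = k_vc.get(cb, 0) + 1
            k_va = k_vc.get(a, 0)
            best_gain, best_c = 1e-13, a
            for b in list(k_vc) + [len(comms)]:
                if b == a:
                    continue
                k_vb = k_vc.get(b, 0)
                sigma_b = sigma[b] if b < len(comms) else 0.0
                gain = ((k_vb - k_va) / m
                        - deg[v] * (sigma_b - (sigma[a] - deg[v])) / (2.0 * m * m))
                if gain > best_gain:
                    best_gain, best_c = gain, b
            if best_c != a:
                comms[a].discard(v)
                sigma[a] -= deg[v]
                if best_c == len(comms):
                    comms.append({v})
                    sigma.append(float(deg[v]))
                else:
                    comms[best_c].add(v)
                    sigma[best_c] += deg[v]
                comm_of[v] = best_c
                improved = True
    return [c for c in comms if c]


def modularity(g: nx.Graph, seed: int = 0, n_restarts: int = 20):
    """Best-found modularity partition and its Q.

    Seeded Louvain optimization with `n_restarts` restarts plus one
    greedy-agglomerative (CNM) candidate, each polished by a
    single-node-move refinement sweep; the highest-Q partition is kept.
    Deterministic under fixed seed.
    """
    if g.number_of_edges() == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best_q, best_part = -np.inf, None
    candidates = [nx.community.louvain_communities(g, seed=int(seed) + r)
                  for r in range(n_restarts)]
    candidates.append([set(c) for c in nx.community.greedy_modularity_communities(g)])
    for part in candidates:
        part = _refine_partition(g, part)
        q = modularity_quality(g, part)
        if q > best_q + 1e-15:
            best_q, best_part = q, part
    return best_q, best_part


def hqs_null_covariance(net, seed: int = 0, n_factors: int | None = None) -> np.ndarray:
    """Random covariance matrix matching the observed off-diagonal moments.

    Hirschberger-Qi-Steuer construction: draw an N x m factor matrix X
    with i.i.d. N(mu, s^2) entries and return S = X X'. With
    mu^2 = e/m and s^2 solving m (s^4 + 2 mu^2 s^2) = v, the off-diagonal
    entries of S have mean e and variance v exactly in expectation, where
    e and v are the observed off-diagonal mean and variance; the number
    of factors m = ceil((dbar^2 - e^2) / v) (floor 1, dbar = mean
    diagonal) puts the diagonal mean at ~dbar. S is positive
    semi-definite by construction. The diagonal is left as drawn (close
    to 1) rather than renormalized: rescaling to an exact unit diagonal
    would bias the off-diagonal moments, and thresholding uses only
    off-diagonal ranks.
    """
    if isinstance(net, CovarianceNetwork):
        m_obs = net.matrix
    else:
        m_obs = np.asarray(net, dtype=float)
    n = m_obs.shape[0]
    if n < 3:
        raise ValueError("need at least 3 regions")
    iu = np.triu_indices(n, k=1)
    off = m_obs[iu]
    e = float(off.mean())
    v = float(off.var())
    dbar = float(np.diag(m_obs).mean())
    if e < 0:
        raise ValueError(
            "off-diagonal mean is negative: the factor construction requires "
            "a nonnegative mean covariance")
    if n_factors is None:
        # v -> 0 drives m -> infinity (a constant matrix has no spread to
        # match); cap m so the draw stays finite — the mean is still
        # matched exactly and the variance is as small as the cap allows
        if v > 0:
            n_factors = int(min(np.ceil((dbar * dbar - e * e) / v), _MAX_FACTORS))
        else:
            n_factors = _MAX_FACTORS
    m = max(1, n_factors)
    mu2 = e / m
    # solve s^4 + 2 mu^2 s^2 - v/m = 0 for s^2 (positive root)
    s2 = -mu2 + np.sqrt(mu2 * mu2 + v / m) if v > 0 else (dbar - e) / m
    rng = np.random.default_rng(seed)
    x = np.sqrt(mu2) + np.sqrt(s2) * rng.standard_normal((n, m))
    return x @ x.T


def normalized_metrics(
    net,
    grid: DensityGrid | None = None,
    n_null: int = 100,
    seed: int = 0,
    n_restarts: int = 20,
    ranking: str = "signed",
    null_generator=hqs_null_covariance,
    normalize_q: bool = False,
) -> pd.DataFrame:
    """Per-density topology metrics normalized by matching null networks.

    For every density on `grid`: threshold the observed matrix and
    compute Q, Cp, Lp; generate `n_null` seeded null covariance matrices,
    threshold each at the same density, and average their Cp and Lp into
    Crand_p / Lrand_p; report gamma = Cp/Crand_p, lambda = Lp/Lrand_p and
    sigma = gamma/lambda. Null graphs that come out disconnected have Lp
    taken on their largest component, and the event is counted in
    ``n_null_disconnected`` (dropping them outright would bias Lrand_p
    downward).

    Q is reported raw; with ``normalize_q=True`` the null-mean Qrand_p
    and Q_norm = Q/Qrand_p are added (costly: one modularity
    optimization per null per density).

    The observed graph must be connected at every grid density; use
    :func:`morphnet.netbuild.min_connected_density` to pick a grid.
    """
    if grid is None:
        grid = DensityGrid()
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    densities = grid.densities
    n = (net.matrix if isinstance(net, CovarianceNetwork) else np.asarray(net)).shape[0]

    # Nested edge sets: build each graph incrementally from the ranking.
    obs_pairs = ranked_pairs(net, ranking)
    seeds = np.random.SeedSequence(seed).spawn(n_null)
    null_pairs = []
    for s in seeds:
        null_pairs.append(ranked_pairs(null_generator(net, seed=s), ranking))

    def _grow(graph: nx.Graph, pairs, upto: int, have: int) -> int:
        graph.add_edges_from(pairs[have:upto])
        return upto

    g_obs = nx.Graph()
    g_obs.add_nodes_from(range(n))
    g_nulls = []
    for _ in range(n_null):
        gn = nx.Graph()
        gn.add_nodes_from(range(n))
        g_nulls.append(gn)
    k_obs = 0
    k_null = [0] * n_null

    records = []
    for d_idx, density in enumerate(densities):
        k = n_edges_at_density(float(density), n)
        if k == 0:
            raise ValueError(f"density {density} yields zero edges")
        k_obs = _grow(g_obs, obs_pairs, k, k_obs)
        if not nx.is_connected(g_obs):
            raise ValueError(
                f"observed graph is disconnected at density {density}; "
                "choose a grid at or above min_connected_density")
        q, _ = modularity(g_obs, seed=seed + 7919 * d_idx, n_restarts=n_restarts)
        cp = clustering_coefficient(g_obs)
        lp = characteristic_path_length(g_obs)

        null_cp = np.empty(n_null)
        null_lp = np.empty(n_null)
        null_q = np.empty(n_null)
        n_disc = 0
        for j in range(n_null):
            k_null[j] = _grow(g_nulls[j], null_pairs[j], k, k_null[j])
            null_cp[j] = clustering_coefficient(g_nulls[j])
            lp_j, disc = _largest_component_path_length(g_nulls[j])
            null_lp[j] = lp_j
            n_disc += int(disc)
            if normalize_q:
                null_q[j] = modularity(g_nulls[j], seed=seed + 13 * j,
                                       n_restarts=n_restarts)[0]
        crand = float(np.nanmean(null_cp))
        lrand = float(np.nanmean(null_lp))
        gamma = cp / crand
        lam = lp / lrand
        row = {
            "density": float(density), "Q": q, "Cp": cp, "Lp": lp,
            "Crand_p": crand, "Lrand_p": lrand,
            "gamma": gamma, "lambda": lam, "sigma": gamma / lam,
            "n_null": n_null, "n_null_disconnected": n_disc,
        }
        if normalize_q:
            row["Qrand_p"] = float(np.mean(null_q))
            row["Q_norm"] = q / row["Qrand_p"]
        records.append(row)
    columns = METRIC_COLUMNS + (["Qrand_p", "Q_norm"] if normalize_q else [])
    return pd.DataFrame.from_records(records, columns=columns)


def maslov_sneppen_null(g: nx.Graph, seed: int = 0, n_swaps_per_edge: int = 10) -> nx.Graph:
    """Degree-preserving rewiring null (labeled alternative to the HQS null)."""
    h = g.copy()
    n_swaps = n_swaps_per_edge * h.number_of_edges()
    nx.double_edge_swap(h, nswap=n_swaps, max_tries=100 * n_swaps + 100,
                        seed=int(seed))
    return h
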