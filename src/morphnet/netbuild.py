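"""Covariance-network construction and density thresholding.

A morphometric (structural covariance) network for a cohort cell is the
matrix of Pearson correlations between regional values across subjects.
Binarization keeps the strongest `d` fraction of region pairs ("density
`d`"); because edges are ranked globally, the graphs at increasing
densities are nested, which makes the minimum fully-connected density
well defined and cheap to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import networkx as nx
import numpy as np

from .morphometry import RegionalMorphometryTable


@dataclass(frozen=True)
class DensityGrid:
    """Densities at which the binarized networks are analyzed.

    Default: 20 densities in 1% steps ascending from the minimum density
    threshold 0.50, i.e. 0.50, 0.51, ..., 0.69.
    """

    min_density: float = 0.50
    n_steps: int = 20
    step: float = 0.01

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.step <= 0:
            raise ValueError("need n_steps >= 1 and step > 0")
        d = self.densities
        if d[0] <= 0 or d[-1] > 1.0 + 1e-12:
            raise ValueError(f"densities must lie in (0, 1], got [{d[0]}, {d[-1]}]")

    @property
    def densities(self) -> np.ndarray:
        return np.round(self.min_density + self.step * np.arange(self.n_steps), 10)


@dataclass
class CovarianceNetwork:
    """Symmetric inter-regional correlation matrix with region labels."""

    matrix: np.ndarray
    region_labels: list[str]
    measure: str | None = None
    group: str | None = None
    field: str | None = None
    n_subjects: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"matrix must be square, got shape {m.shape}")
        if m.shape[0] != len(self.region_labels):
            raise ValueError("matrix size does not match number of region labels")
        if not np.isfinite(m).all():
            raise ValueError("matrix contains non-finite entries")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("matrix diagonal is not 1")
        if np.abs(m).max() > 1.0 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.matrix = m

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


def build_covariance_network(table: RegionalMorphometryTable) -> CovarianceNetwork:
    """Pearson correlation of every region pair across subjects."""
    if table.n_subjects < 3:
        raise ValueError(f"need >= 3 subjects to correlate, got {table.n_subjects}")
    values = table.values.to_numpy(dtype=float)
    sds = values.std(axis=0, ddof=1)
    zero_var = [r for r, s in zip(table.regions, sds) if s == 0.0]
    if zero_var:
        raise ValueError(f"correlation undefined: zero-variance regions {zero_var}")
    corr = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return CovarianceNetwork(
        matrix=corr, region_labels=table.regions, measure=table.measure,
        group=table.group, field=table.field, n_subjects=table.n_subjects)


def _matrix_of(net) -> np.ndarray:
    return net.matrix if isinstance(net, CovarianceNetwork) else np.asarray(net, dtype=float)


def ranked_pairs(net, ranking: str = "signed") -> list[tuple[int, int]]:
    """Off-diagonal pairs ordered strongest-first.

    ``"signed"`` ranks by the signed correlation value (negative
    correlations are the weakest links); ``"absolute"`` by magnitude.
    Ties broken by lexicographic (i, j) so the order is deterministic.
    """
    if ranking not in ("signed", "absolute"):
        raise ValueError("ranking must be 'signed' or 'absolute'")
    m = _matrix_of(net)
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = m[iu, ju]
    key = vals if ranking == "signed" else np.abs(vals)
    order = np.lexsort((ju, iu, -key))
    return list(zip(iu[order].tolist(), ju[order].tolist()))


def n_edges_at_density(density: float, n_nodes: int) -> int:
    n_pairs = n_nodes * (n_nodes - 1) // 2
    k = int(np.floor(density * n_pairs + 1e-9))
    return min(k, n_pairs)


def threshold_to_density(net, density: float, ranking: str = "signed") -> nx.Graph:
    """Binarize at the given edge density.

    Keeps the top ``floor(density * N(N-1)/2)`` pairs of the global
    ranking as undirected unweighted edges. Deterministic; the edge sets
    at increasing densities are nested.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must be in (0, 1], got {density}")
    m = _matrix_of(net)
    n = m.shape[0]
    k = n_edges_at_density(density, n)
    if k == 0:
        raise ValueError(f"density {density} yields zero edges on {n} nodes")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(ranked_pairs(net, ranking)[:k])
    g.graph["density"] = density
    if isinstance(net, CovarianceNetwork):
        g.graph["region_labels"] = list(net.region_labels)
    return g


def graph_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    return g.number_of_edges() / (n * (n - 1) / 2)


def min_connected_density(net, grid_resolution: float = 0.01,
                          ranking: str = "signed") -> float:
    """Smallest grid density at which the binarized graph is connected.

    Because edge sets are nested under the global ranking, connectivity
    is monotone in density: the answer is found by adding edges in rank
    order with a union-find until one component remains, then rounding
    the required edge count up to the grid.
    """
    if not (0.0 < grid_resolution <= 1.0):
        raise ValueError("grid_resolution must be in (0, 1]")
    m = _matrix_of(net)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    uf = nx.utils.UnionFind(range(n))
    n_components = n
    k_connected = None
    for rank, (i, j) in enumerate(ranked_pairs(net, ranking), start=1):
        if uf[i] != uf[j]:
            uf.union(i, j)
            n_components -= 1
            if n_components == 1:
                k_connected = rank
                break
    assert k_connected is not None  # complete pair list always connects
    for step in range(1, int(np.ceil(1.0 / grid_resolution)) + 1):
        d = round(step * grid_resolution, 10)
        if d > 1.0:
            d = 1.0
        if n_edges_at_density(d, n) >= k_connected:
            return d
    return 1.0
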