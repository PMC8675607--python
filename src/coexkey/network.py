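"""Weighted co-expression networks: powered |Pearson r| adjacency, soft-threshold
selection by scale-free fit, edge thresholding, and the network property panel.

The network is unsigned: a_ij = |r_ij| ** beta, so positively and negatively
co-expressed pairs are treated alike.  The simple graph used downstream keeps
the unordered pairs with a_ij >= edge_min (inclusive; default 0.1) and drops
genes isolated by the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CorrelationMatrix",
    "SoftThresholdScan",
    "CoexpressionNetwork",
    "NetworkProperties",
    "correlation_matrix",
    "scale_free_fit",
    "soft_threshold_scan",
    "build_network",
    "network_properties",
    "average_degree",
    "connections_per_node",
]


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Mean degree 2E/N of a simple undirected graph."""
    return 2.0 * n_edges / n_nodes


def connections_per_node(n_nodes: int, n_edges: int) -> float:
    """Edges per node E/N (half the average degree)."""
    return n_edges / n_nodes


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    genes: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        if self.r.shape != (len(self.genes), len(self.genes)):
            raise ValueError("correlation matrix shape does not match gene list")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")


def correlation_matrix(log_expr: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlation of gene rows across samples.

    Genes with zero variance get r = 0 off-diagonal (and 1 on the diagonal)
    by convention.  Requires at least 3 samples.
    """
    if log_expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    x = log_expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    return CorrelationMatrix(genes=list(log_expr.index), r=r)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of the log10(frequency) ~ log10(mean k) degree-histogram fit.

    Connectivities are binned into ``n_bins`` equal-width bins; the
    regression runs over non-empty bins with positive mean connectivity.
    Returns (r_squared, slope); degenerate inputs (fewer than 3 usable bins)
    give (0.0, 0.0).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    sums = np.bincount(which, weights=k, minlength=n_bins)
    ok = counts > 0
    if ok.sum() < 3:
        return 0.0, 0.0
    mean_k = sums[ok] / counts[ok]
    freq = counts[ok] / counts.sum()
    lx, ly = np.log10(mean_k), np.log10(freq)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(r2), float(slope)


@dataclass
class SoftThresholdScan:
    """Scan of candidate powers with their scale-free fit statistics."""

    table: pd.DataFrame  # columns: power, r_squared, slope, mean_connectivity
    chosen_beta: int | None
    fit_threshold: float = 0.90


def soft_threshold_scan(
    cor: CorrelationMatrix,
    powers=range(1, 21),
    fit_threshold: float = 0.90,
    n_bins: int = 10,
    min_mean_connectivity: float = 0.0,
) -> SoftThresholdScan:
    """Scan soft-threshold powers and pick the smallest with R^2 >= threshold.

    For each power beta, weighted connectivity k_i = sum_{j != i} |r_ij|^beta
    is computed, its histogram is fitted on log-log scale, and the smallest
    beta whose fit R^2 reaches ``fit_threshold`` becomes ``chosen_beta``
    (None if no power qualifies).  Powers whose mean connectivity falls below
    ``min_mean_connectivity`` are never chosen: at extreme powers the network
    degenerates to a handful of edges whose histogram can fit a power law
    spuriously well.
    """
    if len(cor.genes) < 2:
        raise ValueError("need at least 2 genes to scan soft thresholds")
    a = np.abs(cor.r).astype(float)
    np.fill_diagonal(a, 0.0)
    rows = []
    chosen = None
    for beta in powers:
        k = np.power(a, beta).sum(axis=1)
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "power": int(beta),
                "r_squared": r2,
                "slope": slope,
                "mean_connectivity": float(k.mean()),
            }
        )
        if chosen is None and r2 >= fit_threshold and k.mean() >= min_mean_connectivity:
            chosen = int(beta)
    return SoftThresholdScan(
        table=pd.DataFrame(rows), chosen_beta=chosen, fit_threshold=fit_threshold
    )


@dataclass
class CoexpressionNetwork:
    """Powered-|r| weighted adjacency plus the thresholded simple graph."""

    genes: list[str]
    adjacency: np.ndarray  # symmetric, in [0, 1], zero diagonal
    beta: float
    edge_min: float
    graph: nx.Graph
    state_label: str = "global"

    @property
    def adjacency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.adjacency, index=self.genes, columns=self.genes)


def build_network(
    cor: CorrelationMatrix,
    beta: float,
    edge_min: float = 0.1,
    state_label: str = "global",
    drop_isolated: bool = True,
) -> CoexpressionNetwork:
    """Power adjacency a_ij = |r_ij|^beta and the graph of edges >= edge_min.

    The threshold is inclusive (an edge of weight exactly ``edge_min`` is
    kept).  Genes left without any retained edge are dropped from the graph
    (but kept in the adjacency matrix) unless ``drop_isolated`` is False.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if not 0 < edge_min < 1:
        raise ValueError("edge_min must be in (0, 1)")
    adjacency = np.power(np.abs(cor.r), beta)
    np.fill_diagonal(adjacency, 0.0)
    graph = nx.Graph()
    if not drop_isolated:
        graph.add_nodes_from(cor.genes)
    iu, ju = np.triu_indices(len(cor.genes), k=1)
    keep = adjacency[iu, ju] >= edge_min
    genes = cor.genes
    graph.add_weighted_edges_from(
        (genes[i], genes[j], float(adjacency[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    )
    return CoexpressionNetwork(
        genes=list(cor.genes),
        adjacency=adjacency,
        beta=float(beta),
        edge_min=float(edge_min),
        graph=graph,
        state_label=state_label,
    )


@dataclass
class NetworkProperties:
    """Structural panel for one network (node/edge counts, diameter, etc.)."""

    n_nodes: int
    n_edges: int
    average_degree: float
    diameter: int
    average_clustering_coefficient: float
    connections_per_node: float
    power_law_slope: float
    power_law_r2: float
    state_label: str = "global"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def network_properties(net: CoexpressionNetwork, n_bins: int = 10) -> NetworkProperties:
    """Node/edge counts, 2E/N, diameter of the largest component, mean
    clustering coefficient, E/N, and the degree-histogram power-law fit."""
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        warnings.warn(f"{net.state_label} network is empty", stacklevel=2)
        return NetworkProperties(0, 0, 0.0, 0, 0.0, 0.0, 0.0, 0.0, net.state_label)
    largest_cc = max(nx.connected_components(g), key=len)
    diameter = nx.diameter(g.subgraph(largest_cc)) if len(largest_cc) > 1 else 0
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    r2, slope = scale_free_fit(degrees, n_bins=n_bins)
    return NetworkProperties(
        n_nodes=n,
        n_edges=e,
        average_degree=average_degree(n, e),
        diameter=int(diameter),
        average_clustering_coefficient=float(nx.average_clustering(g)),
        connections_per_node=connections_per_node(n, e),
        power_law_slope=slope,
        power_law_r2=r2,
        state_label=net.state_label,
    )
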