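"""Global and nodal topology metrics on binarized networks.

Global: mean clustering coefficient Cp, characteristic path length Lp,
global/local efficiency, and the small-world ratios gamma = Cp/Cp_rand,
lambda = Lp/Lp_rand, sigma = gamma/lambda against degree-preserving
(Maslov-Sneppen double-edge-swap) null networks.  Nodal: degree centrality,
unnormalized betweenness centrality, nodal efficiency.  Each metric is
summarized per subject as the trapezoidal area under its curve over the
admissible sparsity grid.

Disconnected graphs are handled with the usual conventions: Lp averages
finite-distance pairs only, efficiencies count infinite distances as zero.
"""

from __future__ import annotations

import dataclasses
import logging
import random
import warnings

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .fc_network import BinaryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GlobalMetricsRecord",
    "NodalMetricsRecord",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "nodal_metrics",
    "random_null_networks",
    "small_world_normalize",
    "global_metrics",
    "auc_over_grid",
]


@dataclasses.dataclass
class GlobalMetricsRecord:
    sparsity: float
    cp: float
    lp: float
    eglob: float
    eloc: float
    gamma: float
    lam: float
    sigma: float


@dataclasses.dataclass
class NodalMetricsRecord:
    sparsity: float
    degree: np.ndarray
    betweenness: np.ndarray
    efficiency: np.ndarray


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf when disconnected)."""
    return shortest_path(csr_matrix(adj), unweighted=True, directed=False)


def clustering_coefficient(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering 2*T_i/(k_i(k_i-1)) (0 when k<2) and the mean Cp."""
    a = net.adjacency.astype(float)
    k = a.sum(axis=1)
    tri2 = np.diag(a @ a @ a)  # = 2 * triangles at each node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c, float(c.mean())


def characteristic_path_length(net: BinaryNetwork) -> float:
    """Mean shortest-path length over pairs at finite distance."""
    d = _distances(net.adjacency)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("fully disconnected network: no finite node pair")
    n_inf = int((~np.isfinite(d[off])).sum())
    if n_inf:
        logger.debug(
            "Lp on disconnected network (subject %s, s=%g): %.1f%% pairs infinite",
            net.subject_id, net.sparsity, 100.0 * n_inf / off.sum(),
        )
    return float(d[finite].mean())


def _efficiency_from_adj(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv[off].mean())


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean over node pairs of 1/d(i,j); infinite distance contributes 0."""
    return _efficiency_from_adj(net.adjacency)


def local_efficiency(net: BinaryNetwork) -> float:
    """Mean over nodes of the global efficiency of each node's neighbor subgraph."""
    a = net.adjacency
    vals = np.zeros(a.shape[0])
    for i in range(a.shape[0]):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        vals[i] = _efficiency_from_adj(a[np.ix_(nbrs, nbrs)])
    return float(vals.mean())


def _igraph_of(adj: np.ndarray) -> ig.Graph:
    return ig.Graph.Adjacency(adj.tolist(), mode="undirected")


def nodal_metrics(net: BinaryNetwork) -> NodalMetricsRecord:
    """Degree, unnormalized betweenness (undirected pairs once), nodal efficiency."""
    a = net.adjacency
    n = a.shape[0]
    degree = a.sum(axis=1).astype(float)
    btw = np.asarray(_igraph_of(a).betweenness(), dtype=float)
    d = _distances(a)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    eff = inv.sum(axis=1) / (n - 1)
    return NodalMetricsRecord(
        sparsity=net.sparsity, degree=degree, betweenness=btw, efficiency=eff
    )


def random_null_networks(
    net: BinaryNetwork, n_null: int, rewires_per_edge: int = 10, seed: int = 0
) -> list[BinaryNetwork]:
    """Degree-preserving null networks via double-edge-swap rewiring.

    Every null has exactly the input's degree sequence; connectedness is not
    enforced.  Graphs admitting no swap come back as copies with a warning.
    """
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    g0 = _igraph_of(net.adjacency)
    n_swaps = rewires_per_edge * net.n_edges
    state = random.getstate()
    random.seed(seed & 0x7FFFFFFF)
    try:
        nulls = []
        warned = False
        for _ in range(n_null):
            g = g0.copy()
            g.rewire(n=n_swaps)
            adj = np.asarray(g.get_adjacency().data, dtype=np.uint8)
            if not warned and np.array_equal(adj, net.adjacency):
                warnings.warn(
                    "degree-preserving rewiring returned the input graph "
                    "(degree sequence may admit a single realization)",
                    stacklevel=2,
                )
                warned = True
            nulls.append(
                BinaryNetwork(adjacency=adj, sparsity=net.sparsity, subject_id=net.subject_id)
            )
    finally:
        random.setstate(state)
    return nulls


def small_world_normalize(
    net: BinaryNetwork, nulls: list[BinaryNetwork]
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) of a network against its null ensemble."""
    if not nulls:
        raise ValueError("null ensemble is empty")
    _, cp = clustering_coefficient(net)
    lp = characteristic_path_length(net)
    cp_null = float(np.mean([clustering_coefficient(g)[1] for g in nulls]))
    lp_null = float(np.mean([characteristic_path_length(g) for g in nulls]))
    if cp_null == 0 or lp_null == 0:
        raise ValueError("null ensemble has zero mean Cp or Lp")
    gamma = cp / cp_null
    lam = lp / lp_null
    return gamma, lam, gamma / lam


def global_metrics(
    net: BinaryNetwork, n_null: int = 100, rewires_per_edge: int = 10, seed: int = 0
) -> GlobalMetricsRecord:
    """All global metrics of one network, normalized against fresh nulls."""
    _, cp = clustering_coefficient(net)
    lp = characteristic_path_length(net)
    nulls = random_null_networks(net, n_null, rewires_per_edge, seed)
    gamma, lam, sigma = small_world_normalize(net, nulls)
    return GlobalMetricsRecord(
        sparsity=net.sparsity,
        cp=cp,
        lp=lp,
        eglob=global_efficiency(net),
        eloc=local_efficiency(net),
        gamma=gamma,
        lam=lam,
        sigma=sigma,
    )


def auc_over_grid(values, grid) -> float:
    """Trapezoidal integral of a metric across the sparsity grid."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape[0] != grid.shape[0]:
        raise ValueError("values and grid lengths differ")
    if grid.shape[0] < 2:
        raise ValueError("AUC needs at least two grid points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return float(np.trapezoid(values, grid))
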