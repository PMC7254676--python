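"""Graph-topology observables of the inferred effective network.

Global efficiency is the mean inverse directed shortest-path length over
ordered node pairs (1/inf = 0).  Communities are found with seeded Louvain
modularity maximization on the largest weakly-connected component (the graph
is treated as undirected for community detection); the headline community
statistic Q is Newman-Girvan modularity, with the literal ratio of
intra-modular to inter-modular edges reported alongside.  Connector hubs
follow the participation-coefficient / within-module-degree cartography:
a node is a connector hub when z >= z_hub (default 1.5) and P > P_hub
(default 0.3), with degrees taken on the union of in- and out-edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "TopologySummary",
    "global_efficiency",
    "detect_communities",
    "classify_connector_hubs",
    "summarize_topology",
]


def global_efficiency(adjacency: np.ndarray) -> float:
    """Mean of 1/d(i, j) over ordered pairs i != j on the directed graph."""
    A = np.atleast_2d(np.asarray(adjacency)).astype(bool)
    n = A.shape[0]
    if n < 2:
        return math.nan
    d = shortest_path(csr_matrix(A), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


@dataclass
class CommunityResult:
    partition: dict[int, int]  # node -> community id (largest component only)
    q: float  # Newman-Girvan modularity of the partition
    intra_inter_ratio: float  # literal intra/inter edge-count ratio
    sizes: list[int]
    component_nodes: list[int]

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.sizes)) if self.sizes else math.nan

    @property
    def n_communities(self) -> int:
        return len(self.sizes)


def detect_communities(
    adjacency: np.ndarray,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 10,
) -> CommunityResult:
    """Seeded Louvain on the largest weakly-connected component.

    Runs ``n_restarts`` restarts and keeps the best-modularity partition.
    """
    A = np.atleast_2d(np.asarray(adjacency)).astype(bool)
    G = nx.from_numpy_array(A, create_using=nx.DiGraph)
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    component = max(nx.weakly_connected_components(G), key=len)
    H = G.subgraph(component).to_undirected()
    best_q = -math.inf
    best_parts: list[set] | None = None
    for r in range(n_restarts):
        parts = nx.community.louvain_communities(
            H, resolution=resolution, seed=seed + r
        )
        if H.number_of_edges() == 0:
            q = math.nan
            best_parts = parts
            break
        q = nx.community.modularity(H, parts, resolution=resolution)
        if q > best_q:
            best_q, best_parts = q, parts
    partition = {
        node: cid for cid, nodes in enumerate(best_parts) for node in nodes
    }
    intra = inter = 0
    for u, v in H.edges():
        if partition[u] == partition[v]:
            intra += 1
        else:
            inter += 1
    ratio = intra / inter if inter else math.inf
    return CommunityResult(
        partition=partition,
        q=best_q if math.isfinite(best_q) else math.nan,
        intra_inter_ratio=ratio,
        sizes=sorted((len(p) for p in best_parts), reverse=True),
        component_nodes=sorted(component),
    )


def classify_connector_hubs(
    adjacency: np.ndarray,
    partition: dict[int, int],
    z_hub: float = 1.5,
    p_hub: float = 0.3,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Connector hubs by Guimera-Amaral cartography on the union graph.

    Returns ``(n_hubs, P, z)``; P and z are indexed by node id (NaN for
    nodes outside the partition).  Isolated nodes get P = 0 and a z-score
    from their module's degree distribution.
    """
    A = np.atleast_2d(np.asarray(adjacency)).astype(bool)
    n = A.shape[0]
    union = A | A.T
    np.fill_diagonal(union, False)
    P = np.full(n, math.nan)
    z = np.full(n, math.nan)
    if not partition:
        return 0, P, z
    nodes = np.array(sorted(partition))
    comm = np.array([partition[v] for v in nodes])
    sub = union[np.ix_(nodes, nodes)]
    k_total = sub.sum(axis=1).astype(float)
    comm_ids = np.unique(comm)
    # participation coefficient
    frac_sq = np.zeros(len(nodes))
    for m in comm_ids:
        k_m = sub[:, comm == m].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_sq += np.where(k_total > 0, (k_m / np.where(k_total > 0, k_total, 1)) ** 2, 0.0)
    P[nodes] = np.where(k_total > 0, 1.0 - frac_sq, 0.0)
    # within-module degree z-score
    for m in comm_ids:
        members = comm == m
        k_within = sub[np.ix_(members, members)].sum(axis=1).astype(float)
        mu, sd = k_within.mean(), k_within.std()
        z[nodes[members]] = (k_within - mu) / sd if sd > 0 else 0.0
    is_hub = (z >= z_hub) & (P > p_hub)
    return int(np.nansum(is_hub)), P, z


@dataclass
class TopologySummary:
    global_efficiency: float
    q: float
    intra_inter_ratio: float
    mean_community_size: float
    n_communities: int
    n_connector_hubs: int
    n_nodes: int
    n_edges: int
    participation: np.ndarray
    within_module_z: np.ndarray
    partition: dict[int, int]


def summarize_topology(
    adjacency: np.ndarray,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 10,
    z_hub: float = 1.5,
    p_hub: float = 0.3,
) -> TopologySummary:
    """All Fig.-2-style observables of one effective network."""
    A = np.atleast_2d(np.asarray(adjacency)).astype(bool)
    eff = global_efficiency(A)
    comm = detect_communities(A, seed=seed, resolution=resolution, n_restarts=n_restarts)
    n_hubs, P, z = classify_connector_hubs(A, comm.partition, z_hub=z_hub, p_hub=p_hub)
    return TopologySummary(
        global_efficiency=eff,
        q=comm.q,
        intra_inter_ratio=comm.intra_inter_ratio,
        mean_community_size=comm.mean_size,
        n_communities=comm.n_communities,
        n_connector_hubs=n_hubs,
        n_nodes=A.shape[0],
        n_edges=int(A.sum()),
        participation=P,
        within_module_z=z,
        partition=comm.partition,
    )
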