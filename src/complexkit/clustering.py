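"""Density-based greedy graph clustering for complex prediction.

Clusters are grown from high-degree seeds and admit a neighbor only while
two thresholds hold: the induced-subgraph density and the candidate's
cluster property (edges into the cluster relative to density x size).
Overlapping mode lets a protein appear in several emitted clusters.

The expansion rule is fully deterministic:

1. seed = unclustered node of highest degree (ties: smallest ID);
2. the cluster starts as the seed plus its neighbor sharing the most
   common neighbors (ties: higher degree, then smallest ID);
3. candidates adjacent to the cluster are ranked by edges-into-cluster
   (descending), degree (descending), then ID; the first candidate whose
   cluster property >= cp_in and whose addition keeps density >= d_in is
   admitted, and the scan restarts;
4. growth stops when no candidate qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet

import networkx as nx

from .network import IntegratedNetwork

__all__ = [
    "ClusterParams",
    "Cluster",
    "density",
    "cluster_property",
    "grow_cluster",
    "cluster_graph",
]


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds controlling cluster growth and emission."""

    d_in: float = 0.6
    cp_in: float = 0.5
    min_size: int = 3
    overlapping: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_in <= 1.0:
            raise ValueError(f"d_in must be in [0,1], got {self.d_in}")
        if self.cp_in < 0.0:
            raise ValueError(f"cp_in must be >= 0, got {self.cp_in}")
        if self.min_size < 2:
            raise ValueError(f"min_size must be >= 2, got {self.min_size}")


@dataclass(frozen=True)
class Cluster:
    """An emitted dense region: members, its density, and the seed node."""

    members: frozenset[str]
    density: float
    seed: str

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def _as_graph(graph: IntegratedNetwork | nx.Graph) -> nx.Graph:
    return graph.graph if isinstance(graph, IntegratedNetwork) else graph


def density(graph: IntegratedNetwork | nx.Graph, members: AbstractSet[str]) -> float:
    """Induced-subgraph density 2*E / (n*(n-1)) for a node set, in [0,1]."""
    g = _as_graph(graph)
    n = len(members)
    if n < 2:
        raise ValueError(f"density requires >=2 members, got {n}")
    missing = [m for m in members if m not in g]
    if missing:
        raise ValueError(f"members not in graph: {missing}")
    e = g.subgraph(members).number_of_edges()
    return 2.0 * e / (n * (n - 1))


def cluster_property(
    graph: IntegratedNetwork | nx.Graph,
    cluster_members: AbstractSet[str],
    candidate: str,
) -> float:
    """Candidate's edges into the cluster, scaled by density * cluster size."""
    g = _as_graph(graph)
    if candidate in cluster_members:
        raise ValueError(f"candidate {candidate} already in cluster")
    d = density(g, cluster_members)
    if d == 0.0:
        raise ValueError("cluster property undefined for zero-density cluster")
    e_c = sum(1 for m in cluster_members if g.has_edge(candidate, m))
    return e_c / (d * len(cluster_members))


def _initial_partner(
    g: nx.Graph, seed: str, blocked: AbstractSet[str] = frozenset()
) -> str | None:
    """Seed's neighbor sharing the most common neighbors (ties: degree, ID)."""
    seed_nbrs = set(g[seed]) - set(blocked)
    best: str | None = None
    best_key: tuple[int, int, str] | None = None
    for v in seed_nbrs:
        shared = len(seed_nbrs & set(g[v]))
        # sort key: more shared first, then higher degree, then smaller ID
        key = (-shared, -g.degree(v), v)
        if best_key is None or key < best_key:
            best, best_key = v, key
    return best


def grow_cluster(
    graph: IntegratedNetwork | nx.Graph,
    params: ClusterParams,
    seed: str,
    blocked: AbstractSet[str] = frozenset(),
) -> Cluster | None:
    """Grow one cluster from ``seed``; returns None if it stays below min_size.

    ``blocked`` nodes are never admitted (used by non-overlapping mode).
    """
    g = _as_graph(graph)
    if seed not in g:
        raise ValueError(f"seed {seed} not in graph")
    partner = _initial_partner(g, seed, blocked)
    if partner is None:
        return None
    members: set[str] = {seed, partner}

    while True:
        candidates: dict[str, int] = {}
        for m in members:
            for v in g[m]:
                if v in members or v in blocked:
                    continue
                candidates[v] = candidates.get(v, 0) + 1
        if not candidates:
            break
        d_now = density(g, members)
        n_now = len(members)
        admitted = None
        for v in sorted(candidates, key=lambda v: (-candidates[v], -g.degree(v), v)):
            e_in = candidates[v]
            cp = e_in / (d_now * n_now)
            if cp < params.cp_in:
                continue
            new_d = density(g, members | {v})
            if new_d >= params.d_in:
                admitted = v
                break
        if admitted is None:
            break
        members.add(admitted)

    if len(members) < params.min_size:
        return None
    return Cluster(members=frozenset(members), density=density(g, members), seed=seed)


def cluster_graph(
    graph: IntegratedNetwork | nx.Graph,
    params: ClusterParams,
) -> list[Cluster]:
    """Run seeded growth over the whole graph.

    Seeds are taken from unclustered nodes in degree order. In overlapping
    mode emitted members are excluded as future seeds but stay available as
    expansion candidates; in non-overlapping mode they leave the graph.
    Output is sorted by (size desc, seed ID) with duplicate member sets
    removed.
    """
    g = _as_graph(graph).copy()
    clustered: set[str] = set()
    emitted: dict[frozenset[str], Cluster] = {}

    while True:
        seeds = [v for v in g.nodes if v not in clustered]
        if not seeds:
            break
        seed = min(seeds, key=lambda v: (-g.degree(v), v))
        cluster = grow_cluster(g, params, seed)
        if cluster is None:
            clustered.add(seed)
            continue
        assert cluster.density >= params.d_in and cluster.size >= params.min_size
        if cluster.members not in emitted:
            emitted[cluster.members] = cluster
        clustered |= cluster.members
        if not params.overlapping:
            g.remove_nodes_from(cluster.members)

    return sorted(emitted.values(), key=lambda c: (-c.size, c.seed))
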