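"""Active-module extraction: differential-correlation edge weighting and
Steiner-tree reduction of the interactome.

Every interactome edge is scored by Fisher's r-to-z test for a
case-control difference in the Pearson correlation of its endpoints; the
two-sided p-value becomes an edge *distance* ``w = 1 / (-ln p)``, so edges
whose co-expression differs most between groups are cheapest.  The module
is then the (approximate) minimum-distance acyclic subgraph connecting the
seed genes — a Steiner tree found with the Kou-Markowsky-Berman
2(1 - 1/l)-approximation.  Tie-breaking in Dijkstra and both MST passes is
lexicographic, so the tree is reproducible across runs.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .data_io import ExpressionData, Interactome

__all__ = [
    "WeightedEdge",
    "SteinerTree",
    "fisher_z_edge_test",
    "weight_interactome",
    "steiner_tree_kou",
    "P_CLAMP_LO",
    "P_CLAMP_HI",
]

# p-value clamp keeping w = 1/(-ln p) finite and strictly positive
P_CLAMP_LO = 1e-16
P_CLAMP_HI = 1.0 - 1e-16


@dataclass
class WeightedEdge:
    source: str
    target: str
    r_case: float
    r_ctrl: float
    z: float
    p: float
    w: float


@dataclass
class SteinerTree:
    """Acyclic connected subgraph spanning the seed genes.

    ``tree`` is an undirected weighted graph; ``connectors`` are the
    non-seed nodes retained to link seeds; ``total_cost`` is the sum of
    edge distances w.
    """

    tree: nx.Graph
    seeds: list[str]
    connectors: list[str]
    total_cost: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.tree.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.tree.edges)


def fisher_z_edge_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z test for a difference between two independent Pearson
    correlations: ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``
    with a two-sided normal p-value."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need more than 3 samples per group")
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise ValueError("degenerate correlation |r| >= 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def weight_interactome(interactome: Interactome, data: ExpressionData) -> nx.Graph:
    """Score every interactome edge by differential correlation.

    Returns an undirected graph whose edges carry
    (r_case, r_ctrl, z, p, w); duplicate orientations of the same gene pair
    collapse to one undirected edge (the statistics are symmetric).  Edges
    with an endpoint absent from the expression data are dropped with a
    warning.
    """
    case = data.subset_group(1).values
    ctrl = data.subset_group(0).values
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need more than 3 samples in each group")
    genes = set(data.gene_ids)
    g = nx.Graph()
    dropped = []
    for u, v in interactome.graph.edges():
        if u not in genes or v not in genes:
            dropped.append((u, v))
            continue
        a, b = sorted((u, v))
        if g.has_edge(a, b):
            continue
        r1 = float(np.corrcoef(case.loc[a], case.loc[b])[0, 1])
        r2 = float(np.corrcoef(ctrl.loc[a], ctrl.loc[b])[0, 1])
        r1 = float(np.clip(r1, -1 + 1e-12, 1 - 1e-12))
        r2 = float(np.clip(r2, -1 + 1e-12, 1 - 1e-12))
        z, p = fisher_z_edge_test(r1, n1, r2, n2)
        pc = float(np.clip(p, P_CLAMP_LO, P_CLAMP_HI))
        w = 1.0 / (-np.log(pc))
        g.add_edge(a, b, r_case=r1, r_ctrl=r2, z=z, p=pc, w=w)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} interactome edges with endpoints missing "
            f"from the expression data",
            stacklevel=2,
        )
    return g


def _dijkstra_lex(graph: nx.Graph, source: str, weight: str = "w"):
    """Dijkstra with lexicographic predecessor tie-breaking.

    Returns (dist, pred) dicts; among equal-length shortest paths the one
    whose predecessor chain is lexicographically smallest is kept, making
    path reconstruction deterministic.
    """
    dist: dict[str, float] = {source: 0.0}
    pred: dict[str, str | None] = {source: None}
    seen: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in seen:
            continue
        seen.add(u)
        for v in sorted(graph.neighbors(u)):
            nd = d + graph.edges[u, v][weight]
            if v not in dist or nd < dist[v] - 1e-15:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= 1e-15 and v not in seen and u < (pred[v] or u):
                pred[v] = u
    return dist, pred


def _path_from_pred(pred: dict[str, str | None], target: str) -> list[str]:
    path = [target]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    return path[::-1]


def _mst_kruskal(nodes, edges) -> list[tuple[str, str]]:
    """Kruskal MST with edges sorted by (weight, endpoints) for determinism.
    ``edges``: iterable of (w, u, v)."""
    parent = {v: v for v in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out = []
    for w, u, v in sorted(edges):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            out.append((u, v))
    return out


def steiner_tree_kou(graph: nx.Graph, seeds: list[str] | set[str], weight: str = "w") -> SteinerTree:
    """Kou-Markowsky-Berman Steiner tree approximation.

    (1) metric closure over the seeds via Dijkstra; (2) MST of the closure;
    (3) replace closure edges by their shortest paths; (4) MST of that
    subgraph; (5) iteratively prune non-seed leaves.  The result is within
    a factor 2(1 - 1/l) of the optimum (l = seed leaves of the optimum).

    Seeds absent from the graph are dropped with a warning; if the
    remaining seeds do not share one connected component, an error lists
    the components.
    """
    seeds = sorted(set(seeds))
    missing = [s for s in seeds if s not in graph]
    if missing:
        warnings.warn(f"seeds absent from the graph were dropped: {missing}", stacklevel=2)
        seeds = [s for s in seeds if s in graph]
    if not seeds:
        raise ValueError("no seed genes present in the graph")
    # metric closure over seeds
    sp_dist: dict[str, dict[str, float]] = {}
    sp_pred: dict[str, dict[str, str | None]] = {}
    for s in seeds:
        d, pr = _dijkstra_lex(graph, s, weight)
        sp_dist[s], sp_pred[s] = d, pr
    unreachable = [
        (a, b) for i, a in enumerate(seeds) for b in seeds[i + 1 :] if b not in sp_dist[a]
    ]
    if unreachable:
        comp = {s: sorted(c) for c in nx.connected_components(graph) for s in seeds if s in c}
        raise ValueError(f"seed pairs not connected: {unreachable}; components: {comp}")
    closure_edges = [
        (sp_dist[a][b], a, b) for i, a in enumerate(seeds) for b in seeds[i + 1 :]
    ]
    closure_mst = _mst_kruskal(seeds, closure_edges)
    # expand closure edges into shortest paths
    sub = nx.Graph()
    for a, b in closure_mst:
        path = _path_from_pred(sp_pred[a], b)
        for u, v in zip(path, path[1:]):
            sub.add_edge(u, v, **graph.edges[u, v])
    # MST of the expanded subgraph, then prune non-seed leaves
    mst_edges = _mst_kruskal(
        sorted(sub.nodes), [(d[weight], u, v) for u, v, d in sub.edges(data=True)]
    )
    tree = nx.Graph()
    tree.add_nodes_from(seeds)
    for u, v in mst_edges:
        tree.add_edge(u, v, **graph.edges[u, v])
    seed_set = set(seeds)
    while True:
        leaves = [v for v in tree if tree.degree(v) <= 1 and v not in seed_set]
        if not leaves:
            break
        tree.remove_nodes_from(leaves)
    connectors = sorted(set(tree.nodes) - seed_set)
    total = float(sum(d[weight] for _, _, d in tree.edges(data=True)))
    return SteinerTree(tree=tree, seeds=seeds, connectors=connectors, total_cost=total)
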