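"""Walk-trap community detection and Newman-Girvan modularity.

Communities are found with the Pons-Latapy walk-trap algorithm (t-step
random-walk distances, agglomerative merging, dendrogram cut at maximum
modularity) as implemented in python-igraph; modularity itself is computed
by this module's own closed form ``Q = sum_c [e_c/m - (d_c/2m)^2]`` so the
two can be cross-checked independently.  Directed input is symmetrized
before clustering; by default edges enter unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx

__all__ = ["CommunityPartition", "modularity", "walktrap"]


@dataclass
class CommunityPartition:
    """Node -> community assignment (ids contiguous from 1) with its
    Newman-Girvan modularity."""

    assignment: dict[str, int]
    modularity: float
    n_communities: int

    def members(self, community: int) -> list[str]:
        return sorted(v for v, c in self.assignment.items() if c == community)

    def as_sets(self) -> list[frozenset[str]]:
        return [frozenset(self.members(c)) for c in range(1, self.n_communities + 1)]


def _as_undirected(graph: nx.Graph | nx.DiGraph) -> nx.Graph:
    return graph.to_undirected() if graph.is_directed() else graph


def modularity(
    graph: nx.Graph | nx.DiGraph,
    assignment: dict[str, int],
    weight: str | None = None,
) -> float:
    """Newman-Girvan modularity ``Q = sum_c [e_c/m - (d_c/2m)^2]``.

    ``e_c`` is the (weighted) number of intra-community edges, ``d_c`` the
    summed degree of the community, ``m`` the total edge weight.  Every
    node must be assigned to exactly one community.
    """
    g = _as_undirected(graph)
    uncovered = [v for v in g.nodes if v not in assignment]
    if uncovered:
        raise ValueError(f"nodes without a community: {sorted(uncovered)}")
    m = g.size(weight=weight)
    if m == 0:
        raise ValueError("graph has no edges")
    communities = set(assignment.values())
    q = 0.0
    for c in communities:
        members = {v for v in g.nodes if assignment[v] == c}
        e_c = sum(
            (d.get(weight, 1.0) if weight else 1.0)
            for u, v, d in g.edges(members, data=True)
            if u in members and v in members
        )
        d_c = sum(g.degree(v, weight=weight) for v in members)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def walktrap(
    graph: nx.Graph | nx.DiGraph,
    steps: int = 4,
    weight: str | None = None,
) -> CommunityPartition:
    """Walk-trap clustering, cut at maximum modularity.

    ``steps`` is the random-walk length t (default 4).  Weights are ignored
    unless ``weight`` names an edge attribute.  Isolated nodes each form
    their own community; community ids are assigned contiguously from 1 in
    order of each community's lexicographically smallest member.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    g = _as_undirected(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(g.nodes)
    h = ig.Graph()
    h.add_vertices([str(v) for v in nodes])
    edges = sorted((min(u, v), max(u, v)) for u, v in g.edges())
    h.add_edges(edges)
    weights = None
    if weight is not None:
        weights = [g.edges[u, v].get(weight, 1.0) for u, v in edges]
    clustering = h.community_walktrap(weights=weights, steps=steps).as_clustering()
    raw = {nodes[i]: mem for i, mem in enumerate(clustering.membership)}
    # renumber contiguously from 1, ordered by smallest member
    groups: dict[int, list[str]] = {}
    for v, c in raw.items():
        groups.setdefault(c, []).append(v)
    ordered = sorted(groups.values(), key=lambda vs: min(vs))
    assignment = {v: i + 1 for i, vs in enumerate(ordered) for v in vs}
    q = modularity(g, assignment, weight=weight) if g.number_of_edges() else 0.0
    return CommunityPartition(assignment=assignment, modularity=q, n_communities=len(ordered))
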