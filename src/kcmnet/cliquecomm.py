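"""K-clique community detection by clique percolation.

A k-clique community is the union of all k-cliques that can be reached
from one another through chains of adjacent k-cliques, where adjacency
means sharing k-1 nodes.  Communities may overlap; nodes belonging to two
or more communities ("bridge nodes") tie distinct biochemical mechanisms
together and are first-class citizens of the analysis.

Percolation is run over maximal cliques of size >= k (two maximal cliques
are adjacent iff they share >= k-1 nodes), which yields exactly the same
communities as percolating all k-cliques directly; the equivalence is
exercised against a definitional brute-force oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

import networkx as nx

from .errors import ValidationError

DEFAULT_CLIQUE_CAP = 10 ** 6


def _as_graph(net) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    return net.graph


def enumerate_maximal_cliques(net, cap: int = DEFAULT_CLIQUE_CAP) -> List[FrozenSet]:
    """All maximal cliques of an undirected simple graph.

    Uses Bron–Kerbosch with pivoting (via networkx).  Aborts with a clear
    error if more than ``cap`` cliques are produced, guarding against
    pathological dense graphs.
    """
    g = _as_graph(net)
    cliques: List[FrozenSet] = []
    for c in nx.find_cliques(g):
        cliques.append(frozenset(c))
        if len(cliques) > cap:
            raise ValidationError(
                f"more than {cap} maximal cliques; graph too dense for "
                "clique percolation at this setting"
            )
    return cliques


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


@dataclass
class CommunitySet:
    """The k-clique communities of one network."""

    k: int
    communities: List[Tuple[str, ...]]       # each sorted; list in canonical order
    membership: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.membership:
            counts: Dict[str, int] = {}
            for comm in self.communities:
                for node in comm:
                    counts[node] = counts.get(node, 0) + 1
            self.membership = counts

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def node_sets(self) -> List[FrozenSet]:
        return [frozenset(c) for c in self.communities]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "communities": [list(c) for c in self.communities],
            "membership": dict(sorted(self.membership.items())),
        }


def k_clique_communities(net, k: int, cap: int = DEFAULT_CLIQUE_CAP) -> CommunitySet:
    """Detect overlapping k-clique communities by clique percolation.

    Maximal cliques of size >= k are percolated: two are joined whenever
    they share at least k-1 nodes; each connected component's node union
    is one community.  Nodes in no k-clique belong to no community.
    Communities are returned in canonical order (sorted node tuples).
    """
    if k < 2:
        raise ValidationError("community order k must be >= 2")
    cliques = [c for c in enumerate_maximal_cliques(net, cap=cap) if len(c) >= k]
    if not cliques:
        return CommunitySet(k=k, communities=[])
    uf = _UnionFind(len(cliques))
    # index cliques by the (k-1)-subsets they contain would be costly in
    # memory for large cliques; pairwise intersection is adequate at the
    # network sizes this framework targets (tens to hundreds of features)
    for i in range(len(cliques)):
        for j in range(i + 1, len(cliques)):
            if uf.find(i) != uf.find(j) and len(cliques[i] & cliques[j]) >= k - 1:
                uf.union(i, j)
    comps: Dict[int, set] = {}
    for i, c in enumerate(cliques):
        comps.setdefault(uf.find(i), set()).update(c)
    communities = sorted(tuple(sorted(nodes)) for nodes in comps.values())
    return CommunitySet(k=k, communities=communities)


@dataclass
class OverlapReport:
    """Distribution of community membership and the bridge nodes."""

    membership_histogram: Dict[int, int]          # membership count -> n nodes
    bridge_nodes: List[dict]                      # id, omics_type, membership
    pairwise_shared: Dict[Tuple[int, int], Tuple[str, ...]]

    def to_dict(self) -> dict:
        return {
            "membership_histogram": {str(k): v for k, v in sorted(self.membership_histogram.items())},
            "bridge_nodes": self.bridge_nodes,
            "pairwise_shared": {f"{i},{j}": list(s) for (i, j), s in sorted(self.pairwise_shared.items())},
        }


def community_overlap(cs: CommunitySet,
                      types: Optional[Mapping[str, str]] = None) -> OverlapReport:
    """Membership histogram, bridge nodes and pairwise shared-node sets."""
    types = types or {}
    hist: Dict[int, int] = {}
    for count in cs.membership.values():
        hist[count] = hist.get(count, 0) + 1
    bridges = [
        {"id": node, "omics_type": types.get(node, ""), "membership": count}
        for node, count in sorted(cs.membership.items())
        if count >= 2
    ]
    shared: Dict[Tuple[int, int], Tuple[str, ...]] = {}
    sets = cs.node_sets()
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            inter = sets[i] & sets[j]
            if inter:
                shared[(i, j)] = tuple(sorted(inter))
    return OverlapReport(membership_histogram=hist, bridge_nodes=bridges,
                         pairwise_shared=shared)
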