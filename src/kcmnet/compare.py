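"""Cross-group comparison of networks and their communal structure.

Groups (baseline vs endpoint, intervention vs placebo, females vs males)
are compared through: global topology deltas, edge-set Jaccard, a
one-to-one Jaccard matching of their k-clique communities (reporting the
"missing elements" on each side and a completeness score), and per-node
differences in community membership (bridge behaviour).

"Extension" of a community is operationalised as its node-set size and
"completeness" as the fraction of the matched partner's nodes present;
both are package choices for notions the protocol names qualitatively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .cliquecomm import CommunitySet, k_clique_communities
from .errors import ValidationError
from .topology import TopologyReport, topology_report

_DELTA_FIELDS = ("n_nodes", "n_edges", "density", "avg_degree",
                 "avg_clustering", "n_components", "n_isolated")


@dataclass
class MatchedPair:
    index_a: int
    index_b: int
    jaccard: float
    shared: Tuple[str, ...]
    missing_in_a: Tuple[str, ...]   # nodes of b's community absent from a's
    missing_in_b: Tuple[str, ...]
    completeness_a: float           # fraction of b's community present in a's
    completeness_b: float

    def to_dict(self) -> dict:
        return {
            "index_a": self.index_a, "index_b": self.index_b,
            "jaccard": self.jaccard, "shared": list(self.shared),
            "missing_in_a": list(self.missing_in_a),
            "missing_in_b": list(self.missing_in_b),
            "completeness_a": self.completeness_a,
            "completeness_b": self.completeness_b,
        }


@dataclass
class CommunityMatching:
    k: int
    matches: List[MatchedPair]
    unmatched_a: List[int]
    unmatched_b: List[int]
    sizes_a: List[int]
    sizes_b: List[int]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "matches": [m.to_dict() for m in self.matches],
            "unmatched_a": self.unmatched_a,
            "unmatched_b": self.unmatched_b,
            "sizes_a": self.sizes_a,
            "sizes_b": self.sizes_b,
        }


def match_communities(a: CommunitySet, b: CommunitySet,
                      min_jaccard: float = 0.5) -> CommunityMatching:
    """Greedy maximum-Jaccard one-to-one matching of two community sets.

    Candidate pairs are taken in order of decreasing Jaccard, ties broken
    by larger intersection and then canonical (index) order; pairs whose
    Jaccard falls below ``min_jaccard`` stay unmatched.  Comparing sets of
    different order k is refused.
    """
    if a.k != b.k:
        raise ValidationError(f"cannot match communities of different order: {a.k} vs {b.k}")
    sets_a, sets_b = a.node_sets(), b.node_sets()
    cands = []
    for i, sa in enumerate(sets_a):
        for j, sb in enumerate(sets_b):
            inter = len(sa & sb)
            union = len(sa | sb)
            jac = inter / union if union else 0.0
            if jac >= min_jaccard and inter > 0:
                cands.append((-jac, -inter, i, j))
    cands.sort()
    used_a, used_b = set(), set()
    matches: List[MatchedPair] = []
    for njac, ninter, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        sa, sb = sets_a[i], sets_b[j]
        matches.append(MatchedPair(
            index_a=i, index_b=j, jaccard=-njac,
            shared=tuple(sorted(sa & sb)),
            missing_in_a=tuple(sorted(sb - sa)),
            missing_in_b=tuple(sorted(sa - sb)),
            completeness_a=len(sa & sb) / len(sb) if sb else 0.0,
            completeness_b=len(sa & sb) / len(sa) if sa else 0.0,
        ))
    matches.sort(key=lambda m: (m.index_a, m.index_b))
    return CommunityMatching(
        k=a.k,
        matches=matches,
        unmatched_a=[i for i in range(len(sets_a)) if i not in used_a],
        unmatched_b=[j for j in range(len(sets_b)) if j not in used_b],
        sizes_a=[len(s) for s in sets_a],
        sizes_b=[len(s) for s in sets_b],
    )


@dataclass
class ComparisonReport:
    group_a: Optional[str]
    group_b: Optional[str]
    topology_a: TopologyReport
    topology_b: TopologyReport
    topology_delta: Dict[str, float]   # a minus b
    edge_jaccard: float
    community_matching: CommunityMatching
    bridge_delta: Dict[str, int]       # membership(a) - membership(b) per node

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "topology_a": self.topology_a.to_dict(),
            "topology_b": self.topology_b.to_dict(),
            "topology_delta": self.topology_delta,
            "edge_jaccard": self.edge_jaccard,
            "community_matching": self.community_matching.to_dict(),
            "bridge_delta": dict(sorted(self.bridge_delta.items())),
        }


def compare_networks(a, b, k: int = 3, min_jaccard: float = 0.5) -> ComparisonReport:
    """Bundle topology deltas, edge Jaccard, community matching and
    bridge-membership differences for two networks.

    Networks are expected to share a node universe (the protocol compares
    the same features at baseline and endpoint); if they do not, the
    comparison proceeds over the union with a warning.
    """
    nodes_a, nodes_b = set(a.nodes), set(b.nodes)
    if nodes_a != nodes_b:
        warnings.warn(
            f"node universes differ ({len(nodes_a ^ nodes_b)} nodes not shared); "
            "comparing over the union",
            stacklevel=2,
        )
    rep_a, rep_b = topology_report(a), topology_report(b)
    delta = {f: float(getattr(rep_a, f)) - float(getattr(rep_b, f)) for f in _DELTA_FIELDS}
    ea, eb = a.edges, b.edges
    union = len(ea | eb)
    edge_jac = len(ea & eb) / union if union else 1.0
    cs_a = k_clique_communities(a, k)
    cs_b = k_clique_communities(b, k)
    matching = match_communities(cs_a, cs_b, min_jaccard=min_jaccard)
    bridge: Dict[str, int] = {}
    for node in nodes_a | nodes_b:
        d = cs_a.membership.get(node, 0) - cs_b.membership.get(node, 0)
        if d != 0:
            bridge[node] = d
    return ComparisonReport(
        group_a=a.provenance.group if hasattr(a, "provenance") else None,
        group_b=b.provenance.group if hasattr(b, "provenance") else None,
        topology_a=rep_a,
        topology_b=rep_b,
        topology_delta=delta,
        edge_jaccard=edge_jac,
        community_matching=matching,
        bridge_delta=bridge,
    )
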