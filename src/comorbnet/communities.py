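"""Clique enumeration and k-clique percolation community detection.

A k-community is the union of all k-cliques reachable through chains of
*adjacent* k-cliques, where two k-cliques are adjacent when they share
k−1 nodes. Communities found this way may overlap in nodes (a diagnosis
can sit in several comorbidity clusters) but never share a whole
k-clique.

Maximal cliques are enumerated with the pivoting Bron–Kerbosch algorithm
(via networkx); k-cliques are generated as k-subsets of maximal cliques
of size ≥ k. Percolation is implemented with (k−1)-subset hashing and
union–find: two distinct k-cliques share k−1 nodes iff they share a
(k−1)-subset, so bucketing cliques by their (k−1)-subsets discovers all
adjacencies without the quadratic clique-pair loop. Percolation runs on
topology only (any positive-weight edge counts); weights re-enter in the
motif-scoring stage.

All outputs are deterministically ordered: cliques lexicographically,
communities by (size descending, smallest member node).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx

__all__ = ["KCommunity", "maximal_cliques", "k_cliques", "k_communities"]


@dataclass(frozen=True)
class KCommunity:
    """Union of a chain of adjacent k-cliques."""

    k: int
    nodes: tuple[str, ...]  # sorted union of member cliques
    cliques: tuple[tuple[str, ...], ...]  # sorted member k-cliques

    def __len__(self) -> int:
        return len(self.nodes)


def maximal_cliques(net: nx.Graph) -> list[tuple[str, ...]]:
    """All maximal cliques of the (unweighted view of the) network.

    Isolated nodes are maximal cliques of size 1. Output sorted
    lexicographically, each clique internally sorted.
    """
    return sorted(tuple(sorted(c)) for c in nx.find_cliques(net)) if len(net) else []


def k_cliques(cliques: Sequence[Sequence[str]], k: int) -> list[tuple[str, ...]]:
    """All distinct k-node cliques, as k-subsets of maximal cliques of size ≥ k."""
    if k < 2:
        raise ValueError("k must be >= 2")
    out: set[tuple[str, ...]] = set()
    for c in cliques:
        if len(c) >= k:
            out.update(combinations(sorted(c), k))
    return sorted(out)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def k_communities(net: nx.Graph, k: int) -> list[KCommunity]:
    """Connected components of the k-clique adjacency relation.

    Adjacency = sharing exactly k−1 nodes (the most two distinct k-cliques
    can share). Returns communities ordered by (size desc, smallest node),
    each carrying its member cliques.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if net.number_of_nodes() < k:
        return []
    cliques = k_cliques(maximal_cliques(net), k)
    if not cliques:
        return []
    uf = _UnionFind(len(cliques))
    buckets: dict[tuple[str, ...], int] = {}
    for idx, clique in enumerate(cliques):
        for sub in combinations(clique, k - 1):
            first = buckets.setdefault(sub, idx)
            if first != idx:
                uf.union(first, idx)
    groups: dict[int, list[int]] = {}
    for idx in range(len(cliques)):
        groups.setdefault(uf.find(idx), []).append(idx)
    communities = []
    for members in groups.values():
        member_cliques = tuple(sorted(cliques[i] for i in members))
        nodes = tuple(sorted({n for c in member_cliques for n in c}))
        communities.append(KCommunity(k=k, nodes=nodes, cliques=member_cliques))
    communities.sort(key=lambda c: (-len(c.nodes), c.nodes))
    return communities
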