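"""Weighted-motif scoring: intensity and coherence of cliques and communities.

For a subgraph g with edge set l_g and weights W_ij, the *intensity*

    I(g) = ( Π_{(i,j) ∈ l_g} W_ij )^(1/|l_g|)

is the geometric mean of the member edge weights, and the *coherence*

    Q(g) = I(g) · |l_g| / Σ_{(i,j) ∈ l_g} W_ij

is the ratio of the geometric to the arithmetic mean. By the AM–GM
inequality Q ∈ (0, 1] for positive weights, with Q = 1 exactly when all
member weights are equal: high coherence flags diagnosis clusters whose
pairwise couplings are homogeneously strong rather than driven by one
dominant pair. Intensity is computed in log-space so products over many
edges neither overflow nor lose precision.

Clique candidates are scored on all their pairwise edges (which must
exist with positive weight); community candidates on the induced edges of
their node union by default, or on member-clique edges only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .communities import KCommunity

__all__ = [
    "MotifScore",
    "intensity",
    "coherence",
    "score_subgraph",
    "rank_motifs",
    "top_motifs",
    "coherence_histogram",
]


@dataclass(frozen=True)
class MotifScore:
    label: str
    kind: str  # "clique" | "community"
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    intensity: float
    coherence: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["edges"] = [list(e) for e in self.edges]
        d["n_edges"] = self.n_edges
        return d


def _collect_edges(
    net: nx.Graph,
    nodes: Sequence[str],
    edges: Iterable[tuple[str, str]] | None,
    complete: bool,
) -> tuple[tuple[str, str, float], ...]:
    if edges is None:
        if complete:
            edges = combinations(sorted(nodes), 2)
        else:
            edges = net.subgraph(nodes).edges()
    out = []
    for u, v in edges:
        if not net.has_edge(u, v):
            raise ValueError(f"edge ({u}, {v}) not present in the network")
        w = net[u][v].get("weight", 1)
        if w <= 0:
            raise ValueError(f"edge ({u}, {v}) has nonpositive weight {w}")
        out.append((u, v, float(w)) if u < v else (v, u, float(w)))
    if not out:
        raise ValueError("subgraph has no edges; intensity/coherence undefined")
    return tuple(sorted(out))


def intensity(
    net: nx.Graph,
    nodes: Sequence[str],
    edges: Iterable[tuple[str, str]] | None = None,
    complete: bool = True,
) -> float:
    """Geometric mean of the subgraph's edge weights (log-space).

    With ``complete=True`` (default) the subgraph is taken to be a clique:
    every node pair must be an edge of the network. Pass ``complete=False``
    to score the induced subgraph, or ``edges`` for an explicit edge set.
    """
    es = _collect_edges(net, nodes, edges, complete)
    return math.exp(sum(math.log(w) for _, _, w in es) / len(es))


def coherence(
    net: nx.Graph,
    nodes: Sequence[str],
    edges: Iterable[tuple[str, str]] | None = None,
    complete: bool = True,
) -> float:
    """Geometric over arithmetic mean of the subgraph's edge weights."""
    es = _collect_edges(net, nodes, edges, complete)
    geo = math.exp(sum(math.log(w) for _, _, w in es) / len(es))
    return geo * len(es) / sum(w for _, _, w in es)


def score_subgraph(
    net: nx.Graph,
    nodes: Sequence[str],
    label: str,
    kind: str,
    edges: Iterable[tuple[str, str]] | None = None,
    complete: bool | None = None,
) -> MotifScore:
    if complete is None:
        complete = kind == "clique"
    es = _collect_edges(net, nodes, edges, complete)
    geo = math.exp(sum(math.log(w) for _, _, w in es) / len(es))
    q = geo * len(es) / sum(w for _, _, w in es)
    return MotifScore(
        label=label, kind=kind, nodes=tuple(sorted(nodes)), edges=es,
        intensity=geo, coherence=q,
    )


def rank_motifs(
    net: nx.Graph,
    cliques: Sequence[Sequence[str]] = (),
    communities: Sequence[KCommunity] = (),
    community_edges: str = "induced",
) -> list[MotifScore]:
    """Score cliques and communities and sort by coherence.

    Order: coherence descending, ties by intensity descending, then by
    lexicographic node labels. Single-node candidates (no edges) are
    skipped — they carry no weight information.

    ``community_edges`` chooses the community edge set: "induced" (all
    network edges among the community's nodes) or "cliques" (member-clique
    edges only).
    """
    if community_edges not in ("induced", "cliques"):
        raise ValueError("community_edges must be 'induced' or 'cliques'")
    scores: list[MotifScore] = []
    for i, c in enumerate(cliques):
        if len(c) < 2:
            continue
        scores.append(score_subgraph(net, tuple(c), label=f"clique:{i:04d}", kind="clique"))
    for i, comm in enumerate(communities):
        if community_edges == "cliques":
            edges = sorted({pair for cl in comm.cliques for pair in combinations(sorted(cl), 2)})
        else:
            edges = None
        scores.append(
            score_subgraph(net, comm.nodes, label=f"community:{i:04d}", kind="community",
                           edges=edges, complete=False)
        )
    scores.sort(key=lambda s: (-s.coherence, -s.intensity, s.nodes))
    return scores


def top_motifs(scores: Sequence[MotifScore], top_n: int = 1) -> list[MotifScore]:
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    return list(scores[:top_n])


def coherence_histogram(scores: Sequence[MotifScore], bin_width: float = 0.05) -> pd.DataFrame:
    """Counts of motifs per coherence bin [left, left + bin_width)."""
    import numpy as np

    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    qs = [s.coherence for s in scores]
    counts, _ = np.histogram(qs, bins=edges)
    # Q = 1 belongs to the last bin, not beyond it
    return pd.DataFrame({"bin_left": edges[:-1], "count": counts})
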