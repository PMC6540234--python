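"""Shared test helpers: table builders and independent brute-force oracles.

The oracles here deliberately avoid the implementation's code paths: the
network oracle is a double loop over events and code pairs, and the
community oracle enumerates every k-subset of nodes, tests cliqueness
edge by edge, and takes connected components of the adjacency relation.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd


def make_events(code_lists, person_ids=None, event_type="consultation", date="2013-06-01"):
    """Event table from explicit per-event diagnosis code lists."""
    k = max((len(c) for c in code_lists), default=1)
    k = max(k, 1)
    rows = []
    for i, codes in enumerate(code_lists):
        row = {
            "event_id": f"E{i:06d}",
            "person_id": person_ids[i] if person_ids else f"P{i:06d}",
            "date": date,
            "event_type": event_type,
        }
        for j in range(k):
            row[f"dx{j + 1}"] = codes[j] if j < len(codes) else ""
        rows.append(row)
    cols = ["event_id", "person_id", "date", "event_type"] + [f"dx{j+1}" for j in range(k)]
    return pd.DataFrame(rows, columns=cols)


def make_deaths(code_lists, person_ids=None, date="2015-03-02"):
    rows = []
    for i, codes in enumerate(code_lists):
        row = {"person_id": person_ids[i] if person_ids else f"P{i:06d}", "date": date}
        for j in range(4):
            row[f"cause{j + 1}"] = codes[j] if j < len(codes) else ""
        rows.append(row)
    cols = ["person_id", "date"] + [f"cause{j+1}" for j in range(4)]
    return pd.DataFrame(rows, columns=cols)


def brute_force_weights(code_lists, mode="complete"):
    """Pair-count oracle: double loop over events and unordered code pairs."""
    weights: dict[tuple[str, str], int] = {}
    for codes in code_lists:
        distinct = list(dict.fromkeys(codes))
        if mode == "complete":
            pairs = combinations(sorted(distinct), 2)
        else:
            pairs = (tuple(sorted((distinct[0], s))) for s in distinct[1:])
        for p in pairs:
            weights[p] = weights.get(p, 0) + 1
    return weights


def network_weights(net: nx.Graph) -> dict[tuple[str, str], int]:
    return {tuple(sorted((u, v))): w for u, v, w in net.edges(data="weight")}


def brute_force_k_communities(net: nx.Graph, k: int):
    """CPM oracle: enumerate all k-subsets, test cliqueness, chain adjacency.

    Returns a set of frozensets of community node unions.
    """
    nodes = sorted(net.nodes)
    kcliques = [
        s for s in combinations(nodes, k)
        if all(net.has_edge(u, v) for u, v in combinations(s, 2))
    ]
    adj = nx.Graph()
    adj.add_nodes_from(range(len(kcliques)))
    for i, j in combinations(range(len(kcliques)), 2):
        if len(set(kcliques[i]) & set(kcliques[j])) == k - 1:
            adj.add_edge(i, j)
    comms = set()
    for comp in nx.connected_components(adj):
        comms.add(frozenset(n for idx in comp for n in kcliques[idx]))
    return comms


def random_weighted_graph(rng, n_nodes=12, p=0.4, max_w=50) -> nx.Graph:
    g = nx.Graph()
    labels = [f"N{i:02d}" for i in range(n_nodes)]
    g.add_nodes_from(labels)
    for u, v in combinations(labels, 2):
        if rng.random() < p:
            g.add_edge(u, v, weight=int(rng.integers(1, max_w + 1)))
    return g
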