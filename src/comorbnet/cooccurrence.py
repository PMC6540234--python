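"""Weighted diagnosis co-occurrence networks.

Nodes are ICD-10 diagnosis codes; the weight W_ij of an edge is the number
of medical events in which diagnoses i and j were recorded together. With
D the event-by-diagnosis incidence matrix (D_ik = 1 if diagnosis i appears
in event k), W = D Dᵀ off the diagonal — every unordered pair of distinct
codes within an event contributes one count ("complete" mode). A "star"
mode counts only (primary, secondary) pairs, the alternative reading in
which secondary diagnoses attach to the main one. The diagonal
(self-pairs) is always discarded: self-loops carry no co-occurrence
meaning and break clique semantics.

Networks are ``networkx.Graph`` objects with integer ``weight`` edge
attributes and graph-level metadata: ``source`` ("morbidity" |
"mortality"), ``mode``, ``cohort`` and ``n_events``. Mortality networks
are built the same way over cause-of-death lists; a degenerate
``main_only`` mode keeps only main-cause frequencies (node attribute
``count``) with no edges.
"""

from __future__ import annotations

import logging
from itertools import combinations
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from . import records_io

logger = logging.getLogger(__name__)

MODES = ("complete", "star")
MORTALITY_MODES = ("complete", "star", "main_only")


def _network_from_code_lists(
    code_lists: Sequence[Sequence[str]],
    mode: str,
    source: str,
    cohort: str | None,
) -> nx.Graph:
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    weights: Counter = Counter()
    nodes: set[str] = set()
    for codes in code_lists:
        nodes.update(codes)
        if mode == "complete":
            pairs = combinations(sorted(set(codes)), 2)
        else:  # star: primary paired with each secondary
            primary = codes[0]
            pairs = ((primary, s) if primary < s else (s, primary)
                     for s in codes[1:] if s != primary)
        weights.update(pairs)
    g = nx.Graph(source=source, mode=mode, cohort=cohort, n_events=len(code_lists))
    g.add_nodes_from(sorted(nodes))
    g.add_weighted_edges_from((i, j, w) for (i, j), w in sorted(weights.items()))
    return g


def build_network(
    events: pd.DataFrame, mode: str = "complete", cohort: str | None = None
) -> nx.Graph:
    """Morbidity network from an event table.

    Default mode is "complete" (the incidence-matrix product): all pairs of
    distinct codes in an event co-occur, not only primary–secondary ones.
    An empty table yields an empty network.
    """
    return _network_from_code_lists(
        records_io.event_code_lists(events), mode, "morbidity", cohort
    )


def build_ego_network(events: pd.DataFrame, person_id: str, mode: str = "complete") -> nx.Graph:
    """One individual's diagnosis network: build_network over their events."""
    own = events[events["person_id"] == person_id]
    if len(own) == 0:
        logger.warning("person %s has no events; returning empty ego-network", person_id)
    g = _network_from_code_lists(records_io.event_code_lists(own), mode, "morbidity", None)
    g.graph["person_id"] = person_id
    return g


def superpose(networks: Iterable[nx.Graph]) -> nx.Graph:
    """Superposition: node union, edge weights added pairwise.

    A cohort network is the superposition of its members' ego-networks.
    Mixing morbidity and mortality networks, or modes, is an error.
    """
    networks = list(networks)
    if not networks:
        return nx.Graph(source="morbidity", mode="complete", cohort=None, n_events=0)
    sources = {g.graph.get("source") for g in networks}
    modes = {g.graph.get("mode") for g in networks}
    if len(sources) > 1:
        raise ValueError(f"cannot superpose networks of mixed sources {sorted(map(str, sources))}")
    if len(modes) > 1:
        raise ValueError(f"cannot superpose networks of mixed modes {sorted(map(str, modes))}")
    weights: Counter = Counter()
    nodes: set[str] = set()
    n_events = 0
    for g in networks:
        nodes.update(g.nodes)
        n_events += g.graph.get("n_events", 0)
        for u, v, w in g.edges(data="weight"):
            weights[(u, v) if u < v else (v, u)] += w
    out = nx.Graph(source=sources.pop(), mode=modes.pop(), cohort=None, n_events=n_events)
    out.add_nodes_from(sorted(nodes))
    out.add_weighted_edges_from((i, j, w) for (i, j), w in sorted(weights.items()))
    return out


def build_mortality_network(
    deaths: pd.DataFrame, mode: str = "complete", cohort: str | None = None
) -> nx.Graph:
    """Cause-of-death co-occurrence network.

    "complete"/"star" mirror the morbidity construction over the ordered
    cause lists (main cause first). "main_only" is the degenerate reading
    in which only the main cause is used: nodes carry a ``count``
    attribute (frequency as main cause) and there are no edges.
    """
    if mode not in MORTALITY_MODES:
        raise ValueError(f"unknown mortality mode {mode!r}; expected one of {MORTALITY_MODES}")
    code_lists = records_io.death_code_lists(deaths)
    if mode == "main_only":
        counts = Counter(codes[0] for codes in code_lists if codes)
        g = nx.Graph(source="mortality", mode=mode, cohort=cohort, n_events=len(code_lists))
        g.add_nodes_from((c, {"count": n}) for c, n in sorted(counts.items()))
        return g
    return _network_from_code_lists(code_lists, mode, "mortality", cohort)


# ---------------------------------------------------------------- export


def write_edgelist(net: nx.Graph, path: str | Path) -> None:
    """Weighted edge list as a three-column TSV (i, j, weight), sorted."""
    rows = sorted((u, v, w) if u < v else (v, u, w) for u, v, w in net.edges(data="weight"))
    pd.DataFrame(rows, columns=["i", "j", "weight"]).to_csv(path, sep="\t", index=False)


def read_edgelist(path: str | Path, source: str = "morbidity", mode: str = "complete") -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"i": str, "j": str})
    g = nx.Graph(source=source, mode=mode, cohort=None, n_events=None)
    g.add_weighted_edges_from(df.itertuples(index=False, name=None))
    return g


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    g = net.copy()
    for k in [k for k, v in g.graph.items() if v is None]:
        del g.graph[k]
    nx.write_graphml(g, path)
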