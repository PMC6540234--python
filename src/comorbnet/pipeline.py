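"""Per-cohort analysis pipeline and cohort comparison.

The per-cohort sequence mirrors the analysis order of the underlying
method: filter records to the cohort → build the weighted co-occurrence
network → degree/strength tables and CCDFs → strength cut → maximal
cliques → k-clique percolation communities → rank cliques and communities
by motif coherence → mortality network → morbidity–mortality overlap.

Cohort comparison is descriptive set algebra on the top-coherence motifs:
shared nodes, nodes exclusive to each cohort, and per-node strength
ratios. Overlap between morbidity motifs and mortality cause cliques is
measured by the Jaccard index of their node sets (stated in every report
header, since "overlap" admits several conventions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import cooccurrence, network_stats, records_io
from .communities import KCommunity, k_communities, maximal_cliques
from .motifs import MotifScore, coherence_histogram, rank_motifs, top_motifs

logger = logging.getLogger(__name__)

OVERLAP_CONVENTION = "jaccard index on node sets"


class ConfigMismatchError(ValueError):
    """Cohort results produced under different thresholds/k cannot be compared."""


@dataclass
class AnalysisConfig:
    strength_threshold: float = network_stats.DEFAULT_STRENGTH_THRESHOLD
    #: percolation clique size; None → max observed diagnoses per event
    k: int | None = 4
    network_mode: str = "complete"
    mortality_mode: str = "complete"
    community_edges: str = "induced"
    iterative_cut: bool = False
    top_n: int = 10

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class OverlapReport:
    """Node-set overlap between morbidity motifs and mortality cliques."""

    convention: str
    pairs: list[dict] = field(default_factory=list)  # sorted best-first

    @property
    def best(self) -> dict | None:
        return self.pairs[0] if self.pairs else None

    def to_dict(self) -> dict:
        return {"convention": self.convention, "pairs": self.pairs, "best": self.best}


@dataclass
class CohortResult:
    cohort: str
    config: AnalysisConfig
    k: int
    n_persons: int
    n_events: int
    n_deaths: int
    network: nx.Graph
    filtered_network: nx.Graph
    degree_strength: pd.DataFrame
    degree_ccdf: network_stats.CCDF | None
    strength_ccdf: network_stats.CCDF | None
    cliques: list[tuple[str, ...]]
    communities: list[KCommunity]
    motifs: list[MotifScore]
    mortality_network: nx.Graph
    overlap: OverlapReport
    provenance: dict

    @property
    def empty(self) -> bool:
        return self.n_persons == 0

    @property
    def top_motif(self) -> MotifScore | None:
        return self.motifs[0] if self.motifs else None

    def summary_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "k": self.k,
            "n_persons": self.n_persons,
            "n_events": self.n_events,
            "n_deaths": self.n_deaths,
            "nodes_full": self.network.number_of_nodes(),
            "edges_full": self.network.number_of_edges(),
            "nodes_filtered": self.filtered_network.number_of_nodes(),
            "edges_filtered": self.filtered_network.number_of_edges(),
            "n_maximal_cliques": len(self.cliques),
            "n_communities": len(self.communities),
            "n_scored_motifs": len(self.motifs),
            "top_motif": self.motifs[0].to_dict() if self.motifs else None,
            "overlap_best": self.overlap.best,
            "provenance": self.provenance,
        }


def _table_digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def motif_overlap(
    morbidity_motifs: Sequence[MotifScore],
    mortality_net: nx.Graph,
) -> OverlapReport:
    """Jaccard overlap between top morbidity motifs and mortality cliques.

    Mortality cliques are the maximal cliques (size ≥ 2) of the mortality
    network. Pairs are sorted by Jaccard descending, ties by shared-node
    count, then lexicographically.
    """
    report = OverlapReport(convention=OVERLAP_CONVENTION)
    mort_cliques = [c for c in maximal_cliques(mortality_net) if len(c) >= 2]
    for motif in morbidity_motifs:
        mset = set(motif.nodes)
        for clique in mort_cliques:
            cset = set(clique)
            shared = sorted(mset & cset)
            union = mset | cset
            report.pairs.append(
                {
                    "morbidity_motif": motif.label,
                    "morbidity_nodes": list(motif.nodes),
                    "mortality_clique": list(clique),
                    "shared_nodes": shared,
                    "jaccard": len(shared) / len(union) if union else 0.0,
                }
            )
    report.pairs.sort(
        key=lambda p: (
            -p["jaccard"],
            -len(p["shared_nodes"]),
            p["morbidity_motif"],
            p["mortality_clique"],
        )
    )
    return report


def run_cohort(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    deaths: pd.DataFrame,
    cohort: str,
    config: AnalysisConfig | None = None,
) -> CohortResult:
    """Run the full analysis for one cohort. An empty cohort yields an
    explicit empty result, not an error."""
    config = config or AnalysisConfig()
    ids = records_io.cohort_person_ids(persons, cohort)
    ev = records_io.filter_by_persons(events, ids)
    de = records_io.filter_by_persons(deaths, ids)
    logger.info("cohort %s: %d persons, %d events, %d deaths", cohort, len(ids), len(ev), len(de))

    net = cooccurrence.build_network(ev, mode=config.network_mode, cohort=cohort)
    ds = network_stats.degree_strength(net)
    degree_ccdf = network_stats.empirical_ccdf(ds["degree"]) if len(ds) else None
    strength_ccdf = network_stats.empirical_ccdf(ds["strength"]) if len(ds) else None

    filtered = network_stats.strength_filter(
        net, config.strength_threshold, iterative=config.iterative_cut
    )
    logger.info(
        "cohort %s: network %d nodes / %d edges -> cut(F>%g) %d nodes / %d edges",
        cohort, net.number_of_nodes(), net.number_of_edges(),
        config.strength_threshold, filtered.number_of_nodes(), filtered.number_of_edges(),
    )

    if config.k is not None:
        k = config.k
    else:
        lists = records_io.event_code_lists(ev)
        k = max((len(c) for c in lists), default=2)
        k = max(k, 2)
    cliques = maximal_cliques(filtered)
    comms = k_communities(filtered, k)
    scored = rank_motifs(filtered, cliques, comms, community_edges=config.community_edges)
    logger.info(
        "cohort %s: %d maximal cliques, %d k=%d communities, %d scored motifs",
        cohort, len(cliques), len(comms), k, len(scored),
    )

    mort_net = cooccurrence.build_mortality_network(de, mode=config.mortality_mode, cohort=cohort)
    overlap = motif_overlap(top_motifs(scored, config.top_n) if scored else [], mort_net)

    provenance = {
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "input_digests": {
            "persons": _table_digest(persons),
            "events": _table_digest(events),
            "deaths": _table_digest(deaths),
        },
        "cohort_sizes": {"persons": len(ids), "events": len(ev), "deaths": len(de)},
    }
    return CohortResult(
        cohort=cohort, config=config, k=k,
        n_persons=len(ids), n_events=len(ev), n_deaths=len(de),
        network=net, filtered_network=filtered,
        degree_strength=ds, degree_ccdf=degree_ccdf, strength_ccdf=strength_ccdf,
        cliques=cliques, communities=comms, motifs=scored,
        mortality_network=mort_net, overlap=overlap, provenance=provenance,
    )


def compare_cohorts(result_a: CohortResult, result_b: CohortResult) -> dict:
    """Descriptive comparison of two cohorts' top-coherence motifs.

    Reports shared top-motif nodes, nodes exclusive to each cohort's top
    motif, and per-node strength ratios (cohort A strength / cohort B
    strength on the full networks). Raises if the two results were
    produced under different k or strength thresholds.
    """
    if (result_a.k != result_b.k
            or result_a.config.strength_threshold != result_b.config.strength_threshold):
        raise ConfigMismatchError(
            "cohorts analysed under different k or strength thresholds cannot be compared"
        )
    top_a = set(result_a.top_motif.nodes) if result_a.top_motif else set()
    top_b = set(result_b.top_motif.nodes) if result_b.top_motif else set()
    sa = dict(result_a.network.degree(weight="weight"))
    sb = dict(result_b.network.degree(weight="weight"))
    ratios = {}
    for node in sorted(top_a | top_b):
        a, b = float(sa.get(node, 0.0)), float(sb.get(node, 0.0))
        ratios[node] = {
            "strength_a": a,
            "strength_b": b,
            "ratio_a_over_b": (a / b) if b > 0 else None,
        }
    return {
        "cohort_a": result_a.cohort,
        "cohort_b": result_b.cohort,
        "top_motif_a": result_a.top_motif.to_dict() if result_a.top_motif else None,
        "top_motif_b": result_b.top_motif.to_dict() if result_b.top_motif else None,
        "shared_top_motif_nodes": sorted(top_a & top_b),
        "exclusive_to_a": sorted(top_a - top_b),
        "exclusive_to_b": sorted(top_b - top_a),
        "strength_ratios": ratios,
    }


# ---------------------------------------------------------------- reports


def write_result(result: CohortResult, outdir: str | Path) -> None:
    """Write all artifacts of a cohort run (deterministic byte-for-byte)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cooccurrence.write_edgelist(result.network, outdir / "network_full.tsv")
    cooccurrence.write_edgelist(result.filtered_network, outdir / "network_filtered.tsv")
    cooccurrence.write_graphml(result.filtered_network, outdir / "network_filtered.graphml")
    if result.mortality_network.number_of_nodes():
        cooccurrence.write_edgelist(result.mortality_network, outdir / "mortality_network.tsv")
    result.degree_strength.to_csv(outdir / "degree_strength.csv", index=False)
    if result.degree_ccdf is not None:
        result.degree_ccdf.to_csv(outdir / "ccdf_degree.csv")
    if result.strength_ccdf is not None:
        result.strength_ccdf.to_csv(outdir / "ccdf_strength.csv")

    communities_payload = [
        {"id": i, "k": c.k, "nodes": list(c.nodes), "cliques": [list(cl) for cl in c.cliques]}
        for i, c in enumerate(result.communities)
    ]
    _write_json(communities_payload, outdir / "communities.json")
    _write_json([m.to_dict() for m in result.motifs], outdir / "motifs.json")
    coherence_histogram(result.motifs).to_csv(outdir / "coherence_histogram.csv", index=False)
    _write_json(result.overlap.to_dict(), outdir / "overlap.json")
    _write_json(result.summary_dict(), outdir / "summary.json")
    (outdir / "summary.md").write_text(_markdown_summary(result))


def write_comparison(report: Mapping, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(dict(report), outdir / "comparison.json")
    lines = [
        f"# Cohort comparison: {report['cohort_a']} vs {report['cohort_b']}",
        "",
        f"Shared top-motif diagnoses: {', '.join(report['shared_top_motif_nodes']) or '(none)'}",
        f"Exclusive to {report['cohort_a']}: {', '.join(report['exclusive_to_a']) or '(none)'}",
        f"Exclusive to {report['cohort_b']}: {', '.join(report['exclusive_to_b']) or '(none)'}",
        "",
    ]
    (outdir / "comparison.md").write_text("\n".join(lines))


def _write_json(payload, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _markdown_summary(result: CohortResult) -> str:
    s = result.summary_dict()
    lines = [
        f"# Cohort analysis: {result.cohort}",
        "",
        f"- persons: {s['n_persons']}, events: {s['n_events']}, deaths: {s['n_deaths']}",
        f"- morbidity network: {s['nodes_full']} nodes / {s['edges_full']} edges",
        f"- after strength cut (F > {result.config.strength_threshold:g}): "
        f"{s['nodes_filtered']} nodes / {s['edges_filtered']} edges",
        f"- maximal cliques: {s['n_maximal_cliques']}; k={result.k} communities: {s['n_communities']}",
        "",
    ]
    if result.top_motif:
        m = result.top_motif
        lines += [
            "## Top motif by coherence",
            "",
            f"- nodes: {', '.join(m.nodes)}",
            f"- intensity I(g) = {m.intensity:.3f}, coherence Q(g) = {m.coherence:.4f} "
            f"({m.n_edges} edges)",
            "",
        ]
    if result.overlap.best:
        b = result.overlap.best
        lines += [
            f"## Morbidity–mortality overlap ({result.overlap.convention})",
            "",
            f"- best pair: motif {b['morbidity_motif']} vs mortality clique "
            f"{{{', '.join(b['mortality_clique'])}}}, shared "
            f"{{{', '.join(b['shared_nodes'])}}}, Jaccard = {b['jaccard']:.4f}",
            "",
        ]
    return "\n".join(lines)
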