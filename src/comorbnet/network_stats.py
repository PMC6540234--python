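"""Degree/strength tables, empirical CCDFs, the strength cut and crude rates.

The degree K_i of a diagnosis is its number of neighbours; its strength
F_i = Σ_j W_ij sums the co-occurrence weights of its edges. Heavy-tailed
K/F distributions are summarised by the empirical complementary
cumulative distribution function P(X ≥ x). The network reduction keeps
nodes with strength strictly above a threshold (default 10), restricting
the analysis to recurrently co-occurring diagnoses.

Crude cause-specific rates per 100,000 are computed per (cohort, sex,
cause group), where cause groups map ICD-10 chapters to broad disease
families; a person counts once per group if any qualifying code appears
in any of their records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import records_io

DEFAULT_STRENGTH_THRESHOLD = 10.0

#: default ICD-10 chapter-prefix → cause-group mapping (overridable)
DEFAULT_CAUSE_GROUPS: dict[str, str] = {
    "I": "cardiovascular",
    "A": "communicable",
    "B": "communicable",
    "F": "mental_behavioral",
    "E": "metabolic",
    "G": "nervous_system",
}


def degree_strength(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree and strength, sorted by strength then degree, descending."""
    deg = dict(net.degree())
    strength = dict(net.degree(weight="weight"))
    df = pd.DataFrame(
        {
            "node": list(net.nodes),
            "degree": [deg[n] for n in net.nodes],
            "strength": [float(strength[n]) for n in net.nodes],
        }
    )
    return df.sort_values(
        ["strength", "degree", "node"], ascending=[False, False, True]
    ).reset_index(drop=True)


@dataclass(frozen=True)
class CCDF:
    """Empirical survival function P(X ≥ x) over the observed support.

    ``values`` are the sorted distinct observations; ``survival[i]`` is the
    fraction of observations ≥ ``values[i]``. By construction survival
    starts at 1 at the minimum and is non-increasing.
    """

    values: tuple[float, ...]
    survival: tuple[float, ...]

    def evaluate(self, x: float) -> float:
        """P(X ≥ x) for arbitrary x (1 below the minimum, 0 above the maximum)."""
        idx = int(np.searchsorted(self.values, x, side="left"))
        if idx >= len(self.values):
            return 0.0
        # the smallest distinct value >= x carries exactly the count of obs >= x
        return self.survival[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "survival": self.survival})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def empirical_ccdf(values: Sequence[float]) -> CCDF:
    """Discrete survival function P(X ≥ x) = #{v : v ≥ x} / n."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empirical_ccdf requires a nonempty value list")
    distinct, counts = np.unique(arr, return_counts=True)
    # #values >= x for each distinct x: reversed cumulative sum
    at_least = counts[::-1].cumsum()[::-1]
    return CCDF(tuple(distinct.tolist()), tuple((at_least / arr.size).tolist()))


def plot_ccdf(ccdfs: Mapping[str, CCDF], path: str | Path, xlabel: str = "value") -> None:
    """Log–log CCDF plot (optional output; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in ccdfs.items():
        ax.loglog(c.values, c.survival, marker="o", ms=3, lw=1, label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("P(X ≥ x)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def strength_filter(
    net: nx.Graph,
    threshold: float = DEFAULT_STRENGTH_THRESHOLD,
    iterative: bool = False,
) -> nx.Graph:
    """Keep nodes with strength strictly greater than *threshold*.

    Strengths are computed on the input network once (one-pass cut): after
    removal a surviving node's strength may fall to or below the threshold,
    so the operation is not idempotent in general. ``iterative=True``
    re-applies the cut until a fixed point.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    current = net
    while True:
        strength = dict(current.degree(weight="weight"))
        keep = [n for n in current.nodes if strength[n] > threshold]
        out = current.subgraph(keep).copy()
        out.graph.update(net.graph)
        if not iterative or out.number_of_nodes() == current.number_of_nodes():
            return out
        current = out


def make_code_grouper(prefix_map: Mapping[str, str] | None = None) -> Callable[[str], str]:
    """Map an ICD-10 code to its cause group by longest matching prefix."""
    pm = dict(DEFAULT_CAUSE_GROUPS if prefix_map is None else prefix_map)
    lengths = sorted({len(p) for p in pm}, reverse=True)

    def group(code: str) -> str:
        for ln in lengths:
            g = pm.get(code[:ln])
            if g is not None:
                return g
        return "other"

    return group


def crude_rates(
    persons: pd.DataFrame,
    table: pd.DataFrame,
    grouping: Mapping[str, str] | Callable[[str], str] | None = None,
    per: float = 100_000.0,
) -> pd.DataFrame:
    """Crude cause-specific rates per *per* inhabitants.

    *table* is an event table (dx columns) or mortality table (cause
    columns). A person counts once per cause group if any of their codes
    maps to it; denominators are the (cohort, sex) population sizes from
    the registry's primary cohort labels. Cells with zero denominator are
    emitted with a missing rate.
    """
    grouper = grouping if callable(grouping) else make_code_grouper(grouping)
    code_cols = [c for c in table.columns if c.startswith("dx") or c.startswith("cause")]
    if not code_cols:
        raise ValueError("table has neither dx* nor cause* columns")

    person_info = persons.set_index("person_id")[["cohort", "sex"]]
    pop = persons.groupby(["cohort", "sex"]).size()

    # (person, group) incidence, deduplicated
    pairs: set[tuple[str, str]] = set()
    for row in table[["person_id"] + code_cols].itertuples(index=False):
        pid = row[0]
        for code in row[1:]:
            if code:
                pairs.add((pid, grouper(code)))

    groups = sorted({g for _, g in pairs} | set(
        (grouping.values() if isinstance(grouping, Mapping) else DEFAULT_CAUSE_GROUPS.values())
        if not callable(grouping) else []
    ))
    records = []
    counts: dict[tuple[str, str, str], int] = {}
    for pid, grp in pairs:
        if pid not in person_info.index:
            continue
        cohort, sex = person_info.loc[pid]
        counts[(cohort, sex, grp)] = counts.get((cohort, sex, grp), 0) + 1
    for cohort in records_io.COHORTS:
        for sex in records_io.SEXES:
            denom = int(pop.get((cohort, sex), 0))
            for grp in groups:
                cases = counts.get((cohort, sex, grp), 0)
                rate = cases / denom * per if denom else np.nan
                records.append(
                    {"cohort": cohort, "sex": sex, "group": grp,
                     "cases": cases, "population": denom, "rate": rate}
                )
    return pd.DataFrame(records)
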