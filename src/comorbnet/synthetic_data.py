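"""Synthetic linked person/event/mortality tables with planted comorbidity structure.

The generator emulates the shape of linked administrative health data: a
person registry with two overlapping vulnerable cohorts (conflict victims,
identified by a persistent flag, and the poorest welfare strata, here
labelled ``sisben``), event-level care contacts carrying one primary and up
to three secondary ICD-10 diagnoses, and a mortality table with a main
cause plus up to three underlying causes.

Known structure is *planted* so that every downstream network stage is
testable: a high-weight metabolic–cardiovascular diagnosis clique present
in both vulnerable cohorts, a mental-health coupling (dysthymia F341 and
mixed anxiety–depression F412 attached to the metabolic cluster) present
only in the victims cohort, and cohort-specific mortality cliques. The
planted structure is recorded in a :class:`SyntheticTruth` manifest for
recovery tests.

Events of a planted motif contain motif codes only; background events draw
from a fixed pool of common primary-care codes with Zipf-like
probabilities, which produces the fat-tailed degree/strength profile
characteristic of real claims networks. The two subnetworks therefore do
not mix — a deliberate idealisation (see the methods note).

Three independent RNG streams (population / events / mortality) are
derived from the master seed, so enlarging one table never reshuffles the
others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .records_io import COHORTS, EVENT_TYPES, validate_icd10

__all__ = [
    "PlantedMotif",
    "GeneratorConfig",
    "SyntheticTruth",
    "ConfigError",
    "GenerationError",
    "generate_population",
    "generate_events",
    "generate_mortality",
    "generate_dataset",
    "write_dataset",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """A planted motif was not realised in the generated data."""


# The seven highest-strength hub diagnoses of a primary-care morbidity
# network (hypertension, urinary tract infection, common cold, gastritis,
# hypothyroidism, intestinal parasitism, low back pain) followed by a tail
# of common ambulatory codes. Zipf-like sampling over this list yields a
# heavy-tailed co-occurrence network without further tuning.
DEFAULT_BACKGROUND_CODES: tuple[str, ...] = (
    "I10X", "N390", "J00X", "K297", "E039", "B829", "M545",
    "R104", "J459", "E669", "R51X", "K021", "M255", "L309",
    "J029", "A09X", "H10X", "N760", "K529", "R509", "M796",
    "J189", "D509", "E785", "N200", "K590", "G439", "L500",
    "M169", "J209", "R060", "N300", "I839", "H811", "K358", "J069",
)

_EVENT_TYPE_PROBS = (0.60, 0.15, 0.15, 0.10)  # consultation, emergency, treatment, follow-up


@dataclass(frozen=True)
class PlantedMotif:
    """A diagnosis clique planted into the events of targeted cohorts.

    Each qualifying event of a targeted person is, with probability
    ``event_rate``, drawn from this motif: ``within_event_draw`` of its
    codes are emitted (without replacement) as the event's diagnoses.
    """

    name: str
    codes: tuple[str, ...]
    target_cohorts: tuple[str, ...]
    event_rate: float
    within_event_draw: int = 2

    def validate(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ConfigError(f"motif {self.name}: duplicate codes")
        for c in self.codes:
            if not validate_icd10(c):
                raise ConfigError(f"motif {self.name}: {c!r} does not match the ICD-10 pattern")
        if not (len(self.codes) >= self.within_event_draw >= 2):
            raise ConfigError(
                f"motif {self.name}: need |codes| >= within_event_draw >= 2, "
                f"got {len(self.codes)} and {self.within_event_draw}"
            )
        if not 0.0 <= self.event_rate <= 1.0:
            raise ConfigError(f"motif {self.name}: event_rate {self.event_rate} outside [0,1]")
        bad = set(self.target_cohorts) - set(COHORTS)
        if bad:
            raise ConfigError(f"motif {self.name}: unknown target cohorts {sorted(bad)}")

    def pair_coverage(self) -> float:
        """Probability that a given code pair appears in one motif event."""
        m, w = len(self.codes), self.within_event_draw
        return comb(m - 2, w - 2) / comb(m, w)


def _default_background_probs(codes: Sequence[str], s: float = 1.1) -> tuple[float, ...]:
    ranks = np.arange(1, len(codes) + 1, dtype=float)
    p = ranks ** (-s)
    return tuple(p / p.sum())


def default_planted_motifs() -> tuple[PlantedMotif, ...]:
    """The default planted structure.

    A metabolic–cardiovascular cluster (type-2 diabetes E119, hypertensive
    heart disease I119, hyperglyceridaemia E781, mixed hyperlipidaemia
    E782) shared by both vulnerable cohorts, and a mental–metabolic
    coupling adding dysthymia (F341) and mixed anxiety–depression (F412)
    to that cluster in the victims cohort only.
    """
    return (
        PlantedMotif(
            name="metabolic_cluster",
            codes=("E119", "I119", "E781", "E782"),
            target_cohorts=("victim", "sisben"),
            event_rate=0.08,
            within_event_draw=3,
        ),
        PlantedMotif(
            name="mental_metabolic_coupling",
            codes=("F341", "F412", "E119", "I119", "E781", "E782"),
            target_cohorts=("victim",),
            event_rate=0.08,
            within_event_draw=3,
        ),
    )


def default_mortality_motifs() -> tuple[PlantedMotif, ...]:
    """Cohort-specific cause-of-death cliques.

    Victims: diabetes without complications (E119), hypertensive heart
    disease (I119) and insulin-dependent diabetes with complications
    (E107). Sisben: E119, hyperglyceridaemia (E781) and primary
    hypertension (I10X). ``event_rate`` is the probability that a targeted
    person's death record is drawn from the motif.
    """
    return (
        PlantedMotif(
            name="victims_mortality_clique",
            codes=("E119", "I119", "E107"),
            target_cohorts=("victim",),
            event_rate=0.3,
            within_event_draw=3,
        ),
        PlantedMotif(
            name="sisben_mortality_clique",
            codes=("E119", "E781", "I10X"),
            target_cohorts=("sisben",),
            event_rate=0.3,
            within_event_draw=3,
        ),
    )


@dataclass
class GeneratorConfig:
    n_persons: int = 10_000
    cohort_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"victim": 0.2, "sisben": 0.3, "other": 0.5}
    )
    #: distribution of care contacts per person over the study window:
    #: ("poisson", {"lam": ...}), ("fixed", {"n": ...}) or
    #: ("nbinom", {"n": ..., "p": ...})
    events_per_person: tuple[str, dict] = ("poisson", {"lam": 10.0})
    max_dx_per_event: int = 4
    background_codes: tuple[str, ...] = DEFAULT_BACKGROUND_CODES
    background_probs: tuple[float, ...] | None = None  # Zipf(1.1) over ranks if None
    planted_motifs: tuple[PlantedMotif, ...] = field(default_factory=default_planted_motifs)
    mortality_motifs: tuple[PlantedMotif, ...] = field(default_factory=default_mortality_motifs)
    mortality_rate: float = 0.024
    #: probability that a sisben/other person additionally carries the
    #: persistent victim flag (the cohorts overlap)
    victim_overlap_rate: float = 0.05
    #: chance that a background event carries each extra secondary code
    background_extra_dx_prob: float = 0.35
    date_start: str = "2011-01-01"
    date_end: str = "2016-12-31"
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_motifs = tuple(
            m if isinstance(m, PlantedMotif) else PlantedMotif(**m) for m in self.planted_motifs
        )
        self.mortality_motifs = tuple(
            m if isinstance(m, PlantedMotif) else PlantedMotif(**m) for m in self.mortality_motifs
        )
        self.background_codes = tuple(self.background_codes)
        if self.background_probs is not None:
            self.background_probs = tuple(self.background_probs)

    def resolved_background_probs(self) -> np.ndarray:
        if self.background_probs is None:
            p = np.asarray(_default_background_probs(self.background_codes))
        else:
            p = np.asarray(self.background_probs, dtype=float)
        if len(p) != len(self.background_codes):
            raise ConfigError("background_probs length differs from background_codes")
        if (p < 0).any():
            raise ConfigError("background probabilities must be nonnegative")
        return p / p.sum()

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ConfigError("n_persons must be nonnegative")
        if set(self.cohort_fractions) != set(COHORTS):
            raise ConfigError(f"cohort_fractions must cover exactly {COHORTS}")
        fr = np.array([self.cohort_fractions[c] for c in COHORTS], dtype=float)
        if (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
            raise ConfigError("cohort_fractions must be nonnegative and sum to 1")
        if self.max_dx_per_event < 1:
            raise ConfigError("max_dx_per_event must be >= 1")
        if not 0.0 <= self.mortality_rate <= 1.0:
            raise ConfigError("mortality_rate outside [0,1]")
        if not 0.0 <= self.victim_overlap_rate <= 1.0:
            raise ConfigError("victim_overlap_rate outside [0,1]")
        name, params = self.events_per_person
        if name not in ("poisson", "fixed", "nbinom"):
            raise ConfigError(f"unknown events_per_person distribution {name!r}")
        for c in self.background_codes:
            if not validate_icd10(c):
                raise ConfigError(f"background code {c!r} does not match the ICD-10 pattern")
        self.resolved_background_probs()
        for m in self.planted_motifs + self.mortality_motifs:
            m.validate()
        for m in self.planted_motifs:
            if m.within_event_draw > self.max_dx_per_event:
                raise ConfigError(
                    f"motif {m.name}: within_event_draw exceeds max_dx_per_event"
                )
        # an event belongs to at most one motif: the applicable rates of any
        # label combination a person can carry must sum to <= 1
        for labels in ({"victim"}, {"sisben"}, {"other"},
                       {"sisben", "victim"}, {"other", "victim"}):
            tot = sum(m.event_rate for m in self.planted_motifs
                      if labels & set(m.target_cohorts))
            if tot > 1.0 + 1e-12:
                raise ConfigError(f"planted motif event rates for labels {sorted(labels)} sum to {tot} > 1")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_motifs"] = [asdict(m) for m in self.planted_motifs]
        d["mortality_motifs"] = [asdict(m) for m in self.mortality_motifs]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "events_per_person" in d and isinstance(d["events_per_person"], (list, tuple)):
            name, params = d["events_per_person"]
            d["events_per_person"] = (name, dict(params))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SyntheticTruth:
    """Manifest of what was planted, for recovery tests."""

    seed: int
    planted_motifs: list[dict]
    mortality_motifs: list[dict]
    #: per (motif name, cohort label): number of generated qualifying events
    realized_events: dict[str, dict[str, int]]
    realized_deaths: dict[str, dict[str, int]]
    #: per (motif name, cohort label): expected weight of each motif pair
    expected_pair_weights: dict[str, dict[str, float]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


# ------------------------------------------------------------------ streams

_POP, _EVENTS, _MORTALITY = 0, 1, 2


def _stream(config: GeneratorConfig, which: int) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(3)
    return np.random.default_rng(children[which])


def _labels_matrix(persons: pd.DataFrame) -> dict[str, np.ndarray]:
    """Boolean membership per cohort label (victim by flag, others by label)."""
    return {
        "victim": persons["victim_flag"].to_numpy(dtype=bool),
        "sisben": (persons["cohort"] == "sisben").to_numpy(),
        "other": (persons["cohort"] == "other").to_numpy(),
    }


def _gumbel_topk(rng: np.random.Generator, logp: np.ndarray, n_rows: int, k: int) -> np.ndarray:
    """Weighted sampling without replacement, vectorised over rows.

    Returns an (n_rows, k) array of column indices: the top-k Gumbel-perturbed
    log-probabilities per row, which is equivalent to successive draws
    without replacement with probabilities proportional to exp(logp).
    """
    keys = logp[None, :] + rng.gumbel(size=(n_rows, logp.size))
    part = np.argpartition(-keys, k - 1, axis=1)[:, :k]
    order = np.argsort(-np.take_along_axis(keys, part, axis=1), axis=1)
    return np.take_along_axis(part, order, axis=1)


def _random_dates(rng: np.random.Generator, config: GeneratorConfig, n: int) -> np.ndarray:
    d0 = date.fromisoformat(config.date_start)
    d1 = date.fromisoformat(config.date_end)
    span = (d1 - d0).days + 1
    if span < 1:
        raise ConfigError("date_end precedes date_start")
    offs = rng.integers(0, span, size=n)
    return np.array([(d0 + timedelta(days=int(o))).isoformat() for o in offs])


# ------------------------------------------------------------------ operations


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Person registry: one row per person with a primary cohort label.

    A fraction ``victim_overlap_rate`` of non-victim persons additionally
    carries the persistent victim flag, so the victims cohort (selected by
    flag) overlaps the sisben/other populations.
    """
    config.validate()
    rng = _stream(config, _POP)
    n = config.n_persons
    fr = [config.cohort_fractions[c] for c in COHORTS]
    cohort = rng.choice(np.array(COHORTS), size=n, p=fr)
    sex = rng.choice(np.array(["M", "F"]), size=n)
    age = rng.integers(0, 90, size=n)
    flag = (cohort == "victim") | (rng.random(n) < config.victim_overlap_rate)
    return pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "sex": sex,
            "age": age.astype(float),
            "cohort": cohort,
            "victim_flag": flag,
        }
    )


def _assign_motifs(
    rng: np.random.Generator,
    motifs: Sequence[PlantedMotif],
    person_idx: np.ndarray,
    labels: dict[str, np.ndarray],
) -> np.ndarray:
    """Per event: index of the planted motif it is drawn from, or -1.

    Motifs claim disjoint probability mass in configuration order; the
    remainder is background.
    """
    n = person_idx.size
    u = rng.random(n)
    assignment = np.full(n, -1, dtype=int)
    cum = np.zeros(n)
    for mi, motif in enumerate(motifs):
        targeted = np.zeros(len(next(iter(labels.values()))) or 0, dtype=bool)
        for lab in motif.target_cohorts:
            targeted |= labels[lab]
        rate = motif.event_rate * targeted[person_idx]
        hit = (assignment == -1) & (u >= cum) & (u < cum + rate)
        assignment[hit] = mi
        cum += rate
    return assignment


def generate_events(registry: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Medical events with 1..max_dx distinct ICD-10 codes, primary first."""
    config.validate()
    rng = _stream(config, _EVENTS)
    k_max = config.max_dx_per_event
    dx_cols = [f"dx{i}" for i in range(1, k_max + 1)]
    empty = pd.DataFrame(columns=["event_id", "person_id", "date", "event_type"] + dx_cols)
    if len(registry) == 0:
        return empty

    name, params = config.events_per_person
    if name == "poisson":
        n_ev = rng.poisson(params["lam"], size=len(registry))
    elif name == "fixed":
        n_ev = np.full(len(registry), int(params["n"]))
    else:  # nbinom
        n_ev = rng.negative_binomial(params["n"], params["p"], size=len(registry))
    person_idx = np.repeat(np.arange(len(registry)), n_ev)
    n_total = person_idx.size
    if n_total == 0:
        return empty

    labels = _labels_matrix(registry)
    assignment = _assign_motifs(rng, config.planted_motifs, person_idx, labels)

    codes = np.full((n_total, k_max), "", dtype=object)

    # background events: Zipf-weighted draw without replacement
    bg = assignment == -1
    n_bg = int(bg.sum())
    if n_bg:
        logp = np.log(config.resolved_background_probs())
        n_dx = 1 + rng.binomial(k_max - 1, config.background_extra_dx_prob, size=n_bg)
        draw = _gumbel_topk(rng, logp, n_bg, min(k_max, logp.size))
        bg_codes = np.asarray(config.background_codes, dtype=object)[draw]
        mask = np.arange(draw.shape[1])[None, :] < n_dx[:, None]
        block = np.where(mask, bg_codes, "")
        codes[bg, : draw.shape[1]] = block

    # planted motif events: uniform draw of within_event_draw motif codes
    for mi, motif in enumerate(config.planted_motifs):
        sel = assignment == mi
        n_m = int(sel.sum())
        if n_m == 0:
            continue
        w = motif.within_event_draw
        draw = _gumbel_topk(rng, np.zeros(len(motif.codes)), n_m, w)
        codes[sel, :w] = np.asarray(motif.codes, dtype=object)[draw]

    events = pd.DataFrame(
        {
            "event_id": [f"E{i:08d}" for i in range(n_total)],
            "person_id": registry["person_id"].to_numpy()[person_idx],
            "date": _random_dates(rng, config, n_total),
            "event_type": rng.choice(np.array(EVENT_TYPES), size=n_total, p=_EVENT_TYPE_PROBS),
        }
    )
    for j, col in enumerate(dx_cols):
        events[col] = codes[:, j]

    _check_realization(config.planted_motifs, assignment, person_idx, labels, "event")
    return events


def _check_realization(
    motifs: Sequence[PlantedMotif],
    assignment: np.ndarray,
    person_idx: np.ndarray,
    labels: dict[str, np.ndarray],
    kind: str,
) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = {}
    for mi, motif in enumerate(motifs):
        counts[motif.name] = {}
        for lab in motif.target_cohorts:
            n = int((assignment == mi)[labels[lab][person_idx]].sum()) if person_idx.size else 0
            counts[motif.name][lab] = n
            if motif.event_rate > 0 and n == 0:
                raise GenerationError(
                    f"planted motif {motif.name!r} produced no {kind} in cohort {lab!r}; "
                    "increase the population, the event rate or the number of events"
                )
    return counts


def generate_mortality(registry: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """At most one death record per person; main cause first, up to 3 underlying.

    Underlying causes are rare for background deaths (as in real vital
    records, where they appear in well under 5% of certificates); planted
    mortality motifs emit their full code set so that the planted cause
    clique is realised.
    """
    config.validate()
    rng = _stream(config, _MORTALITY)
    cause_cols = [f"cause{i}" for i in range(1, 5)]
    empty = pd.DataFrame(columns=["person_id", "date"] + cause_cols)
    if len(registry) == 0 or config.mortality_rate == 0:
        return empty

    dead = rng.random(len(registry)) < config.mortality_rate
    person_idx = np.flatnonzero(dead)
    n = person_idx.size
    if n == 0:
        return empty

    labels = _labels_matrix(registry)
    assignment = _assign_motifs(rng, config.mortality_motifs, person_idx, labels)

    codes = np.full((n, 4), "", dtype=object)
    bg = assignment == -1
    n_bg = int(bg.sum())
    if n_bg:
        logp = np.log(config.resolved_background_probs())
        extra = rng.random(n_bg) < 0.05
        n_causes = np.where(extra, 2 + rng.binomial(2, 0.4, size=n_bg), 1)
        draw = _gumbel_topk(rng, logp, n_bg, min(4, logp.size))
        bg_codes = np.asarray(config.background_codes, dtype=object)[draw]
        mask = np.arange(draw.shape[1])[None, :] < n_causes[:, None]
        codes[bg, : draw.shape[1]] = np.where(mask, bg_codes, "")
    for mi, motif in enumerate(config.mortality_motifs):
        sel = assignment == mi
        n_m = int(sel.sum())
        if n_m == 0:
            continue
        w = min(motif.within_event_draw, 4)
        draw = _gumbel_topk(rng, np.zeros(len(motif.codes)), n_m, w)
        codes[sel, :w] = np.asarray(motif.codes, dtype=object)[draw]

    deaths = pd.DataFrame(
        {
            "person_id": registry["person_id"].to_numpy()[person_idx],
            "date": _random_dates(rng, config, n),
        }
    )
    for j, col in enumerate(cause_cols):
        deaths[col] = codes[:, j]

    _check_realization(config.mortality_motifs, assignment, person_idx, labels, "death record")
    return deaths


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate the three linked tables plus the truth manifest."""
    config.validate()
    persons = generate_population(config)
    events = generate_events(persons, config)
    deaths = generate_mortality(persons, config)
    truth = _build_truth(config, persons, events, deaths)
    return persons, events, deaths, truth


def _build_truth(
    config: GeneratorConfig,
    persons: pd.DataFrame,
    events: pd.DataFrame,
    deaths: pd.DataFrame,
) -> SyntheticTruth:
    labels = _labels_matrix(persons)
    pid_to_idx = {p: i for i, p in enumerate(persons["person_id"])}

    def table_counts(table: pd.DataFrame, motifs: Sequence[PlantedMotif], prefix: str) -> dict:
        cols = [c for c in table.columns if c.startswith(prefix)]
        counts: dict[str, dict[str, int]] = {}
        if len(table) == 0:
            return {m.name: {lab: 0 for lab in m.target_cohorts} for m in motifs}
        rows = table[cols].to_numpy(dtype=object)
        pidx = np.array([pid_to_idx[p] for p in table["person_id"]])
        for motif in motifs:
            codeset = set(motif.codes)
            qualifies = np.array(
                [sum(c in codeset for c in row if c) >= 2 for row in rows]
            )
            counts[motif.name] = {
                lab: int(qualifies[labels[lab][pidx]].sum()) for lab in motif.target_cohorts
            }
        return counts

    ev_counts = table_counts(events, config.planted_motifs, "dx")
    death_counts = table_counts(deaths, config.mortality_motifs, "cause")
    expected = {
        m.name: {
            lab: ev_counts[m.name][lab] * m.pair_coverage() for lab in m.target_cohorts
        }
        for m in config.planted_motifs
    }
    return SyntheticTruth(
        seed=config.seed,
        planted_motifs=[asdict(m) for m in config.planted_motifs],
        mortality_motifs=[asdict(m) for m in config.mortality_motifs],
        realized_events=ev_counts,
        realized_deaths=death_counts,
        expected_pair_weights=expected,
    )


def write_dataset(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write persons.csv, events.csv, deaths.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    persons, events, deaths, truth = generate_dataset(config)
    paths = {
        "persons": outdir / "persons.csv",
        "events": outdir / "events.csv",
        "deaths": outdir / "deaths.csv",
        "truth": outdir / "truth.json",
    }
    persons.to_csv(paths["persons"], index=False)
    events.to_csv(paths["events"], index=False)
    deaths.to_csv(paths["deaths"], index=False)
    truth.to_json(paths["truth"])
    return paths
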