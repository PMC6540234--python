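"""Read, validate and write the three record tables (persons, events, deaths).

All tables are plain pandas DataFrames with documented CSV schemas:

* ``persons.csv``  — ``person_id, sex, age, cohort, victim_flag``
* ``events.csv``   — ``event_id, person_id, date, event_type, dx1..dx4``
  (blank dx cells allowed; ``dx1`` is the primary diagnosis)
* ``deaths.csv``   — ``person_id, date, cause1..cause4``
  (``cause1`` is the main cause of death)

Diagnosis codes follow the ICD-10 alphanumeric pattern (one letter, two
digits, optional alphanumeric fourth character, e.g. ``I10X``, ``E119``,
``F412``). Codes are normalised — uppercased, dot stripped — before
validation. Rows violating an invariant are rejected with a row-numbered
reason; rejects are written to a ``<name>.rejects.csv`` sidecar.

Cohort filtering lives here so downstream network modules never see cohort
logic: the ``victim`` cohort is selected by ``victim_flag`` (the one label
that persists over time regardless of current classification), ``sisben``
and ``other`` by the primary cohort label.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]?$")

EVENT_TYPES = ("consultation", "emergency", "treatment", "follow-up")
COHORTS = ("victim", "sisben", "other")
SEXES = ("M", "F")
DATE_PATTERN = re.compile(r"^\d{4}-\d{2}-\d{2}$")

PERSON_COLUMNS = ["person_id", "sex", "age", "cohort", "victim_flag"]
EVENT_BASE_COLUMNS = ["event_id", "person_id", "date", "event_type"]
DEATH_BASE_COLUMNS = ["person_id", "date"]

DEFAULT_MAX_REJECT_FRACTION = 0.05


class SchemaError(ValueError):
    """A required column is missing or the file cannot be read as CSV."""


class TooManyRejectsError(ValueError):
    """More than ``max_reject_fraction`` of rows failed validation."""


def normalize_code(code: object) -> str:
    """Uppercase and strip dots/whitespace from an ICD-10 code."""
    return str(code).strip().upper().replace(".", "")


def validate_icd10(code: object) -> bool:
    """True iff *code*, after normalisation, matches the ICD-10 pattern.

    Pure predicate: never raises.
    """
    if code is None or (isinstance(code, float) and pd.isna(code)):
        return False
    return bool(ICD10_PATTERN.match(normalize_code(code)))


def _is_blank(value: object) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == ""


def _code_columns(df: pd.DataFrame, prefix: str) -> list[str]:
    cols = [c for c in df.columns if re.fullmatch(rf"{prefix}\d+", c)]
    return sorted(cols, key=lambda c: int(c[len(prefix):]))


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _finish(
    accepted: list[dict],
    rejects: list[dict],
    n_rows: int,
    path: str | Path | None,
    columns: list[str],
    max_reject_fraction: float,
    kind: str,
) -> pd.DataFrame:
    logger.info("%s: accepted %d rows, rejected %d of %d", kind, len(accepted), len(rejects), n_rows)
    if rejects and path is not None:
        sidecar = Path(str(path) + ".rejects.csv")
        pd.DataFrame(rejects).to_csv(sidecar, index=False)
        logger.info("%s: rejects written to %s", kind, sidecar)
    if n_rows > 0 and len(rejects) / n_rows > max_reject_fraction:
        raise TooManyRejectsError(
            f"{kind}: {len(rejects)}/{n_rows} rows rejected "
            f"(> max_reject_fraction={max_reject_fraction})"
        )
    return pd.DataFrame(accepted, columns=columns)


def validate_persons(
    df: pd.DataFrame,
    path: str | Path | None = None,
    max_reject_fraction: float = DEFAULT_MAX_REJECT_FRACTION,
) -> pd.DataFrame:
    _require_columns(df, PERSON_COLUMNS, path or "<frame>")
    accepted: list[dict] = []
    rejects: list[dict] = []
    for row_no, row in enumerate(df.itertuples(index=False)):
        reason = None
        sex = str(row.sex).strip().upper()
        cohort = str(row.cohort).strip().lower()
        flag = str(row.victim_flag).strip().lower() in ("true", "1", "t", "yes")
        try:
            age = float(row.age)
        except (TypeError, ValueError):
            age = float("nan")
        if _is_blank(row.person_id):
            reason = "missing person_id"
        elif sex not in SEXES:
            reason = f"invalid sex {row.sex!r}"
        elif not age >= 0:
            reason = f"invalid age {row.age!r}"
        elif cohort not in COHORTS:
            reason = f"invalid cohort {row.cohort!r}"
        elif cohort == "victim" and not flag:
            reason = "cohort=victim requires victim_flag"
        if reason is None:
            accepted.append(
                {"person_id": str(row.person_id), "sex": sex, "age": age,
                 "cohort": cohort, "victim_flag": flag}
            )
        else:
            rejects.append({"row": row_no, "reason": reason})
    return _finish(accepted, rejects, len(df), path, PERSON_COLUMNS, max_reject_fraction, "persons")


def validate_events(
    df: pd.DataFrame,
    k_max: int = 4,
    path: str | Path | None = None,
    max_reject_fraction: float = DEFAULT_MAX_REJECT_FRACTION,
) -> pd.DataFrame:
    """Validate an event table: 1..k_max distinct valid codes per event.

    Repeated codes within an event are deduplicated (first occurrence kept)
    rather than rejected: claims data contain repeats, and co-occurrence
    counting cares about distinct pairs, not multiplicity.
    """
    _require_columns(df, EVENT_BASE_COLUMNS + ["dx1"], path or "<frame>")
    dx_cols = _code_columns(df, "dx")
    out_cols = EVENT_BASE_COLUMNS + [f"dx{i}" for i in range(1, k_max + 1)]
    accepted: list[dict] = []
    rejects: list[dict] = []
    for row_no, row in enumerate(df.itertuples(index=False)):
        rowd = row._asdict()
        reason = None
        etype = str(rowd["event_type"]).strip().lower()
        codes: list[str] = []
        for c in dx_cols:
            v = rowd.get(c)
            if _is_blank(v):
                continue
            code = normalize_code(v)
            if not validate_icd10(code):
                reason = f"invalid code {v!r} in {c}"
                break
            if code not in codes:  # dedupe, keep first
                codes.append(code)
        if reason is None:
            if _is_blank(rowd["event_id"]) or _is_blank(rowd["person_id"]):
                reason = "missing event_id or person_id"
            elif not DATE_PATTERN.match(str(rowd["date"]).strip()):
                reason = f"invalid date {rowd['date']!r}"
            elif etype not in EVENT_TYPES:
                reason = f"invalid event_type {rowd['event_type']!r}"
            elif not codes:
                reason = "no diagnoses"
            elif len(codes) > k_max:
                reason = f"too many diagnoses ({len(codes)} > k_max={k_max})"
        if reason is None:
            rec = {
                "event_id": str(rowd["event_id"]),
                "person_id": str(rowd["person_id"]),
                "date": str(rowd["date"]).strip(),
                "event_type": etype,
            }
            for i in range(1, k_max + 1):
                rec[f"dx{i}"] = codes[i - 1] if i <= len(codes) else ""
            accepted.append(rec)
        else:
            rejects.append({"row": row_no, "reason": reason})
    return _finish(accepted, rejects, len(df), path, out_cols, max_reject_fraction, "events")


def validate_mortality(
    df: pd.DataFrame,
    path: str | Path | None = None,
    max_reject_fraction: float = DEFAULT_MAX_REJECT_FRACTION,
) -> pd.DataFrame:
    _require_columns(df, DEATH_BASE_COLUMNS + ["cause1"], path or "<frame>")
    cause_cols = _code_columns(df, "cause")
    out_cols = DEATH_BASE_COLUMNS + [f"cause{i}" for i in range(1, 5)]
    accepted: list[dict] = []
    rejects: list[dict] = []
    seen: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False)):
        rowd = row._asdict()
        reason = None
        codes: list[str] = []
        for c in cause_cols:
            v = rowd.get(c)
            if _is_blank(v):
                continue
            code = normalize_code(v)
            if not validate_icd10(code):
                reason = f"invalid code {v!r} in {c}"
                break
            if code not in codes:
                codes.append(code)
        if reason is None:
            pid = str(rowd["person_id"])
            if _is_blank(rowd["person_id"]):
                reason = "missing person_id"
            elif pid in seen:
                reason = "duplicate death record for person"
            elif not DATE_PATTERN.match(str(rowd["date"]).strip()):
                reason = f"invalid date {rowd['date']!r}"
            elif not codes:
                reason = "no causes"
            elif len(codes) > 4:
                reason = f"too many causes ({len(codes)})"
        if reason is None:
            seen.add(pid)
            rec = {"person_id": pid, "date": str(rowd["date"]).strip()}
            for i in range(1, 5):
                rec[f"cause{i}"] = codes[i - 1] if i <= len(codes) else ""
            accepted.append(rec)
        else:
            rejects.append({"row": row_no, "reason": reason})
    return _finish(accepted, rejects, len(df), path, out_cols, max_reject_fraction, "deaths")


# ---------------------------------------------------------------- I/O


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_persons(path: str | Path, max_reject_fraction: float = DEFAULT_MAX_REJECT_FRACTION) -> pd.DataFrame:
    return validate_persons(_read_csv(path), path=path, max_reject_fraction=max_reject_fraction)


def read_events(path: str | Path, k_max: int = 4,
                max_reject_fraction: float = DEFAULT_MAX_REJECT_FRACTION) -> pd.DataFrame:
    return validate_events(_read_csv(path), k_max=k_max, path=path,
                           max_reject_fraction=max_reject_fraction)


def read_mortality(path: str | Path, max_reject_fraction: float = DEFAULT_MAX_REJECT_FRACTION) -> pd.DataFrame:
    return validate_mortality(_read_csv(path), path=path, max_reject_fraction=max_reject_fraction)


def write_persons(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_mortality(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------- helpers


def event_code_lists(events: pd.DataFrame) -> list[list[str]]:
    """Ordered distinct diagnosis codes per event row (primary first)."""
    dx_cols = _code_columns(events, "dx")
    out = []
    for row in events[dx_cols].itertuples(index=False):
        out.append([c for c in row if not _is_blank(c)])
    return out


def death_code_lists(deaths: pd.DataFrame) -> list[list[str]]:
    """Ordered distinct cause codes per death record (main cause first)."""
    cause_cols = _code_columns(deaths, "cause")
    out = []
    for row in deaths[cause_cols].itertuples(index=False):
        out.append([c for c in row if not _is_blank(c)])
    return out


def cohort_person_ids(persons: pd.DataFrame, cohort: str) -> set[str]:
    """Person ids belonging to the analysis cohort *cohort*.

    The victim flag is the one label that persists over time and takes
    precedence: ``victim`` selects every flagged person regardless of their
    current classification, while ``sisben`` and ``other`` select by the
    primary cohort column *excluding* flagged persons. The three analysis
    cohorts therefore partition the registry, and the non-victim cohorts
    are clean controls.
    """
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")
    flagged = persons["victim_flag"].astype(bool)
    if cohort == "victim":
        mask = flagged
    else:
        mask = (persons["cohort"] == cohort) & ~flagged
    return set(persons.loc[mask, "person_id"])


def filter_by_persons(table: pd.DataFrame, person_ids: set[str]) -> pd.DataFrame:
    """Rows of an event/death table whose person_id is in *person_ids*."""
    return table[table["person_id"].isin(person_ids)].reset_index(drop=True)
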