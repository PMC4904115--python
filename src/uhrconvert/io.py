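"""Tabular input/output: cohort CSV schema, contingency-table CSV and
report writing.

The cohort file is a UTF-8 comma-separated table with a header row and
one row per subject. Booleans are encoded ``1``/``0``; an empty cell
means unknown (numeric or boolean). Column order is irrelevant; unknown
columns are warned about and ignored; rows violating a rating-scale
invariant are excluded with a row-numbered warning and parsing
continues.
"""

from __future__ import annotations

import csv
import io as _io
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .agreement import ContingencyTable
from .instruments import (
    CAARMS_SUBSCALES,
    SIPS_SUBSCALES,
    CAARMSRatings,
    ClinicalCourse,
    FunctioningHistory,
    SIPSRatings,
    SubjectRecord,
    TraitRisk,
    validate_record,
)

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "read_contingency_csv",
    "write_contingency_csv",
    "write_report",
    "write_linking_tables",
]

_CAARMS_COLS = [
    f"caarms_p{i}_{part}" for i in range(1, 5) for part in ("severity", "frequency", "substance")
]
_SIPS_COLS = [
    f"sips_p{i}_{part}"
    for i in range(1, 6)
    for part in ("severity", "frequency", "substance_intertwined")
]
_FUNCTIONING_COLS = [
    "sofas_current",
    "sofas_premorbid",
    "sofas_drop_sustained_1m_12m",
    "sofas_below_50_12m",
    "gaf_current_month",
    "gaf_12_months_ago",
]
_TRAIT_COLS = ["schizotypal_pd", "family_history_psychosis"]
_COURSE_COLS = [
    "onset_months_ago",
    "symptoms_gt_5y",
    "severity_increased_past_year",
    "present_past_month",
    "psychotic_duration_days",
    "psychotic_onset_months_ago",
    "resolved_without_antipsychotics",
    "danger_or_disorganization",
    "substance_peak_only",
    "comorbid_better_explains",
    "prior_psychotic_episode",
]
COHORT_COLUMNS = (
    ["subject_id"] + _CAARMS_COLS + _SIPS_COLS + _FUNCTIONING_COLS + _TRAIT_COLS + _COURSE_COLS
)


def _cell_int(row: dict, col: str) -> Optional[int]:
    v = row.get(col, "")
    v = "" if v is None else str(v).strip()
    if v == "":
        return None
    if "," in v:
        raise ValueError(f"{col}: locale-dependent decimal comma in {v!r}")
    return int(float(v))


def _cell_float(row: dict, col: str) -> Optional[float]:
    v = row.get(col, "")
    v = "" if v is None else str(v).strip()
    if v == "":
        return None
    if "," in v:
        raise ValueError(f"{col}: locale-dependent decimal comma in {v!r}")
    return float(v)


def _cell_bool(row: dict, col: str) -> Optional[bool]:
    v = row.get(col, "")
    v = "" if v is None else str(v).strip()
    if v == "":
        return None
    if v in ("1", "1.0", "true", "True"):
        return True
    if v in ("0", "0.0", "false", "False"):
        return False
    raise ValueError(f"{col}: boolean cell must be 0/1/empty, got {v!r}")


def _parse_row(row: dict) -> SubjectRecord:
    sid = str(row.get("subject_id", "")).strip()
    if not sid:
        raise ValueError("subject_id: missing")

    caarms = None
    if any(_cell_int(row, c) is not None for c in _CAARMS_COLS):
        caarms = CAARMSRatings(
            severity={
                s: _cell_int(row, f"caarms_{s.lower()}_severity") or 0 for s in CAARMS_SUBSCALES
            },
            frequency={
                s: _cell_int(row, f"caarms_{s.lower()}_frequency") or 0 for s in CAARMS_SUBSCALES
            },
            substance={
                s: _cell_int(row, f"caarms_{s.lower()}_substance") or 0 for s in CAARMS_SUBSCALES
            },
        )
    sips = None
    if any(
        _cell_int(row, c) is not None
        for c in _SIPS_COLS
        if not c.endswith("substance_intertwined")
    ) or any(
        _cell_bool(row, f"sips_{s.lower()}_substance_intertwined") is not None
        for s in SIPS_SUBSCALES
    ):
        sips = SIPSRatings(
            severity={s: _cell_int(row, f"sips_{s.lower()}_severity") or 0 for s in SIPS_SUBSCALES},
            frequency={
                s: _cell_int(row, f"sips_{s.lower()}_frequency") or 0 for s in SIPS_SUBSCALES
            },
            substance_intertwined={
                s: bool(_cell_bool(row, f"sips_{s.lower()}_substance_intertwined"))
                for s in SIPS_SUBSCALES
            },
        )
    functioning = FunctioningHistory(
        sofas_current=_cell_int(row, "sofas_current"),
        sofas_premorbid=_cell_int(row, "sofas_premorbid"),
        sofas_drop_sustained_one_month_within_12m=_cell_bool(row, "sofas_drop_sustained_1m_12m"),
        sofas_below_50_past_12m=_cell_bool(row, "sofas_below_50_12m"),
        gaf_current_month=_cell_int(row, "gaf_current_month"),
        gaf_12_months_ago=_cell_int(row, "gaf_12_months_ago"),
    )
    trait = TraitRisk(
        schizotypal_personality_disorder=_cell_bool(row, "schizotypal_pd"),
        first_degree_relative_psychosis=_cell_bool(row, "family_history_psychosis"),
    )
    course = ClinicalCourse(
        onset_months_ago=_cell_float(row, "onset_months_ago"),
        symptoms_present_longer_than_5y=_cell_bool(row, "symptoms_gt_5y"),
        severity_increased_past_year=_cell_bool(row, "severity_increased_past_year"),
        symptoms_present_past_month=_cell_bool(row, "present_past_month"),
        psychotic_intensity_duration_days=_cell_float(row, "psychotic_duration_days"),
        psychotic_onset_months_ago=_cell_float(row, "psychotic_onset_months_ago"),
        resolved_without_antipsychotics=_cell_bool(row, "resolved_without_antipsychotics"),
        danger_or_disorganization=_cell_bool(row, "danger_or_disorganization"),
        substance_only_at_peak_intoxication=_cell_bool(row, "substance_peak_only"),
        comorbid_disorder_better_explains=_cell_bool(row, "comorbid_better_explains"),
        prior_psychotic_episode=_cell_bool(row, "prior_psychotic_episode"),
    )
    return SubjectRecord(
        subject_id=sid, caarms=caarms, sips=sips, course=course, functioning=functioning, trait=trait
    )


def read_cohort(path) -> Tuple[List[SubjectRecord], List[str]]:
    """Parse a cohort CSV. Returns ``(records, warnings)``.

    Unknown columns produce a warning and are ignored; a row whose cells
    violate a scale invariant is excluded with a warning naming the row.
    A missing ``subject_id`` header is fatal.
    """
    warnings: List[str] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if "subject_id" not in header:
            raise ValueError("missing required column: subject_id")
        known = set(COHORT_COLUMNS)
        for col in header:
            if col not in known:
                warnings.append(f"unknown column ignored: {col}")
        records: List[SubjectRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = _parse_row(row)
            except ValueError as exc:
                warnings.append(f"row {lineno} excluded: {exc}")
                continue
            violations = validate_record(rec)
            if violations:
                warnings.append(f"row {lineno} excluded: " + "; ".join(violations))
                continue
            records.append(rec)
    return records, warnings


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float) and float(v).is_integer():
        return str(int(v))
    return str(v)


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Render records in the cohort schema (empty string = unknown)."""
    rows = []
    for r in records:
        row: Dict[str, str] = {c: "" for c in COHORT_COLUMNS}
        row["subject_id"] = r.subject_id
        if r.caarms is not None:
            for s in CAARMS_SUBSCALES:
                row[f"caarms_{s.lower()}_severity"] = _fmt(r.caarms.severity[s])
                row[f"caarms_{s.lower()}_frequency"] = _fmt(r.caarms.frequency[s])
                row[f"caarms_{s.lower()}_substance"] = _fmt(r.caarms.substance[s])
        if r.sips is not None:
            for s in SIPS_SUBSCALES:
                row[f"sips_{s.lower()}_severity"] = _fmt(r.sips.severity[s])
                row[f"sips_{s.lower()}_frequency"] = _fmt(r.sips.frequency[s])
                row[f"sips_{s.lower()}_substance_intertwined"] = _fmt(
                    r.sips.substance_intertwined[s]
                )
        f, c, t = r.functioning, r.course, r.trait
        row.update(
            sofas_current=_fmt(f.sofas_current),
            sofas_premorbid=_fmt(f.sofas_premorbid),
            sofas_drop_sustained_1m_12m=_fmt(f.sofas_drop_sustained_one_month_within_12m),
            sofas_below_50_12m=_fmt(f.sofas_below_50_past_12m),
            gaf_current_month=_fmt(f.gaf_current_month),
            gaf_12_months_ago=_fmt(f.gaf_12_months_ago),
            schizotypal_pd=_fmt(t.schizotypal_personality_disorder),
            family_history_psychosis=_fmt(t.first_degree_relative_psychosis),
            onset_months_ago=_fmt(c.onset_months_ago),
            symptoms_gt_5y=_fmt(c.symptoms_present_longer_than_5y),
            severity_increased_past_year=_fmt(c.severity_increased_past_year),
            present_past_month=_fmt(c.symptoms_present_past_month),
            psychotic_duration_days=_fmt(c.psychotic_intensity_duration_days),
            psychotic_onset_months_ago=_fmt(c.psychotic_onset_months_ago),
            resolved_without_antipsychotics=_fmt(c.resolved_without_antipsychotics),
            danger_or_disorganization=_fmt(c.danger_or_disorganization),
            substance_peak_only=_fmt(c.substance_only_at_peak_intoxication),
            comorbid_better_explains=_fmt(c.comorbid_disorder_better_explains),
            prior_psychotic_episode=_fmt(c.prior_psychotic_episode),
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(records: Sequence[SubjectRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_contingency_csv(path) -> ContingencyTable:
    """Read a (k+1)x(k+1) labelled square contingency-table CSV."""
    df = pd.read_csv(path, index_col=0)
    labels = tuple(str(x) for x in df.columns)
    if tuple(str(x) for x in df.index) != labels:
        raise ValueError("row and column labels must be identical and in the same order")
    return ContingencyTable(labels, df.to_numpy(dtype=float))


def write_contingency_csv(table: ContingencyTable, path) -> None:
    pd.DataFrame(table.counts, index=table.labels, columns=table.labels).to_csv(path)


def write_report(results: pd.DataFrame, path, stats_text: str = "") -> None:
    """Write per-subject results to ``path`` (CSV) and, if given,
    cohort-level statistics to a ``.txt`` sidecar of the same stem."""
    if results is None or len(results) == 0:
        raise ValueError("no results to write")
    results.to_csv(path, index=False)
    if stats_text:
        sidecar = str(path)
        sidecar = sidecar[: -len(".csv")] + ".txt" if sidecar.endswith(".csv") else sidecar + ".txt"
        with open(sidecar, "w", encoding="utf-8") as fh:
            fh.write(stats_text.rstrip() + "\n")


def write_linking_tables(tables: Dict[str, "LinkingTable"], path) -> None:
    """Write a set of linking tables as long-format CSV
    (domain, source_score, linked_score)."""
    buf = _io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["domain", "source_score", "linked_score"])
    for name in tables:
        for s, e in tables[name].pairs:
            writer.writerow([name, s, f"{e:.3f}"])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
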