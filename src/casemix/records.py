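"""Hospitalization-level record model and delimited-text interchange.

The unit of analysis is a hospitalization (one admission), not a patient: the
same patient may appear several times.  A record carries demographics, the
admission/discharge timestamps, the list of ICD-9-CM diagnosis codes recorded
during that admission, the ward-stay intervals (with ward class), and the
treatment events relevant to the escalation-of-care outcome (mechanical
ventilation, BiPAP, vasopressor administrations).

Interchange is three rectangular CSV tables mirroring a typical EMR extract:

* ``hospitalizations.csv`` — one row per admission; diagnosis codes serialized
  as a semicolon-separated sub-field.
* ``ward_stays.csv`` — long format, keyed by ``hospitalization_id``.
* ``treatment_events.csv`` — long format, keyed by ``hospitalization_id``.

Timestamps are ISO-8601; booleans are ``true``/``false``.  Age is carried
directly in years rather than as a birth date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "WARD_CLASSES",
    "EVENT_KINDS",
    "SEXES",
    "ADMISSION_SOURCES",
    "WardStay",
    "TreatmentEvent",
    "Hospitalization",
    "RowError",
    "IngestResult",
    "ValidationReport",
    "read_hospitalizations",
    "write_hospitalizations",
    "validate_dataset",
    "record_violations",
]

WARD_CLASSES = ("im_ward", "icu", "imcu", "short_stay", "cardiology", "geriatrics", "other")
EVENT_KINDS = ("mechanical_ventilation", "bipap", "vasopressor")
SEXES = ("male", "female")
ADMISSION_SOURCES = ("emergency", "elective", "internal_transfer")

HOSP_COLUMNS = [
    "hospitalization_id", "patient_id", "admit", "discharge", "age_years",
    "sex", "admission_source", "died_in_hospital", "diagnosis_codes", "drg",
]
WARD_COLUMNS = ["hospitalization_id", "ward_class", "start", "end"]
EVENT_COLUMNS = ["hospitalization_id", "kind", "timestamp", "drug_name"]


@dataclass(frozen=True)
class WardStay:
    ward_class: str
    start: pd.Timestamp
    end: pd.Timestamp


@dataclass(frozen=True)
class TreatmentEvent:
    kind: str
    timestamp: pd.Timestamp
    drug_name: Optional[str] = None


@dataclass
class Hospitalization:
    hospitalization_id: str
    patient_id: str
    admit: pd.Timestamp
    discharge: pd.Timestamp
    age_years: float
    sex: str
    admission_source: str
    died_in_hospital: bool
    diagnosis_codes: tuple[str, ...] = ()
    ward_stays: tuple[WardStay, ...] = ()
    treatment_events: tuple[TreatmentEvent, ...] = ()
    drg: Optional[int] = None


def record_violations(rec: Hospitalization) -> list[str]:
    """Invariant violations for one record (empty list when valid)."""
    out: list[str] = []
    if rec.discharge < rec.admit:
        out.append("discharge precedes admit")
    if rec.age_years < 0:
        out.append("negative age")
    if rec.sex not in SEXES:
        out.append(f"unknown sex {rec.sex!r}")
    if rec.admission_source not in ADMISSION_SOURCES:
        out.append(f"unknown admission_source {rec.admission_source!r}")
    for ws in rec.ward_stays:
        if ws.ward_class not in WARD_CLASSES:
            out.append(f"unknown ward_class {ws.ward_class!r}")
        if ws.end < ws.start:
            out.append("ward stay ends before it starts")
        if ws.start < rec.admit or ws.end > rec.discharge:
            out.append("ward stay outside admission interval")
    for ev in rec.treatment_events:
        if ev.kind not in EVENT_KINDS:
            out.append(f"unknown event kind {ev.kind!r}")
        if not rec.admit <= ev.timestamp <= rec.discharge:
            out.append("treatment event outside admission interval")
        if (ev.kind == "vasopressor") != (ev.drug_name is not None):
            out.append("drug_name must be present exactly for vasopressor events")
    return out


@dataclass(frozen=True)
class RowError:
    table: str
    line: int  # 1-based physical line number, header = line 1
    message: str


@dataclass
class IngestResult:
    records: list[Hospitalization]
    errors: list[RowError] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len({(e.table, e.line) for e in self.errors})


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1"):
        return True
    if v in ("false", "0"):
        return False
    raise ValueError(f"boolean field must be true/false, got {value!r}")


def _parse_ts(value: str) -> pd.Timestamp:
    ts = pd.Timestamp(value)
    if pd.isna(ts):
        raise ValueError("missing timestamp")
    return ts


def _read_table(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    return frame


def read_hospitalizations(directory: str | Path) -> IngestResult:
    """Read a dataset directory into :class:`Hospitalization` records.

    ``hospitalizations.csv`` is required; ``ward_stays.csv`` and
    ``treatment_events.csv`` are optional companions.  A missing required
    column is a hard error; an unparseable or invariant-violating row is
    rejected and reported with its line number, and parsing continues.
    """
    directory = Path(directory)
    hosp = _read_table(directory / "hospitalizations.csv", HOSP_COLUMNS)
    errors: list[RowError] = []

    stays: dict[str, list[WardStay]] = {}
    events: dict[str, list[TreatmentEvent]] = {}
    ward_path = directory / "ward_stays.csv"
    if ward_path.exists():
        for i, row in enumerate(_read_table(ward_path, WARD_COLUMNS).itertuples(index=False)):
            try:
                stays.setdefault(row.hospitalization_id, []).append(
                    WardStay(row.ward_class, _parse_ts(row.start), _parse_ts(row.end))
                )
            except (ValueError, TypeError) as exc:
                errors.append(RowError("ward_stays.csv", i + 2, str(exc)))
    event_path = directory / "treatment_events.csv"
    if event_path.exists():
        for i, row in enumerate(_read_table(event_path, EVENT_COLUMNS).itertuples(index=False)):
            try:
                drug = row.drug_name.strip().lower() or None
                events.setdefault(row.hospitalization_id, []).append(
                    TreatmentEvent(row.kind, _parse_ts(row.timestamp), drug)
                )
            except (ValueError, TypeError) as exc:
                errors.append(RowError("treatment_events.csv", i + 2, str(exc)))

    records: list[Hospitalization] = []
    for i, row in enumerate(hosp.itertuples(index=False)):
        line = i + 2
        try:
            codes = tuple(c.strip() for c in row.diagnosis_codes.split(";") if c.strip())
            rec = Hospitalization(
                hospitalization_id=row.hospitalization_id,
                patient_id=row.patient_id,
                admit=_parse_ts(row.admit),
                discharge=_parse_ts(row.discharge),
                age_years=float(row.age_years),
                sex=row.sex,
                admission_source=row.admission_source,
                died_in_hospital=_parse_bool(row.died_in_hospital),
                diagnosis_codes=codes,
                ward_stays=tuple(stays.get(row.hospitalization_id, ())),
                treatment_events=tuple(events.get(row.hospitalization_id, ())),
                drg=int(row.drg) if row.drg.strip() else None,
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError("hospitalizations.csv", line, str(exc)))
            continue
        violations = record_violations(rec)
        if violations:
            errors.append(RowError("hospitalizations.csv", line, "; ".join(violations)))
            continue
        records.append(rec)
    return IngestResult(records, errors)


def _iso(ts: pd.Timestamp) -> str:
    return pd.Timestamp(ts).isoformat()


def write_hospitalizations(records: Sequence[Hospitalization], directory: str | Path) -> None:
    """Write records as the three interchange CSVs (deterministic formatting)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hosp_rows, ward_rows, event_rows = [], [], []
    for r in records:
        hosp_rows.append({
            "hospitalization_id": r.hospitalization_id,
            "patient_id": r.patient_id,
            "admit": _iso(r.admit),
            "discharge": _iso(r.discharge),
            "age_years": repr(float(r.age_years)),
            "sex": r.sex,
            "admission_source": r.admission_source,
            "died_in_hospital": "true" if r.died_in_hospital else "false",
            "diagnosis_codes": ";".join(r.diagnosis_codes),
            "drg": "" if r.drg is None else str(r.drg),
        })
        for ws in r.ward_stays:
            ward_rows.append({
                "hospitalization_id": r.hospitalization_id,
                "ward_class": ws.ward_class,
                "start": _iso(ws.start),
                "end": _iso(ws.end),
            })
        for ev in r.treatment_events:
            event_rows.append({
                "hospitalization_id": r.hospitalization_id,
                "kind": ev.kind,
                "timestamp": _iso(ev.timestamp),
                "drug_name": ev.drug_name or "",
            })
    pd.DataFrame(hosp_rows, columns=HOSP_COLUMNS).to_csv(
        directory / "hospitalizations.csv", index=False)
    pd.DataFrame(ward_rows, columns=WARD_COLUMNS).to_csv(
        directory / "ward_stays.csv", index=False)
    pd.DataFrame(event_rows, columns=EVENT_COLUMNS).to_csv(
        directory / "treatment_events.csv", index=False)


@dataclass
class ValidationReport:
    n_records: int
    duplicate_ids: int
    duplicated_id_values: tuple[str, ...]
    violations: list[tuple[str, str]]  # (hospitalization_id, message)
    missing_drg: int
    empty_code_lists: int

    @property
    def n_violations(self) -> int:
        return len(self.violations) + self.duplicate_ids


def validate_dataset(records: Sequence[Hospitalization]) -> ValidationReport:
    """Report-only dataset validation: duplicates, invariants, missingness."""
    seen: dict[str, int] = {}
    for r in records:
        seen[r.hospitalization_id] = seen.get(r.hospitalization_id, 0) + 1
    dupes = {k: v for k, v in seen.items() if v > 1}
    violations: list[tuple[str, str]] = []
    for r in records:
        for msg in record_violations(r):
            violations.append((r.hospitalization_id, msg))
    return ValidationReport(
        n_records=len(records),
        duplicate_ids=sum(v - 1 for v in dupes.values()),
        duplicated_id_values=tuple(sorted(dupes)),
        violations=violations,
        missing_drg=sum(1 for r in records if r.drg is None),
        empty_code_lists=sum(1 for r in records if not r.diagnosis_codes),
    )


def records_frame(records: Sequence[Hospitalization]) -> pd.DataFrame:
    """Flat per-hospitalization frame (codes as tuples) for bulk operations."""
    return pd.DataFrame(
        {
            "hospitalization_id": [r.hospitalization_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "admit": [r.admit for r in records],
            "discharge": [r.discharge for r in records],
            "died_in_hospital": [r.died_in_hospital for r in records],
        }
    )
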