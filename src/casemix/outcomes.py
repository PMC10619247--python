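"""Construction of the four dependent variables per hospitalization.

* **In-hospital mortality** — the record's death flag.
* **Escalation of care** — a composite: any ICU stay, any intermediate-care
  (IMCU) stay, mechanical ventilation, *daytime* BiPAP, or receipt of a named
  vasopressor.  Daytime is 08:00-20:00 (half-open); night-time BiPAP is
  excluded because it may treat sleep-disordered breathing rather than
  impending respiratory failure.  A hospitalization can show both escalation
  and death.
* **30-day readmission** — another admission of the same patient whose admit
  is strictly after this discharge, with a calendar-date gap of at most 30
  days (inclusive boundary; same-facility only, no censoring correction).
* **Length of stay** — discharge minus admit in fractional days, modeled on
  the natural-log scale to correct right skew.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .records import Hospitalization

__all__ = [
    "DEFAULT_VASOPRESSORS",
    "OutcomeSet",
    "EscalationConfig",
    "compute_los",
    "log_transform_los",
    "escalation_of_care",
    "readmissions_30d",
    "build_outcomes",
    "outcomes_frame",
]

#: Drugs that count as vasopressors for the escalation outcome.
DEFAULT_VASOPRESSORS = frozenset(
    {"adrenaline", "dobutamine", "dopamine", "milrinone",
     "noradrenaline", "phenylephrine", "vasopressin"}
)

_DAY = pd.Timedelta(days=1)


@dataclass(frozen=True)
class OutcomeSet:
    died: bool
    escalation: bool
    readmit_30d: bool
    los_days: float
    log_los: float


@dataclass(frozen=True)
class EscalationConfig:
    """Tunable definition of the escalation-of-care composite."""

    include_imcu: bool = True
    daytime_start_hour: int = 8
    daytime_end_hour: int = 20
    vasopressor_names: frozenset[str] = DEFAULT_VASOPRESSORS

    def __post_init__(self) -> None:
        if not 0 <= self.daytime_start_hour < self.daytime_end_hour <= 24:
            raise ValueError("need 0 <= daytime_start < daytime_end <= 24")
        if not self.vasopressor_names:
            raise ValueError("vasopressor name set must be non-empty")


def compute_los(hosp: Hospitalization) -> float:
    """Length of stay in fractional days; zero-length stays are rejected."""
    delta = (hosp.discharge - hosp.admit) / _DAY
    if delta <= 0:
        raise ValueError(
            f"{hosp.hospitalization_id}: non-positive length of stay "
            "(undefined under the log transform)"
        )
    return float(delta)


def log_transform_los(los: float) -> float:
    if los <= 0:
        raise ValueError("length of stay must be positive for the log transform")
    return math.log(los)


def escalation_of_care(hosp: Hospitalization, cfg: EscalationConfig = EscalationConfig()) -> bool:
    """Composite escalation flag from ward stays and treatment events.

    Monotone in the event list: adding stays or events can only switch the
    flag from False to True.
    """
    for ws in hosp.ward_stays:
        if ws.ward_class == "icu":
            return True
        if cfg.include_imcu and ws.ward_class == "imcu":
            return True
    for ev in hosp.treatment_events:
        if ev.kind == "mechanical_ventilation":
            return True
        if ev.kind == "bipap":
            if cfg.daytime_start_hour <= ev.timestamp.hour < cfg.daytime_end_hour:
                return True
        elif ev.kind == "vasopressor":
            drug = (ev.drug_name or "").strip().lower()
            if drug in cfg.vasopressor_names:
                return True
    return False


def readmissions_30d(
    records: Sequence[Hospitalization], window_days: int = 30
) -> dict[str, bool]:
    """Flag hospitalizations followed by a readmission within the window.

    For each hospitalization, true iff the same patient has another admission
    strictly after this discharge with a calendar-date gap of at most
    ``window_days`` (inclusive).  Order of the input list is irrelevant;
    overlapping admissions for one patient are processed in admit order with a
    warning.
    """
    if not records:
        return {}
    frame = pd.DataFrame(
        {
            "id": [r.hospitalization_id for r in records],
            "patient": [r.patient_id for r in records],
            "admit": [r.admit for r in records],
            "discharge": [r.discharge for r in records],
        }
    ).sort_values(["patient", "admit"], kind="mergesort")

    grp = frame.groupby("patient", sort=False)
    next_admit = grp["admit"].shift(-1)
    overlap = (next_admit.notna()) & (next_admit < frame["discharge"])
    if overlap.any():
        warnings.warn(
            f"{int(overlap.sum())} overlapping admission(s) for the same patient; "
            "processed in admit order",
            stacklevel=2,
        )
    gap_days = (next_admit.dt.normalize() - frame["discharge"].dt.normalize()) / _DAY
    flag = (next_admit > frame["discharge"]) & (gap_days <= window_days)
    return dict(zip(frame["id"], flag.fillna(False).astype(bool)))


def build_outcomes(
    records: Sequence[Hospitalization],
    cfg: EscalationConfig = EscalationConfig(),
    window_days: int = 30,
) -> dict[str, OutcomeSet]:
    """All four outcomes for every record, keyed by hospitalization id."""
    readmit = readmissions_30d(records, window_days=window_days)
    out: dict[str, OutcomeSet] = {}
    for r in records:
        los = compute_los(r)
        out[r.hospitalization_id] = OutcomeSet(
            died=bool(r.died_in_hospital),
            escalation=escalation_of_care(r, cfg),
            readmit_30d=readmit[r.hospitalization_id],
            los_days=los,
            log_los=log_transform_los(los),
        )
    return out


def outcomes_frame(outcome_map: Mapping[str, OutcomeSet]) -> pd.DataFrame:
    """Tabular view (index = hospitalization_id) of an outcome map."""
    idx = list(outcome_map)
    return pd.DataFrame(
        {
            "died": [outcome_map[i].died for i in idx],
            "escalation": [outcome_map[i].escalation for i in idx],
            "readmit_30d": [outcome_map[i].readmit_30d for i in idx],
            "los_days": [outcome_map[i].los_days for i in idx],
            "log_los": [outcome_map[i].log_los for i in idx],
        },
        index=pd.Index(idx, name="hospitalization_id"),
    )
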