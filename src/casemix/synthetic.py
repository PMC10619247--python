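"""Synthetic internal-medicine hospitalization generator with ground truth.

Emits raw records — diagnosis codes, ward stays, treatment events, readmission
chains — whose statistical structure matches the cohort the risk-adjustment
analysis assumes, together with the true comorbidity flags and outcome labels,
so every pipeline stage can be tested end-to-end without real hospital data.

Generative model
----------------
* Comorbidity flags are independent Bernoulli draws at configurable
  prevalences (defaults: the source cohort's observed prevalences), except
  that complicated diabetes is sampled as a sub-split of "any diabetes" and
  metastatic cancer as a sub-split of "any cancer", so the severity
  hierarchies hold by construction.
* Each true flag emits one or two ICD-9 codes drawn uniformly from the
  condition's expanded code set (codes that would collide with another
  condition are removed from the pool); unparsed "noise" codes that match no
  condition are added at a Poisson rate.
* The three binary outcomes are drawn from logistic models on the flags with
  configurable per-condition log-odds (defaults: published per-condition odds
  ratios for this population) and intercepts calibrated by root-finding so the
  marginal rates hit their targets (defaults: mortality 6.9%, escalation 13%,
  readmission 15%).  Outcomes are generated independently given the flags;
  death and escalation may co-occur.
* log LOS = baseline + X·beta + Gaussian noise.  The default noise SD is set
  from Var(X·beta) so the linear model's expected R-squared is ~0.10, and the
  baseline so the median LOS is ~4.1 days.  Ages follow a piecewise-linear
  quantile curve with median 74 and IQR (61, 84).
* Escalation labels are realized as concrete mechanisms (ICU or IMCU stay,
  mechanical ventilation, daytime BiPAP, or a named vasopressor), chosen at
  random; non-escalation records receive no qualifying event, but may get
  decoys (night-time BiPAP, a non-listed pressor) that must not flip labels.
* Readmission labels are realized by giving the same synthetic patient a
  subsequent admission with a calendar-date gap uniform on [1, 30] days;
  non-readmitted records either end the patient's chain or are followed after
  a gap of 31-90 days.

All randomness flows from one seeded generator: identical config + seed gives
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import elixhauser
from .elixhauser import ComorbidityDefinition, ComorbidityProfile, match_matrix
from .icd9 import format_icd9, pattern_codes
from .records import Hospitalization, TreatmentEvent, WardStay

__all__ = [
    "DEFAULT_PREVALENCES",
    "MORTALITY_OR",
    "ESCALATION_OR",
    "READMISSION_OR",
    "LOG_LOS_BETA",
    "DEFAULT_TARGET_RATES",
    "GeneratorConfig",
    "GroundTruth",
    "generate_profiles",
    "profile_to_codes",
    "calibrate_intercept",
    "generate_records",
]

# ---------------------------------------------------------------------------
# Default calibration: prevalences, per-condition effects, marginal rates.
# ---------------------------------------------------------------------------

#: Marginal comorbidity prevalences (fraction of hospitalizations).
DEFAULT_PREVALENCES: dict[str, float] = {
    "congestive_heart_failure": 0.27,
    "cardiac_arrhythmias": 0.039,
    "valvular_disease": 0.14,
    "pulmonary_circulation_disorders": 0.077,
    "peripheral_vascular_disorders": 0.22,
    "hypertension": 0.46,
    "paralysis": 0.015,
    "other_neurological_disorders": 0.046,
    "chronic_pulmonary_disease": 0.12,
    "diabetes_uncomplicated": 0.12,
    "diabetes_complicated": 0.013,
    "hypothyroidism": 0.11,
    "renal_failure": 0.022,
    "liver_disease": 0.021,
    "peptic_ulcer_disease": 0.009,
    "aids_hiv": 0.0003,
    "lymphoma": 0.008,
    "metastatic_cancer": 0.024,
    "solid_tumor": 0.082,
    "rheumatoid_arthritis": 0.021,
    "coagulopathy": 0.020,
    "obesity": 0.057,
    "weight_loss": 0.005,
    "fluid_electrolyte_disorders": 0.13,
    "blood_loss_anemia": 0.0001,
    "deficiency_anemias": 0.07,
    "alcohol_abuse": 0.004,
    "drug_abuse": 0.0013,
    "psychoses": 0.025,
    "depression": 0.044,
}

#: True per-condition odds ratios for the three binary outcomes and the
#: per-condition log-day effects for LOS (blood-loss anemia carries no effect).
MORTALITY_OR: dict[str, float] = {
    "congestive_heart_failure": 1.69,
    "cardiac_arrhythmias": 0.82,
    "valvular_disease": 0.94,
    "pulmonary_circulation_disorders": 1.10,
    "peripheral_vascular_disorders": 1.26,
    "hypertension": 1.05,
    "paralysis": 1.39,
    "other_neurological_disorders": 2.13,
    "chronic_pulmonary_disease": 0.89,
    "diabetes_uncomplicated": 0.94,
    "diabetes_complicated": 0.82,
    "hypothyroidism": 1.33,
    "renal_failure": 1.58,
    "liver_disease": 1.63,
    "peptic_ulcer_disease": 0.90,
    "aids_hiv": 1.38,
    "lymphoma": 1.76,
    "metastatic_cancer": 2.45,
    "solid_tumor": 2.43,
    "rheumatoid_arthritis": 1.13,
    "coagulopathy": 2.49,
    "obesity": 0.56,
    "weight_loss": 2.16,
    "fluid_electrolyte_disorders": 2.52,
    "deficiency_anemias": 1.19,
    "alcohol_abuse": 0.60,
    "drug_abuse": 0.59,
    "psychoses": 0.83,
    "depression": 0.88,
}

ESCALATION_OR: dict[str, float] = {
    "congestive_heart_failure": 1.85,
    "cardiac_arrhythmias": 1.09,
    "valvular_disease": 1.58,
    "pulmonary_circulation_disorders": 1.24,
    "peripheral_vascular_disorders": 1.15,
    "hypertension": 1.08,
    "paralysis": 1.30,
    "other_neurological_disorders": 1.96,
    "chronic_pulmonary_disease": 1.55,
    "diabetes_uncomplicated": 1.12,
    "diabetes_complicated": 0.84,
    "hypothyroidism": 1.02,
    "renal_failure": 1.39,
    "liver_disease": 1.20,
    "peptic_ulcer_disease": 0.74,
    "aids_hiv": 4.02,
    "lymphoma": 0.89,
    "metastatic_cancer": 1.00,
    "solid_tumor": 0.85,
    "rheumatoid_arthritis": 1.12,
    "coagulopathy": 1.32,
    "obesity": 1.28,
    "weight_loss": 1.13,
    "fluid_electrolyte_disorders": 2.18,
    "deficiency_anemias": 1.06,
    "alcohol_abuse": 1.43,
    "drug_abuse": 1.83,
    "psychoses": 1.32,
    "depression": 0.73,
}

READMISSION_OR: dict[str, float] = {
    "congestive_heart_failure": 1.43,
    "cardiac_arrhythmias": 0.83,
    "valvular_disease": 1.04,
    "pulmonary_circulation_disorders": 1.21,
    "peripheral_vascular_disorders": 1.19,
    "hypertension": 1.04,
    "paralysis": 1.12,
    "other_neurological_disorders": 1.19,
    "chronic_pulmonary_disease": 1.27,
    "diabetes_uncomplicated": 0.99,
    "diabetes_complicated": 1.25,
    "hypothyroidism": 1.13,
    "renal_failure": 1.10,
    "liver_disease": 1.14,
    "peptic_ulcer_disease": 1.21,
    "aids_hiv": 0.54,
    "lymphoma": 1.38,
    "metastatic_cancer": 1.26,
    "solid_tumor": 1.56,
    "rheumatoid_arthritis": 1.07,
    "coagulopathy": 1.13,
    "obesity": 0.83,
    "weight_loss": 1.67,
    "fluid_electrolyte_disorders": 1.33,
    "deficiency_anemias": 1.13,
    "alcohol_abuse": 1.14,
    "drug_abuse": 0.77,
    "psychoses": 1.51,
    "depression": 1.04,
}

LOG_LOS_BETA: dict[str, float] = {
    "congestive_heart_failure": 0.21,
    "cardiac_arrhythmias": 0.02,
    "valvular_disease": 0.12,
    "pulmonary_circulation_disorders": 0.08,
    "peripheral_vascular_disorders": 0.10,
    "hypertension": 0.10,
    "paralysis": 0.31,
    "other_neurological_disorders": 0.27,
    "chronic_pulmonary_disease": 0.05,
    "diabetes_uncomplicated": 0.04,
    "diabetes_complicated": 0.15,
    "hypothyroidism": 0.08,
    "renal_failure": 0.10,
    "liver_disease": 0.16,
    "peptic_ulcer_disease": 0.02,
    "aids_hiv": 0.28,
    "lymphoma": 0.38,
    "metastatic_cancer": 0.22,
    "solid_tumor": 0.23,
    "rheumatoid_arthritis": 0.09,
    "coagulopathy": 0.25,
    "obesity": 0.00,
    "weight_loss": 0.59,
    "fluid_electrolyte_disorders": 0.22,
    "deficiency_anemias": 0.20,
    "alcohol_abuse": 0.14,
    "drug_abuse": 0.04,
    "psychoses": 0.18,
    "depression": 0.06,
}

DEFAULT_TARGET_RATES: dict[str, float] = {
    "mortality": 0.069,
    "escalation": 0.13,
    "readmission": 0.15,
}

#: Severity pairs sampled as sub-splits: (mild key, severe key).
_SUBSPLIT_PAIRS = (
    ("diabetes_uncomplicated", "diabetes_complicated"),
    ("solid_tumor", "metastatic_cancer"),
)

_VASOPRESSOR_NAMES = (
    "adrenaline", "dobutamine", "dopamine", "milrinone",
    "noradrenaline", "phenylephrine", "vasopressin",
)
_DECOY_PRESSOR = "midodrine"  # oral pressor, deliberately not on the list

_AGE_KNOTS_Q = (0.0, 0.25, 0.5, 0.75, 1.0)
_AGE_KNOTS_V = (18.0, 61.0, 74.0, 84.0, 103.0)

_SECONDS_PER_DAY = 86_400


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort."""

    n: int = 10_000
    seed: int = 0
    prevalences: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    mortality_log_odds: Mapping[str, float] = field(
        default_factory=lambda: {k: math.log(v) for k, v in MORTALITY_OR.items()})
    escalation_log_odds: Mapping[str, float] = field(
        default_factory=lambda: {k: math.log(v) for k, v in ESCALATION_OR.items()})
    readmission_log_odds: Mapping[str, float] = field(
        default_factory=lambda: {k: math.log(v) for k, v in READMISSION_OR.items()})
    target_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TARGET_RATES))
    los_beta: Mapping[str, float] = field(default_factory=lambda: dict(LOG_LOS_BETA))
    los_noise_sd: Optional[float] = None  # None -> calibrated for R^2 ~ los_r_squared
    los_baseline: Optional[float] = None  # None -> calibrated for median ~ median_los_days
    los_r_squared: float = 0.10
    median_los_days: float = 4.1
    readmission_window_days: int = 30
    continue_gap_prob: float = 0.15  # non-readmitted chain continues with gap > window
    noise_code_rate: float = 2.0
    extra_code_prob: float = 0.3
    undotted_code_prob: float = 0.3
    decoy_night_bipap_prob: float = 0.05
    decoy_pressor_prob: float = 0.02
    include_imcu: bool = True
    male_fraction: float = 0.53
    emergency_fraction: float = 0.86
    elective_fraction: float = 0.09
    start_date: str = "2016-01-01"
    end_date: str = "2019-12-31"

    def __post_init__(self) -> None:
        if self.n < 100:
            raise ValueError("n must be at least 100")
        for k, p in self.prevalences.items():
            if not 0 <= p < 1:
                raise ValueError(f"prevalence for {k} outside [0, 1): {p}")
        for k, r in self.target_rates.items():
            if not 0 < r < 1:
                raise ValueError(f"target rate for {k} outside (0, 1): {r}")
        if self.los_noise_sd is not None and self.los_noise_sd <= 0:
            raise ValueError("los_noise_sd must be positive")


@dataclass
class GroundTruth:
    """True flags and outcome labels, indexed by hospitalization_id."""

    flags: pd.DataFrame
    outcomes: pd.DataFrame


# ---------------------------------------------------------------------------
# Comorbidity profiles and codes
# ---------------------------------------------------------------------------

def generate_profiles(
    n: int,
    prevalences: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw ``n`` true comorbidity profiles (boolean frame, one column per key).

    Conditions are independent except the two severity pairs, which are drawn
    as a marginal "any" flag sub-split into mild/severe, so no profile ever
    carries both members (hierarchy-consistent by construction).
    """
    prevalences = dict(DEFAULT_PREVALENCES if prevalences is None else prevalences)
    rng = np.random.default_rng() if rng is None else rng
    severe_of = {mild: severe for mild, severe in _SUBSPLIT_PAIRS}
    mild_of = {severe: mild for mild, severe in _SUBSPLIT_PAIRS}
    out: dict[str, np.ndarray] = {}
    for key in prevalences:
        if key in out:
            continue
        partner = severe_of.get(key) or mild_of.get(key)
        if partner is not None and partner in prevalences:
            mild, severe = (key, partner) if key in severe_of else (partner, key)
            p_any = prevalences[mild] + prevalences[severe]
            if p_any >= 1:
                raise ValueError(f"combined prevalence of {mild}/{severe} >= 1")
            has_any = rng.random(n) < p_any
            frac_severe = prevalences[severe] / p_any if p_any > 0 else 0.0
            is_severe = rng.random(n) < frac_severe
            out[mild] = has_any & ~is_severe
            out[severe] = has_any & is_severe
        else:
            out[key] = rng.random(n) < prevalences[key]
    return pd.DataFrame({k: out[k] for k in prevalences})


class DefinitionIndex:
    """Expanded per-condition code pools plus a noise pool, for sampling.

    Pool entries are (namespace, digits) at pattern precision; entries that
    would also match a *different* condition are removed so an emitted code
    can never activate a flag that is false in the ground truth.
    """

    def __init__(self, definitions: Sequence[ComorbidityDefinition]):
        self.definitions = tuple(definitions)
        self.keys = [d.key for d in definitions]
        candidates: list[tuple[str, str]] = []
        owner: list[int] = []
        for j, d in enumerate(definitions):
            seen: set[tuple[str, str]] = set()
            for pat in d.patterns:
                for digits in pattern_codes(pat):
                    entry = (pat.namespace, digits)
                    if entry not in seen:
                        seen.add(entry)
                        candidates.append(entry)
                        owner.append(j)
        display = [format_icd9(ns, dg, dotted=False) for ns, dg in candidates]
        matrix, _ = match_matrix(display, definitions)
        self.pools: dict[str, list[tuple[str, str]]] = {k: [] for k in self.keys}
        for entry, j, row in zip(candidates, owner, matrix):
            if row[j] and row.sum() == 1:
                self.pools[self.keys[j]].append(entry)
        for k, pool in self.pools.items():
            if not pool:
                raise ValueError(f"no unambiguous codes available for condition {k}")
        # noise pool: 4-digit numeric codes matching no condition
        noise_display = [str(v).zfill(4) for v in range(10, 10_000)]
        noise_matrix, _ = match_matrix(noise_display, definitions)
        self.noise_pool: list[tuple[str, str]] = [
            ("numeric", s) for s, row in zip(noise_display, noise_matrix) if not row.any()
        ]


@lru_cache(maxsize=1)
def default_index() -> DefinitionIndex:
    return DefinitionIndex(elixhauser.load_definitions())


def _emit(entry: tuple[str, str], dotted: bool) -> str:
    return format_icd9(entry[0], entry[1], dotted=dotted)


def codes_for_profiles(
    flags: pd.DataFrame,
    index: DefinitionIndex,
    rng: np.random.Generator,
    noise_code_rate: float = 2.0,
    extra_code_prob: float = 0.3,
    undotted_code_prob: float = 0.3,
) -> list[list[str]]:
    """Emit a raw diagnosis-code list realizing each profile row."""
    n = len(flags)
    lists: list[list[str]] = [[] for _ in range(n)]

    def add(row: int, entry: tuple[str, str]) -> None:
        lists[row].append(_emit(entry, dotted=rng.random() >= undotted_code_prob))

    for key in index.keys:
        if key not in flags.columns:
            continue
        rows = np.flatnonzero(flags[key].to_numpy())
        if rows.size == 0:
            continue
        pool = index.pools[key]
        picks = rng.integers(len(pool), size=rows.size)
        extras = rng.random(rows.size) < extra_code_prob
        for r, pick, extra in zip(rows, picks, extras):
            add(int(r), pool[pick])
            if extra:
                add(int(r), pool[rng.integers(len(pool))])
    n_noise = rng.poisson(noise_code_rate, size=n)
    for r in range(n):
        for _ in range(int(n_noise[r])):
            add(r, index.noise_pool[rng.integers(len(index.noise_pool))])
    return lists


def profile_to_codes(
    profile: ComorbidityProfile,
    definitions: Sequence[ComorbidityDefinition] | None = None,
    rng: np.random.Generator | None = None,
    noise_code_rate: float = 0.0,
) -> list[str]:
    """Code list for a single profile (round-trips through the mapper)."""
    index = default_index() if definitions is None else DefinitionIndex(definitions)
    rng = np.random.default_rng() if rng is None else rng
    flags = pd.DataFrame([dict(profile.flags)])
    return codes_for_profiles(flags, index, rng, noise_code_rate=noise_code_rate)[0]


# ---------------------------------------------------------------------------
# Outcome calibration
# ---------------------------------------------------------------------------

def _linear_predictor(flags: pd.DataFrame, coef: Mapping[str, float]) -> np.ndarray:
    xb = np.zeros(len(flags))
    for k, b in coef.items():
        if b != 0.0 and k in flags.columns:
            xb += b * flags[k].to_numpy(dtype=float)
    return xb


def _solve_intercept(xb: np.ndarray, target_rate: float) -> float:
    """Intercept making mean(expit(a + xb)) equal the target rate."""
    if not 0 < target_rate < 1:
        raise ValueError("target rate must lie in (0, 1)")

    def f(a: float) -> float:
        return float(expit(a + xb).mean() - target_rate)

    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target rate unattainable for these coefficients")
    return float(brentq(f, lo, hi, xtol=1e-10))


def calibrate_intercept(
    coefficients: Mapping[str, float],
    prevalences: Mapping[str, float] | None = None,
    target_rate: float = 0.069,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Intercept giving the requested population-average event rate.

    The flag distribution is approximated by a Monte-Carlo draw of ``n_mc``
    profiles; the intercept is then found by 1-D root-finding, so the
    population-averaged probability matches the target to the Monte-Carlo
    resolution.  With all coefficients zero this reduces to logit(target).
    """
    rng = np.random.default_rng(seed)
    flags = generate_profiles(n_mc, prevalences, rng)
    return _solve_intercept(_linear_predictor(flags, coefficients), target_rate)


# ---------------------------------------------------------------------------
# Full record generation
# ---------------------------------------------------------------------------

def _place_in_hours(
    admit_s: int, discharge_s: int, start_hour: int, end_hour: int,
    rng: np.random.Generator,
) -> Optional[int]:
    """A uniform second within [admit, discharge] whose local hour lies in the
    (possibly midnight-wrapping) band [start_hour, end_hour); None if the stay
    never intersects the band."""
    day0 = (admit_s // _SECONDS_PER_DAY - 1) * _SECONDS_PER_DAY
    day = day0
    while day <= discharge_s:
        if start_hour < end_hour:
            w0, w1 = day + start_hour * 3600, day + end_hour * 3600
        else:
            w0, w1 = day + start_hour * 3600, day + (24 + end_hour) * 3600
        lo = max(admit_s, w0)
        hi = min(discharge_s + 1, w1)
        if hi > lo:
            return int(lo + rng.integers(0, hi - lo))
        day += _SECONDS_PER_DAY
    return None


def _ts(seconds: int) -> pd.Timestamp:
    return pd.Timestamp(int(seconds), unit="s")


def generate_records(
    cfg: GeneratorConfig,
    definitions: Sequence[ComorbidityDefinition] | None = None,
) -> tuple[list[Hospitalization], GroundTruth]:
    """Generate a full raw cohort plus its ground-truth labels.

    Returns at least ``cfg.n`` hospitalizations: a handful of extra admissions
    may be appended to close the final readmission chain (a record whose
    readmission label is true must be followed by a real admission).
    """
    rng = np.random.default_rng(cfg.seed)
    definitions = elixhauser.load_definitions() if definitions is None else tuple(definitions)
    index = default_index() if definitions == default_index().definitions \
        else DefinitionIndex(definitions)

    n_spare = 64  # closers for the last readmission chain; practically never exhausted
    n_tot = cfg.n + n_spare

    flags = generate_profiles(n_tot, cfg.prevalences, rng)
    code_lists = codes_for_profiles(
        flags, index, rng,
        noise_code_rate=cfg.noise_code_rate,
        extra_code_prob=cfg.extra_code_prob,
        undotted_code_prob=cfg.undotted_code_prob,
    )

    # --- outcome labels -----------------------------------------------------
    labels: dict[str, np.ndarray] = {}
    for name, coef in (
        ("mortality", cfg.mortality_log_odds),
        ("escalation", cfg.escalation_log_odds),
        ("readmission", cfg.readmission_log_odds),
    ):
        xb = _linear_predictor(flags, coef)
        a = _solve_intercept(xb[: cfg.n], cfg.target_rates[name])
        labels[name] = rng.random(n_tot) < expit(a + xb)

    xb_los = _linear_predictor(flags, cfg.los_beta)
    var_xb = float(xb_los[: cfg.n].var())
    r2 = cfg.los_r_squared
    noise_sd = cfg.los_noise_sd
    if noise_sd is None:
        noise_sd = math.sqrt(var_xb * (1 - r2) / r2)
    baseline = cfg.los_baseline
    if baseline is None:
        baseline = math.log(cfg.median_los_days) - float(xb_los[: cfg.n].mean())
    log_los = baseline + xb_los + rng.normal(0.0, noise_sd, n_tot)
    los_sec = np.maximum(np.rint(np.exp(log_los) * _SECONDS_PER_DAY), 60).astype(np.int64)

    ages = np.interp(rng.random(n_tot), _AGE_KNOTS_Q, _AGE_KNOTS_V).round(1)
    sexes = np.where(rng.random(n_tot) < cfg.male_fraction, "male", "female")
    p_rest = 1.0 - cfg.emergency_fraction - cfg.elective_fraction
    sources = rng.choice(
        ["emergency", "elective", "internal_transfer"],
        p=[cfg.emergency_fraction, cfg.elective_fraction, p_rest], size=n_tot)
    base_wards = rng.choice(
        ["im_ward", "cardiology", "geriatrics", "short_stay"],
        p=[0.80, 0.08, 0.07, 0.05], size=n_tot)

    # --- readmission chains -> patient ids and timestamps -------------------
    lo_s = int(pd.Timestamp(cfg.start_date).timestamp())
    hi_s = int(pd.Timestamp(cfg.end_date).timestamp())
    readmit = labels["readmission"]
    admit_s = np.zeros(n_tot, dtype=np.int64)
    discharge_s = np.zeros(n_tot, dtype=np.int64)
    patient_of = np.zeros(n_tot, dtype=np.int64)
    window = cfg.readmission_window_days

    open_chain = False
    gap_days = 0
    pid = -1
    i = 0
    while i < n_tot:
        if not open_chain:
            pid += 1
            admit_s[i] = rng.integers(lo_s, hi_s)
        else:
            prev_midnight = (discharge_s[i - 1] // _SECONDS_PER_DAY) * _SECONDS_PER_DAY
            admit_s[i] = prev_midnight + gap_days * _SECONDS_PER_DAY \
                + rng.integers(0, _SECONDS_PER_DAY)
        patient_of[i] = pid
        discharge_s[i] = admit_s[i] + los_sec[i]
        if readmit[i]:
            open_chain = True
            gap_days = int(rng.integers(1, window + 1))
        elif rng.random() < cfg.continue_gap_prob:
            open_chain = True
            gap_days = int(rng.integers(window + 1, 3 * window + 1))
        else:
            open_chain = False
        i += 1
        if i >= cfg.n and not open_chain:
            break
    if open_chain:
        raise RuntimeError("spare pool exhausted while closing readmission chain")
    n_emit = i

    # --- realize escalation mechanisms and decoy events ---------------------
    esc = labels["escalation"][:n_emit]
    mechanisms = ["icu", "imcu", "vent", "bipap", "pressor"] if cfg.include_imcu \
        else ["icu", "vent", "bipap", "pressor"]
    stays: dict[int, list[WardStay]] = {}
    events: dict[int, list[TreatmentEvent]] = {}

    def frac_ts(r: int, frac: float) -> int:
        return int(admit_s[r] + frac * los_sec[r])

    for r in range(n_emit):
        a_s, d_s = int(admit_s[r]), int(discharge_s[r])
        row_stays: list[WardStay] = []
        row_events: list[TreatmentEvent] = []
        mech = None
        if esc[r]:
            mech = mechanisms[rng.integers(len(mechanisms))]
            if mech == "bipap":
                ts = _place_in_hours(a_s, d_s, 8, 20, rng)
                if ts is None:
                    mech = "vent"
                else:
                    row_events.append(TreatmentEvent("bipap", _ts(ts)))
            if mech in ("icu", "imcu"):
                s0 = frac_ts(r, float(rng.uniform(0.10, 0.45)))
                s1 = frac_ts(r, float(rng.uniform(0.55, 0.90)))
                row_stays = [
                    WardStay(base_wards[r], _ts(a_s), _ts(s0)),
                    WardStay(mech, _ts(s0), _ts(s1)),
                    WardStay(base_wards[r], _ts(s1), _ts(d_s)),
                ]
            elif mech == "vent":
                row_events.append(TreatmentEvent(
                    "mechanical_ventilation", _ts(frac_ts(r, float(rng.uniform(0.05, 0.95))))))
            elif mech == "pressor":
                drug = _VASOPRESSOR_NAMES[rng.integers(len(_VASOPRESSOR_NAMES))]
                row_events.append(TreatmentEvent(
                    "vasopressor", _ts(frac_ts(r, float(rng.uniform(0.05, 0.95)))), drug))
        else:
            if rng.random() < cfg.decoy_night_bipap_prob:
                ts = _place_in_hours(a_s, d_s, 20, 8, rng)
                if ts is not None:
                    row_events.append(TreatmentEvent("bipap", _ts(ts)))
            if rng.random() < cfg.decoy_pressor_prob:
                row_events.append(TreatmentEvent(
                    "vasopressor", _ts(frac_ts(r, float(rng.uniform(0.05, 0.95)))),
                    _DECOY_PRESSOR))
        if not row_stays:
            row_stays = [WardStay(base_wards[r], _ts(a_s), _ts(d_s))]
        stays[r] = row_stays
        if row_events:
            events[r] = row_events

    # --- assemble records and ground truth ----------------------------------
    records: list[Hospitalization] = []
    ids = [f"h{r:06d}" for r in range(n_emit)]
    for r in range(n_emit):
        records.append(Hospitalization(
            hospitalization_id=ids[r],
            patient_id=f"p{patient_of[r]:06d}",
            admit=_ts(int(admit_s[r])),
            discharge=_ts(int(discharge_s[r])),
            age_years=float(ages[r]),
            sex=str(sexes[r]),
            admission_source=str(sources[r]),
            died_in_hospital=bool(labels["mortality"][r]),
            diagnosis_codes=tuple(code_lists[r]),
            ward_stays=tuple(stays[r]),
            treatment_events=tuple(events.get(r, ())),
            drg=None,
        ))

    los_days = (discharge_s[:n_emit] - admit_s[:n_emit]) / _SECONDS_PER_DAY
    truth_flags = flags.iloc[:n_emit].copy()
    truth_flags.index = pd.Index(ids, name="hospitalization_id")
    truth_outcomes = pd.DataFrame(
        {
            "died": labels["mortality"][:n_emit],
            "escalation": esc,
            "readmit_30d": readmit[:n_emit],
            "los_days": los_days,
            "log_los": np.log(los_days),
        },
        index=truth_flags.index,
    )
    return records, GroundTruth(truth_flags, truth_outcomes)
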