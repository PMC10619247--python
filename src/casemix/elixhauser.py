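"""Elixhauser comorbidity flagging from ICD-9-CM diagnosis codes.

The index defines 30 dichotomous comorbid conditions, each as a set of ICD-9-CM
codes and code ranges, with two severity hierarchies (complicated diabetes over
uncomplicated; metastatic cancer over solid tumor) and an optional DRG screen
that suppresses a flag when the hospitalization's diagnosis-related group shows
the condition was the principal reason for admission.  The hypertension
sub-lists are combined into a single condition, giving a 30-key profile.

Flags are assigned per hospitalization: a condition is present iff at least one
of that hospitalization's own recorded codes matches one of its patterns; codes
from a patient's other hospitalizations never count.

The shipped definition table is a plain-text resource
(``casemix/data/elixhauser_icd9.tsv``); a replacement file in the same format
can be supplied to :func:`load_definitions`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .icd9 import CodePattern, Icd9Error, compile_pattern, normalize_icd9

__all__ = [
    "DRG_GROUPS",
    "HIERARCHY_PAIRS",
    "DEFAULT_EXCLUSIONS",
    "ComorbidityDefinition",
    "ComorbidityProfile",
    "load_definitions",
    "condition_keys",
    "display_names",
    "assign_flags",
    "assign_flags_table",
    "apply_hierarchy",
    "apply_hierarchy_table",
    "apply_drg_screen",
    "apply_drg_screen_table",
    "prevalence_table",
    "select_conditions",
    "design_matrix",
]

logger = logging.getLogger(__name__)


def _expand(*chunks: object) -> frozenset[int]:
    out: set[int] = set()
    for chunk in chunks:
        if isinstance(chunk, tuple):
            out.update(range(chunk[0], chunk[1] + 1))
        else:
            out.add(int(chunk))  # type: ignore[arg-type]
    return frozenset(out)


#: Named DRG groups referenced by the definition table's screen column.
DRG_GROUPS: Mapping[str, frozenset[int]] = {
    "Cardiac": _expand((103, 108), (110, 112), (115, 118), (120, 127), 129, (132, 133)),
    "Renal": _expand((302, 305), (315, 333)),
    "Liver": _expand((199, 202), (205, 208)),
    "Lymphoma": _expand((400, 414)),
    "Cancer": _expand(
        10, 11, 64, 82, 172, 173, 199, 203, 239, (257, 260), 274, 275, 303,
        318, 319, 338, 344, 346, 347, 354, 366, 367, (406, 414),
    ),
}

#: (dropped, kept) severity pairs: when both flags are set, only the more
#: severe member counts.
HIERARCHY_PAIRS: tuple[tuple[str, str], ...] = (
    ("diabetes_uncomplicated", "diabetes_complicated"),
    ("solid_tumor", "metastatic_cancer"),
)

#: Condition excluded from modeling by default (6 cases in the source cohort).
DEFAULT_EXCLUSIONS: tuple[str, ...] = ("blood_loss_anemia",)

_NS_ID = {"numeric": 0, "V": 1, "E": 2}


@dataclass(frozen=True)
class ComorbidityDefinition:
    key: str
    display_name: str
    patterns: tuple[CodePattern, ...]
    drg_screen: frozenset[int]


@dataclass(frozen=True)
class ComorbidityProfile:
    """Boolean flags for the 30 conditions of one hospitalization."""

    flags: Mapping[str, bool]

    def true_keys(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.flags.items() if v)


def _parse_drg_tokens(tokens: str) -> frozenset[int]:
    out: set[int] = set()
    for tok in tokens.split(","):
        tok = tok.strip()
        if not tok:
            continue
        if tok in DRG_GROUPS:
            out.update(DRG_GROUPS[tok])
        elif "-" in tok:
            lo, hi = tok.split("-")
            out.update(range(int(lo), int(hi) + 1))
        elif tok.isdigit():
            out.add(int(tok))
        else:
            raise ValueError(f"unknown DRG group or token {tok!r}")
    return frozenset(out)


def load_definitions(path: str | Path | None = None) -> tuple[ComorbidityDefinition, ...]:
    """Load and compile the comorbidity definition table.

    Parameters
    ----------
    path:
        Optional replacement table; defaults to the packaged resource.
    """
    if path is None:
        text = (resources.files("casemix.data") / "elixhauser_icd9.tsv").read_text()
    else:
        text = Path(path).read_text()
    defs: list[ComorbidityDefinition] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"definition row needs 4 tab-separated fields: {line!r}")
        key, display, code_tokens, drg_tokens = fields
        try:
            patterns = tuple(compile_pattern(t) for t in code_tokens.split(",") if t.strip())
        except Icd9Error as exc:
            raise Icd9Error(f"condition {key!r}: {exc}") from exc
        defs.append(
            ComorbidityDefinition(key, display, patterns, _parse_drg_tokens(drg_tokens))
        )
    keys = [d.key for d in defs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate condition keys in definition table")
    return tuple(defs)


def condition_keys(definitions: Sequence[ComorbidityDefinition]) -> list[str]:
    return [d.key for d in definitions]


def display_names(definitions: Sequence[ComorbidityDefinition]) -> dict[str, str]:
    return {d.key: d.display_name for d in definitions}


# ---------------------------------------------------------------------------
# Vectorized matching
# ---------------------------------------------------------------------------

def _pattern_arrays(definitions: Sequence[ComorbidityDefinition]):
    """Flatten all patterns into parallel arrays for vectorized matching.

    A code right-padded to 5 digits and floor-divided by 10**(5 - precision)
    equals its truncate-or-pad key at that precision, so interval membership
    reduces to integer comparisons.
    """
    ns, div, low, high, cond = [], [], [], [], []
    for j, d in enumerate(definitions):
        for p in d.patterns:
            ns.append(_NS_ID[p.namespace])
            div.append(10 ** (5 - p.precision))
            low.append(int(p.low))
            high.append(int(p.high))
            cond.append(j)
    return (np.array(ns), np.array(div), np.array(low), np.array(high), np.array(cond))


def match_matrix(
    codes: Sequence[str], definitions: Sequence[ComorbidityDefinition]
) -> tuple[np.ndarray, list[int]]:
    """Match each raw code against every condition.

    Returns
    -------
    matrix:
        Boolean array of shape ``(len(codes), len(definitions))``.
    invalid:
        Indices of codes that failed normalization (they match nothing).
    """
    n = len(codes)
    ns_arr = np.full(n, -1)
    c5 = np.zeros(n, dtype=np.int64)
    invalid: list[int] = []
    for i, raw in enumerate(codes):
        try:
            code = normalize_icd9(raw)
        except Icd9Error:
            invalid.append(i)
            continue
        ns_arr[i] = _NS_ID[code.namespace]
        c5[i] = int(code.digits.ljust(5, "0"))
    p_ns, p_div, p_low, p_high, p_cond = _pattern_arrays(definitions)
    matrix = np.zeros((n, len(definitions)), dtype=bool)
    keys = c5[:, None] // p_div[None, :]
    hits = (ns_arr[:, None] == p_ns[None, :]) & (keys >= p_low) & (keys <= p_high)
    np.logical_or.at(matrix.T, p_cond, hits.T)
    return matrix, invalid


def assign_flags_table(
    code_lists: Sequence[Sequence[str]],
    definitions: Sequence[ComorbidityDefinition],
    index: Iterable | None = None,
) -> pd.DataFrame:
    """Assign pre-hierarchy flags for many hospitalizations at once.

    Unparseable codes are skipped (counted in a log entry); a flag is true iff
    at least one of the row's codes matches one of the condition's patterns.
    """
    unique = sorted({c for lst in code_lists for c in lst})
    matrix, invalid = match_matrix(unique, definitions)
    if invalid:
        logger.warning(
            "%d unparseable ICD-9 code(s) skipped (e.g. %r)",
            len(invalid),
            unique[invalid[0]],
        )
    pos = {c: i for i, c in enumerate(unique)}
    out = np.zeros((len(code_lists), len(definitions)), dtype=bool)
    for r, lst in enumerate(code_lists):
        if lst:
            rows = [pos[c] for c in lst]
            out[r] = matrix[rows].any(axis=0)
    return pd.DataFrame(out, columns=condition_keys(definitions), index=index)


def assign_flags(
    codes: Sequence[str], definitions: Sequence[ComorbidityDefinition]
) -> ComorbidityProfile:
    """Assign the pre-hierarchy comorbidity profile for one hospitalization."""
    table = assign_flags_table([list(codes)], definitions)
    return ComorbidityProfile(dict(zip(table.columns, table.iloc[0].tolist())))


def apply_hierarchy_table(flags: pd.DataFrame) -> pd.DataFrame:
    """Resolve severity pairs: the less severe flag is cleared when both are set."""
    out = flags.copy()
    for dropped, kept in HIERARCHY_PAIRS:
        if dropped in out.columns and kept in out.columns:
            out[dropped] = out[dropped] & ~out[kept]
    return out


def apply_hierarchy(profile: ComorbidityProfile) -> ComorbidityProfile:
    flags = dict(profile.flags)
    for dropped, kept in HIERARCHY_PAIRS:
        if flags.get(dropped) and flags.get(kept):
            flags[dropped] = False
    return ComorbidityProfile(flags)


_warned_missing_drg = False


def apply_drg_screen(
    profile: ComorbidityProfile,
    drg: int | None,
    definitions: Sequence[ComorbidityDefinition],
) -> ComorbidityProfile:
    """Clear flags whose condition's DRG screen contains the hospitalization's DRG.

    With no DRG recorded the profile is returned unchanged (one-time warning):
    the screen cannot be evaluated, which is the norm for Israeli extracts.
    """
    global _warned_missing_drg
    if drg is None:
        if not _warned_missing_drg:
            warnings.warn("DRG missing; DRG screen left profiles unchanged", stacklevel=2)
            _warned_missing_drg = True
        return profile
    flags = dict(profile.flags)
    for d in definitions:
        if flags.get(d.key) and drg in d.drg_screen:
            flags[d.key] = False
    return ComorbidityProfile(flags)


def apply_drg_screen_table(
    flags: pd.DataFrame,
    drgs: Sequence[int | None],
    definitions: Sequence[ComorbidityDefinition],
) -> pd.DataFrame:
    out = flags.copy()
    drg_arr = np.array([d if d is not None else -1 for d in drgs])
    for d in definitions:
        if d.key not in out.columns or not d.drg_screen:
            continue
        screened = np.isin(drg_arr, list(d.drg_screen))
        out[d.key] = out[d.key].to_numpy() & ~screened
    return out


def _as_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return pd.DataFrame([dict(p.flags) for p in profiles])


def prevalence_table(profiles) -> pd.DataFrame:
    """Per-condition counts and percents over a cohort.

    Accepts a boolean flag table (rows = hospitalizations) or an iterable of
    :class:`ComorbidityProfile`.  ``percent`` is 100*count/n to one decimal;
    ``fraction`` keeps full precision.
    """
    frame = _as_frame(profiles)
    if len(frame) == 0:
        raise ValueError("prevalence_table requires a non-empty cohort")
    counts = frame.sum(axis=0).astype(int)
    frac = counts / len(frame)
    return pd.DataFrame(
        {
            "condition": counts.index,
            "count": counts.to_numpy(),
            "percent": (100 * frac).round(1).to_numpy(),
            "fraction": frac.to_numpy(),
        }
    ).reset_index(drop=True)


def select_conditions(
    prevalences: pd.DataFrame,
    exclusions: Sequence[str] = DEFAULT_EXCLUSIONS,
    min_count: int = 0,
) -> list[str]:
    """Choose the conditions that enter the design matrix, in table order.

    ``exclusions`` are dropped unconditionally (default: blood-loss anemia,
    matching the 29-condition analysis); conditions with fewer than
    ``min_count`` flagged hospitalizations are dropped as too sparse to model.
    """
    known = set(prevalences["condition"])
    unknown = [e for e in exclusions if e not in known]
    if unknown:
        raise ValueError(f"exclusion of unknown condition(s): {unknown}")
    kept = []
    for _, row in prevalences.iterrows():
        if row["condition"] in exclusions or row["count"] < min_count:
            continue
        kept.append(row["condition"])
    return kept


def design_matrix(flags: pd.DataFrame, conditions: Sequence[str]) -> pd.DataFrame:
    """0/1 design matrix restricted to the selected conditions, in order."""
    missing = [c for c in conditions if c not in flags.columns]
    if missing:
        raise ValueError(f"conditions absent from flag table: {missing}")
    return flags.loc[:, list(conditions)].astype(np.int8)
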