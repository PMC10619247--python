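"""ICD-9-CM diagnosis-code normalization, range compilation, and matching.

ICD-9-CM codes have a 3-digit category (2 digits for V codes) plus up to two
sub-classification digits, conventionally printed with a dot ("428.0").  Hospital
extracts mix dotted and undotted forms, so every code is normalized to a
(namespace, digits) pair before any comparison: namespace is ``numeric``, ``V``
or ``E``, and ``digits`` is the dot-free digit string with no padding.

Comorbidity definitions are given as single codes or inclusive ranges such as
``428.0-428.9``.  A range compiles to a :class:`CodePattern` whose *precision*
is the digit count of its endpoints; a recorded code matches when, truncated to
that precision (if longer) or right-padded with zeros (if shorter), it falls
between the endpoints.  This is the standard administrative-data convention: a
4-digit table entry captures all of its 5-digit children, and a bare category
code counts toward any range that covers the start of the category.

Ranges whose printed endpoints differ in precision (e.g. ``042-044.9``) are
normalized by right-padding the shorter endpoint with zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Icd9Error",
    "Icd9Code",
    "CodePattern",
    "normalize_icd9",
    "compile_pattern",
    "code_matches",
    "pattern_codes",
    "format_icd9",
]

_RANGE_DASHES = ("-", "–", "—")

# (min, max) digit-string lengths per namespace; V categories are 2 digits,
# E categories 3 digits with a single optional sub-digit.
_DIGIT_BOUNDS = {"numeric": (3, 5), "V": (2, 5), "E": (3, 4)}
_CATEGORY_LEN = {"numeric": 3, "V": 2, "E": 3}


class Icd9Error(ValueError):
    """Raised for a malformed ICD-9-CM code or range token."""


@dataclass(frozen=True)
class Icd9Code:
    """A normalized ICD-9-CM code: namespace plus dot-free digit string."""

    namespace: str
    digits: str

    def display(self, dotted: bool = True) -> str:
        return format_icd9(self.namespace, self.digits, dotted=dotted)


@dataclass(frozen=True)
class CodePattern:
    """An inclusive code interval at fixed precision within one namespace."""

    namespace: str
    low: str
    high: str
    precision: int


def normalize_icd9(raw: str) -> Icd9Code:
    """Normalize a raw diagnosis-code string.

    Strips whitespace, removes the dot, detects the V/E namespace from the
    leading letter, and validates digit count per namespace.

    Raises
    ------
    Icd9Error
        If the token is empty, contains non-digits, has a misplaced dot, or
        has an out-of-range digit count.
    """
    token = raw.strip().upper()
    if not token:
        raise Icd9Error("empty code")
    namespace = "numeric"
    if token[0] in ("V", "E"):
        namespace = token[0]
        token = token[1:]
    if token.count(".") > 1:
        raise Icd9Error(f"more than one dot in {raw!r}")
    if "." in token:
        head, tail = token.split(".")
        if len(head) != _CATEGORY_LEN[namespace]:
            raise Icd9Error(
                f"{raw!r}: category part must have {_CATEGORY_LEN[namespace]} digits"
            )
        if len(tail) > 2:
            raise Icd9Error(f"{raw!r}: more than two digits after the dot")
        digits = head + tail
    else:
        digits = token
    if not digits.isdigit():
        raise Icd9Error(f"{raw!r}: non-digit characters")
    lo, hi = _DIGIT_BOUNDS[namespace]
    if not lo <= len(digits) <= hi:
        raise Icd9Error(
            f"{raw!r}: {namespace} codes need {lo}-{hi} digits, got {len(digits)}"
        )
    if namespace == "numeric" and int(digits[:3]) == 0:
        raise Icd9Error(f"{raw!r}: numeric category below 001")
    return Icd9Code(namespace, digits)


def format_icd9(namespace: str, digits: str, dotted: bool = True) -> str:
    """Render a normalized code in its conventional display form."""
    prefix = "" if namespace == "numeric" else namespace
    cut = _CATEGORY_LEN[namespace]
    if dotted and len(digits) > cut:
        return f"{prefix}{digits[:cut]}.{digits[cut:]}"
    return f"{prefix}{digits}"


def compile_pattern(token: str) -> CodePattern:
    """Compile a definition-table token (single code or ``low-high`` range).

    Endpoints are normalized; if they differ in digit count the shorter one is
    right-padded with zeros, so ``042-044.9`` spans 042.0 through 044.9 at
    4-digit precision.  A range across namespaces is a compile error.
    """
    token = token.strip()
    parts = None
    for dash in _RANGE_DASHES:
        # split on the first dash not in leading position (no negative codes exist)
        if dash in token:
            parts = token.split(dash)
            break
    if parts is None:
        code = normalize_icd9(token)
        return CodePattern(code.namespace, code.digits, code.digits, len(code.digits))
    if len(parts) != 2:
        raise Icd9Error(f"range token {token!r} must have exactly two endpoints")
    low, high = (normalize_icd9(p) for p in parts)
    if low.namespace != high.namespace:
        raise Icd9Error(f"range token {token!r} crosses namespaces")
    precision = max(len(low.digits), len(high.digits))
    lo = low.digits.ljust(precision, "0")
    hi = high.digits.ljust(precision, "0")
    if lo > hi:
        raise Icd9Error(f"range token {token!r} has low endpoint above high")
    return CodePattern(low.namespace, lo, hi, precision)


def code_matches(pattern: CodePattern, code: Icd9Code) -> bool:
    """True iff ``code`` falls in the pattern's interval at its precision.

    The code's digits are truncated to the pattern precision when longer and
    right-padded with zeros when shorter; comparison is lexicographic, which
    coincides with numeric order on equal-length digit strings.
    """
    if code.namespace != pattern.namespace:
        return False
    key = code.digits[: pattern.precision].ljust(pattern.precision, "0")
    return pattern.low <= key <= pattern.high


def pattern_codes(pattern: CodePattern) -> list[str]:
    """Enumerate the concrete digit strings of a pattern at its own precision."""
    width = pattern.precision
    return [str(v).zfill(width) for v in range(int(pattern.low), int(pattern.high) + 1)]
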