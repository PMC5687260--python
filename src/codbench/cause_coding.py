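"""ICD-10 disease-category coding for cause-of-death records.

Deaths are grouped into four broad underlying-cause categories — heart
disease, cancer, renal disease, and an "other" complement — defined by
inclusive ranges of 3-character ICD-10 root codes:

* heart:  I00–I09, I11, I13, I20–I51
* cancer: C00–C97
* renal:  N00–N07, N17–N19, N25–N27

Classification operates on the 3-character root only; 4th-character detail
never changes the category. Any syntactically valid root outside the three
defined sets (including unusual roots such as ``U07``) maps to ``other`` —
screening data may contain any code. Range specifications accept both the
typographic en-dash and the ASCII hyphen as separators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError

__all__ = [
    "CATEGORIES",
    "DISEASE_CATEGORIES",
    "OTHER",
    "ALL_CAUSE",
    "DEFAULT_CATEGORY_RANGES",
    "IcdCodeSet",
    "parse_icd10_range",
    "classify_cause",
    "default_codesets",
    "validate_codesets",
]

#: The four-value cause vocabulary; "other" is the complement category.
CATEGORIES: tuple[str, ...] = ("heart", "cancer", "renal", "other")

#: The three explicitly defined disease categories (screened and benchmarked).
DISEASE_CATEGORIES: tuple[str, ...] = ("heart", "cancer", "renal")

OTHER = "other"

#: Pseudo-category for totals across all causes (not an ICD-defined set).
ALL_CAUSE = "all_cause"

#: Packaged category definitions, overridable via configuration.
DEFAULT_CATEGORY_RANGES: dict[str, str] = {
    "heart": "I00-I09,I11,I13,I20-I51",
    "cancer": "C00-C97",
    "renal": "N00-N07,N17-N19,N25-N27",
}

_ROOT_RE = re.compile(r"^[A-Z][0-9]{2}$")
# Root, optionally a dot and up to four alphanumeric subcode characters.
_CODE_RE = re.compile(r"^([A-Z][0-9]{2})(?:\.[0-9A-Z]{1,4})?$")
_DASHES = re.compile(r"[–—-]")  # en-dash, em-dash, ASCII hyphen


@dataclass(frozen=True)
class IcdCodeSet:
    """A cause category together with the set of 3-character roots it covers."""

    category: str
    prefixes: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        for p in self.prefixes:
            if not _ROOT_RE.match(p):
                raise ValidationError(f"invalid ICD-10 root {p!r} in {self.category} code set")

    def __contains__(self, root: str) -> bool:
        return root in self.prefixes


def _parse_root(token: str) -> str:
    token = token.strip().upper()
    if not _ROOT_RE.match(token):
        raise ValidationError(f"malformed ICD-10 root code {token!r}")
    return token


def parse_icd10_range(spec: str, category: str = OTHER) -> IcdCodeSet:
    """Expand a range specification such as ``"I00–I09,I11,I13,I20–I51"``.

    ``spec`` is a comma-separated list of 3-character codes or hyphenated
    ranges; both endpoints of a range must share the same letter and ranges
    are inclusive at both ends.

    Raises
    ------
    ValidationError
        On a malformed code, endpoints with different letters, or a
        reversed range (end < start).
    """
    prefixes: set[str] = set()
    for token in spec.split(","):
        token = token.strip()
        if not token:
            raise ValidationError(f"empty token in ICD-10 range spec {spec!r}")
        parts = _DASHES.split(token)
        if len(parts) == 1:
            prefixes.add(_parse_root(parts[0]))
        elif len(parts) == 2:
            start, end = _parse_root(parts[0]), _parse_root(parts[1])
            if start[0] != end[0]:
                raise ValidationError(
                    f"range endpoints {start}–{end} use different letters"
                )
            lo, hi = int(start[1:]), int(end[1:])
            if hi < lo:
                raise ValidationError(f"reversed ICD-10 range {start}–{end}")
            prefixes.update(f"{start[0]}{i:02d}" for i in range(lo, hi + 1))
        else:
            raise ValidationError(f"malformed ICD-10 range token {token!r}")
    return IcdCodeSet(category=category, prefixes=frozenset(prefixes))


def default_codesets() -> list[IcdCodeSet]:
    """The packaged heart/cancer/renal code sets, validated for disjointness."""
    sets = [
        parse_icd10_range(spec, category)
        for category, spec in DEFAULT_CATEGORY_RANGES.items()
    ]
    validate_codesets(sets)
    return sets


def validate_codesets(codesets: Sequence[IcdCodeSet]) -> None:
    """Check that the defined (non-"other") code sets are pairwise disjoint."""
    seen: dict[str, str] = {}
    for cs in codesets:
        if cs.category == OTHER:
            raise ValidationError('"other" is the complement and takes no code set')
        for p in cs.prefixes:
            if p in seen and seen[p] != cs.category:
                raise ValidationError(
                    f"root {p} assigned to both {seen[p]} and {cs.category}"
                )
            seen[p] = cs.category


def classify_cause(code: str, codesets: Iterable[IcdCodeSet] | None = None) -> str:
    """Map a full ICD-10 code (e.g. ``"I21.9"``) to its cause category.

    Only the 3-character root is used: ``"I21"`` and ``"I21.9"`` classify
    identically. Codes outside every defined set return ``"other"``.

    Raises
    ------
    ValidationError
        If ``code`` is not a syntactically valid ICD-10 code.
    """
    m = _CODE_RE.match(str(code).strip().upper())
    if not m:
        raise ValidationError(f"syntactically invalid ICD-10 code {code!r}")
    root = m.group(1)
    if codesets is None:
        codesets = default_codesets()
    for cs in codesets:
        if root in cs.prefixes:
            return cs.category
    return OTHER
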