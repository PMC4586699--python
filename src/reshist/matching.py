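"""Approximate address-component matching with a tuned edit-distance tolerance.

Address components are compared with the generalized Levenshtein edit
distance (minimal insertions, deletions and substitutions) after a
deterministic normalization pass: case folding, whitespace collapsing,
punctuation removal and a USPS-style abbreviation substitution table.
The tolerance ``d`` is not fixed a priori; it is selected from a small
candidate set by minimizing, over a tuning sample of subjects with a
known number of distinct city names, the fraction of subjects whose
estimated unique-city count is wrong.  ``d = 0`` reduces to exact string
matching.

House numbers are always compared exactly (after stripping unit or
apartment designators); state codes are always compared exactly after
normalization to 2-letter USPS codes.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import edlib

from .types import AddressRecord, EditParam, TuningSubject

#: Candidate edit-distance tolerances evaluated when none are supplied.
DEFAULT_CANDIDATES: tuple[int, ...] = (0, 1, 2, 3, 4)

MATCH_LEVELS = ("city_state", "street", "detailed")

_PUNCT_RE = re.compile(r"[.,\-'/#]+")
_WS_RE = re.compile(r"\s+")


def _load_table(name: str) -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("reshist.data").joinpath(name).read_text(encoding="utf-8")
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        raw, canonical = line.split("\t")
        table[raw] = canonical
    return table


@lru_cache(maxsize=None)
def abbreviation_table() -> dict[str, str]:
    """Token substitution table (e.g. STREET→ST, NORTH→N), loaded once."""
    return _load_table("abbreviations.txt")


@lru_cache(maxsize=None)
def state_table() -> dict[str, str]:
    """Full state names mapped to 2-letter USPS codes."""
    return _load_table("states.txt")


def normalize_component(raw: str) -> str:
    """Canonicalize a free-text address component for distance computation.

    Uppercases, replaces punctuation with spaces, collapses whitespace
    runs, then applies the abbreviation table token-wise.  Idempotent;
    the empty string maps to itself.
    """
    s = _PUNCT_RE.sub(" ", raw.upper())
    tokens = _WS_RE.split(s.strip())
    table = abbreviation_table()
    return " ".join(table.get(t, t) for t in tokens if t)


def normalize_state(raw: str) -> str:
    """Normalize a state to its 2-letter code; full names are mapped via table."""
    s = _WS_RE.sub(" ", _PUNCT_RE.sub(" ", raw.upper())).strip()
    if len(s) == 2:
        return s
    return state_table().get(s, s)


def normalize_house_number(raw: str) -> str:
    """Strip unit/apartment designators, keeping the leading house-number token."""
    s = _PUNCT_RE.sub(" ", raw.upper()).strip()
    if not s:
        return ""
    return s.split()[0]


def edit_distance(a: str, b: str) -> int:
    """Generalized Levenshtein distance between two normalized strings."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def approx_equal(a: str, b: str, d: int) -> bool:
    """True iff the edit distance between ``a`` and ``b`` is at most ``d``."""
    if d < 0:
        raise ValueError("tolerance d must be nonnegative")
    if abs(len(a) - len(b)) > d:  # cheap lower bound
        return False
    return edit_distance(a, b) <= d


def count_unique_strings(strings: Sequence[str], d: int) -> int:
    """Number of distinct strings under tolerance ``d``, by greedy clustering.

    Approximate equality is not transitive, so the count is defined by a
    deterministic rule: scan in input order, keep a list of cluster
    representatives, assign each string to the first representative
    within distance ``d``, otherwise open a new cluster.
    """
    if not strings:
        raise ValueError("cannot count unique strings of an empty list")
    representatives: list[str] = []
    for s in strings:
        if not any(approx_equal(s, rep, d) for rep in representatives):
            representatives.append(s)
    return len(representatives)


def select_edit_param(
    sample: Iterable[TuningSubject],
    candidates: Sequence[int] = DEFAULT_CANDIDATES,
) -> EditParam:
    """Choose the edit-distance tolerance minimizing the unique-city error rate.

    For each candidate ``d`` a tuning subject errs when the greedy
    unique-city count at tolerance ``d`` differs from the known true
    count — either two names that are the same were called different, or
    two different names were called the same.  The error rate is the
    fraction of erring subjects; ties go to the smallest ``d`` (the
    strictest matcher among equally accurate ones).
    """
    candidates = tuple(candidates)
    if not candidates:
        raise ValueError("candidate set must be nonempty")
    if any(c < 0 for c in candidates):
        raise ValueError("candidates must be nonnegative")
    if list(candidates) != sorted(candidates):
        raise ValueError("candidates must be sorted ascending")
    subjects = list(sample)
    if not subjects:
        raise ValueError("tuning sample must be nonempty")

    best: tuple[float, int] | None = None
    best_rate = 1.0
    for d in candidates:
        errors = sum(
            1
            for subj in subjects
            if count_unique_strings(subj.strings, d) != subj.true_unique_count
        )
        rate = errors / len(subjects)
        if best is None or rate < best[0]:
            best = (rate, d)
            best_rate = rate
    assert best is not None
    return EditParam(d=best[1], candidate_set=candidates, error_rate=best_rate)


def compare_components(
    study: AddressRecord, rec: AddressRecord, d: int
) -> tuple[bool, bool, bool]:
    """Component agreement between one study and one records address.

    Returns ``(city_state_ok, street_ok, house_ok)``: city and street
    via approximate matching at tolerance ``d``, state and house number
    exactly.  A missing (empty) component on either side never agrees.
    """
    city_state = (
        bool(study.city)
        and bool(study.state)
        and study.state == rec.state
        and approx_equal(study.city, rec.city, d)
    )
    street = (
        bool(study.street_name)
        and bool(rec.street_name)
        and approx_equal(study.street_name, rec.street_name, d)
    )
    house = bool(study.house_number) and study.house_number == rec.house_number
    return city_state, street, house


def match_level(
    study: AddressRecord,
    records: Sequence[AddressRecord],
    level: str,
    d: int,
) -> bool:
    """Does any same-subject records address match the study address at ``level``?

    Levels are nested: ``city_state`` requires city (approximate) and
    state (exact); ``street`` additionally the street name (approximate);
    ``detailed`` additionally the house number (exact).  A study row
    missing a component required by the level returns ``False``.
    """
    if level not in MATCH_LEVELS:
        raise ValueError(f"unknown match level: {level!r}")
    for rec in records:
        city_state, street, house = compare_components(study, rec, d)
        if not city_state:
            continue
        if level == "city_state":
            return True
        if not street:
            continue
        if level == "street":
            return True
        if house:
            return True
    return False
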