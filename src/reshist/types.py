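"""Core domain types for residential-history concordance assessment.

Time convention
---------------
All occupancy arithmetic is done on a fractional-year axis.  Study
addresses carry a first-seen *year* (optionally a month); a year-only
date is placed at mid-year (July 1), a month is placed at the first of
the month.  Public-records addresses carry first-seen / last-seen
month-year pairs that are interpreted as whole-month intervals: the
first-seen month contributes from its first day, the last-seen month
through its last day.  Under this convention July of year ``y`` starts
at exactly ``y + 0.5``, so a records spell can reproduce a study spell
boundary exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

Frame = Literal["planar-feet", "lon-lat"]

SOURCE_STUDY = "study"
SOURCE_RECORDS = "records"


def date_to_time(year: int, month: Optional[int] = None) -> float:
    """Fractional-year position of a date: month start, or July 1 if year-only."""
    if month is None:
        return year + 0.5
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return year + (month - 1) / 12.0


def month_end_time(year: int, month: int) -> float:
    """Fractional-year position of the *end* of a month (exclusive bound)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return year + month / 12.0


def time_to_year_month(t: float) -> tuple[int, int]:
    """Calendar (year, month) containing fractional-year instant ``t``."""
    year = int(t // 1)
    month = int((t - year) * 12 + 1e-9) + 1
    if month > 12:  # guard against t == year + 1 - eps rounding up
        year, month = year + 1, 1
    return year, month


@dataclass(frozen=True)
class StudyWindow:
    """Follow-up window of the cohort, in calendar years (inclusive)."""

    start: int = 1995
    end: int = 2013

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must precede end")

    @property
    def t0(self) -> float:
        """Window opening instant (Jan 1 of the start year)."""
        return float(self.start)

    @property
    def t_end(self) -> float:
        """Window closing instant for records intervals (Dec 31 of the end year)."""
        return self.end + 1.0

    @property
    def t_study_end(self) -> float:
        """Terminal instant of the study sequence (mid final follow-up year)."""
        return self.end + 0.5

    @property
    def n_years(self) -> int:
        return self.end - self.start + 1

    @property
    def years(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class AddressRecord:
    """One address occurrence from either the study or the records source.

    Components are stored in *normalized* form (see
    :func:`reshist.matching.normalize_component`); temporal fields at
    month resolution (``first_month`` is ``None`` for year-only study
    rows).  ``last_year``/``last_month`` are present only for records
    rows.
    """

    subject_id: str
    house_number: str
    street_name: str
    city: str
    state: str
    first_year: int
    first_month: Optional[int] = None
    last_year: Optional[int] = None
    last_month: Optional[int] = None
    x: Optional[float] = None
    y: Optional[float] = None
    frame: Optional[Frame] = None
    source: str = SOURCE_STUDY

    def __post_init__(self) -> None:
        if not self.state:
            raise ValueError("state must be nonempty")
        if not self.city:
            raise ValueError("city must be nonempty")
        if self.last_year is not None:
            if self.first_time > self.last_end_time:
                raise ValueError(
                    f"first_seen after last_seen for subject {self.subject_id}"
                )

    @property
    def first_time(self) -> float:
        return date_to_time(self.first_year, self.first_month)

    @property
    def last_end_time(self) -> Optional[float]:
        """Exclusive end of the last-seen month (records rows only)."""
        if self.last_year is None:
            return None
        return month_end_time(self.last_year, self.last_month or 12)

    @property
    def has_point(self) -> bool:
        return self.x is not None and self.y is not None

    def detail_key(self) -> tuple[str, str, str, str]:
        """Equality key for duplicate collapsing: all four components."""
        return (self.house_number, self.street_name, self.city, self.state)


@dataclass
class Spell:
    """A study address with its occupancy interval on the fractional-year axis."""

    record: AddressRecord
    start: float
    end: float
    clipped: bool = False

    @property
    def duration(self) -> float:
        return max(self.end - self.start, 0.0)


@dataclass
class SubjectHistory:
    """Ordered, consecutive-duplicate-collapsed spells for one subject."""

    subject_id: str
    spells: list[Spell]

    def __post_init__(self) -> None:
        if not self.spells:
            raise ValueError(f"subject {self.subject_id} has no spells")

    @property
    def n_i(self) -> int:
        """Number of unique study addresses for the subject."""
        return len(self.spells)


@dataclass(frozen=True)
class EditParam:
    """Tuned edit-distance tolerance with its selection context."""

    d: int
    candidate_set: tuple[int, ...]
    error_rate: float

    def __post_init__(self) -> None:
        if self.d not in self.candidate_set:
            raise ValueError("selected d must come from the candidate set")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")


@dataclass(frozen=True)
class TuningSubject:
    """City strings for one subject plus the true number of distinct cities."""

    subject_id: str
    strings: tuple[str, ...]
    true_unique_count: int

    def __post_init__(self) -> None:
        if not self.strings:
            raise ValueError(f"tuning subject {self.subject_id} has no strings")
        if not 1 <= self.true_unique_count <= len(self.strings):
            raise ValueError("true_unique_count out of range")


@dataclass
class MatchVector:
    """Binary match indicators m_i for unique study addresses at one level.

    ``entries`` holds ``(subject_id, address_index, m)`` triples; ``N``
    is the total number of unique study addresses in the denominator and
    ``n`` the number of subjects contributing to it.
    """

    level: str
    entries: list[tuple[str, int, int]]

    @property
    def N(self) -> int:
        return len(self.entries)

    @property
    def n(self) -> int:
        return len({sid for sid, _, _ in self.entries})


@dataclass
class MetricReport:
    """Result container for one agreement metric."""

    metric: int
    name: str
    overall_rate: Optional[float] = None
    mean_rate: Optional[float] = None
    distribution: Optional[dict[str, float]] = None
    per_year: Optional["pd.DataFrame"] = None  # noqa: F821 - forward ref, pandas
    per_stratum: Optional["pd.DataFrame"] = None  # noqa: F821
    histogram: Optional["pd.DataFrame"] = None  # noqa: F821
    counts: dict[str, int] = field(default_factory=dict)

    def as_rows(self) -> Iterator[dict]:
        """Flatten to (metric, statistic, value) rows for CSV output."""
        if self.overall_rate is not None:
            yield {"metric": self.metric, "statistic": "overall_rate", "value": self.overall_rate}
        if self.mean_rate is not None:
            yield {"metric": self.metric, "statistic": "mean_rate", "value": self.mean_rate}
        if self.distribution:
            for k, v in self.distribution.items():
                yield {"metric": self.metric, "statistic": k, "value": v}
        for k, v in self.counts.items():
            yield {"metric": self.metric, "statistic": k, "value": v}


def summarize_distribution(values: Sequence[float]) -> dict[str, float]:
    """Five-number summary plus mean (min, Q1, median, Q3, max, mean)."""
    import numpy as np

    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty distribution")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "min": float(arr.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
    }
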