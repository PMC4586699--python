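"""Agreement metrics between a study address history and a records history.

Eleven metrics quantify how well a public-records address history
reproduces a study-collected one:

1.  city + state match rate,
2.  city + state + street match rate,
3.  detailed match rate (city, state, street, house number),
4.  distribution of years spent at each address, per source,
5.  proportion of study time covered by records, matched addresses only,
6.  distribution of the per-address duration difference
    (records minus study),
7.  mean proportion of each subject's total study time covered,
8.  most-recent address match rate,
9.  baseline (enrollment-year) address match rate,
10. per-calendar-year match rate of study addresses,
11. spatial match rate (records point within a distance threshold of the
    study point).

Rates come in two aggregations.  With ``n`` subjects, subject ``i``
holding ``n_i`` unique addresses and ``m_j`` the binary match indicator
of an address, the *overall* rate pools all ``N = Σ n_i`` addresses::

    overall = Σ m_j / N

while the *mean* rate averages per-subject proportions, weighting
subjects equally::

    mean = (1/n) Σ_i ( Σ_{j in i} m_j / n_i )

Metrics 5–10 use the detailed match.  "Time covered" is calendar
interval intersection (a drifted records spell that still overlaps the
study spell covers the overlapping part), computed on the fractional
year axis described in :mod:`reshist.types`, with all records intervals
clipped to the study window.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .matching import compare_components
from .types import (
    AddressRecord,
    MatchVector,
    MetricReport,
    Spell,
    StudyWindow,
    SubjectHistory,
    summarize_distribution,
)

logger = logging.getLogger(__name__)

#: Minimum credible records spell length in years (one month); guards
#: ratio metrics against degenerate same-month spells.
RECORDS_DURATION_FLOOR = 1.0 / 12.0

#: Default spatial match threshold in feet.
DEFAULT_SPATIAL_THRESHOLD_FT = 100.0

_FEET_PER_METER = 1.0 / 0.3048
_EARTH_RADIUS_FT = 6_371_008.8 * _FEET_PER_METER

METRIC_NAMES = {
    1: "City and state match",
    2: "Street match",
    3: "Detailed match",
    4: "Years at address",
    5: "Years at matched address",
    6: "Difference in time at matched address",
    7: "Time covered",
    8: "Most recent address match",
    9: "Baseline address match",
    10: "Match by year of follow-up",
    11: "Spatial match",
}


# ---------------------------------------------------------------------------
# Spell construction


def build_spells(
    rows: Sequence[AddressRecord], window: StudyWindow
) -> SubjectHistory:
    """Turn one subject's study rows into occupancy spells.

    Rows are taken in first-seen order; consecutive rows reporting the
    same detailed address are collapsed keeping the earliest first-seen.
    Each spell runs until the next spell's first-seen; the last spell
    runs to the window's study end.  Spells are clipped to the window
    (an address first seen before the window is treated as occupied at
    the window opening, with a clip flag).
    """
    if not rows:
        raise ValueError("cannot build spells from zero rows")
    sid = rows[0].subject_id
    if any(r.subject_id != sid for r in rows):
        raise ValueError("build_spells expects rows for a single subject")
    ordered = sorted(rows, key=lambda r: r.first_time)

    collapsed: list[AddressRecord] = []
    for r in ordered:
        if collapsed and r.detail_key() == collapsed[-1].detail_key():
            continue  # duplicate update of the same address; keep earliest
        collapsed.append(r)

    t0, t_end = window.t0, window.t_study_end
    starts, flags = [], []
    for r in collapsed:
        t = r.first_time
        clipped = t < t0 or t > t_end
        starts.append(min(max(t, t0), t_end))
        flags.append(clipped)
    # monotone guard: a lagged update can not precede its predecessor
    for k in range(1, len(starts)):
        starts[k] = max(starts[k], starts[k - 1])

    spells = []
    for k, r in enumerate(collapsed):
        end = starts[k + 1] if k + 1 < len(collapsed) else t_end
        spells.append(Spell(record=r, start=starts[k], end=max(end, starts[k]), clipped=flags[k]))
    return SubjectHistory(subject_id=sid, spells=spells)


def build_histories(
    rows: Iterable[AddressRecord], window: StudyWindow
) -> dict[str, SubjectHistory]:
    """Group study rows by subject and build every subject's spells."""
    by_subject: dict[str, list[AddressRecord]] = defaultdict(list)
    for r in rows:
        by_subject[r.subject_id].append(r)
    return {sid: build_spells(rs, window) for sid, rs in by_subject.items()}


def records_interval(
    rec: AddressRecord, window: StudyWindow
) -> Optional[tuple[float, float]]:
    """Clip a records row's observation interval to the window.

    Returns ``None`` when the row lies entirely outside the window.
    The clipped duration is floored at one month.
    """
    if rec.last_year is None:
        raise ValueError("records row lacks a last-seen date")
    s = max(rec.first_time, window.t0)
    e = min(rec.last_end_time, window.t_end)  # type: ignore[arg-type]
    if e <= s:
        if rec.first_time >= window.t_end or rec.last_end_time <= window.t0:
            return None
        e = s  # degenerate sliver exactly on the boundary
    if e - s < RECORDS_DURATION_FLOOR:
        e = s + RECORDS_DURATION_FLOOR
    return (s, e)


def _union_intersection(
    spell_start: float, spell_end: float, intervals: Sequence[tuple[float, float]]
) -> float:
    """Length of spell ∩ union(intervals) — calendar time covered."""
    clipped = sorted(
        (max(s, spell_start), min(e, spell_end))
        for s, e in intervals
        if min(e, spell_end) > max(s, spell_start)
    )
    covered = 0.0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


# ---------------------------------------------------------------------------
# Per-address matching results


@dataclass
class SpellMatch:
    """Match outcome for one unique study address (one spell)."""

    subject_id: str
    index: int
    state: str
    city: str
    start: float
    end: float
    t_study: float
    complete_street: bool
    complete_house: bool
    m_city_state: bool = False
    m_street: bool = False
    m_detailed: bool = False
    covered: float = 0.0
    best_rec_duration: Optional[float] = None
    spatial: Optional[bool] = None  # None when the study point is missing
    is_last: bool = False
    is_baseline: bool = False


def _point_distance_ft(
    ax: float, ay: float, bx: float, by: float, frame: str
) -> float:
    if frame == "planar-feet":
        return math.hypot(ax - bx, ay - by)
    if frame == "lon-lat":
        lon1, lat1, lon2, lat2 = map(math.radians, (ax, ay, bx, by))
        h = (
            math.sin((lat2 - lat1) / 2) ** 2
            + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
        )
        return 2 * _EARTH_RADIUS_FT * math.asin(min(1.0, math.sqrt(h)))
    raise ValueError(f"unknown coordinate frame: {frame!r}")


def _resolve_frame(records: Iterable[AddressRecord]) -> Optional[str]:
    frames = {r.frame for r in records if r.has_point and r.frame is not None}
    if len(frames) > 1:
        raise ValueError(f"mixed coordinate frames without conversion: {frames}")
    return frames.pop() if frames else None


def match_spells(
    history: SubjectHistory,
    records: Sequence[AddressRecord],
    d: int,
    window: StudyWindow,
    spatial_threshold_ft: float = DEFAULT_SPATIAL_THRESHOLD_FT,
    frame: Optional[str] = None,
) -> list[SpellMatch]:
    """Match every spell of one subject against the subject's records rows.

    Component matching (Metrics 1–3 and the detailed match reused by
    Metrics 5–10) considers all records rows; time coverage uses only
    the rows' window-clipped observation intervals.  The Metric 6
    duration is taken from the single matching records spell with the
    largest calendar overlap (ties to the earliest).
    """
    if spatial_threshold_ft <= 0:
        raise ValueError("spatial threshold must be positive")
    rec_points = [
        (r.x, r.y) for r in records if r.has_point
    ]
    out = []
    n_spells = len(history.spells)
    for j, spell in enumerate(history.spells):
        study = spell.record
        sm = SpellMatch(
            subject_id=history.subject_id,
            index=j,
            state=study.state,
            city=study.city,
            start=spell.start,
            end=spell.end,
            t_study=spell.duration,
            complete_street=bool(study.street_name),
            complete_house=bool(study.house_number),
            is_last=(j == n_spells - 1),
            is_baseline=(j == 0),
        )
        matched_intervals: list[tuple[float, float]] = []
        for rec in records:
            city_state, street, house = compare_components(study, rec, d)
            sm.m_city_state |= city_state
            sm.m_street |= city_state and street
            if city_state and street and house:
                sm.m_detailed = True
                iv = records_interval(rec, window)
                if iv is not None:
                    matched_intervals.append(iv)
        if sm.m_detailed and matched_intervals:
            sm.covered = _union_intersection(spell.start, spell.end, matched_intervals)
            # best-overlap records spell for the duration difference
            def _overlap(iv: tuple[float, float]) -> float:
                return max(0.0, min(iv[1], spell.end) - max(iv[0], spell.start))

            best = max(matched_intervals, key=lambda iv: (_overlap(iv), -iv[0]))
            sm.best_rec_duration = best[1] - best[0]
        if study.has_point:
            sm.spatial = any(
                _point_distance_ft(study.x, study.y, px, py, frame or "planar-feet")
                <= spatial_threshold_ft
                for px, py in rec_points
            )
        out.append(sm)
    return out


# ---------------------------------------------------------------------------
# Rate aggregation (the two aggregations used throughout)


def rates(mv: MatchVector) -> tuple[float, float]:
    """Overall (pooled) and mean-over-subjects match rates of a match vector."""
    if mv.N == 0:
        raise ValueError("empty match vector")
    overall = sum(m for _, _, m in mv.entries) / mv.N
    per_subject: dict[str, list[int]] = defaultdict(list)
    for sid, _, m in mv.entries:
        per_subject[sid].append(m)
    mean = float(np.mean([np.mean(ms) for ms in per_subject.values()]))
    return overall, mean


def _match_vector(
    matches: Sequence[SpellMatch],
    level: str,
) -> MatchVector:
    """Assemble the m_i vector for a level, excluding incomplete addresses.

    Addresses missing a component the level requires are excluded from
    the denominator (they reflect data incompleteness, not matching
    failure) and tallied separately by the caller.
    """
    entries = []
    for sm in matches:
        if level in ("street", "detailed") and not sm.complete_street:
            continue
        if level == "detailed" and not sm.complete_house:
            continue
        m = {"city_state": sm.m_city_state, "street": sm.m_street, "detailed": sm.m_detailed}[level]
        entries.append((sm.subject_id, sm.index, int(m)))
    return MatchVector(level=level, entries=entries)


# ---------------------------------------------------------------------------
# Time metrics


def duration_distribution(durations: Sequence[float]) -> dict[str, float]:
    """Five-number summary plus mean of per-address durations (years)."""
    return summarize_distribution(durations)


def matched_time_coverage(
    matches: Sequence[SpellMatch],
) -> Optional[tuple[float, float]]:
    """Proportion of study time covered by records, matched addresses only.

    Overall: pooled covered time over pooled study time of matched
    addresses.  Mean: per-subject coverage ratios averaged over subjects
    holding at least one matched address with positive study time.
    Returns ``None`` when nothing matched.
    """
    pairs = [sm for sm in matches if sm.m_detailed and sm.t_study > 0]
    if not pairs:
        return None
    overall = sum(sm.covered for sm in pairs) / sum(sm.t_study for sm in pairs)
    per_subject: dict[str, list[SpellMatch]] = defaultdict(list)
    for sm in pairs:
        per_subject[sm.subject_id].append(sm)
    ratios = [
        sum(s.covered for s in sms) / sum(s.t_study for s in sms)
        for sms in per_subject.values()
    ]
    return overall, float(np.mean(ratios))


def time_difference_distribution(
    matches: Sequence[SpellMatch],
    bin_edges: Optional[np.ndarray] = None,
) -> Optional[tuple[dict[str, float], pd.DataFrame]]:
    """Distribution of records-minus-study duration at matched addresses.

    Returns the summary plus a histogram table (year-wide bins centred
    on integers) ready for plotting; ``None`` when nothing matched.
    """
    diffs = [
        sm.best_rec_duration - sm.t_study
        for sm in matches
        if sm.m_detailed and sm.best_rec_duration is not None
    ]
    if not diffs:
        return None
    if bin_edges is None:
        bin_edges = np.arange(-19.5, 20.5, 1.0)
    counts, edges = np.histogram(diffs, bins=bin_edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return summarize_distribution(diffs), hist


def subject_time_covered(
    matches: Sequence[SpellMatch],
) -> tuple[Optional[float], int]:
    """Mean proportion of each subject's total study time covered by records.

    All study addresses enter the denominator; unmatched addresses
    contribute zero covered time.  Subjects with zero total study time
    are excluded; their count is returned alongside the mean.
    """
    per_subject: dict[str, list[SpellMatch]] = defaultdict(list)
    for sm in matches:
        per_subject[sm.subject_id].append(sm)
    ratios = []
    n_zero = 0
    for sms in per_subject.values():
        total = sum(s.t_study for s in sms)
        if total <= 0:
            n_zero += 1
            continue
        ratios.append(sum(s.covered for s in sms) / total)
    if n_zero:
        logger.info("subject_time_covered: excluded %d zero-time subjects", n_zero)
    return (float(np.mean(ratios)) if ratios else None), n_zero


def endpoint_matches(matches: Sequence[SpellMatch]) -> tuple[float, float]:
    """Fractions of subjects whose most recent / baseline address matched."""
    last: dict[str, bool] = {}
    first: dict[str, bool] = {}
    for sm in matches:
        if sm.is_last:
            last[sm.subject_id] = sm.m_detailed
        if sm.is_baseline:
            first[sm.subject_id] = sm.m_detailed
    if not last:
        raise ValueError("no subjects")
    most_recent = sum(last.values()) / len(last)
    baseline = sum(first.values()) / len(first)
    return most_recent, baseline


def match_by_year(
    matches: Sequence[SpellMatch], window: StudyWindow
) -> pd.DataFrame:
    """Detailed match rate of study addresses by calendar year of follow-up.

    An address contributes to year ``y`` when its spell overlaps the
    calendar year; in a move year both the outgoing and incoming address
    are occupied, so both count (``count``).  The alternative
    denominator assigning a move year to the incoming address only
    (occupancy at mid-year) is exposed as ``count_single``.
    """
    rows = []
    for y in window.years:
        occupied = [
            sm for sm in matches if min(sm.end, y + 1.0) > max(sm.start, float(y))
        ]
        single = [sm for sm in matches if sm.start <= y + 0.5 < sm.end]
        n_match = sum(sm.m_detailed for sm in occupied)
        rows.append(
            {
                "year": y,
                "count": len(occupied),
                "count_single": len(single),
                "matched": n_match,
                "percent": 100.0 * n_match / len(occupied) if occupied else np.nan,
            }
        )
    return pd.DataFrame(rows)


def spatial_match(
    matches: Sequence[SpellMatch],
) -> Optional[tuple[float, float, int]]:
    """Eq.-style overall and mean rates of the point-proximity match.

    Addresses without a study point are excluded (their count is
    returned); a subject with no records points simply never matches.
    """
    entries = [
        (sm.subject_id, sm.index, int(sm.spatial))
        for sm in matches
        if sm.spatial is not None
    ]
    n_missing = sum(1 for sm in matches if sm.spatial is None)
    if not entries:
        return None
    overall, mean = rates(MatchVector(level="spatial", entries=entries))
    return overall, mean, n_missing


# ---------------------------------------------------------------------------
# Stratification


def stratify(
    matches: Sequence[SpellMatch],
    key: Callable[[SpellMatch], Hashable],
    level: str = "detailed",
) -> pd.DataFrame:
    """Match rates of one level computed within strata of study addresses.

    Strata are assigned by the *study* address attribute (e.g. its
    state).  Strata with zero contributing addresses are simply absent
    from the output; counts are included so sparsely populated strata
    are visible.
    """
    groups: dict[Hashable, list[SpellMatch]] = defaultdict(list)
    for sm in matches:
        groups[key(sm)].append(sm)
    rows = []
    for stratum in sorted(groups, key=str):
        mv = _match_vector(groups[stratum], level)
        if mv.N == 0:
            continue
        overall, mean = rates(mv)
        rows.append(
            {
                "stratum": stratum,
                "n_addresses": mv.N,
                "n_subjects": mv.n,
                "overall_rate": overall,
                "mean_rate": mean,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class AssessmentResult:
    """All metric reports from one study-vs-records comparison."""

    reports: dict[int, MetricReport]
    matches: list[SpellMatch]
    window: StudyWindow
    d: int
    n_subjects: int
    per_state: pd.DataFrame = field(default_factory=pd.DataFrame)

    def table(self) -> pd.DataFrame:
        """Flat metric × statistic table (machine-readable report)."""
        rows = []
        for rep in self.reports.values():
            rows.extend(rep.as_rows())
        return pd.DataFrame(rows)


def run_metrics(
    study_rows: Sequence[AddressRecord],
    records_rows: Sequence[AddressRecord],
    d: int,
    window: StudyWindow = StudyWindow(),
    spatial_threshold_ft: float = DEFAULT_SPATIAL_THRESHOLD_FT,
    strata_key: Optional[Callable[[SpellMatch], Hashable]] = None,
) -> AssessmentResult:
    """Compute all eleven agreement metrics for a study/records file pair.

    ``d`` is the tuned edit-distance tolerance used for city and street
    comparisons.  Subjects are defined by the study file; a subject
    absent from the records file keeps all its addresses with m = 0
    (nonappearance is a retrieval failure the metrics should reflect).
    """
    frame = _resolve_frame(list(study_rows) + list(records_rows))
    histories = build_histories(study_rows, window)
    recs_by_subject: dict[str, list[AddressRecord]] = defaultdict(list)
    for r in records_rows:
        recs_by_subject[r.subject_id].append(r)

    matches: list[SpellMatch] = []
    for sid in sorted(histories):
        matches.extend(
            match_spells(
                histories[sid],
                recs_by_subject.get(sid, []),
                d,
                window,
                spatial_threshold_ft,
                frame,
            )
        )

    reports: dict[int, MetricReport] = {}
    n_incomplete_street = sum(1 for sm in matches if not sm.complete_street)
    n_incomplete_house = sum(1 for sm in matches if not sm.complete_house)

    for metric, level in ((1, "city_state"), (2, "street"), (3, "detailed")):
        mv = _match_vector(matches, level)
        overall, mean = rates(mv)
        counts = {"n_addresses": mv.N, "n_subjects": mv.n}
        if metric >= 2:
            counts["n_incomplete_excluded"] = (
                n_incomplete_street
                if metric == 2
                else n_incomplete_street + n_incomplete_house
            )
        reports[metric] = MetricReport(
            metric=metric,
            name=METRIC_NAMES[metric],
            overall_rate=overall,
            mean_rate=mean,
            counts=counts,
        )

    study_durations = [sm.t_study for sm in matches]
    rec_durations = []
    for sid, recs in recs_by_subject.items():
        if sid not in histories:
            continue
        for r in recs:
            iv = records_interval(r, window)
            if iv is not None:
                rec_durations.append(iv[1] - iv[0])
    m4 = MetricReport(metric=4, name=METRIC_NAMES[4])
    m4.distribution = {
        f"study_{k}": v for k, v in duration_distribution(study_durations).items()
    }
    if rec_durations:
        m4.distribution.update(
            {f"records_{k}": v for k, v in duration_distribution(rec_durations).items()}
        )
    reports[4] = m4

    m5 = MetricReport(metric=5, name=METRIC_NAMES[5])
    cov = matched_time_coverage(matches)
    if cov is not None:
        m5.overall_rate, m5.mean_rate = cov
    reports[5] = m5

    m6 = MetricReport(metric=6, name=METRIC_NAMES[6])
    td = time_difference_distribution(matches)
    if td is not None:
        m6.distribution, m6.histogram = td
    reports[6] = m6

    m7_mean, n_zero = subject_time_covered(matches)
    reports[7] = MetricReport(
        metric=7,
        name=METRIC_NAMES[7],
        mean_rate=m7_mean,
        counts={"n_zero_time_excluded": n_zero},
    )

    most_recent, baseline = endpoint_matches(matches)
    reports[8] = MetricReport(metric=8, name=METRIC_NAMES[8], mean_rate=most_recent)
    reports[9] = MetricReport(metric=9, name=METRIC_NAMES[9], mean_rate=baseline)

    per_year = match_by_year(matches, window)
    reports[10] = MetricReport(metric=10, name=METRIC_NAMES[10], per_year=per_year)

    m11 = MetricReport(metric=11, name=METRIC_NAMES[11])
    sp = spatial_match(matches)
    if sp is not None:
        m11.overall_rate, m11.mean_rate = sp[0], sp[1]
        m11.counts["n_missing_points"] = sp[2]
    reports[11] = m11

    per_state = stratify(matches, key=lambda sm: sm.state, level="detailed")
    if strata_key is not None:
        reports[3].per_stratum = stratify(matches, key=strata_key, level="detailed")

    return AssessmentResult(
        reports=reports,
        matches=matches,
        window=window,
        d=d,
        n_subjects=len(histories),
        per_state=per_state,
    )
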