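"""CSV contracts, run configuration and the end-to-end assessment driver.

Input contracts (comma-separated, UTF-8, mandatory header, dates as ISO
year-month):

``study_addresses.csv``
    subject_id, seq, house_number, street_name, city, state,
    first_seen_year [, first_seen_month] [, x, y, frame]

``records_addresses.csv``
    subject_id, house_number, street_name, city, state,
    first_seen (YYYY-MM), last_seen (YYYY-MM) [, x, y, frame]

Tuning inputs: ``tuning_sample.csv`` (subject_id, city_string) and
``tuning_truth.csv`` (subject_id, true_unique_count).

Components are normalized on read; malformed rows are rejected with
line-numbered diagnostics rather than aborting the run, except for a
missing required column, which is a hard error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .matching import (
    DEFAULT_CANDIDATES,
    normalize_component,
    normalize_house_number,
    normalize_state,
    select_edit_param,
)
from .metrics import (
    DEFAULT_SPATIAL_THRESHOLD_FT,
    AssessmentResult,
    run_metrics,
)
from .types import AddressRecord, EditParam, StudyWindow, TuningSubject

logger = logging.getLogger(__name__)

_YM_RE = re.compile(r"^(\d{4})[-/]?(\d{1,2})$")

STUDY_REQUIRED = ["subject_id", "house_number", "street_name", "city", "state", "first_seen_year"]
RECORDS_REQUIRED = ["subject_id", "house_number", "street_name", "city", "state", "first_seen", "last_seen"]


@dataclass
class ReadReport:
    """Parse diagnostics for one input file."""

    path: str
    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def log(self) -> None:
        for line, reason in self.rejected:
            logger.warning("%s line %d rejected: %s", self.path, line, reason)
        if self.rejected:
            logger.warning(
                "%s: %d of %d rows rejected", self.path, len(self.rejected), self.n_rows
            )


def _parse_year_month(value) -> tuple[int, int]:
    m = _YM_RE.match(str(value).strip())
    if not m:
        raise ValueError(f"unparseable year-month: {value!r}")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range in {value!r}")
    return year, month


def _opt_point(row) -> tuple[Optional[float], Optional[float], Optional[str]]:
    x = row.get("x")
    y = row.get("y")
    if x is None or y is None or pd.isna(x) or pd.isna(y):
        return None, None, None
    frame = row.get("frame")
    frame = "planar-feet" if frame is None or pd.isna(frame) else str(frame)
    if frame not in ("planar-feet", "lon-lat"):
        raise ValueError(f"unknown coordinate frame: {frame!r}")
    return float(x), float(y), frame


def study_records_from_frame(
    df: pd.DataFrame, origin: str = "<frame>"
) -> tuple[list[AddressRecord], ReadReport]:
    """Parse and normalize study rows from a contract DataFrame."""
    missing = [c for c in STUDY_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{origin}: missing required column(s): {', '.join(missing)}")
    report = ReadReport(path=origin, n_rows=len(df))
    out: list[AddressRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # 1-based with header
        try:
            month = row.get("first_seen_month")
            month = None if month is None or pd.isna(month) else int(month)
            x, y, frame = _opt_point(row)
            out.append(
                AddressRecord(
                    subject_id=str(row["subject_id"]),
                    house_number=normalize_house_number(str(row["house_number"])),
                    street_name=normalize_component(str(row["street_name"])),
                    city=normalize_component(str(row["city"])),
                    state=normalize_state(str(row["state"])),
                    first_year=int(row["first_seen_year"]),
                    first_month=month,
                    x=x, y=y, frame=frame,
                    source="study",
                )
            )
        except (ValueError, TypeError) as exc:
            report.rejected.append((line, str(exc)))
    report.n_accepted = len(out)
    report.log()
    return out, report


def records_records_from_frame(
    df: pd.DataFrame, origin: str = "<frame>"
) -> tuple[list[AddressRecord], ReadReport]:
    """Parse and normalize public-records rows from a contract DataFrame."""
    missing = [c for c in RECORDS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{origin}: missing required column(s): {', '.join(missing)}")
    report = ReadReport(path=origin, n_rows=len(df))
    out: list[AddressRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2
        try:
            fy, fm = _parse_year_month(row["first_seen"])
            ly, lm = _parse_year_month(row["last_seen"])
            x, y, frame = _opt_point(row)
            out.append(
                AddressRecord(
                    subject_id=str(row["subject_id"]),
                    house_number=normalize_house_number(str(row["house_number"])),
                    street_name=normalize_component(str(row["street_name"])),
                    city=normalize_component(str(row["city"])),
                    state=normalize_state(str(row["state"])),
                    first_year=fy, first_month=fm,
                    last_year=ly, last_month=lm,
                    x=x, y=y, frame=frame,
                    source="records",
                )
            )
        except (ValueError, TypeError) as exc:
            report.rejected.append((line, str(exc)))
    report.n_accepted = len(out)
    report.log()
    return out, report


def read_address_csv(
    path: str | Path, source: str
) -> tuple[list[AddressRecord], ReadReport]:
    """Read one address CSV (``source`` is ``"study"`` or ``"records"``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if source == "study":
        return study_records_from_frame(df, origin=str(path))
    if source == "records":
        return records_records_from_frame(df, origin=str(path))
    raise ValueError(f"unknown source: {source!r}")


def write_address_csv(records: Sequence[AddressRecord], path: str | Path) -> None:
    """Write normalized address records back under the matching contract."""
    if not records:
        raise ValueError("nothing to write")
    is_study = records[0].last_year is None
    rows = []
    seq_counter: dict[str, int] = {}
    for r in records:
        base = {
            "subject_id": r.subject_id,
            "house_number": r.house_number,
            "street_name": r.street_name,
            "city": r.city,
            "state": r.state,
            "x": r.x,
            "y": r.y,
            "frame": r.frame,
        }
        if is_study:
            seq = seq_counter.get(r.subject_id, 0)
            seq_counter[r.subject_id] = seq + 1
            base["seq"] = seq
            base["first_seen_year"] = r.first_year
            base["first_seen_month"] = r.first_month if r.first_month else ""
        else:
            base["first_seen"] = f"{r.first_year:04d}-{r.first_month or 1:02d}"
            base["last_seen"] = f"{r.last_year:04d}-{r.last_month or 12:02d}"
        rows.append(base)
    cols = (
        ["subject_id", "seq", "house_number", "street_name", "city", "state",
         "first_seen_year", "first_seen_month", "x", "y", "frame"]
        if is_study
        else ["subject_id", "house_number", "street_name", "city", "state",
              "first_seen", "last_seen", "x", "y", "frame"]
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.4f")


def read_tuning(
    sample_path: str | Path, truth_path: str | Path
) -> list[TuningSubject]:
    """Read the tuning sample and its unique-city truth, normalizing strings."""
    sample = pd.read_csv(sample_path, dtype=str)
    truth = pd.read_csv(truth_path, dtype={"subject_id": str, "true_unique_count": int})
    counts = dict(zip(truth["subject_id"], truth["true_unique_count"]))
    subjects = []
    for sid, grp in sample.groupby("subject_id", sort=True):
        if sid not in counts:
            raise ValueError(f"tuning subject {sid} lacks a true unique count")
        strings = tuple(normalize_component(s) for s in grp["city_string"])
        subjects.append(
            TuningSubject(subject_id=sid, strings=strings, true_unique_count=counts[sid])
        )
    return subjects


# ---------------------------------------------------------------------------
# Assessment driver


@dataclass(frozen=True)
class RunConfig:
    """Everything one assessment run needs."""

    study_path: str
    records_path: str
    tuning_sample_path: Optional[str] = None
    tuning_truth_path: Optional[str] = None
    candidates: tuple[int, ...] = DEFAULT_CANDIDATES
    fixed_d: Optional[int] = None
    spatial_threshold_ft: float = DEFAULT_SPATIAL_THRESHOLD_FT
    window_start: int = 1995
    window_end: int = 2013
    strata: Optional[str] = None  # None | "state" | "state:<CODE>"
    out_dir: str = "reshist_out"

    def __post_init__(self) -> None:
        if self.spatial_threshold_ft <= 0:
            raise ValueError("spatial threshold must be positive")
        StudyWindow(self.window_start, self.window_end)  # validates

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(self.window_start, self.window_end)


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _pct(x: Optional[float]) -> str:
    return "-" if x is None else f"{100 * x:.1f}%"


def render_summary(result: AssessmentResult, edit_param: Optional[EditParam]) -> str:
    """Human-readable summary mirroring the tabular layout of the metrics."""
    lines = []
    lines.append("Residential-history concordance assessment")
    lines.append(f"  window: {result.window.start}-{result.window.end}; "
                 f"subjects: {result.n_subjects}; edit-distance tolerance d={result.d}")
    if edit_param is not None:
        lines.append(
            f"  tuned over candidates {list(edit_param.candidate_set)}, "
            f"tuning error rate {100 * edit_param.error_rate:.1f}%"
        )
    lines.append("")
    lines.append("Match rates (overall over addresses / mean over subjects)")
    for k in (1, 2, 3):
        rep = result.reports[k]
        lines.append(
            f"  Metric {k} {rep.name:<28s} {_pct(rep.overall_rate):>7s} / {_pct(rep.mean_rate)}"
        )
    rep5 = result.reports[5]
    lines.append(
        f"  Metric 5 {rep5.name:<28s} {_pct(rep5.overall_rate):>7s} / {_pct(rep5.mean_rate)}"
    )
    lines.append("")
    lines.append("Years at each address (min / Q1 / median / Q3 / max / mean)")
    dist = result.reports[4].distribution or {}
    for src in ("study", "records"):
        if f"{src}_mean" in dist:
            lines.append(
                "  {:<8s}".format(src)
                + " / ".join(
                    f"{dist[f'{src}_{k}']:.1f}"
                    for k in ("min", "q1", "median", "q3", "max", "mean")
                )
            )
    d6 = result.reports[6].distribution
    if d6:
        lines.append("Difference in years at matched addresses (records - study)")
        lines.append(
            "  " + " / ".join(f"{d6[k]:.1f}" for k in ("min", "q1", "median", "q3", "max", "mean"))
        )
    lines.append("")
    lines.append(f"Metric 7 time covered (mean over subjects): {_pct(result.reports[7].mean_rate)}")
    lines.append(f"Metric 8 most recent address match:         {_pct(result.reports[8].mean_rate)}")
    lines.append(f"Metric 9 baseline address match:            {_pct(result.reports[9].mean_rate)}")
    rep11 = result.reports[11]
    lines.append(
        f"Metric 11 spatial match:                    {_pct(rep11.overall_rate)} / {_pct(rep11.mean_rate)}"
    )
    lines.append("")
    per_year = result.reports[10].per_year
    if per_year is not None:
        lines.append("Metric 10: match by year of follow-up")
        lines.append("  year  count  matched  percent")
        for _, r in per_year.iterrows():
            pct = "-" if pd.isna(r["percent"]) else f"{r['percent']:.1f}%"
            lines.append(f"  {int(r['year'])}  {int(r['count']):5d}  {int(r['matched']):7d}  {pct:>7s}")
    return "\n".join(lines) + "\n"


def run_assessment(
    cfg: RunConfig,
) -> tuple[AssessmentResult, dict]:
    """Tune, match, compute all metrics, and write the report files.

    Returns the assessment result and the provenance block.  Stages:
    read inputs → select the edit-distance tolerance (tuning sample, or
    ``fixed_d``) → build spells and match at all levels → Metrics 1–11
    (+ strata) → write CSV/JSON/text reports under ``out_dir``.
    """
    study, study_report = read_address_csv(cfg.study_path, "study")
    records, records_report = read_address_csv(cfg.records_path, "records")
    if not study:
        raise ValueError("study file produced no usable rows")

    edit_param: Optional[EditParam] = None
    if cfg.fixed_d is not None:
        d = cfg.fixed_d
    elif cfg.tuning_sample_path and cfg.tuning_truth_path:
        tuning = read_tuning(cfg.tuning_sample_path, cfg.tuning_truth_path)
        edit_param = select_edit_param(tuning, cfg.candidates)
        d = edit_param.d
        logger.info(
            "tuned edit distance d=%d (error rate %.3f)", d, edit_param.error_rate
        )
    else:
        raise ValueError(
            "either fixed_d or a tuning sample (sample + truth paths) is required"
        )

    strata_key = None
    if cfg.strata and cfg.strata.startswith("state:"):
        target = cfg.strata.split(":", 1)[1].upper()
        strata_key = lambda sm, _t=target: _t if sm.state == _t else f"non-{_t}"  # noqa: E731

    result = run_metrics(
        study,
        records,
        d=d,
        window=cfg.window,
        spatial_threshold_ft=cfg.spatial_threshold_ft,
        strata_key=strata_key,
    )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table().to_csv(out / "metrics.csv", index=False)
    per_year = result.reports[10].per_year
    if per_year is not None:
        per_year.to_csv(out / "match_by_year.csv", index=False)
    if not result.per_state.empty:
        result.per_state.to_csv(out / "metric3_by_state.csv", index=False)
    if result.reports[3].per_stratum is not None:
        result.reports[3].per_stratum.to_csv(out / "metric3_by_stratum.csv", index=False)
    hist = result.reports[6].histogram
    if hist is not None:
        hist.to_csv(out / "time_diff_histogram.csv", index=False)
    (out / "summary.txt").write_text(render_summary(result, edit_param))

    provenance = {
        "software_version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "edit_distance_d": d,
        "tuning_error_rate": edit_param.error_rate if edit_param else None,
        "tuning_candidates": list(edit_param.candidate_set) if edit_param else None,
        "study_rows": study_report.n_rows,
        "study_rows_rejected": len(study_report.rejected),
        "records_rows": records_report.n_rows,
        "records_rows_rejected": len(records_report.rejected),
        "n_subjects": result.n_subjects,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return result, provenance
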