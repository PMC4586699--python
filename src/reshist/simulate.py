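"""Synthetic residential mobility, study follow-up and records degradation.

The generator produces three linked views of the same underlying truth
so the whole assessment pipeline can be exercised without any external
data:

* **truth** — per subject, a residential history tiling the follow-up
  window without gaps: a per-year Bernoulli move process (annual move
  probability 0.117, matching U.S. one-year mover rates, which gives
  geometric residence durations with median ≈ ln 2 / 0.117 ≈ 5.9 years)
  over a synthetic geography of states, cities and streets with planar
  coordinates.  Moves are placed at mid-year so the year-resolution
  study view and the month-resolution records view align exactly when
  degradation is switched off.
* **study view** — the gold standard: components copied verbatim, but
  each post-baseline address carries a *first-seen year* equal to the
  move year plus an update lag (the recorded year is the address update
  year, not necessarily the change year).
* **records view** — a degraded extract: recall limited to the most
  recent ``recall_depth`` addresses (the "basic" service analogue; the
  "enhanced" analogue is unlimited recall back to the window start),
  random dropout, character-level typos and abbreviation flips in city
  and street strings, digit errors in house numbers, first/last-seen
  drift biased to lengthen spells, and point jitter.

City names are constructed at least ``min_city_name_distance`` edits
apart (street base names ``min_street_name_distance`` apart within a
city), so the tuning ground truth — the number of distinct city names
per subject — is unambiguous even after corruption.

All randomness flows from one seed through four named substreams
(geography+truth, records degradation, study view, tuning sample), and
every per-spell degradation quantity is drawn whether or not it is
applied.  Consequences: the same seed yields byte-identical output; the
basic view is exactly the enhanced view truncated to the most recent
addresses; and raising ``typo_rate`` only enlarges the set of applied
corruptions without changing their content.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .matching import abbreviation_table, edit_distance
from .types import StudyWindow, time_to_year_month

_CONSONANTS = "BCDFGHJKLMNPRSTVWZ"
_VOWELS = "AEIOU"
_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_SUFFIXES = ("ST", "AVE", "RD", "DR", "LN", "CT", "BLVD", "WAY")
_DIRECTIONALS = ("N", "S", "E", "W")
#: Cohort enrollment states used as the synthetic state vocabulary.
_STATE_POOL = ("CA", "FL", "PA", "NJ", "NC", "LA", "GA", "MI",
               "OH", "VA", "WA", "TX", "NY", "IL", "AZ", "CO")

STUDY_COLUMNS = [
    "subject_id", "seq", "house_number", "street_name", "city", "state",
    "first_seen_year", "x", "y", "frame",
]
RECORDS_COLUMNS = [
    "subject_id", "house_number", "street_name", "city", "state",
    "first_seen", "last_seen", "x", "y", "frame",
]


@dataclass(frozen=True)
class SimConfig:
    """All generator parameters.  Defaults are the study conditions emulated.

    ``annual_move_prob`` follows the cited 11.7% U.S. one-year mover
    rate; the window matches the 1995–2013 follow-up; ``recall_depth``
    is the basic-service limit of three known addresses.  Error-model
    parameters (typo, dropout, drift) have no published counterpart and
    are calibration knobs: ``drift_years`` is the mean exponential
    extension of each spell end, so the default lengthens recorded
    spells by ≈ 2.8 years on average, the direction and magnitude a
    records database with early first-seen and late last-seen dates
    produces.
    """

    n_subjects: int = 1000
    window_start: int = 1995
    window_end: int = 2013
    annual_move_prob: float = 0.117
    p_move_same_city: float = 0.4
    p_move_same_state: float = 0.4
    n_states: int = 8
    n_cities_per_state: int = 6
    n_streets_per_city: int = 12
    city_extent_ft: float = 50_000.0
    min_city_name_distance: int = 8
    min_street_name_distance: int = 6
    typo_rate: float = 0.05
    typo_max_edits: int = 2
    abbrev_rate: float = 0.15
    dropout_rate: float = 0.05
    recall_depth: Optional[int] = 3
    drift_years: float = 1.4
    update_lag_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)
    point_jitter_ft: float = 25.0
    tuning_sample_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("annual_move_prob", "typo_rate", "abbrev_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.recall_depth is not None and self.recall_depth < 1:
            raise ValueError("recall_depth must be >= 1 (or None for unlimited)")
        if abs(sum(self.update_lag_probs) - 1.0) > 1e-9:
            raise ValueError("update_lag_probs must sum to 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(self.window_start, self.window_end)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def identity(self) -> "SimConfig":
        """Copy with all degradation switched off (records mirror truth)."""
        return self.replace(
            typo_rate=0.0,
            abbrev_rate=0.0,
            dropout_rate=0.0,
            drift_years=0.0,
            point_jitter_ft=0.0,
            update_lag_probs=(1.0, 0.0, 0.0),
            recall_depth=None,
        )

    # -- flat dotted-key config file ------------------------------------
    def to_file(self, path: str | Path) -> None:
        flat = {f"sim.{k}": v for k, v in dataclasses.asdict(self).items()}
        flat["sim.update_lag_probs"] = list(self.update_lag_probs)
        Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        flat = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for key, value in flat.items():
            name = key.split(".", 1)[1] if key.startswith("sim.") else key
            if name == "update_lag_probs":
                value = tuple(value)
            kw[name] = value
        return cls(**kw)


@dataclass(frozen=True)
class TrueAddress:
    house_number: str
    street_name: str
    city: str
    state: str
    x: float
    y: float


@dataclass
class TrueSpell:
    address: TrueAddress
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TrueHistory:
    subject_id: str
    spells: list[TrueSpell]

    @property
    def unique_city_count(self) -> int:
        return len({sp.address.city for sp in self.spells})


@dataclass
class Geography:
    """Synthetic gazetteer: states → cities → streets, with planar extents."""

    states: list[str]
    cities: list[tuple[str, str]]  # (city, state)
    streets: dict[str, list[str]]  # city -> street names (with suffixes)
    centers: dict[str, tuple[float, float]]
    extent_ft: float


def _make_word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )


def _distinct_names(
    rng: np.random.Generator,
    count: int,
    syllables: tuple[int, int],
    min_distance: int,
    against: Sequence[str] = (),
    max_tries: int = 5000,
) -> list[str]:
    names: list[str] = []
    pool = list(against)
    for _ in range(count):
        for attempt in range(max_tries):
            cand = _make_word(rng, int(rng.integers(syllables[0], syllables[1] + 1)))
            if all(edit_distance(cand, other) >= min_distance for other in pool):
                names.append(cand)
                pool.append(cand)
                break
        else:
            raise RuntimeError("could not place a sufficiently distinct name")
    return names


def build_geography(cfg: SimConfig, rng: np.random.Generator) -> Geography:
    states = list(_STATE_POOL[: cfg.n_states])
    city_names = _distinct_names(
        rng,
        cfg.n_states * cfg.n_cities_per_state,
        syllables=(5, 7),
        min_distance=cfg.min_city_name_distance,
    )
    cities = [
        (city_names[i * cfg.n_cities_per_state + j], st)
        for i, st in enumerate(states)
        for j in range(cfg.n_cities_per_state)
    ]
    streets: dict[str, list[str]] = {}
    centers: dict[str, tuple[float, float]] = {}
    for k, (city, _st) in enumerate(cities):
        bases = _distinct_names(
            rng, cfg.n_streets_per_city, syllables=(4, 5),
            min_distance=cfg.min_street_name_distance,
        )
        full = []
        for b in bases:
            name = f"{b} {_SUFFIXES[rng.integers(len(_SUFFIXES))]}"
            if rng.random() < 0.25:
                name = f"{_DIRECTIONALS[rng.integers(4)]} {name}"
            full.append(name)
        streets[city] = full
        # cities laid out on a coarse grid, addresses jittered inside
        gx, gy = divmod(k, cfg.n_cities_per_state)
        centers[city] = (
            gx * 4.0e6 + rng.uniform(0, 1.0e6),
            gy * 4.0e6 + rng.uniform(0, 1.0e6),
        )
    return Geography(states, cities, streets, centers, cfg.city_extent_ft)


def _sample_address(
    geo: Geography,
    rng: np.random.Generator,
    cfg: SimConfig,
    previous: Optional[TrueAddress],
) -> TrueAddress:
    """Draw a new address; movers favor the same city, then the same state."""
    if previous is None:
        city, state = geo.cities[rng.integers(len(geo.cities))]
    else:
        u = rng.random()
        if u < cfg.p_move_same_city:
            city, state = previous.city, previous.state
        elif u < cfg.p_move_same_city + cfg.p_move_same_state:
            same_state = [c for c in geo.cities if c[1] == previous.state and c[0] != previous.city]
            city, state = same_state[rng.integers(len(same_state))]
        else:
            other = [c for c in geo.cities if c[1] != previous.state]
            city, state = other[rng.integers(len(other))]
    options = geo.streets[city]
    street = options[rng.integers(len(options))]
    if previous is not None and city == previous.city:
        while street == previous.street_name:
            street = options[rng.integers(len(options))]
    cx, cy = geo.centers[city]
    return TrueAddress(
        house_number=str(rng.integers(1, 10_000)),
        street_name=street,
        city=city,
        state=state,
        x=round(cx + rng.uniform(-geo.extent_ft / 2, geo.extent_ft / 2), 1),
        y=round(cy + rng.uniform(-geo.extent_ft / 2, geo.extent_ft / 2), 1),
    )


def generate_truth(cfg: SimConfig) -> tuple[list[TrueHistory], Geography]:
    """Simulate ground-truth histories tiling the window exactly.

    Subjects hold their initial address from the window opening; in each
    subsequent calendar year they move with probability
    ``annual_move_prob``, the move taking effect at mid-year.  Spell
    durations per subject therefore sum exactly to the window length.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    geo = build_geography(cfg, rng)
    window = cfg.window
    histories = []
    width = len(str(cfg.n_subjects))
    for i in range(cfg.n_subjects):
        sid = f"S{i:0{width}d}"
        addr = _sample_address(geo, rng, cfg, None)
        move_times = [
            y + 0.5
            for y in range(window.start + 1, window.end + 1)
            if rng.random() < cfg.annual_move_prob
        ]
        bounds = [window.t0, *move_times, window.t_end]
        spells = []
        for k in range(len(bounds) - 1):
            spells.append(TrueSpell(address=addr, start=bounds[k], end=bounds[k + 1]))
            if k < len(bounds) - 2:
                addr = _sample_address(geo, rng, cfg, addr)
        histories.append(TrueHistory(subject_id=sid, spells=spells))
    return histories, geo


# ---------------------------------------------------------------------------
# Study view


def derive_study_view(truth: Sequence[TrueHistory], cfg: SimConfig) -> pd.DataFrame:
    """Gold-standard view: verbatim components, lagged first-seen years.

    Each subject enrolls in the window's first or second year; the
    baseline row carries the enrollment year, later rows the true move
    year plus an update lag (0–2 years), never exceeding the window end.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    window = cfg.window
    lags = np.arange(len(cfg.update_lag_probs))
    rows = []
    for hist in truth:
        enroll = int(window.start + rng.integers(0, 2))
        enroll_t = enroll + 0.5
        seq = 0
        for sp in hist.spells:
            if sp.end <= enroll_t:
                continue  # vacated before enrollment; unknown to the study
            if sp.start <= enroll_t:
                year = enroll
            else:
                lag = int(rng.choice(lags, p=cfg.update_lag_probs))
                year = min(int(sp.start) + lag, window.end)
            a = sp.address
            rows.append(
                {
                    "subject_id": hist.subject_id,
                    "seq": seq,
                    "house_number": a.house_number,
                    "street_name": a.street_name,
                    "city": a.city,
                    "state": a.state,
                    "first_seen_year": year,
                    "x": a.x,
                    "y": a.y,
                    "frame": "planar-feet",
                }
            )
            seq += 1
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


# ---------------------------------------------------------------------------
# Records view


def _corrupt_string(s: str, n_edits: int, draws: list[tuple[int, float, int]]) -> str:
    """Apply pre-drawn character edits (insert/delete/substitute)."""
    chars = list(s)
    for op, pos_u, ch_i in draws[:n_edits]:
        ch = _ALPHABET[ch_i]
        if op == 0:  # insert
            pos = int(pos_u * (len(chars) + 1))
            chars.insert(pos, ch)
        elif op == 1 and len(chars) > 1:  # delete
            del chars[int(pos_u * len(chars))]
        else:  # substitute
            pos = int(pos_u * len(chars))
            chars[pos] = ch
    return "".join(chars)


def _reverse_abbrev_table() -> dict[str, str]:
    # canonical token -> one expanded form (first listed wins)
    rev: dict[str, str] = {}
    for raw, canonical in abbreviation_table().items():
        if canonical not in rev and raw != canonical:
            rev[canonical] = raw
    return rev


def _ym_str(t: float) -> str:
    y, m = time_to_year_month(t)
    return f"{y:04d}-{m:02d}"


def degrade_to_records(
    truth: Sequence[TrueHistory],
    cfg: SimConfig,
    recall_depth: Optional[int] = None,
) -> pd.DataFrame:
    """Records-view extract of the truth under the configured error model.

    ``recall_depth`` overrides ``cfg.recall_depth`` when given (pass
    ``None`` explicitly via ``cfg.replace(recall_depth=None)`` for the
    unlimited/enhanced analogue).  Every degradation quantity is drawn
    for every spell before recall truncation and dropout are applied, so
    runs differing only in recall depth share all corruptions.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    depth = cfg.recall_depth if recall_depth is None else recall_depth
    window = cfg.window
    rev = _reverse_abbrev_table()
    rows = []
    for hist in truth:
        prepared = []
        for sp in hist.spells:
            u_drop = rng.random()
            bundles = {}
            for comp in ("city", "street"):
                u_apply = rng.random()
                n_edits = int(rng.integers(1, cfg.typo_max_edits + 1))
                draws = [
                    (int(rng.integers(3)), rng.random(), int(rng.integers(26)))
                    for _ in range(n_edits)
                ]
                bundles[comp] = (u_apply, n_edits, draws)
            u_house, house_pos_u, house_digit = (
                rng.random(), rng.random(), int(rng.integers(10)),
            )
            u_abbrev, u_token = rng.random(), rng.random()
            d_early, d_late = rng.exponential(cfg.drift_years, size=2)
            jx, jy = rng.uniform(-cfg.point_jitter_ft, cfg.point_jitter_ft, size=2)

            a = sp.address
            city, street, house = a.city, a.street_name, a.house_number
            u, n, draws = bundles["city"]
            if u < cfg.typo_rate:
                city = _corrupt_string(city, n, draws)
            u, n, draws = bundles["street"]
            if u < cfg.typo_rate:
                street = _corrupt_string(street, n, draws)
            if u_house < cfg.typo_rate / 2:
                pos = int(house_pos_u * len(house))
                house = house[:pos] + str(house_digit) + house[pos + 1:]
            if u_abbrev < cfg.abbrev_rate:
                tokens = street.split()
                flippable = [i for i, t in enumerate(tokens) if t in rev]
                if flippable:
                    i = flippable[int(u_token * len(flippable))]
                    tokens[i] = rev[tokens[i]]
                    street = " ".join(tokens)

            start = max(sp.start - d_early, window.t0 - 10.0)
            end = min(sp.end + d_late, window.t_end)
            prepared.append(
                {
                    "subject_id": hist.subject_id,
                    "house_number": house,
                    "street_name": street,
                    "city": city,
                    "state": a.state,
                    "first_seen": _ym_str(start),
                    "last_seen": _ym_str(end - 1.0 / 24.0),
                    "x": round(a.x + jx, 1),
                    "y": round(a.y + jy, 1),
                    "frame": "planar-feet",
                    "_drop": u_drop < cfg.dropout_rate,
                }
            )
        if depth is not None:
            prepared = prepared[-depth:]
        rows.extend(r for r in prepared if not r.pop("_drop"))
    return pd.DataFrame(rows, columns=RECORDS_COLUMNS)


def records_from_study(study: pd.DataFrame, window: StudyWindow) -> pd.DataFrame:
    """Records rows that exactly mirror the study view's occupancy spells.

    Used as the perfect-copy reference: components, intervals and points
    reproduce the study spells precisely, so every applicable agreement
    metric must come out at 1.0 against it.
    """
    rows = []
    for sid, grp in study.groupby("subject_id", sort=True):
        grp = grp.sort_values(["first_seen_year", "seq"], kind="stable")
        collapsed = []
        for _, r in grp.iterrows():
            key = (r.house_number, r.street_name, r.city, r.state)
            if collapsed and collapsed[-1][0] == key:
                continue
            collapsed.append((key, r))
        starts = [
            min(max(r.first_seen_year + 0.5, window.t0), window.t_study_end)
            for _, r in collapsed
        ]
        for k in range(1, len(starts)):
            starts[k] = max(starts[k], starts[k - 1])
        for k, (_, r) in enumerate(collapsed):
            end = starts[k + 1] if k + 1 < len(starts) else window.t_study_end
            if end <= starts[k]:
                end = starts[k] + 1.0 / 24.0  # zero-length study spell: emit its month
            rows.append(
                {
                    "subject_id": sid,
                    "house_number": r.house_number,
                    "street_name": r.street_name,
                    "city": r.city,
                    "state": r.state,
                    "first_seen": _ym_str(starts[k]),
                    "last_seen": _ym_str(end - 1.0 / 24.0),
                    "x": r.x,
                    "y": r.y,
                    "frame": r.frame,
                }
            )
    return pd.DataFrame(rows, columns=RECORDS_COLUMNS)


# ---------------------------------------------------------------------------
# Tuning sample


def emit_tuning_sample(
    truth: Sequence[TrueHistory],
    records: pd.DataFrame,
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """City strings pooled from both views for a subject sample, plus truth.

    The clean per-spell city names (the study view copies components
    verbatim) come first so greedy unique-counting anchors clusters on
    uncorrupted representatives; the subject's records strings follow.
    The true unique count is the number of distinct city names in the
    subject's true history.
    """
    rng = np.random.default_rng([cfg.seed, 4])
    n = min(cfg.tuning_sample_size, len(truth))
    idx = rng.choice(len(truth), size=n, replace=False)
    by_subject = dict(tuple(records.groupby("subject_id", sort=False)))
    sample_rows, truth_rows = [], []
    for i in sorted(idx):
        hist = truth[i]
        strings = [sp.address.city for sp in hist.spells]
        grp = by_subject.get(hist.subject_id)
        if grp is not None:
            strings.extend(grp["city"].tolist())
        for s in strings:
            sample_rows.append({"subject_id": hist.subject_id, "city_string": s})
        truth_rows.append(
            {"subject_id": hist.subject_id, "true_unique_count": hist.unique_city_count}
        )
    return pd.DataFrame(sample_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# End-to-end emission


def simulate(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the generator and write all CSV artifacts to ``out_dir``.

    Emits the study view, a basic (recall-limited) and an enhanced
    (unlimited recall) records view, the tuning sample with its truth,
    and the full ground truth for verification.  Identical configs
    produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, _geo = generate_truth(cfg)
    study = derive_study_view(truth, cfg)
    basic = degrade_to_records(truth, cfg)
    enhanced = degrade_to_records(truth, cfg.replace(recall_depth=None))
    sample, sample_truth = emit_tuning_sample(truth, enhanced, cfg)

    truth_rows = [
        {
            "subject_id": h.subject_id,
            "seq": k,
            "house_number": sp.address.house_number,
            "street_name": sp.address.street_name,
            "city": sp.address.city,
            "state": sp.address.state,
            "start": sp.start,
            "end": sp.end,
            "x": sp.address.x,
            "y": sp.address.y,
        }
        for h in truth
        for k, sp in enumerate(h.spells)
    ]

    paths = {}
    emit = {
        "study_addresses.csv": study,
        "records_basic.csv": basic,
        "records_enhanced.csv": enhanced,
        "tuning_sample.csv": sample,
        "tuning_truth.csv": sample_truth,
        "truth.csv": pd.DataFrame(truth_rows),
    }
    for name, df in emit.items():
        path = out / name
        df.to_csv(path, index=False, float_format="%.4f")
        paths[name] = path
    cfg.to_file(out / "sim_config.yaml")
    paths["sim_config.yaml"] = out / "sim_config.yaml"
    return paths
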