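"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache

import pytest

import reshist as rh
from reshist.io import records_records_from_frame, study_records_from_frame


def levenshtein_oracle(a: str, b: str) -> int:
    """Exhaustive recursive-definition Levenshtein distance (short strings only).

    Independent of the production implementation: directly evaluates the
    recurrence d(a, b) = min(delete, insert, substitute) with memoization.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1, rec(i - 1, j - 1) + cost)

    return rec(len(a), len(b))


def parse_views(study_df, records_df):
    """Parse simulator output frames into normalized address records."""
    study, _ = study_records_from_frame(study_df)
    records, _ = records_records_from_frame(records_df)
    return study, records


def simulate_and_assess(cfg: rh.SimConfig, d: int = 2, recall_depth=None):
    """One full pipeline pass: truth → views → metrics at tolerance ``d``."""
    truth, _ = rh.generate_truth(cfg)
    study_df = rh.derive_study_view(truth, cfg)
    records_df = rh.degrade_to_records(truth, cfg.replace(recall_depth=recall_depth))
    study, records = parse_views(study_df, records_df)
    return truth, rh.run_metrics(study, records, d=d, window=cfg.window)


@pytest.fixture(scope="session")
def small_cfg() -> rh.SimConfig:
    return rh.SimConfig(n_subjects=60, seed=11)


@pytest.fixture(scope="session")
def small_run(small_cfg):
    """A small default-degradation simulation assessed end to end."""
    return simulate_and_assess(small_cfg)
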