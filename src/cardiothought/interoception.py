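"""Scoring of the heartbeat counting task (HCT) and time estimation task (TET).

The HCT error rate is the standard mean absolute relative miscount,

    (1/n) * sum_i |actual_i - reported_i| / actual_i * 100,

over the session's n timed intervals (n = 6 in the standard design:
2 x 25 s, 2 x 35 s, 2 x 45 s).  Lower error means more accurate
interoception; the value is unbounded above (a report more than double the
actual count scores above 100).  The TET is the control task: the same
formula applied to reported versus actual elapsed time (2 x 23 s, 2 x 49 s,
2 x 56 s).  A near-zero HCT-TET correlation across a cohort indicates that
heartbeat counting was not driven by time estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HctSession",
    "TetSession",
    "InteroceptionScore",
    "hct_error_rate",
    "tet_error_rate",
    "hct_tet_correlation",
    "score_cohort",
]

STANDARD_INTERVALS = 6


@dataclass
class HctSession:
    """One participant's heartbeat-counting session."""

    interval_duration_s: list[float]
    actual_count: list[int]
    reported_count: list[int]

    def validate(self) -> "HctSession":
        if not (
            len(self.interval_duration_s)
            == len(self.actual_count)
            == len(self.reported_count)
        ):
            raise ValueError("HCT session lists must have equal length")
        if len(self.actual_count) == 0:
            raise ValueError("empty HCT session")
        for name, counts in (("actual", self.actual_count), ("reported", self.reported_count)):
            arr = np.asarray(counts)
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError(f"{name} counts must be integers (verbal reports)")
            if np.any(arr < 0):
                raise ValueError(f"{name} counts must be non-negative")
        if any(a == 0 for a in self.actual_count):
            raise ValueError("actual heartbeat count of 0 cannot be scored")
        return self


@dataclass
class TetSession:
    """One participant's time-estimation session."""

    interval_duration_s: list[float]
    reported_duration_s: list[float]

    def validate(self) -> "TetSession":
        if len(self.interval_duration_s) != len(self.reported_duration_s):
            raise ValueError("TET session lists must have equal length")
        if len(self.interval_duration_s) == 0:
            raise ValueError("empty TET session")
        if any(d <= 0 for d in self.interval_duration_s):
            raise ValueError("interval durations must be positive")
        if any(d < 0 for d in self.reported_duration_s):
            raise ValueError("reported durations must be non-negative")
        return self


@dataclass
class InteroceptionScore:
    participant_id: str
    hct_error_rate: float
    tet_error_rate: float = field(default=np.nan)


def _mean_abs_rel_error(actual: np.ndarray, reported: np.ndarray, n: int) -> float:
    if n != STANDARD_INTERVALS:
        warnings.warn(
            f"scoring a session with {n} intervals (standard design has "
            f"{STANDARD_INTERVALS}); divisor is the session's interval count",
            stacklevel=3,
        )
    return float(np.mean(np.abs(actual - reported) / actual) * 100.0)


def hct_error_rate(session: HctSession) -> float:
    """HCT error rate in percent (0 = perfect heartbeat perception)."""
    session.validate()
    actual = np.asarray(session.actual_count, dtype=float)
    reported = np.asarray(session.reported_count, dtype=float)
    return _mean_abs_rel_error(actual, reported, len(session.actual_count))


def tet_error_rate(session: TetSession) -> float:
    """TET error rate in percent, scored exactly like the HCT with
    actual = true interval duration."""
    session.validate()
    actual = np.asarray(session.interval_duration_s, dtype=float)
    reported = np.asarray(session.reported_duration_s, dtype=float)
    return _mean_abs_rel_error(actual, reported, len(actual))


def hct_tet_correlation(scores: list[InteroceptionScore]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between HCT and TET error rates.

    Used as a sanity report that heartbeat counting is not explained by time
    estimation; raises if either score vector is constant.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 participants for a correlation")
    x = np.array([s.hct_error_rate for s in scores], dtype=float)
    y = np.array([s.tet_error_rate for s in scores], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in error rates")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def score_cohort(hct: pd.DataFrame, tet: pd.DataFrame) -> pd.DataFrame:
    """Score every participant in long-format HCT/TET tables.

    ``hct`` columns: participant, duration_s, actual, reported.
    ``tet`` columns: participant, duration_s, reported_s.
    Returns one row per participant: participant, hct_error_rate,
    tet_error_rate.
    """
    rows = []
    tet_by_pid = dict(iter(tet.groupby("participant"))) if len(tet) else {}
    for pid, grp in hct.groupby("participant"):
        h = HctSession(
            grp["duration_s"].tolist(),
            grp["actual"].tolist(),
            grp["reported"].tolist(),
        )
        rec = {"participant": pid, "hct_error_rate": hct_error_rate(h)}
        if pid in tet_by_pid:
            tg = tet_by_pid[pid]
            t = TetSession(tg["duration_s"].tolist(), tg["reported_s"].tolist())
            rec["tet_error_rate"] = tet_error_rate(t)
        rows.append(rec)
    return pd.DataFrame(rows).sort_values("participant").reset_index(drop=True)
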