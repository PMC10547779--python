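"""Event-locked RR-interval analysis around subliminal vibration onsets.

The cardiac substrate is the series of pulse-wave apex times; successive
apex differences are the RR intervals (ms).  In vibration trials a stimulus
is delivered 15 s and 30 s after trial start; the RR interval ending at or
before an onset is RR0 and the next four are RR1..RR4.  Change points of
segment mean and variance are detected in the window spanning 5 s before to
10 s after each onset (trial time 10-25 s, interval 1, and 25-40 s,
interval 2).  The per-block heart-rate change rate is

    (# change points landing at RR1, RR2 or RR3 across the block's windows)
    / (3 * n_windows) * 100

with the fixed denominator 3 x 10 in the standard design (5 analysed trials
x 2 onsets per block); incomplete windows contribute zero hits but stay in
the denominator.  Non-vibration comparison trials (the trials immediately
preceding each vibration trial) are scored identically using the nominal
15 s / 30 s onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .changepoint import detect_changepoints_series

__all__ = [
    "BeatSeries",
    "EventWindow",
    "ChangePointResult",
    "ChangeRate",
    "RR_PLAUSIBLE_MS",
    "VIBRATION_ONSETS_S",
    "WINDOW_BEFORE_S",
    "WINDOW_AFTER_S",
    "SCORED_LABELS",
    "detect_apexes",
    "build_event_windows",
    "rr_deviation_profile",
    "detect_changepoints",
    "change_rate",
    "analysis_trials",
    "compute_change_rates",
]

RR_PLAUSIBLE_MS = (250.0, 3000.0)
VIBRATION_ONSETS_S = (15.0, 30.0)
WINDOW_BEFORE_S = 5.0
WINDOW_AFTER_S = 10.0
SCORED_LABELS = (1, 2, 3)  # RR1-RR3 carry the vibration effect
N_WINDOWS_STANDARD = 10  # 5 analysed trials x 2 onsets


@dataclass
class BeatSeries:
    """Apex times (seconds from session start) for one participant."""

    participant_id: str
    apex_time_s: np.ndarray

    def __post_init__(self):
        self.apex_time_s = np.asarray(self.apex_time_s, dtype=float)
        if self.apex_time_s.ndim != 1:
            raise ValueError("apex times must be one-dimensional")
        if np.any(np.diff(self.apex_time_s) <= 0):
            raise ValueError("apex times must be strictly increasing")

    @property
    def rr_ms(self) -> np.ndarray:
        return np.diff(self.apex_time_s) * 1000.0

    def implausible_rr_fraction(self) -> float:
        """Fraction of RR intervals outside the physiological range."""
        rr = self.rr_ms
        if rr.size == 0:
            return 1.0
        lo, hi = RR_PLAUSIBLE_MS
        return float(np.mean((rr <= lo) | (rr >= hi)))


@dataclass
class EventWindow:
    """RR intervals around one vibration (or nominal) onset.

    ``rr0_index`` marks RR0 inside ``rr_values``; label RRk corresponds to
    position ``rr0_index + k``.  ``complete`` requires RR0..RR4 resolvable.
    """

    trial: int
    interval_id: int
    onset_s: float
    rr_values: np.ndarray
    rr0_index: int
    complete: bool = True

    def label_position(self, k: int) -> int:
        return self.rr0_index + k


@dataclass
class ChangePointResult:
    window: EventWindow
    cp_indices: list[int]
    hits: int = 0
    hit_rr123: bool = False


@dataclass
class ChangeRate:
    participant_id: str
    block: str
    rate_percent: float
    n_windows: int = N_WINDOWS_STANDARD
    n_hits: int = 0


def detect_apexes(trace, fs: float, refractory_s: float = 0.25) -> np.ndarray:
    """Pulse-wave apex times (s) from a sampled trace.

    Local maxima above an adaptive threshold (midpoint of the 10th/90th
    amplitude percentiles) separated by at least the refractory period.
    """
    trace = np.asarray(trace, dtype=float)
    if fs < 20:
        raise ValueError("sampling rate must be >= 20 Hz")
    if trace.size < fs:
        raise ValueError("trace too short for beat detection")
    lo, hi = np.percentile(trace, [10, 90])
    if hi - lo <= 0:
        raise ValueError("flat signal: no beats detectable")
    peaks, _ = find_peaks(trace, height=(lo + hi) / 2.0, distance=max(1, int(refractory_s * fs)))
    if peaks.size == 0:
        raise ValueError("no beats detected")
    return peaks / fs


def _window_from_beats(t: np.ndarray, trial: int, interval_id: int, onset: float) -> EventWindow | None:
    lo, hi = onset - WINDOW_BEFORE_S, onset + WINDOW_AFTER_S
    # RR i terminates at apex t[i] (i >= 1)
    term = t[1:]
    rr = np.diff(t) * 1000.0
    in_span = (term >= lo) & (term <= hi)
    if not np.any(in_span):
        return None
    idx = np.flatnonzero(in_span)
    rr_values = rr[idx]
    # RR0: last interval whose terminating apex is at or before the onset
    before = np.flatnonzero(term[idx] <= onset)
    if before.size == 0:
        return None
    rr0_index = int(before[-1])
    complete = rr0_index + 4 < rr_values.size
    return EventWindow(
        trial=trial,
        interval_id=interval_id,
        onset_s=onset,
        rr_values=rr_values,
        rr0_index=rr0_index,
        complete=complete,
    )


def analysis_trials(schedule: pd.DataFrame) -> pd.DataFrame:
    """Analysed trials with their condition label.

    Vibration trials (condition ``vib``) and the non-vibration trials
    immediately preceding each of them (condition ``non_vib``), scored at
    the same nominal onsets.  Raises if a vibration trial carries no onsets
    or has no preceding non-vibration trial.
    """
    sched = schedule.sort_values("trial").reset_index(drop=True)
    rows = []
    for i, row in sched.iterrows():
        if row["trial_type"] != "vib":
            continue
        if not isinstance(row.get("vib_onsets_s"), str) or not row["vib_onsets_s"]:
            raise ValueError(f"vibration trial {row['trial']} has no vibration onsets")
        rows.append({"trial": int(row["trial"]), "trial_start_s": float(row["trial_start_s"]), "block": "vib"})
        if i == 0 or sched.loc[i - 1, "trial_type"] == "vib":
            raise ValueError(
                f"vibration trial {row['trial']} lacks a preceding non-vibration trial"
            )
        prev = sched.loc[i - 1]
        rows.append({"trial": int(prev["trial"]), "trial_start_s": float(prev["trial_start_s"]), "block": "non_vib"})
    return pd.DataFrame(rows)


def build_event_windows(
    beats: BeatSeries, schedule: pd.DataFrame
) -> dict[str, list[EventWindow]]:
    """Event windows per condition (``vib`` / ``non_vib``) for one participant."""
    t = beats.apex_time_s
    out: dict[str, list[EventWindow]] = {"non_vib": [], "vib": []}
    for _, row in analysis_trials(schedule).iterrows():
        for interval_id, rel_onset in enumerate(VIBRATION_ONSETS_S, start=1):
            onset = row["trial_start_s"] + rel_onset
            w = _window_from_beats(t, int(row["trial"]), interval_id, onset)
            if w is not None:
                out[row["block"]].append(w)
    return out


def rr_deviation_profile(windows: list[EventWindow]) -> np.ndarray:
    """Mean RRk - RR0 (ms) for k = 1..4 over complete windows.

    The profile justifies restricting scoring to RR1-RR3: a transient
    vibration-locked disturbance shows up in the first three intervals and
    has converged back by RR4.
    """
    complete = [w for w in windows if w.complete]
    if not complete:
        raise ValueError("no complete windows")
    devs = np.array(
        [
            [w.rr_values[w.label_position(k)] - w.rr_values[w.rr0_index] for k in range(1, 5)]
            for w in complete
        ]
    )
    return devs.mean(axis=0)


def detect_changepoints(
    window: EventWindow,
    penalty: str | float = "mbic",
    min_seg_len: int = 2,
) -> ChangePointResult:
    """Segment one window's RR values and score hits at RR1-RR3.

    A change point "at RRk" is a segment boundary whose new segment starts
    at the position labelled RRk.
    """
    if window.rr_values.size < 2 * min_seg_len:
        return ChangePointResult(window, [], 0, False)
    cps = detect_changepoints_series(window.rr_values, penalty=penalty, min_seg_len=min_seg_len)
    scored = {window.label_position(k) for k in SCORED_LABELS}
    hits = sum(1 for c in cps if c in scored)
    return ChangePointResult(window, cps, hits, hits > 0)


def change_rate(
    results: list[ChangePointResult],
    participant_id: str = "",
    block: str = "",
    n_windows: int = N_WINDOWS_STANDARD,
) -> ChangeRate:
    """Heart-rate change rate (%) for one participant-block.

    Fixed denominator 3 * n_windows (RR1-3 slots across the block's
    windows); incomplete windows contribute zero hits.
    """
    if n_windows <= 0:
        raise ValueError("n_windows must be positive")
    hits = sum(r.hits for r in results)
    return ChangeRate(
        participant_id=participant_id,
        block=block,
        rate_percent=hits / (3 * n_windows) * 100.0,
        n_windows=n_windows,
        n_hits=hits,
    )


def compute_change_rates(
    beats: BeatSeries,
    schedule: pd.DataFrame,
    penalty: str | float = "mbic",
    min_seg_len: int = 2,
) -> pd.DataFrame:
    """Per-condition change rates for one participant (tidy output)."""
    windows = build_event_windows(beats, schedule)
    trials = analysis_trials(schedule)
    rows = []
    for block in ("non_vib", "vib"):
        # denominator from the schedule (2 onsets per analysed trial), so
        # unresolvable windows still count as misses
        n_windows = 2 * int((trials["block"] == block).sum())
        results = [detect_changepoints(w, penalty, min_seg_len) for w in windows[block]]
        cr = change_rate(results, beats.participant_id, block, n_windows=n_windows)
        rows.append(
            {
                "participant": beats.participant_id,
                "block": block,
                "rate_percent": cr.rate_percent,
                "n_windows": cr.n_windows,
                "n_hits": cr.n_hits,
            }
        )
    return pd.DataFrame(rows)
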