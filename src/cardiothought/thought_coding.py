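"""Coding of probe-caught thought reports and participant exclusions.

Each vigilance-task trial ends with up to three probes: thought category
(1 task-focused, 2 task-relevant, 3 peripheral stimuli, 4 internal body
state, 5 task-unrelated/self-referential, 6 absent-minded), contemplation
(1-3, how deeply) and consistency (1-3, coherence).  Category 6 suppresses
the follow-up probes.  Categories 3 and 6 are excluded from the thought-
shifting analysis; indicators are computed per block (20 trials):

continuation
    adjacent same-category pairs, per category c in {1, 2, 4, 5};
transition
    adjacent pairs between category 1 and the mind-wandering categories
    {2, 4, 5}, both grouped (1 -> MW, MW -> 1) and per category;
highly contemplated / highly consistent 5
    category-5 reports with contemplation in {2, 3} / consistency == 1.

Adjacent pairs touching category 3 or 6 are discarded (non-bridging rule:
1, 6, 1 yields no 1 -> 1 continuation), and no pair spans the between-block
break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CORE_CATEGORIES",
    "MW_CATEGORIES",
    "TRIALS_PER_BLOCK",
    "ExclusionReport",
    "validate_probe_table",
    "count_continuations",
    "count_transitions",
    "count_high_flags",
    "thought_counts",
    "apply_exclusions",
]

CORE_CATEGORIES = (1, 2, 4, 5)
MW_CATEGORIES = (2, 4, 5)
DROPPED_CATEGORIES = (3, 6)
TRIALS_PER_BLOCK = 20
BLOCKS = ("non_vib", "vib")


@dataclass
class ExclusionReport:
    participant_id: str
    excluded: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded flag must match non-empty reasons")


def validate_probe_table(table: pd.DataFrame, n_trials: int = TRIALS_PER_BLOCK) -> pd.DataFrame:
    """Validate one participant's probe table (both blocks).

    Required columns: trial, block, category, contemplation, consistency.
    Enforces 20 rows per block, category codes 1-6, follow-ups present
    exactly when category != 6.
    """
    required = {"trial", "block", "category", "contemplation", "consistency"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    t = table.copy()
    if not set(t["block"].unique()) <= set(BLOCKS):
        raise ValueError(f"block labels must be in {BLOCKS}")
    for block, grp in t.groupby("block"):
        if len(grp) != n_trials:
            raise ValueError(f"block {block!r} has {len(grp)} rows, expected {n_trials}")
    cat = t["category"]
    if not cat.isin(range(1, 7)).all():
        raise ValueError("categories must be integer codes 1-6")
    is6 = cat == 6
    for col in ("contemplation", "consistency"):
        vals = t.loc[~is6, col]
        if vals.isna().any() or not vals.isin((1, 2, 3)).all():
            raise ValueError(f"{col} must be 1-3 when category is 1-5")
        if t.loc[is6, col].notna().any():
            raise ValueError(f"{col} must be absent when category is 6 "
                             "(follow-up probes are not presented)")
    return t


def _clean_pairs(seq) -> list[tuple[int, int]]:
    """Adjacent pairs with any pair touching a dropped category removed."""
    seq = list(seq)
    return [
        (a, b)
        for a, b in zip(seq, seq[1:])
        if a not in DROPPED_CATEGORIES and b not in DROPPED_CATEGORIES
    ]


def count_continuations(seq) -> dict[int, int]:
    """Per-category continuation counts over one block's category sequence."""
    pairs = _clean_pairs(seq)
    return {c: sum(1 for a, b in pairs if a == b == c) for c in CORE_CATEGORIES}


def count_transitions(seq) -> tuple[dict[str, int], dict[str, int]]:
    """Grouped and per-category transition counts anchored on category 1.

    Grouped: 1 -> MW and MW -> 1 with MW = any of {2, 4, 5}; per-category:
    the same split by the MW category involved.
    """
    pairs = _clean_pairs(seq)
    grouped = {
        "1_to_mw": sum(1 for a, b in pairs if a == 1 and b in MW_CATEGORIES),
        "mw_to_1": sum(1 for a, b in pairs if a in MW_CATEGORIES and b == 1),
    }
    percat: dict[str, int] = {}
    for c in MW_CATEGORIES:
        percat[f"1_to_{c}"] = sum(1 for a, b in pairs if a == 1 and b == c)
        percat[f"{c}_to_1"] = sum(1 for a, b in pairs if a == c and b == 1)
    return grouped, percat


def count_high_flags(block_rows: pd.DataFrame) -> tuple[int, int]:
    """(highly contemplated 5, highly consistent 5) counts for one block."""
    five = block_rows[block_rows["category"] == 5]
    high_cont = int(five["contemplation"].isin((2, 3)).sum())
    high_cons = int((five["consistency"] == 1).sum())
    return high_cont, high_cons


def thought_counts(table: pd.DataFrame, participant_id: str | None = None) -> pd.DataFrame:
    """All thought-state indicators per block for one validated probe table."""
    t = validate_probe_table(table)
    if participant_id is None:
        participant_id = str(t["participant"].iloc[0]) if "participant" in t else ""
    rows = []
    for block in BLOCKS:
        grp = t[t["block"] == block].sort_values("trial")
        seq = grp["category"].tolist()
        cont = count_continuations(seq)
        grouped, percat = count_transitions(seq)
        hc5, hcons5 = count_high_flags(grp)
        row = {
            "participant": participant_id,
            "block": block,
            **{f"continuation_{c}": cont[c] for c in CORE_CATEGORIES},
            **{f"transition_{k}": v for k, v in grouped.items()},
            **{f"transition_{k}": v for k, v in percat.items()},
            "highly_contemplated_5": hc5,
            "highly_consistent_5": hcons5,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def apply_exclusions(
    participants: pd.DataFrame,
    probes: dict[str, pd.DataFrame],
    responses: dict[str, pd.DataFrame],
    implausible_rr: dict[str, float] | None = None,
    rr_fraction_threshold: float = 0.05,
) -> pd.DataFrame:
    """Participant-level exclusion screen.

    Rules (any firing excludes):

    - ``noticed_vibration``: self-reported awareness of the vibration or of
      externally induced heart-rate change (debriefing flag in the
      participants table);
    - ``low_correct_response``: correct responses (all targets hit) on no
      more than half of the trials ("more than half" read strictly, so an
      exact 50% performance is excluded);
    - ``no_core_categories``: no probe-1 response in {1, 2, 4, 5} across the
      entire task;
    - ``bad_pulse_data``: fraction of implausible RR intervals above
      ``rr_fraction_threshold`` (pulse trace unusable).

    Returns a tidy table: participant, excluded, reasons ( ';'-joined).
    """
    reports = []
    for _, prow in participants.iterrows():
        pid = str(prow["participant"])
        reasons = []
        if bool(prow.get("noticed_vibration", False)):
            reasons.append("noticed_vibration")
        resp = responses.get(pid)
        if resp is not None and len(resp):
            correct = (resp["n_hits"] >= resp["n_targets"]).mean()
            if correct <= 0.5:
                reasons.append("low_correct_response")
        probe = probes.get(pid)
        if probe is not None and len(probe):
            if not probe["category"].isin(CORE_CATEGORIES).any():
                reasons.append("no_core_categories")
        if implausible_rr is not None and pid in implausible_rr:
            if implausible_rr[pid] > rr_fraction_threshold:
                reasons.append("bad_pulse_data")
        reports.append(
            {
                "participant": pid,
                "excluded": bool(reasons),
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(reports)
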