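"""Apply participant exclusions and code the thought probes.

Exclusion rules: noticed the vibration, correct target responses on no more
than half of trials, never reported a core thought category (1/2/4/5), or
an unusable pulse trace (>5% implausible RR intervals).  Retained
participants' probe tables are coded into per-block continuation,
transition, and high-contemplation / high-consistency counts.

Reads results/data/; writes results/exclusions.csv and
results/thought_counts.csv.
"""

from pathlib import Path

import pandas as pd

from cardiothought.pipeline import load_cohort_dir
from cardiothought.thought_coding import apply_exclusions, thought_counts

DATA = Path("results/data")

if __name__ == "__main__":
    participants, beats, _, probes, responses = load_cohort_dir(DATA)
    implausible = {pid: b.implausible_rr_fraction() for pid, b in beats.items()}
    exclusions = apply_exclusions(participants, probes, responses, implausible)
    exclusions.to_csv("results/exclusions.csv", index=False)
    tally = (
        exclusions.loc[exclusions.excluded, "reasons"].str.split(";").explode().value_counts()
    )
    retained = exclusions.loc[~exclusions.excluded, "participant"]
    print(f"{len(participants)} entering, {len(retained)} retained")
    for reason, n in tally.items():
        print(f"  excluded for {reason}: {n}")

    counts = pd.concat([thought_counts(probes[p], p) for p in retained], ignore_index=True)
    counts.to_csv("results/thought_counts.csv", index=False)
    by_block = counts.groupby("block")[["continuation_5", "highly_contemplated_5"]].mean()
    print("mean per-block counts (retained cohort):")
    print(by_block.round(2).to_string())
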