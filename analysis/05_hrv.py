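"""Frequency-domain HRV per task block (fatigue / arousal control).

For each retained participant and block, the RR series of the final three
quarters of the block is spline-resampled at 4 Hz, detrended
(smoothness priors), and Welch band powers are integrated: VLF
(0.003-0.04 Hz), LF (0.04-0.15 Hz), HF (0.15-0.4 Hz), plus LF/HF.
Comparable HF and LF/HF across blocks indicates autonomic state did not
drift between the task halves.  (Note: the vibration-locked RR
decelerations themselves carry some band power, so a small HF elevation
in the vibration block is expected by construction, not a sign of
autonomic drift.)

Reads results/data/ and results/exclusions.csv; writes results/hrv.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cardiothought.hrv import block_hrv
from cardiothought.pipeline import load_cohort_dir
from cardiothought.synthetic import CohortConfig, block_spans

DATA = Path("results/data")

if __name__ == "__main__":
    participants, beats, schedules, _, _ = load_cohort_dir(DATA)
    retained = pd.read_csv("results/exclusions.csv")
    retained = retained.loc[~retained.excluded, "participant"]
    cfg = CohortConfig()
    hrv = pd.concat(
        [block_hrv(beats[pid], block_spans(schedules[pid], cfg)) for pid in retained],
        ignore_index=True,
    )
    hrv["log_hf"] = np.log(hrv["hf"])
    hrv.to_csv("results/hrv.csv", index=False)
    print(f"HRV for {len(retained)} participants x 2 blocks (last 3/4 of each block)")
    print(hrv.groupby("block")[["hf", "lf", "lf_hf"]].mean().round(2).to_string())
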