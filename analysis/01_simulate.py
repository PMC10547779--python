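"""Generate the synthetic study cohort.

100 participants (70 women), each with heartbeat-counting and
time-estimation sessions, a two-block vigilance task (20 trials per block,
5 subliminal-vibration trials in the second block), continuous pulse apex
times, probe responses and target-response logs.  22 participants carry an
exclusion-triggering profile (2 unusable pulse traces, 9 vibration
noticers, 3 low responders, 6 core-category non-reporters).

Writes results/data/ (participants.csv, hct.csv, tet.csv and per-
participant beats/events/probes/responses files).
"""

from pathlib import Path

from cardiothought.synthetic import CohortConfig, write_cohort

OUT = Path("results/data")
SEED = 20240901

if __name__ == "__main__":
    cfg = CohortConfig(seed=SEED)
    participants = write_cohort(cfg, OUT)
    n_special = int(
        participants[["noticed_vibration", "bad_pulse"]].sum().sum()
        + (~participants["valid_responder"]).sum()
        + (~participants["reporter_of_core_categories"]).sum()
    )
    print(f"wrote {len(participants)} participants to {OUT}")
    print(f"  {int(participants['sex'].sum())} women, "
          f"{n_special} with exclusion-triggering profiles")
    print(f"  latent HCT error: mean {participants['true_hct_error'].mean():.1f}%, "
          f"sd {participants['true_hct_error'].std():.1f}%")
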