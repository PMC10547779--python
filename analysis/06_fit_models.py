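"""Bayesian hierarchical regressions for every study outcome.

Five random-intercept models (4 chains x 1000 retained draws each):

- change rate ~ vibration + score + sex        (Gaussian)
- TC5 continuation ~ score * vibration + sex   (Poisson, log link)
- highly contemplated 5 ~ score * vibration + sex  (Poisson)
- ln HF ~ vibration + sex                      (Gaussian)
- LF/HF ~ vibration + sex                      (Gaussian)

A coefficient is "supported" when its equal-tailed 95% credible interval
excludes 0.  Reads the stage outputs under results/; writes
results/posterior_<model>.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cardiothought.inference import fit_model
from cardiothought.mcmc import SamplerSettings
from cardiothought.pipeline import MODEL_SPECS

SEED = 20240901
RES = Path("results")

if __name__ == "__main__":
    scores = pd.read_csv(RES / "interoception_scores.csv").rename(
        columns={"hct_error_rate": "score"}
    )
    participants = pd.read_csv(RES / "data/participants.csv")
    covs = scores.merge(participants[["participant", "sex"]], on="participant")

    tables = {
        "change_rate": pd.read_csv(RES / "change_rates.csv"),
        "tc5_continuation": pd.read_csv(RES / "thought_counts.csv"),
        "hc5": pd.read_csv(RES / "thought_counts.csv"),
        "hrv_hf": pd.read_csv(RES / "hrv.csv"),
        "hrv_lfhf": pd.read_csv(RES / "hrv.csv"),
    }
    specs = MODEL_SPECS(SamplerSettings())
    root = np.random.SeedSequence(SEED)
    for (name, spec), child in zip(specs.items(), root.spawn(len(specs))):
        table = tables[name].copy()
        table["vibration"] = (table["block"] == "vib").astype(int)
        table = table.merge(covs[["participant", "score", "sex"]], on="participant")
        fit = fit_model(spec, table, seed=int(child.generate_state(1)[0] % 2**31))
        fit.summary.to_csv(RES / f"posterior_{name}.csv")
        focus = "score:vibration" if "score:vibration" in spec.fixed_effects else "vibration"
        c = fit.coefficient(focus)
        verdict = "supported" if fit.supported(focus) else "CI includes 0"
        print(
            f"{name:18s} {focus:16s} b = {c['estimate']:+.3f} "
            f"[{c['l95']:+.3f}, {c['u95']:+.3f}]  {verdict}; "
            f"max Rhat {fit.summary.rhat.max():.3f}"
        )
    print(
        "\nreading: vibration raises the change rate, and the score-by-"
        "vibration interaction on TC5 continuation is negative (accurate "
        "perceivers continue self-referential thought more under vibration). "
        "The highly-contemplated-5 interaction is planted at half the size "
        "and is not always resolvable in a single cohort. ln HF can show a "
        "small vibration-block elevation: the planted cardiac decelerations "
        "themselves carry band power. The clean no-drift HRV null holds when "
        "no vibration effect is planted (see the recovery and test suites)."
    )
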