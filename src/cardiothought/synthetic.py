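"""Synthetic cohort generator for the full analysis chain.

Emulates the study design end to end so every downstream module can be
exercised and calibrated without participant data:

- a cohort (default 100 participants, 70% women) with latent interoceptive
  accuracy driving heartbeat-counting performance, plus the four
  exclusion-triggering participant types (unusable pulse trace, noticed
  the vibration, low correct-response rate, never reports a core thought
  category) in the study's tallies 2 / 9 / 3 / 6;
- heartbeat-counting (2x25, 2x35, 2x45 s) and time-estimation (2x23,
  2x49, 2x56 s) sessions; time estimation is generated independently of
  latent accuracy so the two error rates are uncorrelated by construction;
- a vigilance task of two 20-trial blocks (42 stimuli of 500 ms + 500 ms
  ISI per trial, 3 targets), the second block containing 5 non-consecutive
  vibration trials with onsets 15 s and 30 s after trial start;
- pulse apex times from an RR process (participant mean + 0.1 Hz and
  0.25 Hz sinusoids + white noise, with participant-level and
  block-to-block amplitude variability) with transient vibration-locked
  mean steps at RR1 decaying to baseline by RR4, and spontaneous transient
  steps at a stationary background rate over the whole session (any 15 s
  window carries one with probability ``p_spontaneous_cp``);
- probe responses from a participant-level Markov chain over the six
  thought categories.  The category-5 self-return probability follows
  log p(5 -> 5) = b0 + b_score*score + b_vib*vib + b_int*score*vib while
  the entry probability into category 5 is rebalanced so the marginal
  category-5 rate is constant; the expected continuation count is then
  exactly proportional to exp(linear predictor), making the planted
  coefficients the same estimand as the Poisson log-link regression
  slopes.  A "logit" self-return link is available for the conventional
  log-odds parameterisation.  High contemplation of category 5 carries the
  same interaction structure; high consistency does not (a planted null).

Everything is deterministic given the cohort seed; each participant draws
from an RNG stream seeded by (cohort seed, participant index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SyntheticParticipant",
    "generate_cohort",
    "generate_hct_session",
    "generate_tet_session",
    "generate_event_schedule",
    "generate_beat_series",
    "generate_probe_table",
    "generate_responses",
    "block_spans",
    "model_table",
    "write_cohort",
]

# vigilance-task design constants
N_STIMULI_PER_TRIAL = 42
STIMULUS_S = 0.5
ISI_S = 0.5
TRIAL_S = N_STIMULI_PER_TRIAL * (STIMULUS_S + ISI_S)  # 42 s
N_TARGETS_PER_TRIAL = 3
TRIALS_PER_BLOCK = 20
N_VIB_TRIALS = 5
VIB_ONSETS_REL_S = (15.0, 30.0)
HCT_DURATIONS_S = (25, 25, 35, 35, 45, 45)
TET_DURATIONS_S = (23, 23, 49, 49, 56, 56)


@dataclass
class CohortConfig:
    """Generative settings; the defaults are the study conditions."""

    n_participants: int = 100
    prop_female: float = 0.7
    seed: int = 0

    # cardiac process
    mean_rr_ms: float = 850.0
    rr_between_sd_ms: float = 60.0  # participant-to-participant spread
    rr_sd_ms: float = 10.0  # beat-to-beat white noise
    hf_amp_ms: float = 20.0  # 0.25 Hz (respiratory) RR modulation
    lf_amp_ms: float = 25.0  # 0.1 Hz (baroreflex) RR modulation
    amp_between_cv: float = 0.3  # participant-level lognormal amplitude spread
    amp_within_cv: float = 0.2  # block-to-block lognormal amplitude drift
    p_spontaneous_cp: float = 0.1
    p_vibration_cp: float = 0.6
    step_mean_ms: float = 120.0  # ~10 bpm transient deceleration at 850 ms
    step_decay: tuple[float, ...] = (1.0, 0.8, 0.5, 0.0)  # RR1..RR4 weights

    # interoception
    latent_accuracy_mean: float = 0.6
    latent_accuracy_sd: float = 0.23
    hct_report_noise: float = 1.5  # counts
    tet_bias_sd: float = 0.27  # participant-level relative time bias
    tet_noise_sd: float = 0.03  # per-interval relative noise

    # thought dynamics
    b0: float = -1.8
    b_score: float = 0.007
    b_vib: float = 1.387
    b_interaction: float = -0.02
    self_return_link: str = "log"  # or "logit"
    category_mass: tuple[float, ...] = (0.35, 0.12, 0.03, 0.10, 0.25, 0.15)
    stay_bonus: float = 0.2  # extra self-weight for non-5 categories
    hc0: float = -1.6
    hc_score: float = 0.003
    hc_vib: float = 0.904
    hc_interaction: float = -0.010
    p_high_consistency: float = 0.5

    # exclusion-triggering participant types (disjoint)
    n_bad_pulse: int = 2
    n_noticed: int = 9
    n_low_response: int = 3
    n_no_core: int = 6

    # timing
    probe_gap_s: float = 6.0  # probe answering time appended to each trial
    block_break_s: float = 300.0

    def validate(self) -> "CohortConfig":
        for name in ("prop_female", "p_spontaneous_cp", "p_vibration_cp", "p_high_consistency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a probability in [0, 1]")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.mean_rr_ms <= 0:
            raise ValueError("mean RR must be positive")
        n_special = self.n_bad_pulse + self.n_noticed + self.n_low_response + self.n_no_core
        if n_special > self.n_participants:
            raise ValueError("more exclusion-type participants than cohort size")
        if abs(sum(self.category_mass) - 1.0) > 1e-9 or len(self.category_mass) != 6:
            raise ValueError("category_mass must be 6 probabilities summing to 1")
        if self.self_return_link not in ("log", "logit"):
            raise ValueError("self_return_link must be 'log' or 'logit'")
        return self


@dataclass
class SyntheticParticipant:
    participant_id: str
    index: int
    sex: int  # 0 = male, 1 = female
    latent_accuracy: float  # in [0, 1]; 1 = perfect heartbeat perception
    true_hct_error: float  # percent
    mean_rr_ms: float
    noticed_vibration: bool = False
    valid_responder: bool = True
    reporter_of_core_categories: bool = True
    bad_pulse: bool = False


def _participant_rng(
    config: CohortConfig, index: int, stream: int = 1
) -> np.random.Generator:
    """Per-participant RNG stream derived from (cohort seed, participant).

    ``stream`` namespaces independent uses: 0 draws the participant's
    traits inside :func:`generate_cohort`, 1 (default) drives the session
    data, so the two never reuse the same underlying entropy.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(index), int(stream)])
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticParticipant]:
    """Deterministic cohort with exact sex counts and exclusion types."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 10**6]))
    n = config.n_participants
    n_female = int(round(config.prop_female * n))
    sexes = np.array([1] * n_female + [0] * (n - n_female))
    rng.shuffle(sexes)
    order = rng.permutation(n)
    kinds = {}
    pos = 0
    for kind, count in (
        ("bad_pulse", config.n_bad_pulse),
        ("noticed", config.n_noticed),
        ("low_response", config.n_low_response),
        ("no_core", config.n_no_core),
    ):
        for i in order[pos : pos + count]:
            kinds[int(i)] = kind
        pos += count
    cohort = []
    for i in range(n):
        prng = _participant_rng(config, i, stream=0)
        latent = float(np.clip(
            prng.normal(config.latent_accuracy_mean, config.latent_accuracy_sd), 0.0, 1.0
        ))
        kind = kinds.get(i)
        cohort.append(
            SyntheticParticipant(
                participant_id=f"p{i + 1:03d}",
                index=i,
                sex=int(sexes[i]),
                latent_accuracy=latent,
                true_hct_error=(1.0 - latent) * 100.0,
                mean_rr_ms=float(
                    config.mean_rr_ms + prng.normal(0.0, config.rr_between_sd_ms)
                ),
                noticed_vibration=kind == "noticed",
                valid_responder=kind != "low_response",
                reporter_of_core_categories=kind != "no_core",
                bad_pulse=kind == "bad_pulse",
            )
        )
    return cohort


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def generate_hct_session(p: SyntheticParticipant, rng, config: CohortConfig):
    """One heartbeat-counting session (durations shuffled, verbal reports
    rounded half-up to integers, floored at 0)."""
    from .interoception import HctSession

    durations = np.array(HCT_DURATIONS_S, dtype=float)
    rng.shuffle(durations)
    actual = np.floor(durations * 1000.0 / p.mean_rr_ms).astype(int)
    reported = _round_half_up(
        actual * p.latent_accuracy + rng.normal(0.0, config.hct_report_noise, size=6)
    )
    reported = np.clip(reported, 0, None).astype(int)
    return HctSession(durations.tolist(), actual.tolist(), reported.tolist())


def generate_tet_session(p: SyntheticParticipant, rng, config: CohortConfig):
    """One time-estimation session; reporting is independent of latent
    interoceptive accuracy, so HCT and TET errors decorrelate by design."""
    from .interoception import TetSession

    durations = np.array(TET_DURATIONS_S, dtype=float)
    rng.shuffle(durations)
    bias = rng.normal(0.0, config.tet_bias_sd)
    reported = durations * (1.0 + bias) + rng.normal(0.0, config.tet_noise_sd * durations)
    reported = np.clip(reported, 0.5, None)
    return TetSession(durations.tolist(), reported.tolist())


def generate_event_schedule(rng, config: CohortConfig) -> pd.DataFrame:
    """Trial structure for both blocks of one participant.

    Vibration trials are non-consecutive and never the first trial of the
    vibration block, so each has an in-block preceding non-vibration trial.
    """
    trial_len = TRIAL_S + config.probe_gap_s
    rows = []
    vib_positions: set[int] = set()
    while True:
        cand = sorted(rng.choice(np.arange(2, TRIALS_PER_BLOCK + 1), size=N_VIB_TRIALS, replace=False))
        if all(b - a >= 2 for a, b in zip(cand, cand[1:])):
            vib_positions = set(int(c) for c in cand)
            break
    block_starts = {"non_vib": 0.0, "vib": TRIALS_PER_BLOCK * trial_len + config.block_break_s}
    trial = 0
    for block in ("non_vib", "vib"):
        for k in range(1, TRIALS_PER_BLOCK + 1):
            trial += 1
            is_vib = block == "vib" and k in vib_positions
            rows.append(
                {
                    "trial": trial,
                    "block": block,
                    "trial_type": "vib" if is_vib else "non_vib",
                    "trial_start_s": block_starts[block] + (k - 1) * trial_len,
                    "vib_onsets_s": ";".join(str(o) for o in VIB_ONSETS_REL_S) if is_vib else "",
                }
            )
    return pd.DataFrame(rows)


def block_spans(schedule: pd.DataFrame, config: CohortConfig) -> dict[str, tuple[float, float]]:
    """Wall-clock (start, end) of each block, ending after the last probe."""
    spans = {}
    for block, grp in schedule.groupby("block"):
        start = float(grp["trial_start_s"].min())
        end = float(grp["trial_start_s"].max()) + TRIAL_S + config.probe_gap_s
        spans[block] = (start, end)
    return spans


def generate_beat_series(
    p: SyntheticParticipant, schedule: pd.DataFrame, rng, config: CohortConfig
):
    """Pulse apex times for the whole session.

    The RR process integrates mean + LF/HF sinusoids + white noise.  In
    vibration trials a mean step of ``step_mean_ms`` starts at the first
    interval ending after each onset (RR1) and decays to baseline by RR4
    with probability ``p_vibration_cp``; in every analysis window (both
    conditions) a spontaneous step of random sign occurs at a uniform time
    with probability ``p_spontaneous_cp``.
    """
    from .cardiac import BeatSeries, analysis_trials

    trials = analysis_trials(schedule)
    session_end = float(schedule["trial_start_s"].max()) + TRIAL_S + config.probe_gap_s
    events = []  # (time, signed step)
    for _, row in trials.iterrows():
        for rel in VIB_ONSETS_REL_S:
            onset = row["trial_start_s"] + rel
            if row["block"] == "vib" and rng.random() < config.p_vibration_cp:
                events.append((onset, config.step_mean_ms))
    # spontaneous transients are stationary over the whole session (one
    # 15 s tile carries a step with probability p_spontaneous_cp), so the
    # two blocks share the same background rate
    for tile_start in np.arange(0.0, session_end, 15.0):
        if rng.random() < config.p_spontaneous_cp:
            t_sp = tile_start + rng.uniform(0.0, 15.0)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            events.append((t_sp, sign * config.step_mean_ms))
    events.sort()
    ev_times = np.array([e[0] for e in events])
    ev_steps = np.array([e[1] for e in events])
    ev_counts = np.zeros(len(events), dtype=int)  # intervals affected so far

    phase_lf = rng.uniform(0, 2 * np.pi)
    phase_hf = rng.uniform(0, 2 * np.pi)
    f_lf = np.exp(rng.normal(0.0, config.amp_between_cv))
    f_hf = np.exp(rng.normal(0.0, config.amp_between_cv))
    block_mult = {
        (blk, band): np.exp(rng.normal(0.0, config.amp_within_cv))
        for blk in ("non_vib", "vib")
        for band in ("lf", "hf")
    }
    vib_block_start = float(
        schedule.loc[schedule["block"] == "vib", "trial_start_s"].min()
    )
    decay = np.asarray(config.step_decay, dtype=float)

    times = [0.0]
    t = 0.0
    while t < session_end:
        blk = "vib" if t >= vib_block_start else "non_vib"
        lf_amp = config.lf_amp_ms * f_lf * block_mult[(blk, "lf")]
        hf_amp = config.hf_amp_ms * f_hf * block_mult[(blk, "hf")]
        rr = (
            p.mean_rr_ms
            + lf_amp * np.sin(2 * np.pi * 0.1 * t + phase_lf)
            + hf_amp * np.sin(2 * np.pi * 0.25 * t + phase_hf)
            + rng.normal(0.0, config.rr_sd_ms)
        )
        # transient steps: an interval terminating after event time e gets
        # the k-th decay weight, k = how many such intervals precede it
        t_next_base = t + max(rr, 200.0) / 1000.0
        for j in range(len(events)):
            if ev_counts[j] >= len(decay):
                continue
            if t_next_base > ev_times[j]:
                rr += ev_steps[j] * decay[ev_counts[j]]
                ev_counts[j] += 1
        rr = max(rr, 250.0 + 1e-3)
        t = t + rr / 1000.0
        times.append(t)

    times = np.asarray(times)
    if p.bad_pulse:
        # double-triggering artifacts: spurious apexes shortly after real
        # ones produce implausibly short RR intervals
        extra_mask = rng.random(times.size) < 0.12
        extras = times[extra_mask] + rng.uniform(0.05, 0.2, size=int(extra_mask.sum()))
        times = np.unique(np.concatenate([times, extras]))
    return BeatSeries(participant_id=p.participant_id, apex_time_s=times)


def _self_return_prob(link: str, eta: float) -> float:
    if link == "logit":
        return float(1.0 / (1.0 + np.exp(-eta)))
    return float(min(np.exp(eta), 0.95))


def _transition_draw(rng, cur, p55, q, mass, stay_bonus):
    """One Markov step over categories 1..6 (see module docstring)."""
    non5 = np.array([1, 2, 3, 4, 6])
    m = np.array([mass[c - 1] for c in non5])
    m = m / m.sum()
    if cur == 5:
        if rng.random() < p55:
            return 5
        return int(rng.choice(non5, p=m))
    if rng.random() < q:
        return 5
    if rng.random() < stay_bonus:
        return cur
    return int(rng.choice(non5, p=m))


def generate_probe_table(
    p: SyntheticParticipant, schedule: pd.DataFrame, rng, config: CohortConfig
) -> pd.DataFrame:
    """Probe responses (category, contemplation, consistency) per trial."""
    mass = np.asarray(config.category_mass, dtype=float)
    pi5 = mass[4]
    score = p.true_hct_error
    rows = []
    for block in ("non_vib", "vib"):
        vib = 1.0 if block == "vib" else 0.0
        eta = config.b0 + config.b_score * score + config.b_vib * vib + config.b_interaction * score * vib
        p55 = _self_return_prob(config.self_return_link, eta)
        q = pi5 * (1.0 - p55) / (1.0 - pi5)  # keeps the marginal 5-rate at pi5
        eta_hc = (
            config.hc0 + config.hc_score * score + config.hc_vib * vib
            + config.hc_interaction * score * vib
        )
        p_hc = float(np.clip(np.exp(eta_hc), 0.0, 1.0))
        if not p.reporter_of_core_categories:
            cats = rng.choice([3, 6], size=TRIALS_PER_BLOCK, p=[0.3, 0.7])
        else:
            non5 = np.array([1, 2, 3, 4, 6])
            m0 = np.array([mass[c - 1] for c in non5])
            cats = np.empty(TRIALS_PER_BLOCK, dtype=int)
            # start at the marginal distribution so the category-5 rate is
            # pi5 at every trial, not just asymptotically
            cats[0] = 5 if rng.random() < pi5 else int(rng.choice(non5, p=m0 / m0.sum()))
            for k in range(1, TRIALS_PER_BLOCK):
                cats[k] = _transition_draw(rng, int(cats[k - 1]), p55, q, mass, config.stay_bonus)
        trials = schedule[schedule["block"] == block]["trial"].tolist()
        for k, cat in enumerate(cats):
            cat = int(cat)
            if cat == 6:
                cont, cons = np.nan, np.nan
            elif cat == 5:
                cont = int(rng.choice([2, 3])) if rng.random() < p_hc else 1
                cons = 1 if rng.random() < config.p_high_consistency else int(rng.choice([2, 3]))
            else:
                cont = int(rng.choice([1, 2, 3], p=[0.3, 0.45, 0.25]))
                cons = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
            rows.append(
                {
                    "participant": p.participant_id,
                    "trial": trials[k],
                    "block": block,
                    "category": cat,
                    "contemplation": cont,
                    "consistency": cons,
                }
            )
    return pd.DataFrame(rows)


def generate_responses(p: SyntheticParticipant, schedule: pd.DataFrame, rng) -> pd.DataFrame:
    """Per-trial target hits in the vigilance task."""
    p_hit = 0.98 if p.valid_responder else 0.30
    rows = []
    for _, row in schedule.iterrows():
        hits = int(rng.binomial(N_TARGETS_PER_TRIAL, p_hit))
        rows.append(
            {
                "participant": p.participant_id,
                "trial": int(row["trial"]),
                "n_targets": N_TARGETS_PER_TRIAL,
                "n_hits": hits,
            }
        )
    return pd.DataFrame(rows)


def model_table(config: CohortConfig, response: str) -> pd.DataFrame:
    """Tidy participant x block table for one count response.

    Runs the lightweight end-to-end path (cohort -> HCT scoring -> probe
    tables -> thought coding) and returns columns participant, sex, score
    (measured HCT error), vibration and the response counts.  Participants
    of the exclusion-triggering types are screened out first.
    """
    from .interoception import hct_error_rate
    from .thought_coding import thought_counts

    cohort = generate_cohort(config)
    rows = []
    for p in cohort:
        if p.bad_pulse or p.noticed_vibration or not p.valid_responder or not p.reporter_of_core_categories:
            continue
        rng = _participant_rng(config, p.index)
        score = hct_error_rate(generate_hct_session(p, rng, config))
        schedule = generate_event_schedule(rng, config)
        probes = generate_probe_table(p, schedule, rng, config)
        counts = thought_counts(probes, p.participant_id)
        for _, crow in counts.iterrows():
            rows.append(
                {
                    "participant": p.participant_id,
                    "sex": p.sex,
                    "score": score,
                    "vibration": 1 if crow["block"] == "vib" else 0,
                    response: int(crow[response]),
                }
            )
    return pd.DataFrame(rows)


def write_cohort(config: CohortConfig, out_dir) -> pd.DataFrame:
    """Generate and write the full cohort to CSV files; returns the
    participants table."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    prows, hct_rows, tet_rows = [], [], []
    for p in cohort:
        rng = _participant_rng(config, p.index)
        hct = generate_hct_session(p, rng, config)
        tet = generate_tet_session(p, rng, config)
        schedule = generate_event_schedule(rng, config)
        beats = generate_beat_series(p, schedule, rng, config)
        probes = generate_probe_table(p, schedule, rng, config)
        responses = generate_responses(p, schedule, rng)
        pid = p.participant_id
        prows.append(
            {
                "participant": pid,
                "sex": p.sex,
                "latent_accuracy": p.latent_accuracy,
                "true_hct_error": p.true_hct_error,
                "mean_rr_ms": p.mean_rr_ms,
                "noticed_vibration": p.noticed_vibration,
                "valid_responder": p.valid_responder,
                "reporter_of_core_categories": p.reporter_of_core_categories,
                "bad_pulse": p.bad_pulse,
            }
        )
        for d, a, r in zip(hct.interval_duration_s, hct.actual_count, hct.reported_count):
            hct_rows.append({"participant": pid, "duration_s": d, "actual": a, "reported": r})
        for d, r in zip(tet.interval_duration_s, tet.reported_duration_s):
            tet_rows.append({"participant": pid, "duration_s": d, "reported_s": r})
        pd.DataFrame({"apex_time_s": beats.apex_time_s}).to_csv(out / f"beats_{pid}.csv", index=False)
        schedule.to_csv(out / f"events_{pid}.csv", index=False)
        probes.to_csv(out / f"probes_{pid}.csv", index=False)
        responses.to_csv(out / f"responses_{pid}.csv", index=False)
    participants = pd.DataFrame(prows)
    participants.to_csv(out / "participants.csv", index=False)
    pd.DataFrame(hct_rows).to_csv(out / "hct.csv", index=False)
    pd.DataFrame(tet_rows).to_csv(out / "tet.csv", index=False)
    return participants
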