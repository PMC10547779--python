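"""The synthetic cohort generator: design constants, determinism, planted
structure."""

from dataclasses import replace

import numpy as np
import pytest

from cardiothought import synthetic as syn
from cardiothought.cardiac import build_event_windows, compute_change_rates
from cardiothought.interoception import hct_error_rate, tet_error_rate
from cardiothought.thought_coding import validate_probe_table


def participant_bundle(cfg, index=0):
    cohort = syn.generate_cohort(cfg)
    p = cohort[index]
    rng = syn._participant_rng(cfg, p.index)
    return p, rng


class TestCohort:
    def test_study_scale_sex_ratio(self):
        cohort = syn.generate_cohort(syn.CohortConfig(n_participants=100, prop_female=0.7, seed=1))
        assert len(cohort) == 100
        assert sum(p.sex for p in cohort) == 70

    def test_all_male_boundary(self):
        cohort = syn.generate_cohort(
            syn.CohortConfig(n_participants=2, prop_female=0.0, seed=1,
                             n_bad_pulse=0, n_noticed=0, n_low_response=0, n_no_core=0)
        )
        assert [p.sex for p in cohort] == [0, 0]

    def test_deterministic_given_seed(self, clean_config):
        a = syn.generate_cohort(clean_config)
        b = syn.generate_cohort(clean_config)
        assert a == b

    def test_exclusion_types_disjoint_and_counted(self):
        cohort = syn.generate_cohort(syn.CohortConfig(seed=4))
        kinds = [
            (p.bad_pulse, p.noticed_vibration, not p.valid_responder,
             not p.reporter_of_core_categories)
            for p in cohort
        ]
        assert sum(k[0] for k in kinds) == 2
        assert sum(k[1] for k in kinds) == 9
        assert sum(k[2] for k in kinds) == 3
        assert sum(k[3] for k in kinds) == 6
        assert all(sum(k) <= 1 for k in kinds)  # disjoint

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            syn.CohortConfig(p_vibration_cp=1.4).validate()


class TestHctTet:
    def test_durations_and_totals(self, clean_config):
        p, rng = participant_bundle(clean_config)
        s = syn.generate_hct_session(p, rng, clean_config)
        assert sorted(s.interval_duration_s) == [25, 25, 35, 35, 45, 45]
        assert sum(s.interval_duration_s) == 210
        t = syn.generate_tet_session(p, rng, clean_config)
        assert sorted(t.interval_duration_s) == [23, 23, 49, 49, 56, 56]

    def test_perfect_perceiver_zero_error(self, clean_config):
        cfg = replace(clean_config, hct_report_noise=0.0)
        p, rng = participant_bundle(cfg)
        p.latent_accuracy = 1.0
        s = syn.generate_hct_session(p, rng, cfg)
        assert s.reported_count == s.actual_count
        assert hct_error_rate(s) == 0.0

    def test_eighty_percent_perceiver_scores_near_20(self):
        """latent accuracy 0.8, no noise, counts [30,30,42,42,54,54]:
        reports round to [24,24,34,34,43,43] and score to ~19.8%."""
        from cardiothought.interoception import HctSession

        actual = [30, 30, 42, 42, 54, 54]
        reported = list(np.floor(np.array(actual) * 0.8 + 0.5).astype(int))
        assert reported == [24, 24, 34, 34, 43, 43]
        err = hct_error_rate(HctSession([25, 25, 35, 35, 45, 45], actual, reported))
        assert err == pytest.approx(19.806, abs=0.01)

    def test_unbiased_reporter_zero_tet_error(self, clean_config):
        cfg = replace(clean_config, tet_bias_sd=0.0, tet_noise_sd=0.0)
        p, rng = participant_bundle(cfg)
        assert tet_error_rate(syn.generate_tet_session(p, rng, cfg)) == pytest.approx(0.0)

    def test_hct_tet_errors_uncorrelated_across_seeds(self):
        """Time estimation is generated independently of latent accuracy, so
        cohort-level Pearson r between the two error rates stays small."""
        from scipy.stats import pearsonr

        rs = []
        for seed in range(20):
            cfg = syn.CohortConfig(n_participants=98, seed=seed,
                                   n_bad_pulse=0, n_noticed=0, n_low_response=0, n_no_core=0)
            hct_err, tet_err = [], []
            for p in syn.generate_cohort(cfg):
                rng = syn._participant_rng(cfg, p.index)
                hct_err.append(hct_error_rate(syn.generate_hct_session(p, rng, cfg)))
                tet_err.append(tet_error_rate(syn.generate_tet_session(p, rng, cfg)))
            rs.append(pearsonr(hct_err, tet_err)[0])
        assert np.mean(np.abs(rs)) < 0.15


class TestSchedule:
    def test_design_constants(self, clean_config):
        _, rng = participant_bundle(clean_config)
        sched = syn.generate_event_schedule(rng, clean_config)
        assert len(sched) == 40
        assert (sched.groupby("block").size() == 20).all()
        vib = sched[sched["trial_type"] == "vib"]
        assert len(vib) == 5
        assert (vib["block"] == "vib").all()
        # non-consecutive vibration trials
        trials = sorted(vib["trial"])
        assert all(b - a >= 2 for a, b in zip(trials, trials[1:]))

    def test_trial_duration_is_42s(self, clean_config):
        assert syn.TRIAL_S == pytest.approx(
            syn.N_STIMULI_PER_TRIAL * (syn.STIMULUS_S + syn.ISI_S)
        ) == 42.0


class TestBeatSeries:
    def test_beats_per_trial_arithmetic(self, clean_config):
        cfg = replace(clean_config, rr_between_sd_ms=0.0, rr_sd_ms=0.0,
                      lf_amp_ms=0.0, hf_amp_ms=0.0,
                      p_vibration_cp=0.0, p_spontaneous_cp=0.0)
        p, rng = participant_bundle(cfg)
        p.mean_rr_ms = 850.0
        sched = syn.generate_event_schedule(rng, cfg)
        beats = syn.generate_beat_series(p, sched, rng, cfg)
        t0 = float(sched["trial_start_s"].iloc[0])
        in_trial = ((beats.apex_time_s >= t0) & (beats.apex_time_s < t0 + 42.0)).sum()
        assert abs(in_trial - 42000 / 850) <= 1

    def test_degenerate_probabilities_place_steps_deterministically(self, clean_config):
        """p_vib = 1, p_spont = 0, no noise: every vibration window has a
        mean shift at RR1 and no comparison window has any shift."""
        cfg = replace(clean_config, rr_sd_ms=0.0, lf_amp_ms=0.0, hf_amp_ms=0.0,
                      rr_between_sd_ms=0.0,
                      p_vibration_cp=1.0, p_spontaneous_cp=0.0, step_mean_ms=80.0)
        p, rng = participant_bundle(cfg)
        sched = syn.generate_event_schedule(rng, cfg)
        beats = syn.generate_beat_series(p, sched, rng, cfg)
        windows = build_event_windows(beats, sched)
        for w in windows["vib"]:
            assert w.rr_values[w.label_position(1)] - w.rr_values[w.rr0_index] == pytest.approx(80.0, abs=1e-6)
        for w in windows["non_vib"]:
            assert np.ptp(w.rr_values) == pytest.approx(0.0, abs=1e-6)

    def test_deviation_profile_decays_by_rr4(self, clean_config):
        """Averaged over many vibration windows, RR deviations peak at
        RR1-RR3 and return to ~0 by RR4."""
        from cardiothought.cardiac import rr_deviation_profile

        cfg = replace(clean_config, n_participants=12, p_vibration_cp=1.0,
                      p_spontaneous_cp=0.0)
        profs = []
        for p in syn.generate_cohort(cfg):
            rng = syn._participant_rng(cfg, p.index)
            sched = syn.generate_event_schedule(rng, cfg)
            beats = syn.generate_beat_series(p, sched, rng, cfg)
            profs.append(rr_deviation_profile(build_event_windows(beats, sched)["vib"]))
        prof = np.mean(profs, axis=0)  # >= 120 windows
        assert prof[0] > 40
        assert prof[1] > 10
        assert abs(prof[3]) < prof[0] / 3

    def test_bad_pulse_participants_flagged_by_rr_filter(self):
        cfg = syn.CohortConfig(n_participants=4, seed=9, n_bad_pulse=1,
                               n_noticed=0, n_low_response=0, n_no_core=0)
        fracs = {}
        for p in syn.generate_cohort(cfg):
            rng = syn._participant_rng(cfg, p.index)
            sched = syn.generate_event_schedule(rng, cfg)
            beats = syn.generate_beat_series(p, sched, rng, cfg)
            fracs[p.bad_pulse] = beats.implausible_rr_fraction()
        assert fracs[True] > 0.05
        assert fracs[False] <= 0.05


class TestProbes:
    def test_twenty_rows_per_block_and_category6_rule(self, clean_config):
        p, rng = participant_bundle(clean_config)
        sched = syn.generate_event_schedule(rng, clean_config)
        probes = syn.generate_probe_table(p, sched, rng, clean_config)
        assert len(probes) == 40
        validate_probe_table(probes)  # includes the category-6 rule

    def test_interaction_sign_monte_carlo(self):
        """With a negative planted interaction, accurate perceivers (low HCT
        error) continue category 5 more in the vibration block; the
        vibration-block continuation gap shrinks as error grows."""
        cfg = syn.CohortConfig(n_participants=240, seed=77, n_bad_pulse=0,
                               n_noticed=0, n_low_response=0, n_no_core=0)
        tab = syn.model_table(cfg, "continuation_5")
        vib = tab[tab.vibration == 1]
        accurate = vib[vib.score < vib.score.median()]["continuation_5"].mean()
        inaccurate = vib[vib.score >= vib.score.median()]["continuation_5"].mean()
        assert accurate > inaccurate

    def test_non_reporters_never_use_core_categories(self):
        cfg = syn.CohortConfig(n_participants=8, seed=5, n_bad_pulse=0,
                               n_noticed=0, n_low_response=0, n_no_core=8)
        for p in syn.generate_cohort(cfg):
            rng = syn._participant_rng(cfg, p.index)
            sched = syn.generate_event_schedule(rng, cfg)
            probes = syn.generate_probe_table(p, sched, rng, cfg)
            assert set(probes["category"]) <= {3, 6}


class TestChangeRateMonotonicity:
    def test_rate_increases_with_vibration_probability(self):
        """Expected change rate rises with the planted vibration-step
        probability (3 levels, ~100 windows each)."""
        means = []
        for p_vib in (0.0, 0.4, 0.9):
            cfg = syn.CohortConfig(n_participants=10, seed=31, p_vibration_cp=p_vib,
                                   p_spontaneous_cp=0.05,
                                   n_bad_pulse=0, n_noticed=0, n_low_response=0, n_no_core=0)
            rates = []
            for p in syn.generate_cohort(cfg):
                rng = syn._participant_rng(cfg, p.index)
                sched = syn.generate_event_schedule(rng, cfg)
                beats = syn.generate_beat_series(p, sched, rng, cfg)
                cr = compute_change_rates(beats, sched)
                rates.append(float(cr.loc[cr.block == "vib", "rate_percent"].iloc[0]))
            means.append(np.mean(rates))
        assert means[0] < means[1] < means[2]


def test_written_cohort_is_byte_identical_across_runs(tmp_path, clean_config):
    cfg = replace(clean_config, n_participants=3)
    a, b = tmp_path / "a", tmp_path / "b"
    syn.write_cohort(cfg, a)
    syn.write_cohort(cfg, b)
    files = sorted(f.name for f in a.iterdir())
    assert files == sorted(f.name for f in b.iterdir())
    for name in files:
        assert (a / name).read_bytes() == (b / name).read_bytes()
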