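"""Event-locked RR windows, deviation profiles and the change-rate statistic."""

import numpy as np
import pandas as pd
import pytest

from cardiothought.cardiac import (
    BeatSeries,
    ChangePointResult,
    EventWindow,
    analysis_trials,
    build_event_windows,
    change_rate,
    detect_apexes,
    detect_changepoints,
    rr_deviation_profile,
)

def uniform_beats(rr_ms=1000.0, duration_s=60.0, pid="p"):
    return BeatSeries(pid, np.arange(0.0, duration_s, rr_ms / 1000.0))


def single_trial_schedule(vib=True):
    return pd.DataFrame(
        [
            {"trial": 1, "block": "vib", "trial_type": "non_vib", "trial_start_s": 0.0, "vib_onsets_s": ""},
            {"trial": 2, "block": "vib", "trial_type": "vib", "trial_start_s": 48.0,
             "vib_onsets_s": "15.0;30.0" if vib else ""},
        ]
    )


class TestApexDetection:
    @staticmethod
    def pulse_train(fs=100.0, duration=60.0):
        # 1 Hz raised-cosine pulses with apexes at 0.5, 1.5, ..., 59.5 s
        t = np.arange(0, duration, 1 / fs)
        return t, np.maximum(np.cos(2 * np.pi * 1.0 * (t - 0.5)), 0.0) ** 2

    def test_pure_pulse_train(self):
        fs = 100.0
        _, trace = self.pulse_train(fs)
        apexes = detect_apexes(trace, fs)
        assert len(apexes) == 60
        assert np.allclose(np.diff(apexes), 1.0, atol=0.02)

    def test_robust_to_20db_noise(self):
        fs = 100.0
        t, clean = self.pulse_train(fs)
        noise = np.random.default_rng(1).normal(0, np.std(clean) / 10, t.size)  # SNR 20 dB
        assert len(detect_apexes(clean + noise, fs)) == 60

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError, match="flat|beats"):
            detect_apexes(np.zeros(6000), 100.0)


class TestEventWindows:
    def test_uniform_beats_label_assignment(self):
        beats = uniform_beats(1000.0, 120.0)
        sched = single_trial_schedule()
        windows = build_event_windows(beats, sched)
        w = windows["vib"][0]  # onset at 48 + 15 = 63 s... trial 2 starts at 48
        # onset is 63 s; apex at exactly 63 s ends the 62-63 s interval -> RR0
        assert w.onset_s == pytest.approx(63.0)
        assert w.complete

    def test_tie_rule_interval_ending_at_onset_is_rr0(self):
        # beats every second; onset exactly on an apex
        beats = BeatSeries("p", np.arange(0.0, 40.0))
        sched = pd.DataFrame(
            [
                {"trial": 1, "block": "vib", "trial_type": "non_vib", "trial_start_s": -48.0, "vib_onsets_s": ""},
                {"trial": 2, "block": "vib", "trial_type": "vib", "trial_start_s": 0.0, "vib_onsets_s": "15.0;30.0"},
            ]
        )
        w = build_event_windows(beats, sched)["vib"][0]
        term = beats.apex_time_s[1:]
        lo = w.onset_s - 5.0
        in_span = np.flatnonzero((term >= lo) & (term <= w.onset_s + 10.0))
        # RR0 terminates exactly at the onset (15 s)
        assert term[in_span[w.rr0_index]] == pytest.approx(15.0)
        # RR1 terminates at 16 s
        assert term[in_span[w.label_position(1)]] == pytest.approx(16.0)

    def test_windows_complete_at_850ms(self):
        beats = uniform_beats(850.0, 120.0)
        sched = single_trial_schedule()
        for w in build_event_windows(beats, sched)["vib"]:
            assert w.complete
            assert w.rr_values.size >= 17  # 15 s span at 850 ms

    def test_vibration_trial_without_onsets_rejected(self):
        sched = single_trial_schedule(vib=False)
        with pytest.raises(ValueError, match="onsets"):
            analysis_trials(sched)

    def test_vibration_trial_without_preceding_trial_rejected(self):
        sched = pd.DataFrame(
            [{"trial": 1, "block": "vib", "trial_type": "vib", "trial_start_s": 0.0,
              "vib_onsets_s": "15.0;30.0"}]
        )
        with pytest.raises(ValueError, match="preceding"):
            analysis_trials(sched)


class TestDeviationProfile:
    @staticmethod
    def stepped_window(step, decay=(1.0, 0.6, 0.3, 0.0)):
        rr = np.full(18, 850.0)
        rr0 = 6
        for k, d in enumerate(decay):
            rr[rr0 + 1 + k] += step * d
        return EventWindow(trial=1, interval_id=1, onset_s=15.0, rr_values=rr, rr0_index=rr0)

    def test_constant_rr_gives_zero_profile(self):
        w = EventWindow(1, 1, 15.0, np.full(18, 850.0), 6)
        assert np.allclose(rr_deviation_profile([w]), 0.0)

    def test_planted_decaying_step_profile(self):
        prof = rr_deviation_profile([self.stepped_window(80.0)])
        assert prof == pytest.approx([80.0, 48.0, 24.0, 0.0])

    def test_sign_symmetry(self):
        up = rr_deviation_profile([self.stepped_window(80.0)])
        down = rr_deviation_profile([self.stepped_window(-80.0)])
        assert np.allclose(up, -down)


class TestChangeRate:
    @staticmethod
    def result(rr, rr0=6, **kw):
        w = EventWindow(1, 1, 15.0, np.asarray(rr, float), rr0)
        return detect_changepoints(w, **kw)

    def test_no_changepoints_rate_zero(self):
        results = [self.result(np.full(18, 850.0)) for _ in range(10)]
        assert change_rate(results).rate_percent == 0.0

    def test_saturated_rate_100(self):
        results = [
            ChangePointResult(None, [7, 8, 9], hits=3, hit_rr123=True) for _ in range(10)
        ]
        assert change_rate(results).rate_percent == 100.0

    def test_direct_count_example(self):
        # change point at RR1 only, in 6 of 10 windows -> 6 / 30 * 100
        hit = ChangePointResult(None, [7], hits=1, hit_rr123=True)
        miss = ChangePointResult(None, [], hits=0, hit_rr123=False)
        cr = change_rate([hit] * 6 + [miss] * 4)
        assert cr.rate_percent == pytest.approx(20.0)

    def test_step_at_rr1_is_scored_as_hit(self):
        rr = np.full(18, 850.0) + np.random.default_rng(0).normal(0, 4, 18)
        rr[7:] += 90.0  # new segment starts at RR1 (rr0_index 6 + 1)
        res = self.result(rr)
        assert res.hit_rr123 and 7 in res.cp_indices

    def test_rate_invariant_to_unit_rescaling(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            rr = rng.normal(850, 10, 18)
            rr[9:] += 100
            a, b = self.result(rr), self.result(rr / 1000.0)
            assert a.cp_indices == b.cp_indices

    def test_zero_windows_rejected(self):
        with pytest.raises(ValueError, match="n_windows"):
            change_rate([], n_windows=0)
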