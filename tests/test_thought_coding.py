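"""Thought-probe validation, indicators and participant exclusions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiothought.thought_coding import (
    apply_exclusions,
    count_continuations,
    count_high_flags,
    count_transitions,
    thought_counts,
    validate_probe_table,
)


def probe_table(categories_nonvib, categories_vib, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    rows = []
    for block, cats in (("non_vib", categories_nonvib), ("vib", categories_vib)):
        for i, c in enumerate(cats):
            cont = np.nan if c == 6 else int(rng.integers(1, 4))
            cons = np.nan if c == 6 else int(rng.integers(1, 4))
            rows.append(
                {"trial": i + 1, "block": block, "category": c,
                 "contemplation": cont, "consistency": cons}
            )
    return pd.DataFrame(rows)


class TestValidation:
    def test_valid_table_accepted(self):
        t = probe_table([1] * 20, [5] * 20)
        assert len(validate_probe_table(t)) == 40

    def test_category6_with_followup_rejected(self):
        t = probe_table([1] * 20, [5] * 20)
        t.loc[0, "category"] = 6  # leaves contemplation present
        with pytest.raises(ValueError, match="absent"):
            validate_probe_table(t)

    def test_wrong_row_count_rejected(self):
        t = probe_table([1] * 19, [5] * 20)
        with pytest.raises(ValueError, match="19"):
            validate_probe_table(t)

    def test_out_of_range_category_rejected(self):
        t = probe_table([1] * 20, [5] * 20)
        t.loc[3, "category"] = 7
        with pytest.raises(ValueError, match="1-6"):
            validate_probe_table(t)


class TestContinuations:
    @pytest.mark.parametrize(
        "seq, cat, expected",
        [
            ([5] * 20, 5, 19),  # maximal
            ([5, 5, 5, 1, 5], 5, 2),
            ([1, 6, 1], 1, 0),  # pair broken by an excluded category
            ([1, 3, 1], 1, 0),  # non-bridging rule for category 3 too
            ([2, 2, 4, 4, 4], 2, 1),
            ([2, 2, 4, 4, 4], 4, 2),
        ],
    )
    def test_adjacent_pair_counts(self, seq, cat, expected):
        assert count_continuations(seq)[cat] == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 6), min_size=20, max_size=20))
    def test_total_continuations_bounded_by_19(self, seq):
        assert sum(count_continuations(seq).values()) <= 19


class TestTransitions:
    def test_enumerated_example(self):
        grouped, percat = count_transitions([1, 5, 1, 2])
        assert grouped == {"1_to_mw": 2, "mw_to_1": 1}
        assert percat["1_to_5"] == 1 and percat["1_to_2"] == 1 and percat["5_to_1"] == 1
        assert percat["1_to_4"] == 0

    def test_constant_sequence_no_transitions(self):
        grouped, percat = count_transitions([5] * 20)
        assert all(v == 0 for v in grouped.values())
        assert all(v == 0 for v in percat.values())

    def test_transitions_anchored_on_category_1(self):
        grouped, _ = count_transitions([2, 4, 2, 4])
        assert grouped == {"1_to_mw": 0, "mw_to_1": 0}

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 6), min_size=2, max_size=20))
    def test_reversal_symmetry(self, seq):
        """1 -> MW count of a sequence equals MW -> 1 of its reversal."""
        fwd, _ = count_transitions(seq)
        rev, _ = count_transitions(seq[::-1])
        assert fwd["1_to_mw"] == rev["mw_to_1"]
        assert fwd["mw_to_1"] == rev["1_to_mw"]


class TestHighFlags:
    def test_rule_application(self):
        rows = pd.DataFrame(
            {
                "category": [5, 5, 2],
                "contemplation": [3, 1, 3],
                "consistency": [1, 1, 1],
            }
        )
        assert count_high_flags(rows) == (1, 2)

    def test_no_category5_rows(self):
        rows = pd.DataFrame({"category": [1, 2], "contemplation": [1, 2], "consistency": [2, 3]})
        assert count_high_flags(rows) == (0, 0)

    def test_saturation(self):
        rows = pd.DataFrame(
            {"category": [5] * 20, "contemplation": [2] * 20, "consistency": [1] * 20}
        )
        assert count_high_flags(rows) == (20, 20)


def test_thought_counts_no_pair_spans_blocks():
    # vib block starts with the same category the non-vib block ended on;
    # the spanning pair must not be counted
    t = probe_table([1] * 19 + [5], [5] + [1] * 19)
    counts = thought_counts(t, "p")
    assert counts.set_index("block").loc["vib", "continuation_5"] == 0


class TestExclusions:
    @staticmethod
    def cohort(n=6):
        participants = pd.DataFrame(
            {"participant": [f"p{i}" for i in range(n)], "noticed_vibration": [False] * n}
        )
        probes = {
            f"p{i}": pd.DataFrame({"category": [1, 5, 2]}) for i in range(n)
        }
        responses = {
            f"p{i}": pd.DataFrame({"n_targets": [3] * 10, "n_hits": [3] * 10}) for i in range(n)
        }
        return participants, probes, responses

    def test_all_clear_retained(self):
        participants, probes, responses = self.cohort()
        rep = apply_exclusions(participants, probes, responses)
        assert not rep["excluded"].any()

    def test_noticed_vibration_excluded(self):
        participants, probes, responses = self.cohort()
        participants.loc[0, "noticed_vibration"] = True
        rep = apply_exclusions(participants, probes, responses).set_index("participant")
        assert rep.loc["p0", "excluded"] and "noticed_vibration" in rep.loc["p0", "reasons"]

    def test_exactly_half_correct_is_excluded(self):
        """'More than half' is read strictly: 50% correct trials fails."""
        participants, probes, responses = self.cohort()
        responses["p1"] = pd.DataFrame({"n_targets": [3] * 10, "n_hits": [3] * 5 + [0] * 5})
        rep = apply_exclusions(participants, probes, responses).set_index("participant")
        assert "low_correct_response" in rep.loc["p1", "reasons"]

    def test_no_core_categories_excluded(self):
        participants, probes, responses = self.cohort()
        probes["p2"] = pd.DataFrame({"category": [3, 6, 3, 6]})
        rep = apply_exclusions(participants, probes, responses).set_index("participant")
        assert "no_core_categories" in rep.loc["p2", "reasons"]

    def test_bad_pulse_excluded_via_rr_fraction(self):
        participants, probes, responses = self.cohort()
        rep = apply_exclusions(
            participants, probes, responses, implausible_rr={"p3": 0.2}
        ).set_index("participant")
        assert "bad_pulse_data" in rep.loc["p3", "reasons"]
        assert not rep.loc["p4", "excluded"]
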