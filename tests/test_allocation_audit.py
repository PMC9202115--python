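"""Allocation balance, restriction rule, and cross-over direction test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import randaudit as ra
from randaudit.allocation_audit import StratumAllocation
from randaudit.trial_model import StratumKey, TimeStratum

from oracles import binom_pmf_oracle, max_partial_block_imbalance


def _frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "clinical_center", "time_stratum", "arm", "enrollment_index"])


class TestAllocationCounts:
    def test_empty_input_gives_empty_table(self):
        table = ra.allocation_counts(_frame([]))
        assert table.strata == [] and table.time_margins == {}

    def test_counts_and_margins(self, small_frame):
        table = ra.allocation_counts(small_frame)
        assert len(table.strata) == 4
        for row in table.strata:
            assert row.delta == abs(row.n_treatment - row.n_control)
        early = table.margin("early")
        assert early.n_treatment + early.n_control == 20

    def test_conservation(self, trial_frame):
        """Sum of stratum sizes equals the number of records."""
        table = ra.allocation_counts(trial_frame)
        assert table.n_total == len(trial_frame)
        margins = sum(m.n_treatment + m.n_control for m in table.time_margins.values())
        assert margins == len(trial_frame)

    def test_favored_arm_none_iff_balanced(self):
        assert StratumAllocation(TimeStratum.EARLY, 10, 10).favored_arm is None
        assert StratumAllocation(TimeStratum.EARLY, 12, 9).favored_arm is ra.Arm.TREATMENT


class TestFlagDeviations:
    @staticmethod
    def _table(n_t, n_c):
        table = ra.AllocationTable()
        table.strata.append(StratumAllocation(StratumKey("C01", TimeStratum.EARLY), n_t, n_c))
        return table

    def test_balanced_not_flagged(self):
        assert ra.flag_allocation_deviations(self._table(10, 10)) == []

    def test_imbalance_beyond_block_bound(self):
        """Δ=3 under blocks of at most 4 cannot arise from a truncated
        block: the enumeration oracle says the max mid-block imbalance is 2."""
        assert max_partial_block_imbalance([2, 4], horizon=4) == 2
        flagged = ra.flag_allocation_deviations(self._table(12, 9), max_block_size=4)
        assert len(flagged) == 1
        assert flagged[0].exceeds_block_bound is True

    def test_imbalance_within_block_bound(self):
        flagged = ra.flag_allocation_deviations(self._table(11, 9), max_block_size=4)
        assert flagged[0].exceeds_block_bound is False

    @pytest.mark.parametrize("bad", [1, 3, 0])
    def test_invalid_max_block_size(self, bad):
        with pytest.raises(ValueError):
            ra.flag_allocation_deviations(self._table(10, 10), max_block_size=bad)

    def test_clean_synthetic_trial_never_exceeds_block_bound(self, trial_frame):
        table = ra.allocation_counts(trial_frame)
        ra.flag_allocation_deviations(table, max_block_size=8)
        assert all(row.exceeds_block_bound is False for row in table.strata)


class TestRestriction:
    @staticmethod
    def _center(n_early, n_late):
        rows = [(f"e{i}", "C01", "early", "treatment", i + 1) for i in range(n_early)]
        rows += [(f"l{i}", "C01", "late", "control", n_early + i + 1) for i in range(n_late)]
        return _frame(rows)

    def test_difference_below_threshold(self):
        assert ra.check_time_strata_restriction(self._center(10, 12)) == []

    def test_difference_at_threshold_violates(self):
        violations = ra.check_time_strata_restriction(self._center(10, 13))
        assert len(violations) == 1
        assert violations[0].diff == 3

    def test_sequential_mode_reports_first_position(self):
        # early, early, early at positions 1..3: running diff hits 3 at index 3
        rows = [("a", "C01", "early", "treatment", 1), ("b", "C01", "early", "control", 2),
                ("c", "C01", "early", "treatment", 3), ("d", "C01", "late", "control", 4)]
        violations = ra.check_time_strata_restriction(_frame(rows), mode="sequential")
        assert violations[0].running_violation_index == 3

    def test_sequential_requires_enrollment_index(self):
        rows = [("a", "C01", "early", "treatment", None), ("b", "C01", "late", "control", None)]
        with pytest.raises(ValueError, match="enrollment_index"):
            ra.check_time_strata_restriction(_frame(rows), mode="sequential")

    def test_sequential_transient_violation_hidden_in_final_counts(self):
        # diff reaches 3 mid-trial but ends at 0: only the replay sees it
        rows = [("a", "C01", "early", "treatment", 1), ("b", "C01", "early", "control", 2),
                ("c", "C01", "early", "treatment", 3), ("d", "C01", "late", "control", 4),
                ("e", "C01", "late", "treatment", 5), ("f", "C01", "late", "control", 6)]
        assert ra.check_time_strata_restriction(_frame(rows), mode="final") == []
        assert len(ra.check_time_strata_restriction(_frame(rows), mode="sequential")) == 1

    def test_compliant_generator_never_violates(self, trial_frame):
        """The simulator enforces the rule, so neither mode reports anything."""
        assert ra.check_time_strata_restriction(trial_frame, mode="final") == []
        assert ra.check_time_strata_restriction(trial_frame, mode="sequential") == []


class TestCrossoverDirectionTest:
    def test_trivial_half(self):
        res = ra.crossover_direction_test(2, 1)
        assert res.point_probability == pytest.approx(0.5, abs=1e-12)

    def test_published_pattern_point_and_tail(self):
        """21 of 22 cross-overs one way: point mass C(22,21)/2^22, upper
        tail 23/2^22 (brute-force sum over k in {21, 22})."""
        res = ra.crossover_direction_test(22, 21)
        assert res.point_probability == pytest.approx(binom_pmf_oracle(21, 22, 0.5), rel=1e-12)
        assert res.tail_probability == pytest.approx(23 * 0.5**22, rel=1e-12)

    @pytest.mark.parametrize("n", [1, 7, 100, 1000])
    def test_pmf_sums_to_one(self, n):
        total = sum(ra.crossover_direction_test(n, k).point_probability for k in range(n + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(n=st.integers(1, 200), data=st.data(),
           p=st.floats(0.01, 0.99, allow_nan=False))
    def test_probability_ordering_invariant(self, n, data, p):
        """0 <= point <= tail <= 1 for any admissible inputs."""
        k = data.draw(st.integers(0, n))
        res = ra.crossover_direction_test(n, k, p)
        assert 0.0 <= res.point_probability <= res.tail_probability <= 1.0

    @pytest.mark.parametrize("n, k, p", [(5, 6, 0.5), (5, -1, 0.5), (5, 3, 0.0), (5, 3, 1.0)])
    def test_invalid_inputs(self, n, k, p):
        with pytest.raises(ValueError):
            ra.crossover_direction_test(n, k, p)


def test_crossover_counts_from_records():
    rows = []
    for i in range(21):
        rows.append({"participant_id": f"x{i}", "clinical_center": "C01", "time_stratum": "early",
                     "arm": "control", "crossover": True})
    rows.append({"participant_id": "y", "clinical_center": "C01", "time_stratum": "early",
                 "arm": "treatment", "crossover": True})
    rows.append({"participant_id": "z", "clinical_center": "C01", "time_stratum": "early",
                 "arm": "treatment", "crossover": False})
    n, to_control = ra.crossover_counts(pd.DataFrame(rows))
    assert (n, to_control) == (22, 21)
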