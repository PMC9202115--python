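"""Baseline-imbalance tests and scans."""

import numpy as np
import pandas as pd
import pytest

import randaudit as ra
from randaudit.imbalance_scan import Direction
from randaudit.trial_model import StratumKey, TimeStratum

from oracles import welch_from_stats_oracle, welch_oracle, yates_oracle


class TestWelch:
    def test_identical_groups(self):
        values = [1.0, 2.0, 3.0, 4.0]
        stat, p = ra.welch_t_test(values, values)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_summary_variant_reproduces_published_severity_gap(self):
        """Baseline NIHSS 15.4 +/- 6.9 (n=167) vs 13.5 +/- 7.6 (n=155):
        the published raw-data comparison printed p = .021; the closed-form
        Welch evaluation of the rounded summaries gives t ~ 2.34, p ~ .019."""
        stat, p = ra.welch_t_from_stats(15.4, 6.9, 167, 13.5, 7.6, 155)
        t_expected, p_expected = welch_from_stats_oracle(15.4, 6.9, 167, 13.5, 7.6, 155)
        assert stat == pytest.approx(t_expected, abs=1e-10)
        assert p == pytest.approx(p_expected, abs=1e-10)
        assert stat == pytest.approx(2.343, abs=5e-4)
        assert p == pytest.approx(0.0197, abs=5e-4)

    def test_symmetric_under_group_exchange(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 2, 14)
        s1, p1 = ra.welch_t_test(a, b)
        s2, p2 = ra.welch_t_test(b, a)
        assert s1 == pytest.approx(-s2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ra.welch_t_test([1.0, 1.0, 1.0], [1.0, 1.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            ra.welch_t_test([1.0], [2.0, 3.0])


class TestYates:
    def test_proportional_table_is_null(self):
        stat, p = ra.chisq_yates(10, 10, 20, 20)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_reconstructed_aspirin_table(self):
        """Counts reconstructed from the published 24% vs 41% aspirin split
        (arm sizes 167/155) give a corrected statistic ~ 10.3, p ~ .001."""
        stat, p = ra.chisq_yates(64, 91, 40, 127)
        t_expected, p_expected = yates_oracle(64, 91, 40, 127)
        assert stat == pytest.approx(t_expected, abs=1e-10)
        assert p == pytest.approx(p_expected, abs=1e-10)
        assert stat == pytest.approx(10.27, abs=0.01)
        assert p == pytest.approx(0.00135, abs=5e-5)

    def test_doubling_cells_increases_statistic(self):
        s1, _ = ra.chisq_yates(12, 8, 6, 14)
        s2, _ = ra.chisq_yates(24, 16, 12, 28)
        assert s2 > s1

    def test_truncated_to_zero_inside_continuity_band(self):
        # |ad - bc| = 4 <= N/2 = 6.5
        stat, p = ra.chisq_yates(4, 3, 4, 2)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            ra.chisq_yates(0, 5, 0, 7)

    def test_small_expected_cell_warns(self):
        result = ra.chisq_yates(2, 30, 8, 25)
        assert result.warning is not None and "below 5" in result.warning

    def test_invariant_under_row_and_column_exchange(self):
        s1, p1 = ra.chisq_yates(12, 8, 6, 14)
        s2, p2 = ra.chisq_yates(14, 6, 8, 12)  # both rows and columns swapped
        assert s1 == pytest.approx(s2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)


def _imbalanced_frame(n=120):
    """Treatment arm with clearly milder severity and more aspirin use."""
    rng = np.random.default_rng(42)
    half = n // 2
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "clinical_center": "C01",
            "time_stratum": "late",
            "arm": ["treatment"] * half + ["control"] * half,
            "nihss_baseline": np.concatenate([rng.normal(11, 5, half), rng.normal(17, 5, half)]).round().clip(0, 42),
            "aspirin_pre": np.concatenate([rng.random(half) < 0.55, rng.random(half) < 0.15]),
            "hyperintense_artery": rng.random(n) < 0.15,
        }
    )


class TestScanCovariates:
    def test_flags_and_prognostic_direction(self):
        report = ra.scan_covariates(
            _imbalanced_frame(), TimeStratum.LATE, ["nihss_baseline", "aspirin_pre", "hyperintense_artery"]
        )
        by_cov = {r.covariate: r for r in report.results}
        assert by_cov["nihss_baseline"].flagged
        # lower mean severity under higher-is-worse favors the treatment arm
        assert by_cov["nihss_baseline"].favors is ra.Arm.TREATMENT
        assert by_cov["nihss_baseline"].test == "welch_t"
        assert by_cov["aspirin_pre"].flagged
        assert by_cov["aspirin_pre"].favors is ra.Arm.TREATMENT  # presence is favorable
        assert by_cov["aspirin_pre"].test == "chisq_yates"

    def test_unflagged_results_carry_no_favor_annotation(self):
        report = ra.scan_covariates(_imbalanced_frame(), TimeStratum.LATE, ["hyperintense_artery"])
        (result,) = report.results
        if not result.flagged:
            assert result.favors is None

    def test_flagged_iff_p_below_alpha(self):
        for result in ra.scan_covariates(_imbalanced_frame(), TimeStratum.LATE).results:
            assert result.flagged == (result.p_value <= 0.05)
            assert 0.0 <= result.p_value <= 1.0

    def test_absent_covariate_diagnostic_scan_continues(self):
        report = ra.scan_covariates(_imbalanced_frame(), TimeStratum.LATE, ["nihss_baseline", "not_a_column"])
        assert len(report.results) == 1
        assert report.diagnostics[0]["covariate"] == "not_a_column"

    def test_unknown_direction_gives_no_favors(self):
        frame = _imbalanced_frame()
        report = ra.scan_covariates(
            frame, TimeStratum.LATE, ["nihss_baseline"], prognosis={"nihss_baseline": Direction.UNKNOWN}
        )
        assert report.results[0].flagged
        assert report.results[0].favors is None

    def test_degenerate_covariate_skipped_with_diagnostic(self):
        frame = _imbalanced_frame()
        frame["hyperintense_artery"] = False
        report = ra.scan_covariates(frame, TimeStratum.LATE, ["hyperintense_artery"])
        assert report.results == []
        assert "degenerate" in report.diagnostics[0]["reason"]


class TestScanCtByUniqueStratum:
    def test_empty_arm_stratum_skipped(self):
        frame = _imbalanced_frame()
        solo = frame.copy()
        solo.loc[:, "clinical_center"] = "C01"
        extra = frame.head(3).copy()
        extra["clinical_center"] = "C02"
        extra["arm"] = "treatment"  # no controls in C02
        combined = pd.concat([solo, extra], ignore_index=True)
        report = ra.scan_ct_by_unique_stratum(combined, ["hyperintense_artery"])
        scopes = {r.stratum for r in report.results}
        assert StratumKey("C02", TimeStratum.LATE) not in scopes
        assert any(d["reason"].startswith("fewer than 2") for d in report.diagnostics)

    def test_runs_over_all_populated_strata(self, trial_frame):
        report = ra.scan_ct_by_unique_stratum(trial_frame)
        scopes = {r.stratum for r in report.results}
        assert len({(s.clinical_center, s.time_stratum) for s in scopes}) == 16
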