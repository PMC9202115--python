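"""Synthetic trial generator: schedules, restriction, subversion, outcomes."""

import numpy as np
import pandas as pd
import pytest

import randaudit as ra
from randaudit.synthetic_trial import generate_schedule
from randaudit.trial_model import Arm, TimeStratum


def _running_imbalance(allocations):
    steps = np.where(np.array([a is Arm.TREATMENT for a in allocations]), 1, -1)
    return np.abs(np.cumsum(steps))


class TestSchedules:
    def test_blocks_of_two_alternate(self):
        config = ra.SimConfig(block_sizes=(2,))
        schedule = generate_schedule(config, np.random.default_rng(0), 10)
        assert _running_imbalance(schedule.allocations).max() <= 1

    def test_blocks_of_four_split_evenly(self):
        config = ra.SimConfig(block_sizes=(4,))
        schedule = generate_schedule(config, np.random.default_rng(1), 40)
        allocations = schedule.allocations
        for start in schedule.block_boundaries:
            window = allocations[start:start + 4]
            assert sum(a is Arm.TREATMENT for a in window) == 2

    def test_every_complete_block_is_balanced(self):
        config = ra.SimConfig(block_sizes=(2, 4, 6, 8))
        schedule = generate_schedule(config, np.random.default_rng(2), 200)
        bounds = schedule.block_boundaries + [len(schedule.allocations)]
        for start, stop in zip(bounds, bounds[1:]):
            block = schedule.allocations[start:stop]
            assert sum(a is Arm.TREATMENT for a in block) == len(block) // 2

    def test_reproducible_from_seed(self):
        config = ra.SimConfig(block_sizes=(2, 4, 6, 8))
        s1 = generate_schedule(config, np.random.default_rng(3), 50)
        s2 = generate_schedule(config, np.random.default_rng(3), 50)
        assert s1.allocations == s2.allocations
        assert s1.block_boundaries == s2.block_boundaries


class TestConfigValidation:
    def test_odd_block_size_rejected(self):
        with pytest.raises(ValueError, match="block size 3"):
            ra.SimConfig(block_sizes=(2, 3)).validate()

    def test_probability_bounds_checked(self):
        bad = ra.SimConfig(subversion=ra.SubversionConfig(crossover_prob=1.5))
        with pytest.raises(ValueError, match="crossover_prob"):
            bad.validate()

    def test_yaml_round_trip(self, tmp_path):
        config = ra.SimConfig(target_n=100, seed=9,
                              subversion=ra.SubversionConfig(crossover_prob=0.05, crossover_direction_bias=1.0))
        path = config.to_yaml(tmp_path / "config.yaml")
        assert ra.SimConfig.from_yaml(path) == config


class TestEnrollment:
    def test_clean_trial_respects_block_bound_and_restriction(self, trial_frame):
        table = ra.allocation_counts(trial_frame)
        assert max(row.delta for row in table.strata) <= 8 // 2
        assert ra.check_time_strata_restriction(trial_frame, mode="sequential") == []

    def test_restriction_enforced_sequentially_at_other_thresholds(self):
        config = ra.SimConfig(target_n=200, n_centers=3, restriction_threshold=2, seed=4)
        frame = ra.simulate_enrollment(config)
        assert ra.check_time_strata_restriction(frame, threshold=2, mode="sequential") == []

    def test_seed_determinism_is_byte_identical(self, tmp_path):
        config = ra.SimConfig(target_n=150, seed=77)
        a = ra.simulate_trial(config)
        b = ra.simulate_trial(ra.SimConfig(target_n=150, seed=77))
        p1 = ra.write_trial_table(a, tmp_path / "a.csv")
        p2 = ra.write_trial_table(b, tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_unreachable_target_raises(self):
        # every late arrival beyond parity is excluded, and late arrivals
        # are nearly all that show up -> enrollment stalls
        config = ra.SimConfig(target_n=50, n_centers=1, p_late=0.999, restriction_threshold=1, seed=0)
        with pytest.raises(ra.SimulationError):
            ra.simulate_enrollment(config)

    def test_directional_crossovers_mimic_audited_pattern(self):
        """chi = 0.035 with full direction bias: every cross-over moves a
        scheduled-treatment participant onto control, about 22 in 624."""
        config = ra.SimConfig(seed=21, subversion=ra.SubversionConfig(
            crossover_prob=0.035, crossover_direction_bias=1.0))
        frame = ra.simulate_enrollment(config)
        cross = frame[frame["crossover"].astype(bool)]
        assert len(cross) > 0
        assert (cross["arm"] == Arm.CONTROL.value).all()
        # binomial(624, 0.035) stays within wide bounds
        assert 8 <= len(cross) <= 40

    def test_unblinding_flags_set(self):
        config = ra.SimConfig(target_n=400, seed=5, subversion=ra.SubversionConfig(unblind_prob=0.1))
        frame = ra.simulate_enrollment(config)
        assert 10 <= int(frame["unblinded"].sum()) <= 90

    def test_foresight_depresses_treatment_arm_severity(self):
        """Foresight exclusion of severe candidates ahead of treatment
        allocations lowers the treatment arm's mean baseline NIHSS."""
        diffs = []
        for seed in range(25):
            config = ra.SimConfig(target_n=300, seed=1000 + seed, subversion=ra.SubversionConfig(
                foresight_prob=0.5, foresight_covariate="nihss_baseline", foresight_cutoff=15.0))
            frame = ra.simulate_enrollment(config)
            by_arm = frame.groupby("arm")["nihss_baseline"].mean()
            diffs.append(by_arm["treatment"] - by_arm["control"])
        assert np.mean(diffs) < -0.5


class TestOutcomeModel:
    def test_equal_thresholds_give_identical_endpoint_tables(self):
        config = ra.SimConfig(target_n=200, seed=6)
        config.outcome.endpoint_thresholds = {"mrs": 0.0, "barthel": 0.0, "gos": 0.0, "nihss": 0.0}
        frame = ra.simulate_trial(config)
        mrs = ra.dichotomize_frame(frame, ra.Endpoint.MRS)
        for endpoint in (ra.Endpoint.BARTHEL, ra.Endpoint.NIHSS, ra.Endpoint.GOS):
            assert ra.dichotomize_frame(frame, endpoint).equals(mrs)

    def test_null_treatment_effect_centers_odds_ratio_at_one(self):
        """beta_t = 0: the mean log odds ratio over replicates is near 0."""
        log_ors = []
        for seed in range(40):
            config = ra.SimConfig(target_n=300, seed=2000 + seed)
            config.outcome.treatment = 0.0
            frame = ra.simulate_trial(config)
            est = ra.estimate_treatment_effect(frame, ra.Endpoint.MRS, TimeStratum.EARLY)
            log_ors.append(np.log(est.odds_ratio))
        mean = np.mean(log_ors)
        # SE of the mean of ~N(0, 0.28^2) over 40 replicates is ~0.045
        assert abs(mean) < 0.15

    def test_outcome_scores_respect_dichotomization_backmap(self, trial_frame):
        assert set(trial_frame["mrs_90d"].dropna().unique()) <= {1, 3}
        assert set(trial_frame["barthel_90d"].dropna().unique()) <= {100, 60}
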