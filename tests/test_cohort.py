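import math

import numpy as np
import pandas as pd
import pytest

from ckdplatform import (
    ConfigError,
    DomainConfig,
    PlatformConfig,
    TruthParams,
    apply_dropout,
    assign_arms,
    default_visit_schedule,
    sample_baseline,
    simulate_accrual,
    simulate_cohort,
    simulate_trajectories,
)
from ckdplatform.config import WEEKS_PER_YEAR


class TestAccrual:
    def test_poisson_mean_matches_rate(self):
        # E[count by week 78] = 9.6 * 78 = 748.8; average over seeds
        counts = [
            (simulate_accrual(9.6, 1000, seed) <= 78.0).sum() for seed in range(20)
        ]
        assert 730 <= np.mean(counts) <= 768

    def test_times_sorted_and_truncated(self):
        times = simulate_accrual(9.6, 1000, 0)
        assert len(times) == 1000
        assert np.all(np.diff(times) >= 0)

    def test_single_participant(self):
        assert simulate_accrual(5.0, 1, 1).shape == (1,)

    def test_doubled_horizon_doubles_count(self):
        counts_1 = [(simulate_accrual(9.6, 4000, s) <= 100).sum() for s in range(10)]
        counts_2 = [(simulate_accrual(9.6, 4000, s) <= 200).sum() for s in range(10)]
        assert np.mean(counts_2) == pytest.approx(2 * np.mean(counts_1), rel=0.05)

    def test_invalid_args(self):
        with pytest.raises(ConfigError):
            simulate_accrual(0.0, 10, 0)
        with pytest.raises(ConfigError):
            simulate_accrual(1.0, 0, 0)


class TestBaseline:
    def test_distribution_matches_registry_parameters(self, null_truth):
        parts = sample_baseline(10_000, null_truth, 7)
        # log-normal UACR: median 89 mg/g, sigma from the printed IQR
        median_uacr = float(np.exp(parts["baseline_log_uacr"]).median())
        assert 80 <= median_uacr <= 99
        assert (parts["baseline_egfr"] >= 25).all()
        # truncation at 25 pulls the mean above the untruncated 52.9
        assert parts["baseline_egfr"].mean() > 52.9

    def test_latent_slope_centered_on_placebo_decline(self, null_truth):
        parts = sample_baseline(20_000, null_truth, 8)
        assert parts["latent_slope"].mean() == pytest.approx(-3.42, abs=0.12)


class TestAssignment:
    def test_permuted_blocks_exact_balance(self, null_truth):
        parts = sample_baseline(1000, null_truth, 1)
        parts = assign_arms(parts, [DomainConfig()], 2, block_size=2)
        assert parts["arm"].value_counts().to_dict() == {
            "placebo": 500,
            "intervention": 500,
        }

    def test_multifactorial_independence(self, null_truth):
        from scipy.stats import chi2_contingency

        parts = sample_baseline(4000, null_truth, 2)
        domains = [DomainConfig(name="a"), DomainConfig(name="b")]
        parts = assign_arms(parts, domains, 3)
        table = pd.crosstab(parts["arm_a"], parts["arm_b"])
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.001

    def test_single_participant_single_arm(self, null_truth):
        parts = sample_baseline(1, null_truth, 3)
        parts = assign_arms(parts, [DomainConfig()], 4)
        assert parts.loc[0, "arm"] in {"placebo", "intervention"}

    def test_no_open_domain_is_error(self, null_truth):
        parts = sample_baseline(5, null_truth, 3)
        with pytest.raises(ConfigError):
            assign_arms(parts, [], 0)


class TestTrajectories:
    def _noise_free_cohort(self, truth, n=40, seed=5):
        parts = sample_baseline(n, truth, seed)
        parts["enroll_week"] = 0.0
        return assign_arms(parts, [DomainConfig()], seed + 1)

    def test_noise_free_formula(self):
        truth = TruthParams(
            acute_effect=-2.0,
            chronic_slope_effect=0.0,
            residual_sd=0.0,
            dropout_rate=0.0,
        )
        parts = self._noise_free_cohort(truth)
        obs = simulate_trajectories(parts, truth, default_visit_schedule(), 6)
        merged = obs.merge(
            parts[["participant_id", "baseline_egfr", "latent_slope"]],
            on="participant_id",
        )
        active = merged["arm"] == "intervention"
        w4 = merged[(merged["week"] == 4) & active]
        expected_w4 = (
            w4["baseline_egfr"] - 2.0 + w4["latent_slope"] * 4 / WEEKS_PER_YEAR
        )
        assert np.allclose(w4["egfr"], expected_w4)
        # acute effect fully reversed at the end of washout
        w108 = merged[merged["week"] == 108]
        expected_w108 = (
            w108["baseline_egfr"] + w108["latent_slope"] * 108 / WEEKS_PER_YEAR
        )
        assert np.allclose(w108["egfr"], expected_w108)

    def test_on_treatment_flag_off_after_treatment_end(self, small_cohort):
        _, obs = small_cohort
        assert (~obs.loc[obs["week"] > 104, "on_treatment"]).all()
        assert obs.loc[obs["week"] <= 104, "on_treatment"].all()

    def test_reversibility_equivalence(self):
        # with full reversal and no noise the annualized change from baseline
        # to end of washout equals the chronic slope for every participant
        truth = TruthParams(
            chronic_slope_effect=1.3,
            residual_sd=0.0,
            slope_sd_between=1.0,
            placebo_slope_mean=-3.0,
            dropout_rate=0.0,
        )
        parts = self._noise_free_cohort(truth)
        obs = simulate_trajectories(parts, truth, default_visit_schedule(), 9)
        w0 = obs[obs["week"] == 0].set_index("participant_id")["egfr"]
        w108 = obs[obs["week"] == 108].set_index("participant_id")["egfr"]
        annualized = (w108 - w0) / (108 / WEEKS_PER_YEAR)
        p = parts.set_index("participant_id")
        expected = p["latent_slope"] + np.where(p["arm"] == "intervention", 1.3, 0.0)
        assert np.allclose(annualized, expected)

    def test_multi_domain_additivity(self):
        # gentle slope variance so no trajectory hits the eGFR floor
        truth = TruthParams(
            residual_sd=0.0, dropout_rate=0.0, slope_sd_between=1.0,
            placebo_slope_mean=-3.0,
        )
        parts = sample_baseline(400, truth, 11)
        parts["enroll_week"] = 0.0
        domains = [DomainConfig(name="a"), DomainConfig(name="b")]
        parts = assign_arms(parts, domains, 12)
        effects = {"a": (0.7, 0.0, 0.0), "b": (-1.9, 0.0, 0.0)}
        obs = simulate_trajectories(
            parts, truth, default_visit_schedule(), 13, domain_effects=effects
        )
        merged = obs[obs["week"] == 104].merge(
            parts[["participant_id", "baseline_egfr", "latent_slope"]],
            on="participant_id",
        )
        shift = (
            merged["egfr"]
            - merged["baseline_egfr"]
            - merged["latent_slope"] * 104 / WEEKS_PER_YEAR
        )
        cells = shift.groupby(
            [merged["arm_a"], merged["arm_b"]]
        ).mean()
        base = cells[("placebo", "placebo")]
        assert cells[("intervention", "placebo")] - base == pytest.approx(0.7)
        assert cells[("placebo", "intervention")] - base == pytest.approx(-1.9)
        assert cells[("intervention", "intervention")] - base == pytest.approx(-1.2)


class TestDropout:
    def test_zero_rate_is_identity(self, null_truth):
        truth = TruthParams(dropout_rate=0.0)
        parts = sample_baseline(50, truth, 1)
        parts["enroll_week"] = 0.0
        parts = assign_arms(parts, [DomainConfig()], 2)
        obs = simulate_trajectories(parts, truth, default_visit_schedule(), 3)
        censored, _ = apply_dropout(obs, parts, truth, 4)
        pd.testing.assert_frame_equal(censored, obs)

    def test_week104_retention_matches_hazard(self):
        # retention at t years is (1 - rate)^t; at 104 weeks ~ 0.902
        truth = TruthParams(dropout_rate=0.05)
        parts = sample_baseline(10_000, truth, 5)
        parts["enroll_week"] = 0.0
        parts = assign_arms(parts, [DomainConfig()], 6)
        obs = simulate_trajectories(parts, truth, default_visit_schedule(), 7)
        censored, parts2 = apply_dropout(obs, parts, truth, 8)
        retained = (censored["week"] == 104).sum() / len(parts)
        assert retained == pytest.approx(0.95 ** (104 / WEEKS_PER_YEAR), abs=0.012)

    def test_early_dropout_leaves_no_chronic_data(self):
        truth = TruthParams(dropout_rate=0.5)
        parts = sample_baseline(300, truth, 9)
        parts["enroll_week"] = 0.0
        parts = assign_arms(parts, [DomainConfig()], 10)
        obs = simulate_trajectories(parts, truth, default_visit_schedule(), 11)
        censored, parts2 = apply_dropout(obs, parts, truth, 12)
        early = parts2[parts2["dropout_week"] < 4]
        assert len(early) > 0  # rate 0.5 guarantees some
        chronic = censored[censored["week"] >= 4]
        assert not chronic["participant_id"].isin(early["participant_id"]).any()


class TestDeterminism:
    def test_same_seed_identical_cohort(self, fast_domain, platform, null_truth):
        p1, o1 = simulate_cohort(fast_domain, platform, null_truth, 123)
        p2, o2 = simulate_cohort(fast_domain, platform, null_truth, 123)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(o1, o2)

    def test_different_seed_differs(self, fast_domain, platform, null_truth):
        _, o1 = simulate_cohort(fast_domain, platform, null_truth, 123)
        _, o2 = simulate_cohort(fast_domain, platform, null_truth, 124)
        assert not o1["egfr"].equals(o2["egfr"])
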