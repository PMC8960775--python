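"""Performance tables, signal-detection and rank statistics, engagement."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from autrain.agents import AgentSpec, simulate_session
from autrain.analysis import (
    binomial_vs_chance,
    bonferroni_adjust,
    bonferroni_alpha,
    detection_level_counts,
    dprime,
    engagement_summary,
    hit_rate_table,
    kruskal_wallis_ranks,
    learning_curve_bins,
    partial_pearson,
    reaction_times_by_sound,
)
from autrain.io import to_frame


def make_log(rows):
    """Minimal session-log frame from (animal, session, sound, choice, correct, rt, t) tuples."""
    return pd.DataFrame(
        [
            {
                "session_id": s, "animal_id": a, "task": "2ac", "step": None,
                "trial": i, "t_start_s": t, "sound_id": snd, "level_db": None,
                "target_visual": "face", "target_side": "left", "choice": c,
                "correct": corr, "rewarded": bool(corr), "reaction_time_s": rt,
            }
            for i, (a, s, snd, c, corr, rt, t) in enumerate(rows)
        ]
    )


class TestHitRateTable:
    def test_counts_and_rates(self):
        rows = (
            [("a", "s1", "voc", "face", True, 0.5, float(i)) for i in range(8)]
            + [("a", "s1", "voc", "ignored", None, None, 8.0)]
            + [("a", "s1", "voc", "pattern", False, 0.5, 9.0)]
        )
        table = hit_rate_table(make_log(rows))
        row = table.iloc[0]
        assert row["n_trials"] == 10
        assert row["n_scored"] == 9
        assert row["n_ignored"] == 1
        assert row["hit_rate"] == pytest.approx(8 / 9)

    def test_last_k_sessions_window(self):
        rows = [
            ("a", f"s{j}", "voc", "face", True, 0.5, 1.0)
            for j in range(1, 9)
        ]
        table = hit_rate_table(make_log(rows), last_k_sessions=5)
        assert table.iloc[0]["n_trials"] == 5

    def test_empty_log_gives_empty_table(self):
        assert hit_rate_table(make_log([])).empty

    def test_zero_scored_rows_flagged_with_nan(self):
        rows = [("a", "s1", "voc", "ignored", None, None, 1.0)]
        table = hit_rate_table(make_log(rows))
        assert np.isnan(table.iloc[0]["hit_rate"])
        assert np.isnan(table.iloc[0]["p_value_raw"])

    def test_dprime_uses_other_stimulus_as_false_alarms(self):
        rows = (
            [("a", "s1", "voc", "face", True, 0.5, 1.0)] * 84
            + [("a", "s1", "voc", "pattern", False, 0.5, 1.0)] * 16
            + [("a", "s1", "sTr", "pattern", True, 0.5, 1.0)] * 84
            + [("a", "s1", "sTr", "face", False, 0.5, 1.0)] * 16
        )
        table = hit_rate_table(make_log([r for r in rows]))
        expected = stats.norm.ppf(0.84) - stats.norm.ppf(0.16)
        assert table["d_prime"].to_numpy() == pytest.approx([expected, expected])


class TestDprime:
    def test_symmetric_chance_is_zero(self):
        assert dprime(0.5, 0.5, 100, 100) == pytest.approx(0.0)

    def test_textbook_value(self):
        # z(0.84) - z(0.16), standard-normal quantile oracle
        assert dprime(0.84, 0.84, 100, 100) == pytest.approx(1.9889157664, abs=1e-6)

    def test_perfect_rates_stay_finite_via_half_count_rule(self):
        # corrected rates 0.95 / 0.05 for N = 10
        expected = stats.norm.ppf(0.95) - stats.norm.ppf(0.05)
        assert dprime(1.0, 1.0, 10, 10) == pytest.approx(expected)

    def test_antisymmetry_under_role_swap(self):
        # swapping which stimulus counts as signal flips the sign
        assert dprime(0.9, 0.7, 50, 50) == pytest.approx(
            -dprime(1 - 0.9, 1 - 0.7, 50, 50)
        )

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            dprime(0.5, 0.5, 0, 10)


class TestBinomialVsChance:
    def test_brute_force_enumeration_small_n(self):
        """Exact pmf summation oracle for every (n <= 20, k)."""
        for n in range(1, 21):
            for k in range(n + 1):
                expected = float(
                    sum(Fraction(comb(n, j), 2**n) for j in range(k, n + 1))
                )
                assert binomial_vs_chance(k, n, 0.5) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "k, n, p, expected",
        [
            (10, 10, 0.5, 2**-10),
            (5, 10, 0.5, 0.623046875),
            (64, 70, 0.5, 1.22136323407e-13),
        ],
    )
    def test_examples(self, k, n, p, expected):
        assert binomial_vs_chance(k, n, p) == pytest.approx(expected, rel=1e-6)

    def test_chance_third_for_3ac(self):
        # P(X >= 1 | n=1, p=1/3) = 1/3
        assert binomial_vs_chance(1, 1, 1 / 3) == pytest.approx(1 / 3)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            binomial_vs_chance(0, 0)


class TestBonferroni:
    def test_corrected_alpha_for_family_of_26(self):
        assert bonferroni_alpha(0.05, 26) == pytest.approx(0.0019, abs=5e-5)

    def test_adjusted_p_capped_at_one(self):
        assert bonferroni_adjust([0.1], 26)[0] == 1.0

    def test_family_of_one_is_identity(self):
        assert bonferroni_adjust([0.03], 1)[0] == pytest.approx(0.03)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.05], 0)


class TestKruskalWallis:
    def test_identical_groups_no_effect(self):
        res = kruskal_wallis_ranks([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.H == 0.0 and res.p_value == 1.0

    def test_hand_computed_ranks(self):
        # ranks 1-6, group means 2 and 5: H = 12/(6*7) * 3*(1.5^2)*2 = 27/7
        res = kruskal_wallis_ranks([1, 2, 3], [4, 5, 6])
        assert res.H == pytest.approx(27 / 7, abs=1e-9)
        assert res.df == 1

    def test_detects_shifted_lognormals(self):
        detected = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.lognormal(0.0, 0.4, 200)
            b = rng.lognormal(0.3, 0.4, 200)
            detected += kruskal_wallis_ranks(a, b).p_value < 0.05
        assert detected >= 8

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_ranks([1.0, 2.0])

    def test_rt_effect_detected_in_simulated_logs(self, task2):
        spec = AgentSpec(
            policy="fixed-accuracy", p_correct=0.85,
            rt_model={"voc": (0.1, 0.3), "sTr": (-0.3, 0.3)},
        )
        frame = to_frame(simulate_session(task2, spec, 600, seed=0))
        groups = reaction_times_by_sound(frame)
        res = kruskal_wallis_ranks(groups["voc"], groups["sTr"])
        assert res.df == 1
        assert res.p_value < 0.001


class TestEngagement:
    def test_median_normalized_timestamp(self):
        rows = [("a", "s1", "voc", "face", True, 0.5, 10.0 * k) for k in range(1, 11)]
        summary = engagement_summary(make_log(rows), {("a", "s1"): 100.0})
        assert summary.per_session.iloc[0]["median_normalized_timestamp"] == pytest.approx(0.55)

    def test_zero_trial_sessions_counted(self):
        rows = [("a", "s1", "voc", "face", True, 0.5, 5.0)]
        summary = engagement_summary(
            make_log(rows), {("a", "s1"): 10.0, ("a", "s2"): 10.0, ("a", "s3"): 10.0}
        )
        animal = summary.per_animal.iloc[0]
        assert animal["n_sessions"] == 3
        assert animal["n_zero_trial_sessions"] == 2

    def test_single_trial_at_session_end(self):
        rows = [("a", "s1", "voc", "face", True, 0.5, 10.0)]
        summary = engagement_summary(make_log(rows), {("a", "s1"): 10.0})
        assert summary.per_session.iloc[0]["median_normalized_timestamp"] == 1.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            engagement_summary(make_log([]), {("a", "s1"): 0.0})

    def test_timestamp_outside_duration_rejected(self):
        rows = [("a", "s1", "voc", "face", True, 0.5, 20.0)]
        with pytest.raises(ValueError):
            engagement_summary(make_log(rows), {("a", "s1"): 10.0})


class TestLearningCurveBins:
    def test_100_trials_in_5pct_bins(self):
        rows = [("a", "s1", "voc", "face", True, 0.5, float(i)) for i in range(100)]
        bins = learning_curve_bins(make_log(rows), bin_percent=5)
        assert len(bins) == 20
        assert (bins["n_trials"] == 5).all()
        assert (bins["hit_rate"] == 1.0).all()

    def test_bin_counts_conserve_trials(self):
        rng = np.random.default_rng(0)
        rows = [
            ("a", "s1", "voc", "face", bool(rng.random() < 0.7), 0.5, float(i))
            for i in range(237)
        ]
        bins = learning_curve_bins(make_log(rows), bin_percent=10)
        assert bins["n_trials"].sum() == 237

    def test_subjects_with_different_n_share_axis(self):
        rows = [("a", "s1", "voc", "face", True, 0.5, float(i)) for i in range(40)]
        rows += [("b", "s1", "voc", "face", True, 0.5, float(i)) for i in range(400)]
        bins = learning_curve_bins(make_log(rows), bin_percent=10)
        for animal in ("a", "b"):
            sub = bins[bins["animal_id"] == animal]
            assert list(sub["pct_hi"]) == [10 * b for b in range(1, 11)]

    def test_non_divisor_bin_rejected(self):
        with pytest.raises(ValueError):
            learning_curve_bins(make_log([]), bin_percent=3)


class TestPartialPearson:
    def test_uncorrelated_covariate_matches_plain_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        z = rng.normal(size=200)
        partial = partial_pearson(x, y, z)
        plain = stats.pearsonr(x, y)
        assert partial.r == pytest.approx(plain.statistic, abs=0.02)

    def test_covariate_driven_association_removed(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=300)
        y = z + rng.normal(scale=1e-6, size=300)
        x = rng.normal(size=300) + 0.5 * z
        assert abs(partial_pearson(x, y, z).r) < 0.1

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"x": rng.normal(size=60), "z": rng.normal(size=60)}
        )
        df["y"] = 0.4 * df["x"] + 0.6 * df["z"] + rng.normal(size=60)
        ours = partial_pearson(df["x"], df["y"], df["z"])
        ref = pg.partial_corr(data=df, x="x", y="y", covar="z")
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours.p_value == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)
        ref_ci = ref["CI95"].iloc[0]
        assert ours.ci95[0] == pytest.approx(ref_ci[0], abs=0.01)
        assert ours.ci95[1] == pytest.approx(ref_ci[1], abs=0.01)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            partial_pearson([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 4.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            partial_pearson([1.0] * 10, list(range(10)), list(range(10)))


class TestDetectionLevelCounts:
    def test_counts_presence_responses_per_level(self, det_task):
        spec = AgentSpec(policy="ideal")
        frame = to_frame(simulate_session(det_task, spec, 700, seed=1))
        counts = detection_level_counts(frame)
        assert set(counts.levels) <= {0.0, 15.0, 30.0, 45.0, 60.0, 70.0, 80.0}
        # the ideal agent says "present" on every non-silent trial
        silent = counts.levels == 0.0
        assert counts.k[silent].sum() == 0
        assert (counts.k[~silent] == counts.n[~silent]).all()
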