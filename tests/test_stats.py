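"""Summaries, load effects, effect sizes, correlations and the mixed model."""

import numpy as np
import pandas as pd
import pytest

from gazeload.errors import UndefinedMetricError
from gazeload.pipeline import reference_summary_frame
from gazeload.stats import (
    cohens_d,
    condition_summary,
    correlation_p_from_r,
    fit_mixed_model,
    load_effect,
    pearson_correlation,
    pooled_group_mean,
    quiz_accuracy,
)
from gazeload.synthetic import simulate_trial_metrics_table


def _metrics_table(rows):
    return pd.DataFrame(
        rows,
        columns=["participant_id", "group", "condition", "trial", "aoi_sample_pct"],
    )


class TestConditionSummary:
    def test_group_mean_and_sd_over_participant_means(self):
        rows = []
        for pid, val in (("a", 60.0), ("b", 70.0)):
            for trial in range(2):
                rows.append((pid, "control", "no_load", trial, val))
        s = condition_summary(_metrics_table(rows), metric_cols=("aoi_sample_pct",))
        assert s["mean"].iloc[0] == pytest.approx(65.0)
        assert s["sd"].iloc[0] == pytest.approx(7.0710678, abs=1e-6)
        assert s["n"].iloc[0] == 2

    def test_trial_imbalance_does_not_skew_the_group_mean(self):
        # participant-level means first: participant "a" has 3 trials, "b" one
        rows = [("a", "g", "no_load", k, 60.0) for k in range(3)]
        rows += [("b", "g", "no_load", 0, 70.0)]
        s = condition_summary(_metrics_table(rows), metric_cols=("aoi_sample_pct",))
        assert s["mean"].iloc[0] == pytest.approx(65.0)

    def test_single_participant_cell_warns_sd_zero(self):
        rows = [("a", "g", "no_load", 0, 60.0)]
        with pytest.warns(UserWarning, match="degenerate"):
            s = condition_summary(_metrics_table(rows), metric_cols=("aoi_sample_pct",))
        assert s["sd"].iloc[0] == 0.0


class TestPooledAndLoadEffect:
    @pytest.fixture(scope="class")
    def ref(self):
        return reference_summary_frame()

    def test_pooled_depression_aoi_pct(self, ref):
        assert pooled_group_mean(ref, "aoi_sample_pct", "depression") == pytest.approx(
            60.835
        )

    def test_pooled_control_duration(self, ref):
        assert pooled_group_mean(
            ref, "aoi_fixation_duration_s", "control"
        ) == pytest.approx(404.7)

    def test_pooled_identity_when_conditions_equal(self):
        df = pd.DataFrame(
            {
                "group": ["g", "g"],
                "condition": ["no_load", "high_load"],
                "metric": ["m", "m"],
                "mean": [3.2, 3.2],
                "sd": [1, 1],
                "n": [5, 5],
            }
        )
        assert pooled_group_mean(df, "m", "g") == pytest.approx(3.2)

    def test_control_aoi_absolute_increase(self, ref):
        e = load_effect(ref, "aoi_sample_pct", "control")
        assert e.absolute_change == pytest.approx(5.06)

    def test_depression_duration_relative_increase(self, ref):
        e = load_effect(ref, "aoi_fixation_duration_s", "depression")
        assert e.percent_change == pytest.approx(12.05, abs=0.005)

    def test_no_change_gives_zero(self):
        df = pd.DataFrame(
            {
                "group": ["g", "g"],
                "condition": ["no_load", "high_load"],
                "metric": ["m", "m"],
                "mean": [5.0, 5.0],
                "sd": [1, 1],
                "n": [5, 5],
            }
        )
        e = load_effect(df, "m", "g")
        assert e.absolute_change == 0.0 and e.percent_change == 0.0

    def test_missing_condition_is_an_error(self, ref):
        with pytest.raises(UndefinedMetricError):
            pooled_group_mean(ref, "aoi_sample_pct", "nosuch")


class TestCohensD:
    def test_identical_groups_zero(self):
        with pytest.raises(UndefinedMetricError):
            cohens_d([1.0, 1.0], [1.0, 1.0])  # zero pooled SD
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_shift_unit_sd_gives_one(self, rng):
        a = rng.normal(0, 1, 100_000)
        # pooled SD is the sample SD of a, so d approaches 1 at large n
        assert cohens_d(a + 1.0, a) == pytest.approx(1.0, abs=0.01)

    def test_matches_direct_formula_on_random_arrays(self, rng):
        for _ in range(50):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), int(rng.integers(2, 30)))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), int(rng.integers(2, 30)))
            na, nb = len(a), len(b)
            sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
            assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / sp)

    def test_antisymmetry_and_location_invariance(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(1, 2, 15)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))
        assert cohens_d(a + 7, b + 7) == pytest.approx(cohens_d(a, b))


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_published_r_yields_published_p(self):
        # r(52) = -0.334 corresponds to a two-tailed p of about 0.016
        assert correlation_p_from_r(-0.334, 52) == pytest.approx(0.016, abs=0.0005)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r0, _ = pearson_correlation(x, y)
        r1, _ = pearson_correlation(3.0 * x + 2.0, 0.5 * y - 1.0)
        assert r1 == pytest.approx(r0)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pearson_correlation(np.ones(10), np.arange(10.0))


class TestMixedModel:
    def test_condition_effect_recovery(self):
        df = simulate_trial_metrics_table(condition_effect=0.07, seed=42)
        res = fit_mixed_model(df, "aoi_proportion")
        est = res.fixed_effects.set_index("term")["estimate"]
        slope = est[[t for t in est.index if "condition" in t][0]]
        # the contrast is no_load - high_load or vice versa depending on level order
        assert abs(abs(slope) - 0.07) < 0.01
        assert res.effect("condition").p_value < 0.001

    def test_group_effect_detected_when_present(self):
        df = simulate_trial_metrics_table(
            group_effects={"depression": -0.12}, seed=7
        )
        res = fit_mixed_model(df, "aoi_proportion")
        assert res.effect("group").p_value < 0.05

    def test_reports_f_and_dfs_for_both_effects(self):
        df = simulate_trial_metrics_table(seed=3)
        res = fit_mixed_model(df, "aoi_proportion")
        names = {e.effect for e in res.effects}
        assert names == {"group", "condition"}
        assert res.effect("group").df_num == 2
        assert res.effect("condition").df_num == 1
        assert all(e.f_stat >= 0 for e in res.effects)


class TestQuizAccuracy:
    def test_percent_correct(self):
        quiz = pd.DataFrame(
            {"group": ["g"] * 30, "correct": [1] * 18 + [0] * 12}
        )
        assert quiz_accuracy(quiz)["g"] == pytest.approx(60.0)

    def test_all_correct(self):
        quiz = pd.DataFrame({"group": ["g"] * 5, "correct": [1] * 5})
        assert quiz_accuracy(quiz)["g"] == 100.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            quiz_accuracy(pd.DataFrame(columns=["group", "correct"]))
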