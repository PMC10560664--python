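"""Feature vector layout, fold-safe preprocessing and the dense classifier."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from gazeload.features import (
    N_FEATURES,
    augment_features,
    build_feature_table,
    build_feature_vector,
    crossvalidate,
    feature_names,
    standardize_features,
    apply_standardization,
)
from gazeload.network import ClassifierConfig, DenseClassifier


def _participant_metrics(values=None):
    rows = []
    for k in range(20):
        cond = ("high_load", "high_load", "no_load", "no_load")[k % 4]
        v = 50.0 + k if values is None else values
        rows.append(
            {
                "participant_id": "p",
                "group": "control",
                "trial": k,
                "condition": cond,
                "aoi_sample_pct": v,
                "aoi_fixation_duration_s": v / 10,
                "fixation_distribution": v / 100,
            }
        )
    return pd.DataFrame(rows)


class TestFeatureVector:
    def test_length_is_108(self):
        vec = build_feature_vector(_participant_metrics(), np.full(48, 1 / 48))
        assert vec.shape == (N_FEATURES,) == (108,)

    def test_zero_inputs_give_zero_vector(self):
        vec = build_feature_vector(_participant_metrics(values=0.0), np.zeros(48))
        assert not vec.any()

    def test_row_order_is_canonicalized_by_trial(self, rng):
        pm = _participant_metrics()
        grid = rng.random(48)
        shuffled = pm.sample(frac=1.0, random_state=3)
        np.testing.assert_array_equal(
            build_feature_vector(pm, grid), build_feature_vector(shuffled, grid)
        )

    def test_missing_trials_imputed_with_own_condition_mean(self):
        pm = _participant_metrics()
        pm.loc[pm["trial"] == 0, "fixation_distribution"] = np.nan  # high_load trial
        vec = build_feature_vector(pm, np.zeros(48))
        fd_block = vec[48 + 40 :]
        hl_trials = pm[pm["condition"] == "high_load"]["trial"].to_numpy()
        expected = pm.loc[
            (pm["condition"] == "high_load") & (pm["trial"] != 0), "fixation_distribution"
        ].mean()
        assert fd_block[0] == pytest.approx(expected)

    def test_wrong_grid_length_rejected(self):
        with pytest.raises(ValueError):
            build_feature_vector(_participant_metrics(), np.zeros(47))

    def test_layout_is_stable(self):
        names = feature_names()
        assert len(names) == 108
        assert names[0] == "g_r0_c0" and names[47] == "g_r5_c7"
        assert names[48] == "aoi_pct_t0" and names[68] == "aoi_dur_t0"
        assert names[-1] == "fd_t19"
        digest = hashlib.sha256(",".join(names).encode()).hexdigest()
        assert digest == hashlib.sha256(",".join(feature_names()).encode()).hexdigest()


class TestStandardize:
    def test_train_columns_become_standard(self, rng):
        X = rng.normal(5, 3, (40, 10))
        _, Z = standardize_features(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-9)

    def test_constant_column_floored_with_warning(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            _, Z = standardize_features(X)
        assert np.allclose(Z[:, 1], 0.0, atol=1e-6)

    def test_test_fold_uses_train_statistics(self, rng):
        train = rng.normal(0, 1, (20, 4))
        test = rng.normal(10, 1, (5, 4))
        params, _ = standardize_features(train)
        Zt = apply_standardization(params, test)
        _, Zself = standardize_features(test)
        assert not np.allclose(Zt, Zself)
        assert Zt.mean() > 5  # an outlying fold stays outlying


class TestAugmentation:
    def test_factor_four_gives_five_n_rows(self, rng):
        X = rng.normal(size=(6, 8))
        Xa, ya = augment_features(X, np.arange(6), factor=4, seed=0)
        assert Xa.shape == (30, 8) and len(ya) == 30
        np.testing.assert_array_equal(Xa[:6], X)  # originals retained

    def test_zero_jitter_duplicates_exactly(self, rng):
        X = rng.normal(size=(3, 4))
        Xa, _ = augment_features(X, np.zeros(3), factor=2, jitter_sd=0.0, seed=0)
        np.testing.assert_array_equal(Xa[3:6], X)

    def test_seed_reproducibility(self, rng):
        X = rng.normal(size=(5, 7))
        a, _ = augment_features(X, np.zeros(5), seed=9)
        b, _ = augment_features(X, np.zeros(5), seed=9)
        np.testing.assert_array_equal(a, b)


class TestNetwork:
    def test_parameter_count_matches_architecture(self):
        clf = DenseClassifier(108)
        assert clf.n_parameters == 108 * 64 + 64 + 64 * 40 + 40 + 40 * 2 + 2 == 9658

    def test_loss_decreases_on_a_toy_problem(self, rng):
        X = np.vstack([rng.normal(-1, 0.3, (10, 5)), rng.normal(1, 0.3, (10, 5))])
        y = np.array([0] * 10 + [1] * 10)
        clf = DenseClassifier(5, ClassifierConfig(epochs=10, dropout_keep=1.0, seed=0))
        clf.fit(X, y)
        assert clf.loss_history[-1] < clf.loss_history[0]

    def test_training_is_seed_deterministic(self, rng):
        X = rng.normal(size=(12, 6))
        y = np.array([0, 1] * 6)
        w = []
        for _ in range(2):
            clf = DenseClassifier(6, ClassifierConfig(epochs=5, seed=3))
            clf.fit(X, y)
            w.append(clf.weights[0].copy())
        np.testing.assert_array_equal(w[0], w[1])

    def test_non_binary_labels_rejected(self, rng):
        clf = DenseClassifier(4, ClassifierConfig(epochs=1))
        with pytest.raises(ValueError):
            clf.fit(rng.normal(size=(6, 4)), np.array([0, 1, 2, 0, 1, 2]))


class TestCrossValidation:
    def test_no_leak_of_heldout_statistics(self, rng):
        """Standardization inside a fold must ignore held-out rows: an
        outlier in the held-out fold cannot shift the train statistics."""
        train = rng.normal(0, 1, (20, 4))
        params, _ = standardize_features(train)
        outlier = np.full((1, 4), 1e6)
        params_with, _ = standardize_features(train)  # outlier never enters
        np.testing.assert_array_equal(params[0], params_with[0])
        z = apply_standardization(params, outlier)
        assert np.all(z > 1e5)

    def test_separable_classes_reach_high_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 108)), rng.normal(3, 1, (30, 108))])
        y = np.array(["control"] * 30 + ["depression"] * 30)
        res = crossvalidate(X, y, k=10, seed=0,
                            config=ClassifierConfig(epochs=30, seed=0))
        assert res["mean_accuracy"] >= 0.95
        assert len(res["fold_accuracies"]) == 10

    def test_stratification_error_when_class_missing(self):
        X = np.zeros((4, 3))
        y = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError):
            crossvalidate(X, y, k=4)


class TestFeatureTable:
    def test_cohort_feature_table_shape_and_labels(self, small_cohort, aoi_set):
        cohort, sched = small_cohort
        from gazeload.pipeline import compute_cohort_metrics

        metrics, _ = compute_cohort_metrics(cohort.recordings, aoi_set, sched)
        table = build_feature_table(cohort.recordings, metrics)
        assert len(table) == len(cohort.recordings)
        assert set(feature_names()).issubset(table.columns)
        assert table[feature_names()].notna().all().all()
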