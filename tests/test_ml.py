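"""Classification harness: folds, SMOTE, metrics, baselines, importance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from phenodep.ml import (
    CvConfig,
    cohen_kappa,
    demographic_columns,
    dt_baseline,
    metric_set,
    nested_cv,
    one_hot_demographics,
    permutation_importance_auc,
    rwc_baseline,
    smote,
    stratified_folds,
)


class TestOneHotDemographics:
    def _profiles(self):
        return pd.DataFrame(
            {
                "participant_id": ["P1", "P2"],
                "age_group": ["25-34", "65+"],
                "gender": ["female", "male"],
            }
        )

    def test_adds_eight_indicator_columns(self):
        samples = pd.DataFrame({"participant_id": ["P1", "P2", "P1"], "label": [0, 1, 0]})
        out = one_hot_demographics(samples, self._profiles())
        added = demographic_columns(out)
        assert len(added) == 8
        age_cols = [c for c in added if c.startswith("age_group__")]
        assert (out[age_cols].sum(axis=1) == 1).all()
        assert out.loc[0, "age_group__25-34"] == 1

    def test_feature_only_mode_adds_nothing(self):
        samples = pd.DataFrame({"participant_id": ["P1"], "label": [0]})
        out = one_hot_demographics(samples, self._profiles(), include=False)
        assert demographic_columns(out) == []

    def test_unknown_category_rejected(self):
        profiles = self._profiles()
        profiles.loc[0, "age_group"] = "12-17"
        samples = pd.DataFrame({"participant_id": ["P1"], "label": [0]})
        with pytest.raises(ValueError, match="unknown"):
            one_hot_demographics(samples, profiles)


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        y = np.array([1] * 20 + [0] * 80)
        folds = stratified_folds(y, 10, seed=0)
        for f in range(10):
            assert y[folds == f].sum() == 2
            assert (folds == f).sum() == 10

    def test_deterministic(self):
        y = np.array([0, 1] * 30)
        np.testing.assert_array_equal(
            stratified_folds(y, 5, seed=4), stratified_folds(y, 5, seed=4)
        )

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds([0] * 50 + [1] * 3, 5, seed=0)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds([0, 1] * 10, 1, seed=0)


class TestSmote:
    def test_balances_classes_with_exact_count(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 4))
        y = np.array([0] * 90 + [1] * 10)
        xr, yr = smote(x, y, seed=1)
        assert (yr == 1).sum() == (yr == 0).sum() == 90
        assert len(xr) == 180  # 80 synthetic points appended

    def test_identical_minority_points_reproduce_themselves(self):
        x = np.vstack([np.zeros((6, 3)), np.ones((2, 3)) * 7.0])
        y = np.array([0] * 6 + [1] * 2)
        xr, yr = smote(x, y, seed=2)
        np.testing.assert_allclose(xr[yr == 1], 7.0)

    def test_interpolation_stays_on_segment(self):
        x = np.array([[0.0], [1.0]] + [[10.0]] * 20)
        y = np.array([1, 1] + [0] * 20)
        xr, yr = smote(x, y, seed=3)
        synth = xr[2 + 20 :]
        assert ((synth >= 0.0) & (synth <= 1.0)).all()

    def test_singleton_minority_duplicates_with_warning(self):
        x = np.vstack([np.zeros((5, 2)), [[3.0, 3.0]]])
        y = np.array([0] * 5 + [1])
        with pytest.warns(UserWarning, match="singleton"):
            xr, yr = smote(x, y, seed=4)
        np.testing.assert_allclose(xr[yr == 1], 3.0)

    def test_balanced_input_unchanged(self):
        x = np.arange(8.0).reshape(4, 2)
        y = np.array([0, 0, 1, 1])
        xr, yr = smote(x, y, seed=5)
        np.testing.assert_allclose(xr, x)


class TestMetrics:
    def test_kappa_perfect_agreement(self):
        assert cohen_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_kappa_confusion_oracle(self):
        # TP=40, TN=40, FP=10, FN=10: po=0.8, pe=0.5 -> kappa 0.6
        t = [1] * 40 + [0] * 40 + [0] * 10 + [1] * 10
        p = [1] * 40 + [0] * 40 + [1] * 10 + [0] * 10
        assert cohen_kappa(t, p) == pytest.approx(0.6)

    def test_kappa_matches_sklearn(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 2, 500)
        p = rng.integers(0, 2, 500)
        assert cohen_kappa(t, p) == pytest.approx(cohen_kappa_score(t, p), abs=1e-12)

    def test_kappa_degenerate_marginals(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 0.0  # pe = 1 convention

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(1)
        t = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        m = metric_set(t, p)
        if m["precision"] + m["recall"] > 0:
            expected = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
            assert m["f1"] == pytest.approx(expected)
        assert -1.0 <= m["kappa"] <= 1.0
        assert 0.0 <= m["auc"] <= 1.0

    def test_auc_antisymmetric_under_score_negation(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 2, 300)
        s = rng.normal(size=300)
        assert roc_auc_score(t, s) == pytest.approx(1.0 - roc_auc_score(t, -s))


class TestRwcBaseline:
    def test_null_kappa_and_auc(self):
        rng = np.random.default_rng(3)
        y = (rng.random(800) < 0.2).astype(int)
        tab = rwc_baseline(y, n_draws=4000, seed=0).set_index("metric")
        se_k = tab.loc["kappa", "sd"] / np.sqrt(4000)
        se_a = tab.loc["auc", "sd"] / np.sqrt(4000)
        assert abs(tab.loc["kappa", "mean"]) < 3 * se_k
        assert abs(tab.loc["auc", "mean"] - 50.0) < 3 * se_a

    def test_recall_equals_draw_probability(self):
        # predictions are i.i.d. with P(pred=1) = prevalence, so the
        # expected recall equals the prevalence itself
        rng = np.random.default_rng(4)
        pi = 0.3
        y = (rng.random(1000) < pi).astype(int)
        pi_emp = y.mean()
        tab = rwc_baseline(y, n_draws=4000, seed=1).set_index("metric")
        se = tab.loc["recall", "sd"] / np.sqrt(4000)
        assert tab.loc["recall", "mean"] == pytest.approx(100 * pi_emp, abs=3 * se)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rwc_baseline([1, 1, 1])


def _separable_table(n=120, seed=0, n_features=4):
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n * 3 // 4) + [1] * (n // 4))
    x = rng.normal(size=(n, n_features)) + y[:, None] * 6.0
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(n_features)])
    df["label"] = y
    df["participant_id"] = [f"P{i}" for i in range(n)]
    return df


SMALL_CONFIG = dict(
    outer_folds=3,
    inner_folds=2,
    grids={
        "RF": {"n_estimators": [30], "max_depth": [None]},
        "LR": {"C": [0.1, 1.0]},
        "DT": {"max_depth": [None, 3]},
    },
    permutation_repeats=2,
)


class TestNestedCv:
    def test_separable_data_solved(self):
        table = _separable_table()
        cfg = CvConfig(classifiers=("RF", "LR"), seed=1, **SMALL_CONFIG)
        rep = nested_cv(table, cfg, feature_names=[f"f{i}" for i in range(4)])
        mean_auc = rep["folds"].groupby("classifier")["auc"].mean()
        assert (mean_auc > 0.97).all()
        assert rep["folds"].groupby("classifier")["kappa"].mean().min() > 0.8

    def test_deterministic_under_seed(self):
        table = _separable_table(seed=2)
        cfg = CvConfig(classifiers=("RF",), seed=7, **SMALL_CONFIG)
        a = nested_cv(table, cfg, feature_names=[f"f{i}" for i in range(4)])
        b = nested_cv(table, cfg, feature_names=[f"f{i}" for i in range(4)])
        pd.testing.assert_frame_equal(a["folds"], b["folds"])
        pd.testing.assert_frame_equal(a["importance"], b["importance"])

    def test_expected_fold_count_and_importance_coverage(self):
        table = _separable_table(seed=3)
        feats = [f"f{i}" for i in range(4)]
        cfg = CvConfig(classifiers=("LR",), seed=0, **SMALL_CONFIG)
        rep = nested_cv(table, cfg, feature_names=feats)
        assert len(rep["folds"]) == 3
        assert set(rep["importance"]["feature"]) == set(feats)

    def test_missing_values_rejected(self):
        table = _separable_table()
        table.loc[0, "f0"] = np.nan
        cfg = CvConfig(classifiers=("LR",), seed=0, **SMALL_CONFIG)
        with pytest.raises(ValueError, match="missing"):
            nested_cv(table, cfg, feature_names=[f"f{i}" for i in range(4)])

    def test_audit_shows_no_test_rows_in_fits(self):
        table = _separable_table(seed=4)
        cfg = CvConfig(classifiers=("RF",), seed=3, **SMALL_CONFIG)
        rep = nested_cv(table, cfg, feature_names=[f"f{i}" for i in range(4)])
        for entry in rep["audit"]:
            assert np.intersect1d(entry["fit_rows"], entry["test_rows"]).size == 0


class TestBaselinesAndImportance:
    def test_dt_baseline_learns_demographic_label(self):
        rng = np.random.default_rng(5)
        n = 120
        profiles = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "age_group": rng.choice(["18-24", "65+"], n),
                "gender": rng.choice(["female", "male"], n),
            }
        )
        samples = pd.DataFrame({"participant_id": profiles["participant_id"]})
        samples["label"] = (profiles["age_group"] == "65+").astype(int)
        table = one_hot_demographics(samples, profiles)
        cfg = CvConfig(classifiers=("DT",), seed=0, **SMALL_CONFIG)
        rep = dt_baseline(table, cfg)
        assert rep["folds"]["auc"].mean() > 0.95

    def test_ignored_feature_has_zero_importance(self):
        class OnlyFirstColumn:
            def predict_proba(self, x):
                p = 1 / (1 + np.exp(-x[:, 0]))
                return np.column_stack([1 - p, p])

        rng = np.random.default_rng(6)
        x = rng.normal(size=(200, 3))
        y = (x[:, 0] > 0).astype(int)
        imp = permutation_importance_auc(OnlyFirstColumn(), x, y, repeats=3, seed=0)
        assert imp[0] > 0.3
        assert imp[1] == pytest.approx(0.0, abs=1e-12) or abs(imp[1]) < 0.05
        assert abs(imp[2]) < 0.05

    def test_perfect_single_indicator_importance_near_half(self):
        class Identity:
            def predict_proba(self, x):
                return np.column_stack([1 - x[:, 0], x[:, 0]])

        y = np.array([0, 1] * 100)
        x = y[:, None].astype(float)
        imp = permutation_importance_auc(Identity(), x, y, repeats=10, seed=1)
        # permuting the only informative column drives AUC to ~0.5
        assert imp[0] == pytest.approx(0.5, abs=0.05)

    def test_constant_column_zero_importance(self):
        class OnlyFirstColumn:
            def predict_proba(self, x):
                p = 1 / (1 + np.exp(-x[:, 0]))
                return np.column_stack([1 - p, p])

        rng = np.random.default_rng(7)
        x = rng.normal(size=(100, 2))
        x[:, 1] = 3.14
        y = (x[:, 0] > 0).astype(int)
        imp = permutation_importance_auc(OnlyFirstColumn(), x, y, repeats=3, seed=0)
        assert imp[1] == 0.0
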