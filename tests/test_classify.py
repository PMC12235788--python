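import numpy as np
import pandas as pd
import pytest

from leafletmotion.classify import (
    ModelSpec,
    build_feature_table,
    compare_models,
    delong_test,
    evaluate,
    feature_importance,
    remove_collinear,
    run_task,
    stratified_split,
    tune_and_fit,
)
from leafletmotion.simulate import SimulationConfig, cohort_to_frame, \
    simulate_feature_cohort

SMALL_ENET_GRID = ({"C": 0.1, "l1_ratio": 0.5}, {"C": 1.0, "l1_ratio": 0.5},
                   {"C": 10.0, "l1_ratio": 0.5})


def brute_force_auc(y, scores):
    """Concordant-pair fraction with half credit for ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestBuildFeatureTable:
    def test_binary_shape_and_positives(self, default_cohort_df):
        x, y = build_feature_table(default_cohort_df, "binary_significant_AS")
        assert x.shape == (200, 8)
        assert int(y.sum()) == 140

    def test_multiclass_shape(self, default_cohort_df):
        x, y = build_feature_table(default_cohort_df, "multiclass_severity")
        assert x.shape == (200, 10)
        assert set(y.cat.categories) == {"control", "moderate", "severe"}

    def test_doppler_fields_never_enter(self, default_cohort_df):
        for task in ("binary_significant_AS", "multiclass_severity"):
            x, _ = build_feature_table(default_cohort_df, task)
            assert not ({"ava", "mean_gradient", "peak_velocity",
                         "dimensionless_index"} & set(x.columns))

    def test_missing_value_names_record(self, default_cohort_df):
        df = default_cohort_df.copy()
        df.loc[df.index[3], "pwd"] = np.nan
        pid = df.loc[df.index[3], "patient_id"]
        with pytest.raises(ValueError, match=pid):
            build_feature_table(df, "multiclass_severity")


class TestRemoveCollinear:
    def test_duplicated_column_dropped_once(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        df = pd.DataFrame({"a": a, "a_copy": a, "b": rng.normal(size=500)})
        kept, dropped = remove_collinear(df)
        assert dropped == ["a_copy"]
        assert kept == ["a", "b"]

    def test_orthogonal_features_all_kept(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(500, 4)),
                          columns=list("abcd"))
        kept, dropped = remove_collinear(df)
        assert dropped == []
        assert kept == list("abcd")

    def test_drops_member_with_larger_mean_correlation(self):
        """r(a,b)=0.95, r(a,c)=0.4, r(b,c)=0.1: a has the larger mean |r|
        and is dropped."""
        target = np.array([[1.0, 0.95, 0.4],
                           [0.95, 1.0, 0.1],
                           [0.4, 0.1, 1.0]])
        rng = np.random.default_rng(2)
        chol = np.linalg.cholesky(target)
        z = rng.normal(size=(20_000, 3)) @ chol.T
        df = pd.DataFrame(z, columns=["a", "b", "c"])
        kept, dropped = remove_collinear(df, threshold=0.9)
        assert dropped == ["a"]
        assert kept == ["b", "c"]


class TestStratifiedSplit:
    def test_multiclass_exact_fifths(self, default_cohort_df):
        x, y = build_feature_table(default_cohort_df, "multiclass_severity")
        _, x_te, _, y_te = stratified_split(x, y, 0.2, seed=0)
        counts = y_te.value_counts()
        assert counts["control"] == 12
        assert counts["moderate"] == 14
        assert counts["severe"] == 14

    def test_binary_split_counts(self, default_cohort_df):
        x, y = build_feature_table(default_cohort_df, "binary_significant_AS")
        x_tr, x_te, y_tr, y_te = stratified_split(x, y, 0.2, seed=0)
        assert int(y_te.sum()) == 28
        assert len(y_te) == 40
        assert set(x_tr.index).isdisjoint(x_te.index)
        assert len(x_tr) + len(x_te) == 200

    def test_same_seed_same_split(self, default_cohort_df):
        x, y = build_feature_table(default_cohort_df, "binary_significant_AS")
        a = stratified_split(x, y, 0.2, seed=5)[1]
        b = stratified_split(x, y, 0.2, seed=5)[1]
        assert list(a.index) == list(b.index)

    def test_small_level_rejected(self, default_cohort_df):
        x, y = build_feature_table(default_cohort_df, "binary_significant_AS")
        # a window with only 4 controls cannot be stratified
        with pytest.raises(ValueError, match="stratif"):
            stratified_split(x.iloc[56:70], y.iloc[56:70], 0.2, seed=0)


class TestTuneAndFit:
    def test_separable_toy_data_reaches_perfect_auc(self):
        rng = np.random.default_rng(3)
        n = 100
        x = pd.DataFrame({"f1": np.r_[rng.normal(-3, 0.3, n // 2),
                                      rng.normal(3, 0.3, n // 2)],
                          "f2": rng.normal(size=n)})
        y = pd.Series(np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int))
        order = rng.permutation(n)
        x, y = x.iloc[order].reset_index(drop=True), y.iloc[order].reset_index(drop=True)
        x_tr, x_te = x.head(70), x.tail(30)
        y_tr, y_te = y.head(70), y.tail(30)
        spec = ModelSpec("elastic_net_logistic", "binary_significant_AS",
                         seed=0, tuning_grid=SMALL_ENET_GRID)
        fitted = tune_and_fit(spec, x_tr, y_tr)
        report = evaluate(fitted, x_te, y_te)
        assert report.auc == pytest.approx(1.0)

    def test_label_permutation_destroys_cv_signal(self, default_cohort_df):
        x, y = build_feature_table(default_cohort_df, "binary_significant_AS")
        rng = np.random.default_rng(4)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        x_tr, _, y_tr, _ = stratified_split(x, y_perm, 0.2, seed=0)
        spec = ModelSpec("elastic_net_logistic", "binary_significant_AS",
                         seed=0, tuning_grid=SMALL_ENET_GRID)
        fitted = tune_and_fit(spec, x_tr, y_tr)
        best_cv = fitted.cv_summary.mean_cv_auc.max()
        assert 0.35 < best_cv < 0.65

    def test_determinism(self, default_cohort_df):
        x, y = build_feature_table(default_cohort_df, "binary_significant_AS")
        x_tr, _, y_tr, _ = stratified_split(x, y, 0.2, seed=1)
        spec = ModelSpec("elastic_net_logistic", "binary_significant_AS",
                         seed=1, tuning_grid=SMALL_ENET_GRID)
        a = tune_and_fit(spec, x_tr, y_tr)
        b = tune_and_fit(spec, x_tr, y_tr)
        assert a.best_params == b.best_params
        pd.testing.assert_frame_equal(a.cv_summary, b.cv_summary)


class TestEvaluate:
    def _fitted_stub(self, proba_map, classes=(0, 1)):
        """Minimal fitted model returning fixed probabilities."""
        class Stub:
            classes_ = np.asarray(classes)

            def predict_proba(self, x):
                return np.asarray([proba_map[i] for i in x.index])

            @property
            def named_steps(self):
                return {"model": self}

        from leafletmotion.classify import FittedModel
        return FittedModel(
            spec=ModelSpec("k_nearest_neighbors", "binary_significant_AS",
                           tuning_grid=({"n_neighbors": 3},)),
            pipeline=Stub(), feature_names=("f",), classes=tuple(classes),
            best_params={}, cv_summary=pd.DataFrame())

    def test_perfect_predictions(self):
        y = pd.Series([0, 1, 0, 1, 1, 0])
        x = pd.DataFrame({"f": np.zeros(6)})
        proba = {i: [1 - t, t] for i, t in zip(y.index, y)}
        rep = evaluate(self._fitted_stub(proba), x, y)
        assert rep.accuracy == 1.0
        assert rep.auc == 1.0

    def test_constant_probability_gives_half_auc(self):
        y = pd.Series([0, 1, 0, 1])
        x = pd.DataFrame({"f": np.zeros(4)})
        proba = {i: [0.5, 0.5] for i in y.index}
        rep = evaluate(self._fitted_stub(proba), x, y)
        assert rep.auc == pytest.approx(0.5)

    def test_auc_matches_brute_force_on_fixture(self):
        scores = [0.9, 0.8, 0.8, 0.55, 0.5, 0.3, 0.2, 0.1]
        y = pd.Series([1, 1, 0, 1, 0, 1, 0, 0])
        x = pd.DataFrame({"f": np.zeros(8)})
        proba = {i: [1 - s, s] for i, s in zip(y.index, scores)}
        rep = evaluate(self._fitted_stub(proba), x, y)
        assert rep.auc == pytest.approx(brute_force_auc(y, scores))

    def test_single_class_test_set_rejected(self):
        y = pd.Series([1, 1, 1])
        x = pd.DataFrame({"f": np.zeros(3)})
        proba = {i: [0.2, 0.8] for i in y.index}
        with pytest.raises(ValueError):
            evaluate(self._fitted_stub(proba), x, y)


class TestDeLong:
    def test_self_comparison_p_is_one(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 50)
        y[:5] = 1; y[5:10] = 0
        s = rng.normal(size=50)
        diff, p = delong_test(y, s, s)
        assert diff == 0.0
        assert p == 1.0

    def test_extreme_difference_significant(self):
        rng = np.random.default_rng(6)
        y = np.r_[np.zeros(100), np.ones(100)].astype(int)
        perfect = y + rng.normal(0, 0.01, 200)
        useless = rng.normal(size=200)
        _, p = delong_test(y, perfect, useless)
        assert p < 0.01

    def test_structural_components_match_brute_force(self):
        """Hand-evaluated psi-kernel components on a 6-observation fixture."""
        from leafletmotion.classify import _delong_components

        y = np.array([1, 1, 1, 0, 0, 0])
        s = np.array([0.9, 0.6, 0.4, 0.7, 0.4, 0.1])
        auc, v10, v01 = _delong_components(y, s)

        def psi(a, b):
            return 1.0 if a > b else (0.5 if a == b else 0.0)

        pos, neg = s[y == 1], s[y == 0]
        auc_bf = np.mean([[psi(a, b) for b in neg] for a in pos])
        v10_bf = [np.mean([psi(a, b) for b in neg]) for a in pos]
        v01_bf = [np.mean([psi(a, b) for a in pos]) for b in neg]
        assert auc == pytest.approx(auc_bf, abs=1e-12)
        assert v10 == pytest.approx(v10_bf, abs=1e-12)
        assert v01 == pytest.approx(v01_bf, abs=1e-12)

    def test_compare_models_wiring(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.zeros(60), np.ones(60)].astype(int)
        good = np.column_stack([1 - y, y]) + rng.normal(0, 0.05, (120, 2))
        bad = rng.uniform(size=(120, 2))
        res = compare_models(y, {"good": good, "bad": bad},
                             "binary_significant_AS")
        assert res["pairwise"][0]["p"] < 0.01
        assert res["global_p"] < 0.01


class TestFeatureImportance:
    def _enet_fixture(self, coef):
        from leafletmotion.classify import FittedModel, _make_estimator

        spec = ModelSpec("elastic_net_logistic", "binary_significant_AS",
                         tuning_grid=({"C": 1.0, "l1_ratio": 0.5},))
        pipe = _make_estimator(spec, {"C": 1.0, "l1_ratio": 0.5})
        x = pd.DataFrame(np.random.default_rng(8).normal(size=(40, len(coef))),
                         columns=[f"f{i}" for i in range(len(coef))])
        y = pd.Series(np.r_[np.zeros(20), np.ones(20)].astype(int))
        pipe.fit(x, y)
        pipe.named_steps["model"].coef_ = np.asarray([coef], dtype=float)
        return FittedModel(spec=spec, pipeline=pipe,
                           feature_names=tuple(x.columns),
                           classes=(0, 1), best_params={},
                           cv_summary=pd.DataFrame())

    def test_single_nonzero_coefficient_ranks_first(self):
        fitted = self._enet_fixture([0.0, 2.5, 0.0])
        imp = feature_importance(fitted)
        assert imp.feature.iloc[0] == "f1"
        assert imp.importance.iloc[0] == pytest.approx(1.0)

    def test_all_zero_coefficients(self):
        fitted = self._enet_fixture([0.0, 0.0, 0.0])
        imp = feature_importance(fitted)
        assert (imp.importance == 0).all()
        assert list(imp.feature) == ["f0", "f1", "f2"]

    def test_linear_displacement_usually_matters(self):
        """A linear-displacement feature lands in the top 3 importances in
        most default cohorts."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            df = cohort_to_frame(simulate_feature_cohort(
                SimulationConfig(seed=seed)))
            fitted, _ = run_task(df, "binary_significant_AS",
                                 "elastic_net_logistic", seed=seed,
                                 tuning_grid=SMALL_ENET_GRID)
            imp = feature_importance(fitted)
            top3 = set(imp.feature.head(3))
            if top3 & {"ld_mid", "ld_tip", "ld_global"}:
                hits += 1
        assert hits >= 0.8 * n_seeds
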