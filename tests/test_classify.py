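import numpy as np
import pandas as pd
import pytest

from catransient.classify import (
    ARRANGEMENTS,
    GRID_3CLASS,
    GRID_4CLASS,
    ClassifierSpec,
    baselines,
    loo_evaluate,
    run_grid,
    select_arrangement,
    standardize,
)
from catransient.signal_io import CLASS_LABELS, FEATURE_COLUMNS


class TestBaselines:
    def test_study_cohort_values(self):
        random, majority = baselines({"LQT1": 90, "HCM": 71, "CPVT": 233,
                                      "WT": 133})
        assert random == 25.0
        assert round(majority, 1) == 44.2

    def test_single_class_both_hundred(self):
        random, majority = baselines([42])
        assert random == 100.0 and majority == 100.0

    def test_empty_total_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            baselines([0, 0])


class TestArrangements:
    @pytest.fixture
    def table(self, rng):
        rows = []
        for lbl, n, n_abn in (("LQT1", 10, 4), ("HCM", 8, 3), ("CPVT", 12, 6),
                              ("WT", 9, 1)):
            for i in range(n):
                rows.append({"signal_id": f"{lbl}{i}", "label": lbl,
                             "abnormal": i < n_abn,
                             **{c: rng.normal() for c in FEATURE_COLUMNS}})
        return pd.DataFrame(rows)

    def test_disease_partition(self, table):
        normal = select_arrangement(table, "1.1")
        abnormal = select_arrangement(table, "1.2")
        pooled = select_arrangement(table, "1.3")
        assert len(normal) + len(abnormal) == len(pooled) == 30
        assert set(normal.signal_id).isdisjoint(abnormal.signal_id)
        assert "WT" not in set(pooled.label)

    def test_four_class_arrangements(self, table):
        assert len(select_arrangement(table, "2.2")) == len(table)
        norm4 = select_arrangement(table, "2.1")
        assert set(norm4.label) == set(CLASS_LABELS)
        assert not norm4.abnormal.any()

    def test_controls_stay_inside_wt_in_pooled(self, table):
        pooled = select_arrangement(table, "2.2")
        assert set(pooled.label) == set(CLASS_LABELS)
        assert pooled[pooled.label == "WT"].abnormal.sum() == 1

    def test_unknown_arrangement_rejected(self, table):
        with pytest.raises(ValueError, match="unknown arrangement"):
            select_arrangement(table, "3.1")
        assert ARRANGEMENTS == ("1.1", "1.2", "1.3", "2.1", "2.2")


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng, feature_frame_factory):
        df = feature_frame_factory(rng, 50, shift=3.0)
        out, params = standardize(df)
        for c in FEATURE_COLUMNS:
            assert out[c].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[c].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
        assert set(params.index) == set(FEATURE_COLUMNS)

    def test_constant_column_maps_to_zero(self, rng, feature_frame_factory):
        df = feature_frame_factory(rng, 20, shift=1.0)
        df["A_l"] = 7.0
        out, _ = standardize(df)
        assert (out["A_l"] == 0.0).all()


class TestSpecs:
    def test_grids_match_published_configurations(self):
        assert len(GRID_3CLASS) == 6 and len(GRID_4CLASS) == 8
        rf3 = [s for s in GRID_3CLASS if s.family == "random_forest"]
        rf4 = [s for s in GRID_4CLASS if s.family == "random_forest"]
        assert rf3[0].n_trees == 35 and rf4[0].n_trees == 54
        poly = [s for s in GRID_3CLASS if s.kernel == "poly3"
                and s.family == "ls_svm"]
        assert poly[0].C == pytest.approx(2.0**-5)
        rbf4 = [s for s in GRID_4CLASS if s.family == "ls_svm"][0]
        assert rbf4.C == pytest.approx(16.0) and rbf4.sigma == 2.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ClassifierSpec("svm")
        with pytest.raises(ValueError, match="metric"):
            ClassifierSpec("knn", metric="cosine")
        with pytest.raises(ValueError, match="C and sigma"):
            ClassifierSpec("ls_svm", C=-1.0)


class TestLooEvaluate:
    def test_far_separated_classes_near_perfect(self, rng,
                                                feature_frame_factory):
        df = feature_frame_factory(rng, 60, shift=30.0)
        for spec in (ClassifierSpec("knn", k=1),
                     ClassifierSpec("random_forest", n_trees=20),
                     ClassifierSpec("ls_svm", kernel="rbf", C=2.0, sigma=2.0)):
            rep = loo_evaluate(df, spec)
            assert rep.accuracy >= 99.0, spec.describe()

    def test_confusion_matrix_invariants(self, rng, feature_frame_factory):
        df = feature_frame_factory(rng, 25, shift=1.0,
                                   labels=("LQT1", "HCM", "CPVT"))
        rep = loo_evaluate(df, ClassifierSpec("knn", k=3))
        assert rep.confusion.to_numpy().sum() == len(df)
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), [25, 25, 25])
        for lbl in ("LQT1", "HCM", "CPVT"):
            tpr = 100.0 * rep.confusion.loc[lbl, lbl] / 25
            assert rep.tpr[lbl] == pytest.approx(tpr)
        acc = 100.0 * np.trace(rep.confusion.to_numpy()) / len(df)
        assert rep.accuracy == pytest.approx(acc)

    def test_knn_matches_sklearn_reference(self, rng, feature_frame_factory):
        # independent cross-check: sklearn's kNN on the same folds
        from sklearn.neighbors import KNeighborsClassifier

        df = feature_frame_factory(rng, 30, shift=1.5)
        rep = loo_evaluate(df, ClassifierSpec("knn", metric="euclidean", k=3),
                           standardize_mode="global")
        X = df.loc[:, list(FEATURE_COLUMNS)].to_numpy()
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        y = df["label"].to_numpy()
        correct = 0
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            clf = KNeighborsClassifier(n_neighbors=3).fit(X[mask], y[mask])
            correct += clf.predict(X[i : i + 1])[0] == y[i]
        assert rep.accuracy == pytest.approx(100.0 * correct / len(y))

    def test_nearest_neighbor_identity(self, rng):
        # duplicate every point; k=1 must recover every label exactly
        X = rng.normal(size=(40, 10))
        df = pd.DataFrame(np.vstack([X, X]), columns=FEATURE_COLUMNS)
        df["label"] = ["LQT1", "WT"] * 40
        rep = loo_evaluate(df, ClassifierSpec("knn", k=1))
        assert rep.accuracy == 100.0

    def test_mahalanobis_metric_runs_and_reports(self, rng,
                                                 feature_frame_factory):
        # pooled covariance partially whitens away the class-mean offset,
        # so expect clearly-above-chance, not near-perfect, accuracy
        df = feature_frame_factory(rng, 30, shift=4.0)
        rep = loo_evaluate(df, ClassifierSpec("knn", metric="mahalanobis", k=1))
        assert rep.accuracy > 70.0
        assert rep.confusion.to_numpy().sum() == len(df)

    def test_deterministic_given_seed(self, rng, feature_frame_factory):
        df = feature_frame_factory(rng, 20, shift=0.5,
                                   labels=("LQT1", "HCM", "CPVT", "WT"))
        r1 = loo_evaluate(df, ClassifierSpec("random_forest", n_trees=15, seed=3))
        r2 = loo_evaluate(df, ClassifierSpec("random_forest", n_trees=15, seed=3))
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)

    def test_per_fold_standardization_close_to_global(self, rng,
                                                      feature_frame_factory):
        df = feature_frame_factory(rng, 50, shift=8.0)
        g = loo_evaluate(df, ClassifierSpec("knn", k=3),
                         standardize_mode="global")
        f = loo_evaluate(df, ClassifierSpec("knn", k=3),
                         standardize_mode="per_fold")
        assert abs(g.accuracy - f.accuracy) < 2.0

    def test_too_few_rows_rejected(self, rng, feature_frame_factory):
        df = feature_frame_factory(rng, 1, shift=1.0)
        with pytest.raises(ValueError, match="at least"):
            loo_evaluate(df, ClassifierSpec("knn"))


class TestLsSvm:
    def test_separable_poly3_and_linear(self, rng, feature_frame_factory):
        df = feature_frame_factory(rng, 40, shift=20.0)
        for kernel in ("linear", "poly3"):
            rep = loo_evaluate(df, ClassifierSpec("ls_svm", kernel=kernel,
                                                  C=2.0**-5))
            assert rep.accuracy >= 99.0, kernel

    def test_rbf_handles_nonlinear_boundary(self, rng):
        # concentric classes: linear kernel fails, RBF separates
        n = 80
        r1 = rng.normal(size=(n, 10)) * 0.3
        r2 = rng.normal(size=(n, 10))
        r2 = r2 / np.linalg.norm(r2, axis=1, keepdims=True) * 4.0
        df = pd.DataFrame(np.vstack([r1, r2]), columns=FEATURE_COLUMNS)
        df["label"] = ["LQT1"] * n + ["WT"] * n
        rbf = loo_evaluate(df, ClassifierSpec("ls_svm", kernel="rbf",
                                              C=2.0, sigma=2.0))
        lin = loo_evaluate(df, ClassifierSpec("ls_svm", kernel="linear", C=2.0))
        assert rbf.accuracy > 90.0 > lin.accuracy


class TestRunGrid:
    def test_cardinality_and_layout(self, rng, feature_frame_factory):
        df = feature_frame_factory(rng, 15, shift=3.0,
                                   labels=("LQT1", "HCM", "CPVT", "WT"))
        specs = [ClassifierSpec("knn", k=1), ClassifierSpec("knn", k=3)]
        reports, ranked = run_grid(df, ["2.2"], specs)
        assert len(reports) == 2 and len(ranked) == 2
        tpr_cols = [c for c in ranked.columns if c.startswith("TPR_")]
        assert tpr_cols == ["TPR_LQT1", "TPR_HCM", "TPR_CPVT", "TPR_WT"]
        assert ranked.best.sum() == 1

    def test_rerun_identical(self, rng, feature_frame_factory):
        df = feature_frame_factory(rng, 15, shift=2.0,
                                   labels=("LQT1", "HCM", "CPVT"))
        specs = [ClassifierSpec("random_forest", n_trees=10, seed=5)]
        _, r1 = run_grid(df, ["1.3"], specs)
        _, r2 = run_grid(df, ["1.3"], specs)
        pd.testing.assert_frame_equal(r1, r2)
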