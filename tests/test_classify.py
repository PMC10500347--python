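"""Classifier protocol: base-learner contracts, ensemble equivalences,
cross-validation determinism and the discrimination-task machinery."""

import numpy as np
import pandas as pd
import pytest

from octraman.classify import (
    SIX_PAIRINGS,
    TASKS,
    ClassifierSpec,
    EnsembleSpec,
    WeightedLDA,
    best_per_classifier,
    cross_validate,
    rank_features,
    run_fused_experiment,
    run_task,
    train_predict,
)

NONE = EnsembleSpec(method="none")


def blobs(n_per_class=50, sep=10.0, p=2, seed=0, classes=("a", "b")):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, c in enumerate(classes):
        X.append(rng.normal(i * sep, 1.0, size=(n_per_class, p)))
        y += [c] * n_per_class
    return np.vstack(X), np.array(y)


class TestBaseLearners:
    def test_knn_k1_memorises_training_set(self):
        X, y = blobs(sep=0.5)  # heavily overlapping: still 100% on train
        pred = train_predict(ClassifierSpec(base="KNN"), NONE, X, y, X)
        assert (pred == y).all()

    def test_tree_shatters_consistent_data(self):
        X, y = blobs(sep=0.3, seed=3)
        pred = train_predict(ClassifierSpec(base="TREE"), NONE, X, y, X)
        assert (pred == y).all()

    def test_lda_separates_distant_blobs(self):
        X, y = blobs(n_per_class=50, sep=10.0, seed=1)
        Xt, yt = blobs(n_per_class=30, sep=10.0, seed=2)
        pred = train_predict(ClassifierSpec(base="LDA"), NONE, X, y, Xt)
        assert (pred == yt).all()

    def test_weighted_lda_matches_uniform_weights(self):
        X, y = blobs(sep=3.0, seed=4)
        a = WeightedLDA().fit(X, y).predict(X)
        b = WeightedLDA().fit(X, y, sample_weight=np.full(len(y), 2.5)).predict(X)
        assert (a == b).all()

    def test_lda_handles_singular_covariance(self):
        """More features than samples: the pseudo-inverse path."""
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (10, 50)), rng.normal(5, 1, (10, 50))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        pred = WeightedLDA().fit(X, y).predict(X)
        assert (pred == y).all()

    def test_knn_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        Xtr = rng.normal(size=(150, 5))
        ytr = rng.integers(0, 3, 150).astype(str)
        Xte = rng.normal(size=(80, 5))
        pred = train_predict(ClassifierSpec(base="KNN"), NONE, Xtr, ytr, Xte)
        d2 = ((Xte[:, None, :] - Xtr[None, :, :]) ** 2).sum(-1)
        assert (pred == ytr[np.argmin(d2, axis=1)]).all()

    def test_knn_is_scale_sensitive(self):
        """No standardisation: inflating one feature changes predictions."""
        X = np.array([[0.0, 0.0], [10.0, 1.0]])
        y = np.array(["a", "b"])
        Xt = np.array([[9.0, 0.1]])  # near b in x, near a in y
        before = train_predict(ClassifierSpec(base="KNN"), NONE, X, y, Xt)
        X2, Xt2 = X.copy(), Xt.copy()
        X2[:, 1] *= 1e6
        Xt2[:, 1] *= 1e6
        after = train_predict(ClassifierSpec(base="KNN"), NONE, X2, y, Xt2)
        assert before[0] == "b" and after[0] == "a"

    def test_single_class_training_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="single class"):
            train_predict(ClassifierSpec(), NONE, X, np.array(["a"] * 5), X)

    def test_boosting_knn_rejected(self):
        X, y = blobs()
        with pytest.raises(ValueError, match="sample-weight"):
            train_predict(
                ClassifierSpec(base="KNN"), EnsembleSpec(method="boosting"), X, y, X
            )


class TestEnsembles:
    @pytest.mark.parametrize("base", ["LDA", "TREE"])
    def test_single_learner_bagging_equals_base(self, base):
        X, y = blobs(sep=1.5, seed=5)
        Xt, _ = blobs(sep=1.5, seed=6)
        spec = ClassifierSpec(base=base)
        solo = EnsembleSpec(method="bagging", n_learners=1, bootstrap=False)
        a = train_predict(spec, solo, X, y, Xt, seed=0)
        b = train_predict(spec, NONE, X, y, Xt, seed=0)
        assert (a == b).all()

    @pytest.mark.parametrize("method", ["bagging", "boosting", "subspace"])
    def test_ensembles_learn_separable_data(self, method):
        base = "KNN" if method == "subspace" else "TREE"
        X, y = blobs(n_per_class=40, sep=8.0, p=4, seed=8)
        Xt, yt = blobs(n_per_class=20, sep=8.0, p=4, seed=9)
        pred = train_predict(
            ClassifierSpec(base=base), EnsembleSpec(method=method, n_learners=10), X, y, Xt
        )
        assert (pred == yt).all()

    def test_subspace_dim_validated(self):
        X, y = blobs(p=3)
        with pytest.raises(ValueError, match="subspace_dim"):
            train_predict(
                ClassifierSpec(base="KNN"),
                EnsembleSpec(method="subspace", subspace_dim=7),
                X, y, X,
            )


class TestCrossValidate:
    def test_separable_data_perfect_accuracy(self):
        X, y = blobs(n_per_class=30, sep=12.0)
        res = cross_validate(ClassifierSpec(base="KNN"), NONE, X, y, seed=0)
        assert res.accuracy == 1.0
        assert res.n_folds == 10

    def test_null_labels_give_chance_accuracy(self):
        """Features independent of labels: pooled CV accuracy stays in a
        chance band around 0.5 for balanced binary labels."""
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(100, 4))
            y = np.array(["a", "b"] * 50)
            accs.append(
                cross_validate(ClassifierSpec(base="KNN"), NONE, X, y, seed=seed).accuracy
            )
        assert 0.35 <= np.mean(accs) <= 0.65
        assert all(0.25 <= a <= 0.75 for a in accs)

    def test_deterministic_per_seed(self):
        X, y = blobs(sep=1.0, seed=2)
        r1 = cross_validate(ClassifierSpec(base="TREE"), EnsembleSpec(method="bagging"), X, y, seed=5)
        r2 = cross_validate(ClassifierSpec(base="TREE"), EnsembleSpec(method="bagging"), X, y, seed=5)
        assert r1.accuracy == r2.accuracy
        assert np.array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_confusion_matrix_row_sums(self):
        X, y = blobs(n_per_class=25, sep=0.5, classes=("a", "b", "c"))
        res = cross_validate(ClassifierSpec(base="TREE"), NONE, X, y, seed=1)
        assert 0.0 <= res.accuracy <= 1.0
        assert (res.confusion_matrix.sum(axis=1) == 25).all()
        assert res.confusion_matrix.to_numpy().sum() == len(y)

    def test_small_class_degrades_folds(self):
        X, y = blobs(n_per_class=6, sep=5.0)
        res = cross_validate(ClassifierSpec(base="KNN"), NONE, X, y, n_folds=10, seed=0)
        assert res.n_folds == 6

    def test_too_few_folds_rejected(self):
        X, y = blobs()
        with pytest.raises(ValueError, match="n_folds"):
            cross_validate(ClassifierSpec(), NONE, X, y, n_folds=1)


class TestRankFeatures:
    def test_informative_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 60
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        X = rng.normal(size=(n, 4))
        X[:, 2] += np.where(y == "a", 0.0, 8.0)  # only column 2 informative
        order = rank_features(ClassifierSpec(base="KNN"), NONE, X, y, seed=0)
        assert order[0] == 2

    def test_single_feature(self):
        X, y = blobs(p=1)
        assert rank_features(ClassifierSpec(base="KNN"), NONE, X, y, seed=0) == [0]

    def test_duplicated_columns_tie_break_stable(self):
        X, y = blobs(p=1, sep=6.0)
        X = np.hstack([X, X])
        order = rank_features(ClassifierSpec(base="KNN"), NONE, X, y, seed=0)
        assert order == [0, 1]


class TestRunTask:
    @pytest.fixture()
    def oct_features(self, small_population_features):
        df = small_population_features
        X = df[
            ["volume_um3", "compactness", "surface_roughness_um",
             "mean_intensity", "intensity_sd"]
        ].rename(columns={
            "volume_um3": "V", "compactness": "C", "surface_roughness_um": "SR",
            "mean_intensity": "AI", "intensity_sd": "IS",
        })
        return X, df["class_label"].to_numpy()

    def test_cancer_vs_normal_grid(self, oct_features):
        X, y = oct_features
        grid = run_task(
            X, y, TASKS["cancer_vs_normal"],
            pairings=(("bagging", "TREE"), ("subspace", "KNN")),
            feature_subsets=("IS", "1&2&3", "ALL"),
            seed=0,
        )
        assert len(grid) == 6
        assert grid["accuracy"].between(0, 1).all()
        assert (grid["n_samples"] == 60).all()
        best = best_per_classifier(grid)
        assert set(best["classifier"]) == {"TREE", "KNN"}
        assert grid["accuracy"].max() >= 0.85

    def test_task_dropping_samples(self, oct_features):
        X, y = oct_features
        grid = run_task(
            X, y, TASKS["bcc_vs_scc"],
            pairings=(("bagging", "TREE"),), feature_subsets=("ALL",), seed=0,
        )
        assert (grid["n_samples"] == 24).all()

    def test_empty_task_rejected(self, oct_features):
        X, y = oct_features
        from octraman.classify import TaskSpec

        with pytest.raises(ValueError, match="no samples"):
            run_task(X, y, TaskSpec("none", {}), seed=0)


class TestFusion:
    def separable_modalities(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        classes = ["HaCaT", "melanocyte", "SCC", "BCC", "melanoma"]
        oct_centres = {
            "HaCaT": (0, 0), "melanocyte": (8, 0),
            "SCC": (0, 30), "BCC": (4, 30), "melanoma": (8, 30),
        }
        raman_centres = {"SCC": 0.0, "BCC": 25.0, "melanoma": 50.0,
                         "HaCaT": 10.0, "melanocyte": 12.0}
        Xo, Xr, y = [], [], []
        for c in classes:
            Xo.append(rng.normal(oct_centres[c], 0.5, size=(n, 2)))
            Xr.append(rng.normal(raman_centres[c], 0.5, size=(n, 3)))
            y += [c] * n
        return (
            pd.DataFrame(np.vstack(Xo)),
            pd.DataFrame(np.vstack(Xr)),
            np.array(y),
        )

    def test_separable_classes_perfect(self):
        Xo, Xr, y = self.separable_modalities()
        out = run_fused_experiment(Xo, Xr, y, n_folds=5, seed=0)
        assert out["accuracy"] == 1.0
        assert out["confusion_matrix"].to_numpy().sum() == len(y)

    def test_permuted_labels_near_chance(self):
        Xo, Xr, y = self.separable_modalities(n=10)
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            yp = rng.permutation(y)
            accs.append(run_fused_experiment(Xo, Xr, yp, n_folds=5, seed=seed)["accuracy"])
        assert np.mean(accs) <= 0.2 + 0.15

    def test_deterministic(self):
        Xo, Xr, y = self.separable_modalities(seed=3)
        a = run_fused_experiment(Xo, Xr, y, n_folds=5, seed=2)
        b = run_fused_experiment(Xo, Xr, y, n_folds=5, seed=2)
        assert a["accuracy"] == b["accuracy"]
        assert (a["predictions"] == b["predictions"]).all()

    def test_misaligned_modalities_rejected(self):
        Xo, Xr, y = self.separable_modalities()
        with pytest.raises(ValueError, match="row-aligned"):
            run_fused_experiment(Xo.iloc[:-1], Xr, y)
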