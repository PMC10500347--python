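"""Ensemble classification protocol for the cell-discrimination tasks.

Three base classifiers with fixed, deliberately simple settings —

* **LDA**: linear discriminant with pooled covariance (pseudo-inverse when
  singular), regularisation knobs delta/gamma both 0;
* **KNN**: k = 1, Euclidean distance, equal weights, *no* standardisation
  (so it is intentionally scale-sensitive);
* **TREE**: CART with Gini impurity, up to n − 1 splits, minimum leaf size 1,
  all variables considered at each split —

wrapped in three ensemble architectures (bagging = bootstrap aggregation,
boosting = adaptive reweighting, subspace = random feature subsets), and
evaluated with stratified 10-fold cross-validation.  The six attempted
pairings are boosting/bagging/subspace + LDA, subspace + KNN and
boosting/bagging + TREE.  Features are ranked by single-feature CV accuracy
to form the "1&2" and "1&2&3" subsets.

LDA is implemented here rather than taken from scikit-learn because boosting
requires sample-weight support, which the library estimator lacks; the
weighted pooled-covariance formulation below reduces to ordinary LDA at
uniform weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import pinvh
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec",
    "EnsembleSpec",
    "TaskSpec",
    "CVResult",
    "WeightedLDA",
    "TASKS",
    "SIX_PAIRINGS",
    "build_estimator",
    "train_predict",
    "cross_validate",
    "rank_features",
    "run_task",
    "run_fused_experiment",
]


@dataclass(frozen=True)
class ClassifierSpec:
    base: str = "LDA"  # LDA | KNN | TREE
    lda_delta: float = 0.0
    lda_gamma: float = 0.0
    knn_k: int = 1
    knn_metric: str = "euclidean"
    knn_weights: str = "uniform"
    knn_standardize: bool = False
    tree_criterion: str = "gini"
    tree_max_splits: int | None = None  # None → n_samples − 1
    tree_min_leaf: int = 1
    tree_vars_per_split: str | int = "all"

    def __post_init__(self) -> None:
        if self.base not in ("LDA", "KNN", "TREE"):
            raise ValueError(f"unknown base classifier {self.base!r}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass(frozen=True)
class EnsembleSpec:
    method: str = "none"  # none | bagging | boosting | subspace
    n_learners: int = 30
    subspace_dim: int | None = None  # None → ceil(p / 2)
    boost_learning_rate: float = 1.0
    bootstrap: bool = True  # bagging only

    def __post_init__(self) -> None:
        if self.method not in ("none", "bagging", "boosting", "subspace"):
            raise ValueError(f"unknown ensemble method {self.method!r}")
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")


@dataclass(frozen=True)
class TaskSpec:
    """A discrimination task: a mapping of cell-class labels onto task labels.
    Classes absent from the grouping are dropped from the task."""

    name: str
    class_grouping: dict[str, str]


#: the four discrimination tasks
TASKS: dict[str, TaskSpec] = {
    "cancer_vs_normal": TaskSpec(
        "cancer_vs_normal",
        {
            "HaCaT": "normal",
            "melanocyte": "normal",
            "SCC": "cancer",
            "BCC": "cancer",
            "melanoma": "cancer",
        },
    ),
    "hacat_vs_melanocyte": TaskSpec(
        "hacat_vs_melanocyte", {"HaCaT": "HaCaT", "melanocyte": "melanocyte"}
    ),
    "melanoma_vs_keratinocyte_cancers": TaskSpec(
        "melanoma_vs_keratinocyte_cancers",
        {"melanoma": "melanoma", "SCC": "keratinocyte_cancer", "BCC": "keratinocyte_cancer"},
    ),
    "bcc_vs_scc": TaskSpec("bcc_vs_scc", {"BCC": "BCC", "SCC": "SCC"}),
}

#: the six attempted (ensemble, base) pairings
SIX_PAIRINGS: tuple[tuple[str, str], ...] = (
    ("boosting", "LDA"),
    ("bagging", "LDA"),
    ("subspace", "LDA"),
    ("subspace", "KNN"),
    ("boosting", "TREE"),
    ("bagging", "TREE"),
)


class WeightedLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant analysis with sample-weight support.

    Weighted class means and a pooled weighted covariance define the linear
    discriminant scores ``x·Σ⁻¹µ_k − µ_kᵀΣ⁻¹µ_k/2 + log π_k``; the inverse
    is a pseudo-inverse so singular pooled covariances (p > n) are handled.
    ``gamma`` shrinks the covariance toward a scaled identity; ``delta``
    zeroes small linear coefficients (both default 0 = plain LDA).
    """

    def __init__(self, gamma: float = 0.0, delta: float = 0.0):
        self.gamma = gamma
        self.delta = delta

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2D")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training set contains a single class")
        n, p = X.shape
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        if w.sum() <= 0:
            w = np.ones(n)
        wsum = w.sum()
        means = np.zeros((self.classes_.size, p))
        priors = np.zeros(self.classes_.size)
        cov = np.zeros((p, p))
        for k in range(self.classes_.size):
            sel = y_idx == k
            wk = w[sel]
            if wk.sum() <= 0:  # class lost all weight: fall back to uniform
                wk = np.ones(sel.sum())
            means[k] = np.average(X[sel], axis=0, weights=wk)
            priors[k] = w[sel].sum() / wsum
            d = X[sel] - means[k]
            cov += (d * wk[:, None]).T @ d
        cov /= wsum
        if self.gamma > 0:
            cov = (1 - self.gamma) * cov + self.gamma * np.trace(cov) / p * np.eye(p)
        inv = pinvh(cov)
        self.coef_ = means @ inv  # (K, p)
        if self.delta > 0:
            self.coef_ = np.where(np.abs(self.coef_) > self.delta, self.coef_, 0.0)
        self.intercept_ = -0.5 * np.einsum("kp,kp->k", self.coef_, means) + np.log(
            np.clip(priors, 1e-300, None)
        )
        return self

    def decision_scores(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_.T + self.intercept_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]

    def predict_proba(self, X):
        s = self.decision_scores(X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)


def _base_estimator(spec: ClassifierSpec, n_train: int, seed: int):
    if spec.base == "LDA":
        return WeightedLDA(gamma=spec.lda_gamma, delta=spec.lda_delta)
    if spec.base == "KNN":
        return KNeighborsClassifier(
            n_neighbors=spec.knn_k,
            metric=spec.knn_metric,
            weights="uniform" if spec.knn_weights in ("uniform", "equal") else spec.knn_weights,
            algorithm="brute",  # ties resolve to the lowest sample index
        )
    max_splits = spec.tree_max_splits if spec.tree_max_splits is not None else max(n_train - 1, 1)
    return DecisionTreeClassifier(
        criterion=spec.tree_criterion,
        max_leaf_nodes=max_splits + 1,  # a tree with S splits has S + 1 leaves
        min_samples_leaf=spec.tree_min_leaf,
        max_features=None if spec.tree_vars_per_split == "all" else spec.tree_vars_per_split,
        random_state=seed,
    )


def build_estimator(
    spec: ClassifierSpec, ensemble: EnsembleSpec, n_train: int, n_features: int, seed: int
):
    """Assemble the (possibly ensembled) scikit-learn style estimator."""
    base = _base_estimator(spec, n_train, seed)
    if ensemble.method == "none":
        return base
    if ensemble.method == "bagging":
        if ensemble.n_learners == 1 and not ensemble.bootstrap:
            return base  # degenerate ensemble: exactly the base learner
        return BaggingClassifier(
            estimator=base,
            n_estimators=ensemble.n_learners,
            bootstrap=ensemble.bootstrap,
            max_samples=1.0 if ensemble.bootstrap else n_train,
            random_state=seed,
        )
    if ensemble.method == "subspace":
        dim = ensemble.subspace_dim
        if dim is None:
            dim = int(np.ceil(n_features / 2))
        if dim > n_features:
            raise ValueError(
                f"subspace_dim {dim} exceeds the feature count {n_features}"
            )
        return BaggingClassifier(
            estimator=base,
            n_estimators=ensemble.n_learners,
            bootstrap=False,
            max_samples=n_train,
            max_features=dim,
            bootstrap_features=False,
            random_state=seed,
        )
    # boosting: adaptive reweighting; the base learner must accept sample_weight
    if spec.base == "KNN":
        raise ValueError("boosting requires sample-weight support; KNN has none")
    return AdaBoostClassifier(
        estimator=base,
        n_estimators=ensemble.n_learners,
        learning_rate=ensemble.boost_learning_rate,
        random_state=seed,
    )


def train_predict(
    spec: ClassifierSpec,
    ensemble: EnsembleSpec,
    X_train: np.ndarray,
    y_train: Sequence,
    X_test: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit on the training split and predict labels for the test split."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    if np.isnan(X_train).any() or np.isnan(X_test).any():
        raise ValueError("missing values are not supported")
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class")
    est = build_estimator(spec, ensemble, X_train.shape[0], X_train.shape[1], seed)
    est.fit(X_train, y_train)
    return np.asarray(est.predict(X_test))


@dataclass
class CVResult:
    accuracy: float
    confusion_matrix: pd.DataFrame  # rows = true, cols = predicted
    fold_assignments: np.ndarray
    seed: int
    spec: ClassifierSpec
    ensemble: EnsembleSpec
    n_folds: int


def cross_validate(
    spec: ClassifierSpec,
    ensemble: EnsembleSpec,
    X: np.ndarray,
    y: Sequence,
    n_folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation with pooled accuracy.

    When the smallest class has fewer members than ``n_folds``, the fold
    count degrades to that class size (stratification is kept rather than
    the nominal fold count).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    eff_folds = int(min(n_folds, counts.min()))
    if eff_folds < 2:
        raise ValueError("smallest class has fewer than 2 members")
    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    pred = np.empty(y.shape, dtype=y.dtype)
    folds = np.empty(y.shape[0], dtype=int)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        pred[te] = train_predict(spec, ensemble, X[tr], y[tr], X[te], seed=seed + f)
        folds[te] = f
    acc = float(np.mean(pred == y))
    cm = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred, name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)
    return CVResult(acc, cm, folds, int(seed), spec, ensemble, eff_folds)


def rank_features(
    spec: ClassifierSpec,
    ensemble: EnsembleSpec,
    X: np.ndarray,
    y: Sequence,
    n_folds: int = 10,
    seed: int = 0,
) -> list[int]:
    """Order features by single-feature cross-validated accuracy (descending);
    ties break toward the lower column index."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    sub_ens = ensemble
    if ensemble.method == "subspace":
        sub_ens = replace(ensemble, subspace_dim=1)  # single-column input
    accs = []
    for j in range(X.shape[1]):
        accs.append(
            cross_validate(spec, sub_ens, X[:, [j]], y, n_folds=n_folds, seed=seed).accuracy
        )
    order = sorted(range(len(accs)), key=lambda j: (-accs[j], j))
    return order


def _subset_columns(
    subset: str, feature_names: list[str], ranking: list[int]
) -> list[int]:
    if subset == "ALL":
        return list(range(len(feature_names)))
    if subset == "1&2":
        return ranking[:2]
    if subset == "1&2&3":
        return ranking[:3]
    if subset in feature_names:
        return [feature_names.index(subset)]
    raise ValueError(f"unknown feature subset {subset!r}")


def run_task(
    X: pd.DataFrame,
    class_labels: Sequence[str],
    task: TaskSpec,
    pairings: Sequence[tuple[str, str]] = SIX_PAIRINGS,
    feature_subsets: Sequence[str] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    ensemble_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Evaluate every (pairing × feature subset) cell for one task.

    ``X`` is a samples × features frame (five-feature table or spectral
    matrix); ``class_labels`` are the five-class cell labels, mapped through
    the task grouping (samples outside the task are dropped).  Returns a
    long-format grid with one row per evaluated cell plus the per-classifier
    best, analogous to the published accuracy charts.
    """
    class_labels = np.asarray(list(class_labels))
    mapped = np.array([task.class_grouping.get(c, "") for c in class_labels])
    keep = mapped != ""
    if not keep.any():
        raise ValueError(f"task {task.name!r} leaves no samples after grouping")
    Xarr = np.asarray(X, dtype=float)
    Xk = Xarr[keep]
    yk = mapped[keep]
    feature_names = (
        [str(c) for c in X.columns]
        if isinstance(X, pd.DataFrame)
        else [str(j) for j in range(Xarr.shape[1])]
    )
    if feature_subsets is None:
        feature_subsets = (*feature_names, "1&2", "1&2&3", "ALL") if len(
            feature_names
        ) <= 8 else ("ALL",)
    ekw = ensemble_kwargs or {}
    records = []
    for ens_name, base_name in pairings:
        spec = ClassifierSpec(base=base_name)
        ens = EnsembleSpec(method=ens_name, **ekw)
        ranking = rank_features(spec, ens, Xk, yk, n_folds=n_folds, seed=seed)
        for subset in feature_subsets:
            cols = _subset_columns(subset, feature_names, ranking)
            res = cross_validate(spec, ens, Xk[:, cols], yk, n_folds=n_folds, seed=seed)
            records.append(
                {
                    "task": task.name,
                    "classifier": base_name,
                    "ensemble": ens_name,
                    "feature_subset": subset,
                    "accuracy": res.accuracy,
                    "n_samples": int(yk.size),
                    "seed": int(seed),
                }
            )
    return pd.DataFrame.from_records(records)


def best_per_classifier(grid: pd.DataFrame) -> pd.DataFrame:
    """Per base classifier, the best accuracy over ensembles and subsets."""
    idx = grid.groupby("classifier")["accuracy"].idxmax()
    return grid.loc[idx].reset_index(drop=True)


def run_fused_experiment(
    oct_X: pd.DataFrame,
    raman_X: pd.DataFrame,
    class_labels: Sequence[str],
    n_folds: int = 10,
    seed: int = 0,
    n_learners: int = 30,
) -> dict:
    """Two-stage OCT + Raman fusion for five-class discrimination.

    Per cross-validation fold: stage 1 decides cancer vs normal on the OCT
    features (bagged trees); stage 2a splits predicted normals into HaCaT vs
    melanocyte on OCT features (bagged trees); stage 2b splits predicted
    cancers into melanoma vs BCC vs SCC on the Raman matrix (1-NN).  Both
    modalities must be present, row-aligned, for every sample.
    """
    y = np.asarray(list(class_labels))
    if len(oct_X) != len(raman_X) or len(oct_X) != y.size:
        raise ValueError("OCT features, Raman matrix and labels must be row-aligned")
    Xo = np.asarray(oct_X, dtype=float)
    Xr = np.asarray(raman_X, dtype=float)
    normal = {"HaCaT", "melanocyte"}
    y_stage1 = np.where(np.isin(y, list(normal)), "normal", "cancer")
    tree = ClassifierSpec(base="TREE")
    knn = ClassifierSpec(base="KNN")
    bag = EnsembleSpec(method="bagging", n_learners=n_learners)
    none = EnsembleSpec(method="none")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty(y.shape, dtype=object)
    folds = np.empty(y.size, dtype=int)
    for f, (tr, te) in enumerate(skf.split(Xo, y)):
        folds[te] = f
        s1 = train_predict(tree, bag, Xo[tr], y_stage1[tr], Xo[te], seed=seed + f)
        tr_norm = tr[y_stage1[tr] == "normal"]
        tr_canc = tr[y_stage1[tr] == "cancer"]
        te_norm = te[s1 == "normal"]
        te_canc = te[s1 == "cancer"]
        if te_norm.size:
            pred[te_norm] = train_predict(
                tree, bag, Xo[tr_norm], y[tr_norm], Xo[te_norm], seed=seed + f
            )
        if te_canc.size:
            pred[te_canc] = train_predict(
                knn, none, Xr[tr_canc], y[tr_canc], Xr[te_canc], seed=seed + f
            )
    pred = pred.astype(str)
    acc = float(np.mean(pred == y))
    classes = np.unique(y)
    cm = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred, name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)
    return {
        "accuracy": acc,
        "predictions": pred,
        "confusion_matrix": cm,
        "fold_assignments": folds,
        "seed": int(seed),
    }
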