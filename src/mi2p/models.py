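"""Marker-gene selection and phenotype classifiers.

The feature space is the gene × sample abundance table (RPKM values); the
positive class is ``"case"``.  Selection is a two-stage screen — a
Wilcoxon rank-sum q-value pre-filter followed by tree-importance or
L1-based selection — and classification offers the model families RF, SVM,
DT, KN and an RBM-feature neural network, mirroring common practice for
microbiome phenotype prediction.  Everything is exposed twice: as
scikit-learn estimators (transformers / classifier, composable with
pipelines and model selection) and as thin table-level functions.

Estimators follow the scikit-learn convention of X with shape
(n_samples, n_features); the table-level functions take gene × sample
DataFrames and transpose internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import BernoulliRBM
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, MinMaxScaler, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .differential import bh_qvalues, wrs_test_rows

FAMILIES = ("RF", "SVM", "DT", "KN", "NN")

#: FPR grid shared by every ROC curve so fold curves can be averaged vertically
ROC_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class ModelSpec:
    """Classifier family and its family-specific settings."""

    family: str = "RF"
    n_trees: int = 100  # RF
    n_neighbors: int = 20  # KN
    n_hidden: int = 3200  # NN (Bernoulli RBM hidden units)
    seed: int = 0

    def __post_init__(self) -> None:
        self.family = self.family.upper()
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n_trees": self.n_trees,
            "n_neighbors": self.n_neighbors,
            "n_hidden": self.n_hidden,
            "seed": self.seed,
        }


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    return classes


def _case_class(classes: np.ndarray):
    """The positive class: 'case' when present, else the last class."""
    return "case" if "case" in classes else classes[-1]


class WilcoxonSelector(SelectorMixin, BaseEstimator):
    """Keep features whose two-group WRS q-value is at most ``q_cutoff``.

    Per-feature Wilcoxon rank-sum p-values are adjusted across all features
    with Benjamini–Hochberg; fitted attributes expose the statistics
    (``pvalues_``, ``qvalues_``, ``directions_`` with +1 = up in case).
    """

    def __init__(self, q_cutoff: float = 0.05):
        self.q_cutoff = q_cutoff

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes = _check_two_classes(y)
        case = _case_class(classes)
        idx1 = np.flatnonzero(y == case)
        idx2 = np.flatnonzero(y != case)
        if idx1.size < 2 or idx2.size < 2:
            raise ValueError("need at least 2 samples per group")
        Xo = np.concatenate([X[idx1], X[idx2]]).T  # features × samples
        u, p, sign = wrs_test_rows(Xo, idx1.size)
        self.n_features_in_ = X.shape[1]
        self.u_statistics_ = u
        self.pvalues_ = p
        self.qvalues_ = bh_qvalues(p)
        self.directions_ = sign
        self.support_ = self.qvalues_ <= self.q_cutoff
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class TreeImportanceSelector(SelectorMixin, BaseEstimator):
    """Tree-ensemble importance selection with a shadow-feature threshold.

    An ensemble of 100 randomized decision trees is fit on the features
    together with one column-permuted ("shadow") copy of each; a feature is
    kept when its impurity importance strictly exceeds the largest shadow
    importance, i.e. when it is more informative than the best feature
    known to carry no signal.  This keeps an informative but homogeneous
    feature set intact (where a relative threshold such as the mean
    importance, which always equals 1/n, would arbitrarily discard half)
    while still rejecting noise features.  ``threshold="mean"`` switches to
    the plain above-average-importance convention.

    If no feature passes the threshold the selector falls back to keeping
    all features, so a degenerate input (e.g. identical columns) never
    yields an empty model.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        threshold: str = "shadow",
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        _check_two_classes(y)
        if self.threshold not in ("shadow", "mean"):
            raise ValueError("threshold must be 'shadow' or 'mean'")
        n = X.shape[1]
        forest = ExtraTreesClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        )
        if self.threshold == "shadow":
            rng = np.random.default_rng(self.random_state)
            shadow = np.column_stack([rng.permutation(X[:, j]) for j in range(n)])
            forest.fit(np.hstack([X, shadow]), y)
            imp = forest.feature_importances_[:n]
            cut = float(forest.feature_importances_[n:].max())
        else:
            forest.fit(X, y)
            imp = forest.feature_importances_
            cut = float(imp.mean())
        self.n_features_in_ = n
        self.importances_ = imp
        self.threshold_ = cut
        mask = imp > cut
        if not mask.any():
            mask = np.ones_like(mask, dtype=bool)
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class L1Selector(SelectorMixin, BaseEstimator):
    """Keep features with non-zero coefficient in an L1 logistic fit.

    Features are standardized before fitting; ``penalty_strength`` is the
    inverse of the usual C (larger = sparser).
    """

    def __init__(self, penalty_strength: float = 1.0):
        self.penalty_strength = penalty_strength

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        _check_two_classes(y)
        if self.penalty_strength <= 0:
            raise ValueError("penalty_strength must be positive")
        Z = StandardScaler().fit_transform(X)
        model = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=1.0 / self.penalty_strength
        )
        model.fit(Z, y)
        self.n_features_in_ = X.shape[1]
        self.coefficients_ = model.coef_.ravel()
        self.support_ = self.coefficients_ != 0.0
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def _build_family_pipeline(spec: ModelSpec):
    """Underlying sklearn estimator for one model family.

    Distance/margin families (SVM, KN, NN) see log(1+x)-transformed,
    rescaled abundances; the tree families consume raw values.
    """
    log = FunctionTransformer(np.log1p, validate=False)
    rs = spec.seed
    if spec.family == "RF":
        return RandomForestClassifier(n_estimators=spec.n_trees, random_state=rs)
    if spec.family == "DT":
        return DecisionTreeClassifier(random_state=rs)
    if spec.family == "SVM":
        return Pipeline(
            [("log", log), ("scale", StandardScaler()), ("svc", SVC(probability=True, random_state=rs))]
        )
    if spec.family == "KN":
        return Pipeline(
            [("log", log), ("scale", StandardScaler()), ("kn", KNeighborsClassifier(n_neighbors=spec.n_neighbors))]
        )
    if spec.family == "NN":
        return Pipeline(
            [
                ("log", log),
                ("scale", MinMaxScaler()),
                ("rbm", BernoulliRBM(n_components=spec.n_hidden, random_state=rs)),
                ("head", LogisticRegression(max_iter=1000)),
            ]
        )
    raise ValueError(spec.family)


class PhenotypeClassifier(ClassifierMixin, BaseEstimator):
    """Phenotype predictor over marker-gene abundances (sklearn estimator).

    Wraps one of the supported model families behind a uniform interface
    with a calibrated-in-[0,1] score for the case class
    (:meth:`case_probability`).  Accepts DataFrames (feature names are
    recorded and checked downstream) or arrays.
    """

    def __init__(
        self,
        family: str = "RF",
        n_trees: int = 100,
        n_neighbors: int = 20,
        n_hidden: int = 3200,
        random_state: int = 0,
    ):
        self.family = family
        self.n_trees = n_trees
        self.n_neighbors = n_neighbors
        self.n_hidden = n_hidden
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            family=self.family,
            n_trees=self.n_trees,
            n_neighbors=self.n_neighbors,
            n_hidden=self.n_hidden,
            seed=self.random_state,
        )

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=np.float64)
        else:
            X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        self.classes_ = _check_two_classes(y)
        counts = [int((y == c).sum()) for c in self.classes_]
        if min(counts) < 2:
            raise ValueError("need at least 2 samples per class")
        self.n_features_in_ = X.shape[1]
        self.model_ = _build_family_pipeline(self._spec())
        self.model_.fit(X, y)
        return self

    def _prepare(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.predict_proba(self._prepare(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def case_probability(self, X) -> np.ndarray:
        """Probability of the case class for each sample."""
        case = _case_class(self.classes_)
        col = int(np.flatnonzero(self.classes_ == case)[0])
        return self.predict_proba(X)[:, col]


@dataclass
class CVResult:
    """Cross-validation outcome with fold ROC curves on a shared FPR grid."""

    scheme: str  # "loocv" | "kfold5"
    per_fold: list[tuple[np.ndarray, np.ndarray, float]]  # (fpr grid, tpr, auc)
    mean_auc: float
    averaged_roc: tuple[np.ndarray, np.ndarray]

    @property
    def fold_aucs(self) -> list[float]:
        return [auc for _, _, auc in self.per_fold]


# ---------------------------------------------------------------------------
# table-level functions (gene × sample DataFrames)


def _labels_vector(table: pd.DataFrame, labels: Mapping[str, str] | Sequence[str]) -> np.ndarray:
    if isinstance(labels, Mapping):
        missing = [s for s in table.columns if s not in labels]
        if missing:
            raise ValueError(f"samples without labels: {missing}")
        return np.asarray([labels[s] for s in table.columns])
    y = np.asarray(labels)
    if y.shape[0] != table.shape[1]:
        raise ValueError("label vector length does not match sample count")
    return y


def qvalue_prefilter(
    table: pd.DataFrame, labels: Mapping[str, str] | Sequence[str], q_cutoff: float = 0.05
) -> pd.DataFrame:
    """Keep genes with two-group WRS q-value <= cutoff (original order)."""
    y = _labels_vector(table, labels)
    sel = WilcoxonSelector(q_cutoff=q_cutoff).fit(table.T.to_numpy(dtype=np.float64), y)
    return table.loc[sel.get_support()]


def tree_select(
    table: pd.DataFrame, labels: Mapping[str, str] | Sequence[str], seed: int = 0
) -> list[str]:
    """Gene ids whose tree-ensemble importance exceeds the mean importance."""
    if table.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    y = _labels_vector(table, labels)
    sel = TreeImportanceSelector(random_state=seed).fit(table.T.to_numpy(dtype=np.float64), y)
    return list(table.index[sel.get_support()])


def l1_select(
    table: pd.DataFrame,
    labels: Mapping[str, str] | Sequence[str],
    penalty_strength: float = 1.0,
) -> list[str]:
    """Gene ids with non-zero coefficient in an L1-penalized logistic fit."""
    if table.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    y = _labels_vector(table, labels)
    sel = L1Selector(penalty_strength=penalty_strength).fit(table.T.to_numpy(dtype=np.float64), y)
    return list(table.index[sel.get_support()])


def train_predictor(
    table: pd.DataFrame, labels: Mapping[str, str] | Sequence[str], spec: ModelSpec
) -> PhenotypeClassifier:
    """Fit a phenotype classifier on a gene × sample abundance table."""
    y = _labels_vector(table, labels)
    clf = PhenotypeClassifier(
        family=spec.family,
        n_trees=spec.n_trees,
        n_neighbors=spec.n_neighbors,
        n_hidden=spec.n_hidden,
        random_state=spec.seed,
    )
    clf.fit(table.T, y)
    return clf


def average_roc(
    per_fold_curves: Sequence[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical ROC averaging: mean TPR at each grid FPR."""
    if not per_fold_curves:
        raise ValueError("need at least one curve")
    grid = np.asarray(per_fold_curves[0][0], dtype=np.float64)
    tprs = []
    for fpr, tpr in per_fold_curves:
        if not np.array_equal(np.asarray(fpr), grid):
            raise ValueError("all curves must share one FPR grid")
        tprs.append(np.asarray(tpr, dtype=np.float64))
    return grid, np.mean(tprs, axis=0)


def _roc_on_grid(y_true: np.ndarray, scores: np.ndarray, case) -> tuple[np.ndarray, float]:
    """Interpolated TPR on ROC_GRID plus the AUC of the raw curve."""
    y_bin = (y_true == case).astype(int)
    if np.ptp(scores) == 0:  # constant scores: chance-level diagonal
        return ROC_GRID.copy(), 0.5
    fpr, tpr, _ = roc_curve(y_bin, scores)
    auc = float(roc_auc_score(y_bin, scores))
    grid_tpr = np.interp(ROC_GRID, fpr, tpr)
    grid_tpr[0], grid_tpr[-1] = 0.0, 1.0
    return grid_tpr, auc


def _fit_select_score(
    table: pd.DataFrame,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    spec: ModelSpec,
    q_cutoff: float,
    selection: str | None,
) -> np.ndarray:
    """Select features on the training fold only, fit, score the test fold."""
    sub_train = table.iloc[:, train_idx]
    kept = qvalue_prefilter(sub_train, y[train_idx], q_cutoff)
    if selection == "tree" and kept.shape[0] >= 2:
        genes = tree_select(kept, y[train_idx], seed=spec.seed)
    elif selection == "l1" and kept.shape[0] >= 2:
        genes = l1_select(kept, y[train_idx])
    else:
        genes = list(kept.index)
    if not genes:
        # nothing survives selection in this fold: chance-level scores
        return np.full(test_idx.size, 0.5)
    clf = train_predictor(table.loc[genes].iloc[:, train_idx], y[train_idx], spec)
    return clf.case_probability(table.loc[genes].iloc[:, test_idx].T)


def cross_validate(
    table: pd.DataFrame,
    labels: Mapping[str, str] | Sequence[str],
    spec: ModelSpec | None = None,
    scheme: str = "kfold5",
    q_cutoff: float = 0.05,
    selection: str | None = "tree",
) -> CVResult:
    """Cross-validated evaluation with in-fold feature selection.

    Feature selection (q-value pre-filter, then the chosen selector) is
    refit inside every training fold so held-out samples never influence
    which genes are used.  ``kfold5`` uses stratified folds and reports
    per-fold ROC curves on a common 101-point FPR grid plus their vertical
    average; ``loocv`` pools the held-out case-probabilities into a single
    ROC, since a per-fold ROC is undefined for single-sample folds.
    """
    spec = spec or ModelSpec()
    y = _labels_vector(table, labels)
    classes = _check_two_classes(y)
    case = _case_class(classes)

    if scheme == "kfold5":
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=spec.seed)
        per_fold = []
        for train_idx, test_idx in splitter.split(np.zeros(y.size), y):
            scores = _fit_select_score(table, y, train_idx, test_idx, spec, q_cutoff, selection)
            tpr, auc = _roc_on_grid(y[test_idx], scores, case)
            per_fold.append((ROC_GRID.copy(), tpr, auc))
        mean_auc = float(np.mean([a for _, _, a in per_fold]))
        avg = average_roc([(g, t) for g, t, _ in per_fold])
        return CVResult("kfold5", per_fold, mean_auc, avg)

    if scheme == "loocv":
        pooled = np.empty(y.size)
        for train_idx, test_idx in LeaveOneOut().split(np.zeros(y.size)):
            pooled[test_idx] = _fit_select_score(
                table, y, train_idx, test_idx, spec, q_cutoff, selection
            )
        tpr, auc = _roc_on_grid(y, pooled, case)
        curve = (ROC_GRID.copy(), tpr, auc)
        return CVResult("loocv", [curve], auc, (ROC_GRID.copy(), tpr))

    raise ValueError(f"unknown scheme {scheme!r}; use 'kfold5' or 'loocv'")
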