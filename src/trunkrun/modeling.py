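"""Nested cross-validated injury-risk classification.

The classification pipeline, run inside every fold: one-hot encoding of
categorical features + standardization of numeric features (training
statistics only), PCA, ANOVA-F selection of principal components, and a
class-weighted classifier (L1 logistic regression, random forest, or SVM
with cross-fitted Platt-scaled probabilities). Hyperparameters — the number
of PCA components, the number of selected components and the classifier's
own knobs — are tuned by grid search on a 3-fold inner CV maximizing AUC;
the winning configuration is refit on the full outer-fold training split
and scored (AUC, Brier) on the held-aside test split.

Class weights are inversely proportional to the training-split class
frequencies, compensating the roughly 1:3 injured/uninjured imbalance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.compose import ColumnTransformer
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import brier_score_loss, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import FeatureTable

__all__ = [
    "RiskModel",
    "FoldResult",
    "ModelResult",
    "make_folds",
    "default_grid",
    "grid_search",
    "nested_cv_evaluate",
    "auc",
    "brier",
    "pooled_roc",
]

ALGORITHMS = ("LR", "RFT", "SVM")


class RiskModel(BaseEstimator, ClassifierMixin):
    """Encode -> standardize -> PCA -> ANOVA-F select -> class-weighted classifier.

    Parameters
    ----------
    algorithm : {'LR', 'RFT', 'SVM'}
        L1-regularized logistic regression, random forest, or support vector
        machine (probabilities via Platt scaling cross-fitted 3-fold on the
        training data).
    n_pca : int
        Number of principal components fitted.
    k_select : int
        Number of components kept, by largest ANOVA F-statistic against the
        label; must not exceed ``n_pca``.
    C : float
        Inverse regularization strength (LR and SVM).
    solver : {'liblinear', 'saga'}
        LR optimizer (coordinate descent vs. stochastic average gradient).
    kernel : {'poly', 'rbf', 'sigmoid'}, degree : int
        SVM kernel options.
    max_depth, min_samples_split, criterion, min_impurity_decrease, n_trees
        Random-forest options.
    random_state : int or None
        Seeds PCA's randomized fallback, the forest and saga.

    Attributes
    ----------
    pipeline_ : sklearn Pipeline, the fitted transform + classifier.
    classes_ : label classes.
    feature_names_in_ : input column names (DataFrame input).
    """

    def __init__(
        self,
        algorithm: str = "LR",
        n_pca: int = 10,
        k_select: int = 2,
        C: float = 1.0,
        solver: str = "liblinear",
        kernel: str = "rbf",
        degree: int = 3,
        n_trees: int = 100,
        max_depth: int = 3,
        min_samples_split: int = 3,
        criterion: str = "gini",
        min_impurity_decrease: float = 0.0,
        random_state: Optional[int] = None,
    ):
        self.algorithm = algorithm
        self.n_pca = n_pca
        self.k_select = k_select
        self.C = C
        self.solver = solver
        self.kernel = kernel
        self.degree = degree
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.criterion = criterion
        self.min_impurity_decrease = min_impurity_decrease
        self.random_state = random_state

    # -- construction --------------------------------------------------------

    def _make_classifier(self):
        if self.algorithm == "LR":
            return LogisticRegression(
                l1_ratio=1.0,  # lasso penalty
                C=self.C,
                solver=self.solver,
                class_weight="balanced",
                max_iter=5000,
                random_state=self.random_state,
            )
        if self.algorithm == "RFT":
            return RandomForestClassifier(
                n_estimators=self.n_trees,
                max_depth=self.max_depth,
                min_samples_split=self.min_samples_split,
                criterion=self.criterion,
                min_impurity_decrease=self.min_impurity_decrease,
                class_weight="balanced",
                random_state=self.random_state,
            )
        if self.algorithm == "SVM":
            svc = SVC(
                kernel=self.kernel,
                degree=self.degree,
                C=self.C,
                class_weight="balanced",
                random_state=self.random_state,
            )
            return CalibratedClassifierCV(svc, method="sigmoid", cv=3)
        raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")

    @staticmethod
    def _split_columns(X: pd.DataFrame) -> tuple[list, list]:
        cat = [c for c in X.columns if X[c].dtype == object or str(X[c].dtype) == "category"]
        num = [c for c in X.columns if c not in cat]
        return num, cat

    def fit(self, X: Union[pd.DataFrame, np.ndarray], y) -> "RiskModel":
        X = pd.DataFrame(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training split contains a single class")
        if self.k_select > self.n_pca:
            raise ValueError(f"k_select ({self.k_select}) must be <= n_pca ({self.n_pca})")
        if self.n_pca > len(X):
            raise ValueError(f"n_pca ({self.n_pca}) exceeds the number of training subjects ({len(X)})")
        num, cat = self._split_columns(X)
        if X[num].isna().any().any():
            bad = X[num].columns[X[num].isna().any()].tolist()
            raise ValueError(
                f"missing values in feature(s) {bad}; subjects with missing features "
                "should have been excluded (exclusion criterion 3)"
            )
        encode = ColumnTransformer(
            [
                ("num", StandardScaler(), num),
                ("cat", OneHotEncoder(handle_unknown="ignore", sparse_output=False), cat),
            ],
            verbose_feature_names_out=False,
        )
        self.pipeline_ = Pipeline(
            [
                ("encode", encode),
                ("pca", PCA(n_components=self.n_pca, random_state=self.random_state)),
                ("select", SelectKBest(f_classif, k=self.k_select)),
                ("clf", self._make_classifier()),
            ]
        )
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.named_steps["clf"].classes_
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform_components(self, X) -> np.ndarray:
        """Selected principal-component scores for ``X`` (post encode/PCA/select)."""
        check_is_fitted(self, "pipeline_")
        return self.pipeline_[:-1].transform(pd.DataFrame(X))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(pd.DataFrame(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(pd.DataFrame(X))


# --------------------------------------------------------------------------
# metrics


def auc(labels, scores) -> float:
    """Area under the ROC curve (probability a positive outscores a negative)."""
    return float(roc_auc_score(np.asarray(labels).astype(int), scores))


def brier(labels, probabilities) -> float:
    """Mean squared difference between predicted probability and 0/1 outcome."""
    return float(brier_score_loss(np.asarray(labels).astype(int), probabilities))


def pooled_roc(labels, scores) -> pd.DataFrame:
    """ROC points (fpr, tpr, threshold) on pooled outer-fold test predictions."""
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# --------------------------------------------------------------------------
# folds and grids


def make_folds(labels, k: int, seed: int) -> np.ndarray:
    """Label-stratified fold assignment (0..k-1) with a fixed seed."""
    y = np.asarray(labels).astype(int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    out = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        out[test_idx] = f
    return out


N_PCA_OPTIONS = (10, 15, 20, 25, 30)
K_SELECT_OPTIONS = (2, 3, 4, 5, 6)
C_OPTIONS = (0.01, 0.1, 1.0, 10.0)


def default_grid(algorithm: str, cohort: str = "all", *, compact: bool = False) -> list[dict]:
    """The default hyperparameter grid for one algorithm and cohort.

    The female cohort omits 30 PCA components (it is too small for them).
    ``compact=True`` gives a reduced grid for quick runs and permutation
    baselines.
    """
    n_pca = [n for n in N_PCA_OPTIONS if not (cohort == "female" and n == 30)]
    k_sel = list(K_SELECT_OPTIONS)
    cs = list(C_OPTIONS)
    if compact:
        n_pca = [n for n in n_pca if n in (10, 20)]
        k_sel = [2, 4, 6]
        cs = [0.1, 1.0]
    base = [{"n_pca": n, "k_select": k} for n, k in itertools.product(n_pca, k_sel)]
    configs: list[dict] = []
    if algorithm == "LR":
        solvers = ["liblinear"] if compact else ["liblinear", "saga"]
        for b, solver, C in itertools.product(base, solvers, cs):
            configs.append({**b, "algorithm": "LR", "solver": solver, "C": C})
    elif algorithm == "SVM":
        kernels = [("rbf", 3), ("sigmoid", 3)] + [("poly", d) for d in (1, 2, 3)]
        if compact:
            kernels = [("rbf", 3), ("poly", 2)]
        for b, (kernel, degree), C in itertools.product(base, kernels, cs):
            configs.append({**b, "algorithm": "SVM", "kernel": kernel, "degree": degree, "C": C})
    elif algorithm == "RFT":
        mids = [0.0] if compact else [0.0, 0.01]
        for b, depth, mss, crit, mid in itertools.product(base, (3, 4), (3, 4), ("gini", "entropy"), mids):
            configs.append(
                {
                    **b,
                    "algorithm": "RFT",
                    "max_depth": depth,
                    "min_samples_split": mss,
                    "criterion": crit,
                    "min_impurity_decrease": mid,
                }
            )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    return configs


def _config_sort_key(cfg: dict):
    extras = tuple(sorted((k, repr(v)) for k, v in cfg.items() if k not in ("n_pca", "k_select")))
    return (cfg["n_pca"], cfg["k_select"], extras)


def grid_search(
    X: pd.DataFrame,
    y,
    configs: Sequence[dict],
    seed: int,
    *,
    inner_k: int = 3,
) -> tuple[dict, pd.DataFrame]:
    """Pick the configuration with the best mean inner-CV AUC.

    Every candidate repeats the full pipeline (encode, standardize, PCA,
    selection, classifier) inside each inner fold, so no statistic leaks
    from an inner validation split. Ties break deterministically toward
    smaller ``n_pca``, then smaller ``k_select``, then lexicographically
    over the remaining parameters. Configurations infeasible for the inner
    training size are skipped.

    Returns the winning config and a table of per-config mean AUCs.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    folds = make_folds(y, inner_k, seed)
    ordered = sorted(configs, key=_config_sort_key)
    results = []
    best_cfg, best_auc = None, -math.inf
    for cfg in ordered:
        aucs = []
        feasible = True
        for f in range(inner_k):
            tr, te = folds != f, folds == f
            if cfg["n_pca"] > int(tr.sum()):
                feasible = False
                break
            model = RiskModel(**cfg, random_state=seed)
            try:
                model.fit(X[tr], y[tr])
            except ValueError:
                feasible = False
                break
            p = model.predict_proba(X[te])[:, list(model.classes_).index(1)]
            aucs.append(auc(y[te], p))
        if not feasible or not aucs:
            continue
        mean_auc = float(np.mean(aucs))
        results.append({**cfg, "mean_inner_auc": mean_auc})
        if mean_auc > best_auc:
            best_auc, best_cfg = mean_auc, cfg
    if best_cfg is None:
        raise ValueError("no feasible configuration in the grid")
    return dict(best_cfg), pd.DataFrame(results)


# --------------------------------------------------------------------------
# nested CV


@dataclass
class FoldResult:
    """One outer fold: chosen configuration and held-out test performance."""

    fold: int
    config: dict
    auc: float
    brier: float
    predictions: pd.DataFrame  # subject_id, y_true, probability


@dataclass
class ModelResult:
    """Nested-CV outcome: per-fold results and the pooled summary."""

    cohort: str
    feature_subset: str
    algorithm: str
    folds: list = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))

    @property
    def sd_auc(self) -> float:
        return float(np.std([f.auc for f in self.folds], ddof=1))

    @property
    def mean_brier(self) -> float:
        return float(np.mean([f.brier for f in self.folds]))

    @property
    def sd_brier(self) -> float:
        return float(np.std([f.brier for f in self.folds], ddof=1))

    @property
    def pooled_predictions(self) -> pd.DataFrame:
        return pd.concat(
            [f.predictions.assign(fold=f.fold) for f in self.folds], ignore_index=True
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cohort": self.cohort,
                    "feature_subset": self.feature_subset,
                    "algorithm": self.algorithm,
                    "mean_auc": self.mean_auc,
                    "sd_auc": self.sd_auc,
                    "mean_brier": self.mean_brier,
                    "sd_brier": self.sd_brier,
                }
            ]
        )


def _resolve_table(
    table: Union[FeatureTable, pd.DataFrame], feature_subset: str
) -> pd.DataFrame:
    if isinstance(table, FeatureTable):
        return table.subset(feature_subset).values
    if feature_subset != "All":
        raise ValueError("feature subsets require a FeatureTable with category tags")
    return pd.DataFrame(table)


def nested_cv_evaluate(
    table: Union[FeatureTable, pd.DataFrame],
    labels,
    *,
    cohort: str = "all",
    feature_subset: str = "All",
    algorithm: str = "LR",
    seed: int = 0,
    outer_k: Optional[int] = None,
    grid: Optional[Sequence[dict]] = None,
    genders: Optional[Sequence[str]] = None,
    return_models: bool = False,
) -> ModelResult:
    """Nested cross-validated evaluation of one cohort/subset/algorithm cell.

    ``cohort`` is ``all``, ``male`` or ``female``; gender-specific cohorts are
    selected through ``genders`` (per-subject gender, aligned with the table)
    and evaluated with 6 outer folds for females (whose grid omits 30 PCA
    components) and 5 otherwise. Per outer fold, a grid search with 3-fold
    inner CV picks the configuration, which is refit on the full training
    split and scored on the held-aside test split.
    """
    X = _resolve_table(table, feature_subset)
    y = pd.Series(np.asarray(labels).astype(int), index=X.index)

    if cohort not in ("all", "male", "female"):
        raise ValueError(f"unknown cohort {cohort!r}")
    if cohort != "all":
        if genders is None:
            raise ValueError("gender-specific cohorts need per-subject genders")
        mask = pd.Series(list(genders), index=X.index) == cohort
        X, y = X[mask], y[mask]
        # gender is constant within the cohort; drop it if present
        X = X.drop(columns=[c for c in ("gender",) if c in X.columns])
    if outer_k is None:
        outer_k = 6 if cohort == "female" else 5
    if grid is None:
        grid = default_grid(algorithm, cohort)

    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < outer_k:
        raise ValueError(
            f"cohort too small for {outer_k} stratified folds with both classes (counts: {counts.to_dict()})"
        )

    folds = make_folds(y.to_numpy(), outer_k, seed)
    result = ModelResult(cohort=cohort, feature_subset=feature_subset, algorithm=algorithm)
    models = []
    for f in range(outer_k):
        tr, te = folds != f, folds == f
        best_cfg, _ = grid_search(X[tr], y[tr].to_numpy(), grid, seed)
        model = RiskModel(**best_cfg, random_state=seed).fit(X[tr], y[tr].to_numpy())
        p = model.predict_proba(X[te])[:, list(model.classes_).index(1)]
        result.folds.append(
            FoldResult(
                fold=f,
                config=best_cfg,
                auc=auc(y[te].to_numpy(), p),
                brier=brier(y[te].to_numpy(), p),
                predictions=pd.DataFrame(
                    {"subject_id": X.index[te], "y_true": y[te].to_numpy(), "probability": p}
                ),
            )
        )
        models.append(model)
    if return_models:
        result.models = models  # type: ignore[attr-defined]
    return result
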