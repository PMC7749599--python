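"""PCA-reduced, cross-validated classification of VOI transition features.

Protocol: stratified outer folds (default 15); within each training
fold, median imputation, standardization, PCA and hyperparameter grid
search (inner stratified CV) are fitted on training data only, then the
held-out fold is scored.  Reported ACC/SEN/SPE are means over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from cpcmorph.voi import VoiFeatureTable

#: Elements tied to GM/CSF exchange, the default classification inputs.
ATROPHY_ELEMENTS = ("F_gg", "F_cc", "F_gc", "F_cg")

MODELS = ("svm_linear", "svm_rbf", "rf", "gbc")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm_linear": {"model__C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "svm_rbf": {
        "model__C": [0.01, 0.1, 1.0, 10.0, 100.0],
        "model__gamma": list(np.logspace(-4, 0, 5)),
    },
    "rf": {
        "model__n_estimators": [100, 300, 500],
        "model__class_weight": ["balanced", None],
    },
    "gbc": {"model__n_estimators": [100, 300, 500], "model__max_depth": [2, 3, 5]},
}

DEFAULT_PCA_COMPONENTS = (2, 5, 10, 20)


@dataclass(frozen=True)
class ClassifierSpec:
    model: str = "svm_linear"
    grid: dict[str, list] | None = None
    pca_components: tuple[int, ...] = DEFAULT_PCA_COMPONENTS
    n_folds: int = 15
    inner_folds: int = 5
    nested: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")

    def param_grid(self) -> dict[str, list]:
        grid = dict(self.grid) if self.grid is not None else dict(DEFAULT_GRIDS[self.model])
        return grid


@dataclass
class ClassificationReport:
    model: str
    acc: float
    sen: float
    spe: float
    pos_label: str
    neg_label: str
    elements_used: tuple[str, ...]
    n_folds: int
    seed: int
    fold_assignments: list[list[str]] = field(default_factory=list)
    params_per_fold: list[dict[str, Any]] = field(default_factory=list)
    fold_metrics: list[dict[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": self.model,
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "pos_label": self.pos_label,
            "neg_label": self.neg_label,
            "elements_used": list(self.elements_used),
            "n_folds": self.n_folds,
            "seed": self.seed,
            "fold_assignments": self.fold_assignments,
            "params_per_fold": self.params_per_fold,
            "fold_metrics": self.fold_metrics,
        }


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPE = TN/(TN+FP)."""
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "acc": (tp + tn) / total,
        "sen": tp / (tp + fn) if tp + fn else np.nan,
        "spe": tn / (tn + fp) if tn + fp else np.nan,
    }


def select_features(
    features: VoiFeatureTable, elements: Sequence[str] | str
) -> tuple[pd.DataFrame, pd.Series]:
    """Restrict the wide feature matrix to the requested elements.

    ``elements`` is an iterable of element names or the string
    ``"combined"`` (all four GM/CSF-exchange elements).  Returns the
    subject x feature matrix (NaNs preserved; imputation happens inside
    the CV pipeline) and the per-subject group labels.
    """
    if isinstance(elements, str):
        if elements != "combined":
            elements = (elements,)
        else:
            elements = ATROPHY_ELEMENTS
    elements = tuple(elements)
    if not elements:
        raise ValueError("empty element selection")
    available = set(features.rows["element"].unique())
    unknown = [e for e in elements if e not in available]
    if unknown:
        raise ValueError(f"unknown element(s) {unknown}; available: {sorted(available)}")
    wide = features.to_wide()
    y = wide["group"]
    cols = [c for c in wide.columns if c != "group" and c.split("|", 1)[1] in elements]
    return wide[cols], y


def _make_model(spec: ClassifierSpec):
    if spec.model == "svm_linear":
        return SVC(kernel="linear", random_state=spec.seed)
    if spec.model == "svm_rbf":
        return SVC(kernel="rbf", random_state=spec.seed)
    if spec.model == "rf":
        return RandomForestClassifier(random_state=spec.seed)
    return GradientBoostingClassifier(random_state=spec.seed)


def _make_pipeline(spec: ClassifierSpec) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("pca", PCA(random_state=spec.seed)),
            ("model", _make_model(spec)),
        ]
    )


def _component_candidates(spec: ClassifierSpec, n_train: int, n_features: int) -> list[int]:
    # PCA rank limit inside the inner CV: fit sees ~ (inner-1)/inner of the
    # outer training fold.
    inner_train = n_train - n_train // spec.inner_folds if spec.nested else n_train
    cap = max(1, min(n_features, inner_train - 1))
    cands = sorted({c for c in spec.pca_components if c <= cap} | {cap})
    return [c for c in cands if c >= 1]


def cross_validate(
    matrix: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    spec: ClassifierSpec,
    pos_label: str,
) -> ClassificationReport:
    """Stratified CV with leakage-safe preprocessing and grid search.

    ``pos_label`` names the clinically positive class (SEN is computed on
    it, SPE on the other class).  With ``spec.nested`` (default) the grid
    search runs on inner folds of each training fold; otherwise a single
    grid search over the full data picks one parameter set that is then
    CV-evaluated (optimistic; provided for protocol mimicry only).
    """
    X = np.asarray(matrix, dtype=np.float64)
    y = np.asarray(groups)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if pos_label not in classes:
        raise ValueError(f"pos_label {pos_label!r} not among {classes.tolist()}")
    neg_label = classes[classes != pos_label][0]
    class_sizes = {c: int((y == c).sum()) for c in classes}
    if spec.n_folds > min(class_sizes.values()):
        raise ValueError(
            f"n_folds={spec.n_folds} exceeds smallest class size {min(class_sizes.values())}"
        )

    subject_ids = (
        list(matrix.index) if isinstance(matrix, pd.DataFrame) else [str(i) for i in range(len(y))]
    )
    outer = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    base_grid = spec.param_grid()

    fixed_params: dict[str, Any] | None = None
    if not spec.nested:
        grid = dict(base_grid)
        grid["pca__n_components"] = _component_candidates(spec, len(y), X.shape[1])
        search = GridSearchCV(
            _make_pipeline(spec),
            grid,
            cv=StratifiedKFold(spec.inner_folds, shuffle=True, random_state=spec.seed),
            scoring="accuracy",
        )
        search.fit(X, y)
        fixed_params = search.best_params_

    fold_assignments: list[list[str]] = []
    params_per_fold: list[dict[str, Any]] = []
    fold_metrics: list[dict[str, float]] = []
    for train_idx, test_idx in outer.split(X, y):
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        min_class_tr = min(int((y_tr == c).sum()) for c in classes)
        inner_k = min(spec.inner_folds, min_class_tr)
        if fixed_params is not None:
            estimator = _make_pipeline(spec).set_params(**fixed_params)
            estimator.fit(X_tr, y_tr)
            chosen = fixed_params
        elif inner_k < 2:
            # training fold too small for inner CV: take the first grid point
            chosen = {k: v[0] for k, v in base_grid.items()}
            chosen["pca__n_components"] = _component_candidates(
                spec, len(train_idx), X.shape[1]
            )[0]
            estimator = _make_pipeline(spec).set_params(**chosen)
            estimator.fit(X_tr, y_tr)
        else:
            grid = dict(base_grid)
            grid["pca__n_components"] = _component_candidates(
                spec, len(train_idx), X.shape[1]
            )
            search = GridSearchCV(
                _make_pipeline(spec),
                grid,
                cv=StratifiedKFold(inner_k, shuffle=True, random_state=spec.seed),
                scoring="accuracy",
            )
            search.fit(X_tr, y_tr)
            estimator = search.best_estimator_
            chosen = search.best_params_
        pred = estimator.predict(X_te)
        tp = int(np.sum((y_te == pos_label) & (pred == pos_label)))
        fn = int(np.sum((y_te == pos_label) & (pred != pos_label)))
        tn = int(np.sum((y_te == neg_label) & (pred == neg_label)))
        fp = int(np.sum((y_te == neg_label) & (pred != neg_label)))
        fold_metrics.append(confusion_metrics(tp, fn, tn, fp))
        fold_assignments.append([subject_ids[i] for i in test_idx])
        params_per_fold.append({k: _jsonable(v) for k, v in chosen.items()})

    mean = lambda key: float(np.nanmean([m[key] for m in fold_metrics]))
    elements_used = tuple(
        sorted({c.split("|", 1)[1] for c in matrix.columns})
        if isinstance(matrix, pd.DataFrame)
        else ()
    )
    return ClassificationReport(
        model=spec.model,
        acc=mean("acc"),
        sen=mean("sen"),
        spe=mean("spe"),
        pos_label=str(pos_label),
        neg_label=str(neg_label),
        elements_used=elements_used,
        n_folds=spec.n_folds,
        seed=spec.seed,
        fold_assignments=fold_assignments,
        params_per_fold=params_per_fold,
        fold_metrics=fold_metrics,
    )


def permutation_null(
    matrix: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    spec: ClassifierSpec,
    pos_label: str,
    n_permutations: int,
    seed: int,
) -> np.ndarray:
    """Accuracies under label permutation (chance-level sanity check)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(groups)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(y))
        report = cross_validate(matrix, y[perm], spec, pos_label)
        accs[i] = report.acc
    return accs


def _jsonable(v: Any) -> Any:
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v
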