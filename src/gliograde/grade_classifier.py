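"""Layered linear-SVM grade classifiers with nested cross-validation.

Patch features are averaged to one row per patient and joined with the
clinical columns, giving three named feature layers: conventional (26),
texture (18) and clinical (2).  Seven models are defined over subsets of
the layers (Ia/Ib/Ic one layer, IIa/IIb/IIc two layers, IIIa all three).

Each model is evaluated by stratified 10-fold cross-validation.  Inside
every training fold — and only there — features are z-scaled, greedy
forward feature selection is run with an inner 5-fold linear SVM (skipped
for the clinical-only model, whose dimensionality is too small to prune),
and the soft-margin cost C is tuned on the grid 2^-5..2^5 by inner 5-fold
accuracy.  Test-fold decision scores are pooled over folds; accuracy,
sensitivity and specificity come from the pooled confusion matrix with HGG
as the positive class, and AUC from the pooled scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "LAYER_PREFIXES",
    "C_GRID",
    "ModelSpec",
    "MODEL_SPECS",
    "CVResult",
    "aggregate_patient_features",
    "layer_columns",
    "forward_select",
    "tune_C",
    "run_cv",
]

logger = logging.getLogger(__name__)

#: Feature layer -> column-name prefix in the aggregated table.
LAYER_PREFIXES = {"conventional": "conv_", "texture": "tex_", "clinical": "clin_"}

#: Soft-margin cost grid: C = 2^mu for integer mu in -5..5 (11 values).
C_GRID: tuple[float, ...] = tuple(2.0 ** mu for mu in range(-5, 6))


@dataclass(frozen=True)
class ModelSpec:
    """Which feature layers a model uses and whether it prunes them."""

    id: str
    layers: tuple[str, ...]
    do_feature_selection: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.layers) - set(LAYER_PREFIXES)
        if unknown:
            raise ValueError(f"unknown layers: {sorted(unknown)}")


#: The seven layered models.  Feature selection is off for the
#: clinical-only model Ic (only two features).
MODEL_SPECS: dict[str, ModelSpec] = {
    "Ia": ModelSpec("Ia", ("conventional",)),
    "Ib": ModelSpec("Ib", ("texture",)),
    "Ic": ModelSpec("Ic", ("clinical",), do_feature_selection=False),
    "IIa": ModelSpec("IIa", ("conventional", "texture")),
    "IIb": ModelSpec("IIb", ("conventional", "clinical")),
    "IIc": ModelSpec("IIc", ("texture", "clinical")),
    "IIIa": ModelSpec("IIIa", ("conventional", "texture", "clinical")),
}


@dataclass
class CVResult:
    """Pooled outcome of one 10-fold cross-validation run."""

    model_id: str
    accuracy: float          # percent
    sensitivity: float       # percent, HGG = positive class
    specificity: float       # percent
    auc: float               # [0, 1], pooled decision scores
    scores: np.ndarray       # per-sample decision score, row order of the table
    y_true: np.ndarray       # 1 = HGG
    selected: list[list[str]] = field(default_factory=list)  # per outer fold
    chosen_C: list[float] = field(default_factory=list)      # per outer fold
    seed: int = 0


def aggregate_patient_features(patch_features: pd.DataFrame,
                               clinical: pd.DataFrame) -> pd.DataFrame:
    """Average patch rows per patient and join clinical columns.

    ``patch_features`` must contain a ``patient_id`` column plus conv_/tex_
    feature columns; ``clinical`` must contain patient_id, age, gender and
    grade.  Gender is encoded male=1, female=0 as ``clin_gender``; age
    becomes ``clin_age``.  Patients present in the clinical table but
    without any patch row are dropped with a warning.
    """
    feature_cols = [c for c in patch_features.columns if c != "patient_id"]
    agg = patch_features.groupby("patient_id", sort=True)[feature_cols].mean()

    clin = clinical.set_index("patient_id")
    missing = clin.index.difference(agg.index)
    if len(missing):
        msg = f"dropping {len(missing)} patient(s) without valid patches: {list(missing)[:5]}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        clin = clin.drop(index=missing)

    table = agg.join(clin, how="inner")
    table["clin_age"] = table.pop("age").astype(float)
    table["clin_gender"] = (table.pop("gender") == "male").astype(float)
    if table.isna().any().any():
        raise ValueError("aggregated feature table contains missing values")
    return table


def layer_columns(table: pd.DataFrame, layers: tuple[str, ...]) -> list[str]:
    """Feature columns of the requested layers, in table order."""
    prefixes = tuple(LAYER_PREFIXES[layer] for layer in layers)
    return [c for c in table.columns if c.startswith(prefixes)]


def _zscale_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # zero-sd features: center only
    return mean, sd


def _inner_folds(y: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _cv_accuracy(X: np.ndarray, y: np.ndarray,
                 folds: list[tuple[np.ndarray, np.ndarray]], C: float) -> float:
    correct = 0
    for tr, te in folds:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[tr], y[tr])
        correct += int((clf.predict(X[te]) == y[te]).sum())
    return correct / len(y)


def forward_select(X: np.ndarray, y: np.ndarray, feature_names: list[str],
                   inner_folds: int = 5, C: float = 1.0, tol: float = 1e-3,
                   seed: int = 0, max_features: int | None = None) -> list[str]:
    """Greedy forward selection by inner-CV accuracy of a linear SVM.

    The best single feature is always taken; afterwards a feature is added
    only while the best achievable gain in inner 5-fold accuracy exceeds
    ``tol`` (steady state) and is not negative (drop).  Ties go to the
    earlier column.  Returns feature names in selection order.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < inner_folds:
        raise ValueError("need >= inner_folds samples of each class for selection")
    folds = _inner_folds(y, inner_folds, seed)
    n_feat = X.shape[1]
    if max_features is None:
        max_features = n_feat
    selected: list[int] = []
    remaining = list(range(n_feat))
    best_score = -np.inf
    while remaining and len(selected) < max_features:
        step_scores = np.array([
            _cv_accuracy(X[:, selected + [f]], y, folds, C) for f in remaining
        ])
        best_idx = int(np.argmax(step_scores))  # first max wins ties
        gain = step_scores[best_idx] - (best_score if selected else -np.inf)
        if selected and gain <= tol:
            break
        best_score = step_scores[best_idx]
        selected.append(remaining.pop(best_idx))
    return [feature_names[f] for f in selected]


def tune_C(X: np.ndarray, y: np.ndarray, inner_folds: int = 5, seed: int = 0,
           c_grid: tuple[float, ...] = C_GRID) -> float:
    """Grid-search C by inner 5-fold accuracy; ties break to smaller C."""
    if len(c_grid) == 1:
        return float(c_grid[0])
    folds = _inner_folds(y, inner_folds, seed)
    best_C, best_acc = None, -np.inf
    for C in sorted(c_grid):
        acc = _cv_accuracy(X, y, folds, C)
        if acc > best_acc:
            best_acc, best_C = acc, C
    return float(best_C)


def _fit_fold(X_train: np.ndarray, y_train: np.ndarray, feature_names: list[str],
              do_selection: bool, seed: int,
              c_grid: tuple[float, ...] = C_GRID,
              selection_tol: float = 1e-3):
    """Fit one outer fold: scale, select, tune, train.  Sees training data
    only; returns (classifier, mean, sd, selected column indices, C)."""
    mean, sd = _zscale_fit(X_train)
    Xs = (X_train - mean) / sd
    if do_selection:
        names = forward_select(Xs, y_train, feature_names, seed=seed,
                               tol=selection_tol)
        cols = [feature_names.index(n) for n in names]
    else:
        names = list(feature_names)
        cols = list(range(len(feature_names)))
    C = tune_C(Xs[:, cols], y_train, seed=seed, c_grid=c_grid)
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xs[:, cols], y_train)
    return clf, mean, sd, cols, names, C


def run_cv(table: pd.DataFrame, spec: ModelSpec | str, outer_folds: int = 10,
           seed: int = 0, c_grid: tuple[float, ...] = C_GRID,
           feature_selection: bool | None = None,
           selection_tol: float = 1e-3,
           folds: list[tuple[np.ndarray, np.ndarray]] | None = None) -> CVResult:
    """Stratified ``outer_folds``-fold cross-validation of one layered model.

    ``feature_selection=None`` follows the model spec; a bool overrides it.
    ``folds`` may supply explicit (train, test) index pairs, overriding the
    stratified split — useful for audits of the fold protocol.
    Deterministic given (table, spec, seed).
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    cols = layer_columns(table, spec.layers)
    if not cols:
        raise ValueError(f"no feature columns for layers {spec.layers}")
    X = table[cols].to_numpy(dtype=np.float64)
    y = (table["grade"] == "HGG").to_numpy(dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or (folds is None and counts.min() < outer_folds):
        raise ValueError("need >= outer_folds samples of each class")

    do_selection = spec.do_feature_selection if feature_selection is None \
        else feature_selection
    if folds is None:
        skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    scores = np.zeros(len(y), dtype=np.float64)
    selected_per_fold: list[list[str]] = []
    chosen_C: list[float] = []
    for fold_i, (tr, te) in enumerate(folds):
        clf, mean, sd, col_idx, names, C = _fit_fold(
            X[tr], y[tr], cols, do_selection, seed=seed + fold_i,
            c_grid=c_grid, selection_tol=selection_tol)
        Xte = (X[te] - mean) / sd
        scores[te] = clf.decision_function(Xte[:, col_idx])
        selected_per_fold.append(names)
        chosen_C.append(C)

    pred = (scores > 0).astype(np.int64)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return CVResult(
        model_id=spec.id,
        accuracy=100.0 * (tp + tn) / len(y),
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        auc=float(roc_auc_score(y, scores)),
        scores=scores,
        y_true=y,
        selected=selected_per_fold,
        chosen_C=chosen_C,
        seed=seed,
    )
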