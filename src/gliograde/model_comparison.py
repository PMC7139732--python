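"""Permutation-based model comparison and feature effect sizes.

Each model is re-run many times, each time on a different random permutation
of the patient rows (which reshuffles the cross-validation fold assignment),
yielding a distribution of AUCs per model.  Two models run on the *same*
sequence of permutations give paired AUC differences; the mean difference,
its 2.5th-97.5th percentile interval and an empirical p-value summarize
whether one model outperforms the other.  The difference is declared
significant when the percentile interval excludes zero.

Feature discriminability is ranked by Cohen's d with the convention that a
positive sign means the feature is higher in high-grade tumors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grade_classifier import C_GRID, ModelSpec, run_cv

__all__ = [
    "PermutationRunSet",
    "ComparisonResult",
    "permuted_runs",
    "compare_models",
    "effect_size",
    "effect_size_table",
    "auc_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationRunSet:
    """AUCs of one model over permuted re-runs (iteration t uses seed
    base_seed + t for both the row permutation and the CV fold split)."""

    model_id: str
    aucs: np.ndarray
    base_seed: int

    def __post_init__(self) -> None:
        aucs = np.asarray(self.aucs, dtype=np.float64)
        if aucs.ndim != 1 or len(aucs) == 0:
            raise ValueError("aucs must be a non-empty vector")
        if np.any((aucs < 0) | (aucs > 1)):
            raise ValueError("AUCs must lie in [0, 1]")
        object.__setattr__(self, "aucs", aucs)


@dataclass(frozen=True)
class ComparisonResult:
    """Paired AUC-difference summary for models A and B (d = AUC_A - AUC_B)."""

    model_a: str
    model_b: str
    mean_auc_diff: float
    ci95: tuple[float, float]
    p_value: float
    significant: bool
    n_iterations: int


def permuted_runs(table: pd.DataFrame, spec: ModelSpec | str,
                  n_iterations: int = 1000, base_seed: int = 0,
                  outer_folds: int = 10, c_grid: tuple[float, ...] = C_GRID,
                  feature_selection: bool | None = None) -> PermutationRunSet:
    """Run one model ``n_iterations`` times, each on a freshly permuted row
    order, and collect the pooled-CV AUCs.  Fully reproducible: iteration t
    permutes with seed ``base_seed + t`` and passes the same seed to the CV.
    """
    n = len(table)
    aucs = np.empty(n_iterations, dtype=np.float64)
    for t in range(n_iterations):
        rng = np.random.default_rng(base_seed + t)
        perm = rng.permutation(n)
        result = run_cv(table.iloc[perm], spec, outer_folds=outer_folds,
                        seed=base_seed + t, c_grid=c_grid,
                        feature_selection=feature_selection)
        aucs[t] = result.auc
    model_id = spec if isinstance(spec, str) else spec.id
    return PermutationRunSet(model_id=model_id, aucs=aucs, base_seed=base_seed)


def compare_models(runs_a: PermutationRunSet,
                   runs_b: PermutationRunSet) -> ComparisonResult:
    """Paired comparison of two permutation run sets (A minus B).

    The 95% interval is the 2.5th-97.5th percentile range of the paired
    differences; significance means that interval excludes zero.  The
    one-sided empirical p-value (A better than B) uses the add-one
    permutation correction, counting ties as half:
    p = (1 + #{d < 0} + 0.5 #{d = 0}) / (n + 1).
    """
    if len(runs_a.aucs) != len(runs_b.aucs):
        raise ValueError("run sets must have equal length (paired differences)")
    if runs_a.base_seed != runs_b.base_seed:
        raise ValueError("run sets must share base_seed so differences pair up")
    d = runs_a.aucs - runs_b.aucs
    n = len(d)
    lo, hi = np.percentile(d, [2.5, 97.5])
    p = (1.0 + np.sum(d < 0) + 0.5 * np.sum(d == 0)) / (n + 1.0)
    return ComparisonResult(
        model_a=runs_a.model_id,
        model_b=runs_b.model_id,
        mean_auc_diff=float(np.mean(d)),
        ci95=(float(lo), float(hi)),
        p_value=float(p),
        significant=bool(lo > 0 or hi < 0),
        n_iterations=n,
    )


def effect_size(values: np.ndarray, labels: np.ndarray) -> float:
    """Cohen's d between classes: (mean_HGG - mean_LGG) / pooled sd.

    ``labels`` may be the strings LGG/HGG or binary with 1 = HGG.  Positive
    d means the feature runs higher in high-grade tumors.  A zero pooled sd
    makes d undefined; 0 is returned with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    hgg = labels == ("HGG" if labels.dtype.kind in "UOS" else 1)
    if not hgg.any() or hgg.all():
        raise ValueError("both classes must be present")
    a, b = values[hgg], values[~hgg]
    n1, n2 = len(a), len(b)
    pooled_var = (((n1 - 1) * a.var(ddof=1) if n1 > 1 else 0.0)
                  + ((n2 - 1) * b.var(ddof=1) if n2 > 1 else 0.0)) / (n1 + n2 - 2)
    if pooled_var == 0:
        warnings.warn("zero pooled sd; effect size undefined, reporting 0",
                      stacklevel=2)
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def effect_size_table(table: pd.DataFrame,
                      feature_cols: list[str] | None = None) -> pd.Series:
    """Cohen's d of every feature column against the grade label, sorted by
    absolute discriminability (largest first)."""
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c != "grade"]
    labels = table["grade"].to_numpy()
    d = {c: effect_size(table[c].to_numpy(), labels) for c in feature_cols}
    s = pd.Series(d, name="cohens_d")
    return s.reindex(s.abs().sort_values(ascending=False).index)


def auc_correlation(runs_a: PermutationRunSet,
                    runs_b: PermutationRunSet) -> float:
    """Pearson correlation of two paired AUC vectors; NaN (with a warning)
    when either vector has zero variance."""
    if len(runs_a.aucs) != len(runs_b.aucs):
        raise ValueError("run sets must have equal length")
    a, b = runs_a.aucs, runs_b.aucs
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance AUC vector; correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
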