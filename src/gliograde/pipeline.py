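"""End-to-end workflow: simulate -> extract -> features -> train -> compare.

Thin orchestration over the computational modules, with file I/O and run
metadata so any results bundle can be regenerated from its config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conventional_features import EmptyComponentError, conventional_features
from .grade_classifier import (MODEL_SPECS, CVResult, aggregate_patient_features,
                               run_cv)
from .model_comparison import compare_models, permuted_runs
from .synthetic_cohort import CohortConfig, generate_cohort
from .texture_features import extract_texture

__all__ = ["RunConfig", "patch_feature_table", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "results/run"
    # cohort simulation (None -> read patches/clinical from disk instead)
    cohort: CohortConfig | None = None
    patch_dir: str | None = None
    clinical_csv: str | None = None
    # features
    area_threshold: int = 100
    quant_levels: int = 16
    # models
    model_ids: tuple[str, ...] = ("Ia", "Ib", "Ic", "IIa", "IIb", "IIc", "IIIa")
    outer_folds: int = 10
    compare_pairs: tuple[tuple[str, str], ...] = ()
    n_iterations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.cohort is None:
            if not self.patch_dir or not self.clinical_csv:
                raise ValueError("either a cohort config or patch_dir + clinical_csv is required")
            for p in (self.patch_dir, self.clinical_csv):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        unknown = set(self.model_ids) - set(MODEL_SPECS)
        if unknown:
            raise ValueError(f"unknown model ids: {sorted(unknown)}")
        clinical_models = {m for m in self.model_ids
                           if "clinical" in MODEL_SPECS[m].layers}
        if clinical_models and self.cohort is None and not self.clinical_csv:
            raise ValueError(f"models {sorted(clinical_models)} need a clinical table")


def patch_feature_table(patches: dict[str, list[np.ndarray]],
                        area_threshold: int = 100,
                        quant_levels: int = 16) -> pd.DataFrame:
    """Per-patch feature rows (26 conventional + 18 texture) for a cohort.

    Patches whose segmentation yields no retained component are dropped
    with a warning, matching the artifact-rejection behavior of the manual
    curation step they stand in for.
    """
    rows = []
    n_dropped = 0
    for pid, plist in patches.items():
        for j, patch in enumerate(plist):
            try:
                feats = conventional_features(patch, area_threshold=area_threshold)
            except EmptyComponentError:
                n_dropped += 1
                continue
            feats.update(extract_texture(patch, levels=quant_levels))
            feats["patient_id"] = pid
            feats["patch_id"] = f"{pid}_patch{j:03d}"
            rows.append(feats)
    if n_dropped:
        msg = f"dropped {n_dropped} patch(es) with no component above area threshold"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not rows:
        raise ValueError("no patch produced features")
    df = pd.DataFrame(rows)
    front = ["patient_id", "patch_id"]
    return df[front + [c for c in df.columns if c not in front]]


def _load_patches_from_dir(patch_dir: str) -> dict[str, list[np.ndarray]]:
    import imageio.v3 as iio

    patches: dict[str, list[np.ndarray]] = {}
    files = sorted(Path(patch_dir).glob("*.png")) + sorted(Path(patch_dir).glob("*.tif*"))
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF patches under {patch_dir}")
    for f in files:
        pid = f.stem.split("_patch")[0]
        patches.setdefault(pid, []).append(np.asarray(iio.imread(f)))
    return patches


def _cv_result_dict(res: CVResult) -> dict:
    return {
        "model": res.model_id,
        "accuracy": res.accuracy,
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "auc": res.auc,
        "selected_features_per_fold": res.selected,
        "chosen_C_per_fold": res.chosen_C,
        "seed": res.seed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the results bundle.

    Writes per-patch and per-patient feature CSVs, one metrics JSON per
    model, one JSON per comparison pair, and run metadata.  Byte-identical
    metric JSONs on re-run with the same config.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("gliograde")
    root_logger.addHandler(log_handler)
    try:
        return _run_pipeline_stages(config, out)
    finally:
        root_logger.removeHandler(log_handler)
        log_handler.close()


def _run_pipeline_stages(config: RunConfig, out: Path) -> dict:
    if config.cohort is not None:
        patches, clinical = generate_cohort(config.cohort)
    else:
        patches = _load_patches_from_dir(config.patch_dir)
        clinical = pd.read_csv(config.clinical_csv)

    logger.info("featurizing %d patients", len(clinical))
    patch_df = patch_feature_table(patches, config.area_threshold, config.quant_levels)
    patch_df.to_csv(out / "patch_features.csv", index=False)

    table = aggregate_patient_features(patch_df.drop(columns=["patch_id"]), clinical)
    table.to_csv(out / "patient_features.csv")

    results = {}
    for mid in config.model_ids:
        res = run_cv(table, MODEL_SPECS[mid], outer_folds=config.outer_folds,
                     seed=config.seed)
        logger.info("model %s: accuracy %.2f%% auc %.3f", mid, res.accuracy, res.auc)
        results[mid] = _cv_result_dict(res)
        (out / f"model_{mid}.json").write_text(
            json.dumps(results[mid], indent=2, sort_keys=True))

    comparisons = {}
    run_cache: dict[str, object] = {}
    for a, b in config.compare_pairs:
        for mid in (a, b):
            if mid not in run_cache:
                run_cache[mid] = permuted_runs(
                    table, MODEL_SPECS[mid], n_iterations=config.n_iterations,
                    base_seed=config.seed, outer_folds=config.outer_folds)
        cmp = compare_models(run_cache[a], run_cache[b])
        comparisons[f"{a}_vs_{b}"] = dataclasses.asdict(cmp)
        (out / f"compare_{a}_vs_{b}.json").write_text(
            json.dumps(comparisons[f"{a}_vs_{b}"], indent=2, sort_keys=True))

    meta = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "n_patients": int(len(table)),
        "n_patch_rows": int(len(patch_df)),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return {"models": results, "comparisons": comparisons,
            "table": table, "out_dir": str(out)}
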