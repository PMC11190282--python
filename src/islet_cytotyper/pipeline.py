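"""End-to-end orchestration: synthesize -> features -> explore ->
preprocess -> train -> evaluate -> stability, from one seeded config.

Every stage draws its seed deterministically from the global seed and the
stage name, so stages are independent yet the whole run is reproducible:
two runs with the same config produce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_features import FeatureSchema, default_schema, write_feature_matrix
from .classify import (CVSpec, ImportanceRanking, ModelSpec, SearchSpec,
                       cross_validate, feature_cutoff_sweep,
                       importance_ranking, predict)
from .explore import cluster_auc, elbow_scan, gini_report, pca_embed
from .preprocess import (CleaningManifest, PreprocessState, impute_missing,
                         run_preprocessing, scale_minmax)
from .stability import (classify_excluded, evaluate, salzberg_test,
                        tenfold_variant)
from .synthetic_islet import SynthConfig, generate_feature_matrix

logger = logging.getLogger(__name__)

ALL_STAGES = ("synth", "explore", "preprocess", "train", "evaluate",
              "stability")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    test_fraction: float = 0.25
    cv_folds: int = 5
    cv_repeats: int = 3
    search_strategy: str = "sampled"
    search_budget: int = 50
    cutoffs: list[int] | None = None
    threshold: float = 0.5
    elbow_k_max: int = 30
    stages: tuple[str, ...] = ALL_STAGES
    run_salzberg: bool = True
    run_tenfold: bool = False
    manifest: CleaningManifest | None = None
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and return (and optionally write) the
    summary.  Any stage error aborts with the failing stage named; outputs
    of completed stages are retained on disk."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_config.json").write_text(json.dumps(
            {"version": __version__, "seed": config.seed,
             "synth": asdict(config.synth),
             "stages": list(config.stages)}, indent=1, default=str))
    summary: dict = {"version": __version__, "seed": config.seed}
    schema = default_schema()
    matrix = target = None
    stage = "?"
    try:
        stage = "synth"
        if stage in config.stages:
            cfg = SynthConfig(**{**asdict(config.synth),
                                 "seed": config.stage_seed("synth")})
            matrix, target = generate_feature_matrix(cfg, schema=schema)
            summary["synth"] = {
                "n_rows": int(matrix.shape[0]),
                "n_features": int(matrix.shape[1]),
                "class_counts": target.value_counts().to_dict(),
            }
            if out is not None:
                write_feature_matrix(matrix, target, out / "features.csv",
                                     schema)
            logger.info("synth: %d rows x %d features", *matrix.shape)

        stage = "explore"
        if stage in config.stages and matrix is not None:
            summary["explore"] = explore_stage(
                matrix, target, k_max=config.elbow_k_max,
                seed=config.stage_seed("explore"))

        stage = "preprocess"
        prep = None
        if stage in config.stages and matrix is not None:
            prep = run_preprocessing(
                matrix, target, manifest=config.manifest,
                test_fraction=config.test_fraction,
                seed=config.stage_seed("preprocess"))
            summary["preprocess"] = {
                "n_train": int(len(prep.y_train)),
                "n_test": int(len(prep.y_test)),
                "n_excluded": int(len(prep.y_excluded)),
                "train_class_counts": prep.y_train.value_counts().to_dict(),
                "n_outlier_rows": int(prep.outlier_flags.sum()),
            }

        stage = "train"
        model = report = ranking = None
        if stage in config.stages and prep is not None:
            cv = CVSpec(n_folds=config.cv_folds, n_repeats=config.cv_repeats,
                        seed=config.stage_seed("cv"))
            search = SearchSpec(strategy=config.search_strategy,
                                budget=config.search_budget,
                                seed=config.stage_seed("search"))
            spec = ModelSpec("boosted-trees")
            model, report = cross_validate(prep.X_train, prep.y_train, spec,
                                           cv=cv, search=search)
            ranking = importance_ranking(model,
                                         list(prep.X_train.columns))
            summary["train"] = {
                "cv_mean_roc_auc": report.best_mean,
                "cv_sd_roc_auc": report.best_sd,
                "best_params": report.best_params,
                "top9_features": ranking.pairs[:9],
            }
            if config.cutoffs:
                table, subset, model, report = feature_cutoff_sweep(
                    prep.X_train, prep.y_train, ranking, config.cutoffs,
                    spec, cv=cv, search=search)
                summary["train"]["cutoff_sweep"] = table.drop(
                    columns="params").to_dict("records")
                summary["train"]["best_cutoff"] = len(subset)
                prep.X_test = prep.X_test[subset]
                if len(prep.X_excluded):
                    prep.X_excluded = prep.X_excluded[subset]

        stage = "evaluate"
        test_report = None
        if stage in config.stages and model is not None:
            test_report = evaluate(model, prep.X_test, prep.y_test,
                                   threshold=config.threshold)
            summary["evaluate"] = test_report.as_dict()

        stage = "stability"
        if stage in config.stages and model is not None:
            stab: dict = {}
            cv = CVSpec(n_folds=config.cv_folds, n_repeats=config.cv_repeats,
                        seed=config.stage_seed("cv"))
            search = SearchSpec(strategy=config.search_strategy,
                                budget=config.search_budget,
                                seed=config.stage_seed("search"))
            if config.run_salzberg:
                sz = salzberg_test(prep.X_train, prep.y_train, prep.X_test,
                                   prep.y_test, ModelSpec("boosted-trees"),
                                   cv=cv, search=search,
                                   seed=config.stage_seed("salzberg"),
                                   real_report=test_report, real_model=model)
                stab["salzberg"] = {
                    "shuffled_test": sz.shuffled.as_dict(),
                    "shuffled_train": sz.shuffled_train.as_dict(),
                    "relative_drop_test": sz.relative_drop_test,
                    "relative_drop_train": sz.relative_drop_train,
                }
            if config.run_tenfold:
                table = tenfold_variant(prep.X_train, prep.y_train,
                                        ModelSpec("boosted-trees"),
                                        search=search,
                                        seed=config.stage_seed("tenfold"),
                                        base_folds=config.cv_folds,
                                        n_repeats=config.cv_repeats)
                stab["tenfold"] = {
                    "table": table.drop(columns="best_params").to_dict("records"),
                    "abs_difference": table.attrs["abs_difference"],
                }
            excl = classify_excluded(model, prep.X_excluded, prep.y_excluded,
                                     threshold=config.threshold)
            stab["excluded"] = excl.as_dict() if excl is not None else None
            summary["stability"] = stab
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out is not None:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True, default=float))
    return summary


def explore_stage(matrix: pd.DataFrame, target: pd.Series, k_max: int = 30,
                  seed: int = 0, knee_k: int | None = None) -> dict:
    """Exploratory analysis on the imputed, min-max-scaled matrix:
    explained variance, WCSS elbow scan, Gini table at the knee, and the
    two-cluster k-means ROC-AUC baseline on the 2-component PCA."""
    X, _ = scale_minmax(impute_missing(matrix))
    k_embed = min(10, min(X.shape) - 1)
    emb = pca_embed(X, k=k_embed)
    emb2 = emb.coordinates[:, :2]
    k_max = min(k_max, X.shape[0] - 1)
    curve, knee, confident = elbow_scan(emb2, k_min=2, k_max=k_max, seed=seed)
    if knee_k is not None:
        knee = knee_k
    from .explore import _fit_kmeans
    km = _fit_kmeans(emb2, knee, seed)
    per_cluster, mean_gini = gini_report(km.labels_, target)
    auc = cluster_auc(emb2, target, k=2, seed=seed)
    return {
        "explained_variance": [float(v) for v in emb.explained_variance],
        "wcss_curve": curve.to_dict("records"),
        "knee_k": int(knee),
        "knee_confident": bool(confident),
        "per_cluster_gini": {str(k): float(v)
                             for k, v in sorted(per_cluster.items())},
        "mean_gini": float(mean_gini),
        "cluster_auc_k2": float(auc),
    }
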