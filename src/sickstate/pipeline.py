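"""End-to-end orchestration of the FOS classification pipeline.

Stage order per sex stratum: Yeo-Johnson normalization -> repeated Boruta
selection -> nested cross-validated elastic-net multinomial classification
on the retained regions -> SHAP/hybrid attribution -> clustering metrics
on the full vs selected feature sets. A single master seed drives named
substreams for every stage, so identical configurations reproduce
identical artifact bundles. Artifacts are written as delimited text and
JSON with the configuration echoed alongside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import attribute as attr_mod
from . import clustermetrics as cm_mod
from . import io as io_mod
from . import select as sel_mod
from . import transform as tf
from .classify import CVConfig, CVResult, nested_cv
from .simulate import FosSimConfig, generate_fos, _config_dict

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    input_path: str | None = None  # None -> simulate
    out_dir: str = "pipeline_out"
    sim: FosSimConfig = field(default_factory=FosSimConfig)
    selection_reps: int = 100
    selection_top_pct: float = 5.0
    boruta_max_iter: int = 100
    boruta_n_estimators: int = 500
    cv: CVConfig = field(default_factory=CVConfig)
    stratify_by_sex: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = FosSimConfig(**raw.pop("sim", {}))
        cv = CVConfig(**raw.pop("cv", {}))
        return cls(sim=sim, cv=cv, **raw)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_jsonable(payload), fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


@dataclass
class FosPipelineBundle:
    """All artifacts of one stratum's pipeline run."""

    stratum: str
    selection: sel_mod.SelectionResult
    cv_result: CVResult
    attribution: attr_mod.AttributionResult
    cluster_metrics: pd.DataFrame


def _load_input(config: PipelineConfig) -> pd.DataFrame:
    if config.input_path is not None:
        return io_mod.read_matrix(config.input_path)
    frames = []
    for sex in config.sim.sex_labels if config.stratify_by_sex else config.sim.sex_labels[:1]:
        table, _ = generate_fos(config.sim, sex=sex)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def _run_stratum(matrix: pd.DataFrame, stratum: str, config: PipelineConfig) -> FosPipelineBundle:
    y = matrix["condition"].to_numpy()
    X = matrix.drop(columns=[c for c in io_mod.LABEL_COLUMNS if c in matrix.columns])
    if pd.unique(y).size < 2:
        raise ValueError("need at least 2 conditions")

    try:
        params = tf.fit_transform_params(X)
        X_std = tf.standardize(X, params)
    except Exception as exc:
        raise StageError("transform", exc) from exc

    try:
        selection = sel_mod.repeated_selection(
            X_std, y,
            n_reps=config.selection_reps,
            top_pct=config.selection_top_pct,
            seed=config.seed,
            max_iter=config.boruta_max_iter,
            n_estimators=config.boruta_n_estimators,
        )
    except Exception as exc:
        raise StageError("select", exc) from exc
    retained = selection.retained or list(X.columns)
    if not selection.retained:
        logger.warning("selection retained nothing for %s; classifying on all features", stratum)

    try:
        cv_result = nested_cv(X[retained], y, config.cv)
    except Exception as exc:
        raise StageError("classify", exc) from exc

    try:
        attribution = attr_mod.attribute_from_cv(cv_result)
    except Exception as exc:
        raise StageError("attribute", exc) from exc

    try:
        metrics = cm_mod.compare_feature_sets(X_std.to_numpy(), X_std[retained].to_numpy(), y)
    except Exception as exc:
        raise StageError("clustermetrics", exc) from exc

    return FosPipelineBundle(stratum, selection, cv_result, attribution, metrics)


def run_fos_pipeline(config: PipelineConfig) -> dict[str, FosPipelineBundle]:
    """Run the pipeline, one bundle per sex stratum; writes artifacts.

    Returns a dict keyed by stratum label ("all" if the input has no sex
    column or stratification is off).
    """
    matrix = _load_input(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.stratify_by_sex and "sex" in matrix.columns:
        strata = {s: matrix[matrix["sex"] == s] for s in pd.unique(matrix["sex"])}
    else:
        strata = {"all": matrix}

    bundles: dict[str, FosPipelineBundle] = {}
    for stratum, sub in strata.items():
        logger.info("running stratum %r (%d animals)", stratum, len(sub))
        bundle = _run_stratum(sub.reset_index(drop=True), stratum, config)
        bundles[stratum] = bundle
        prefix = out / stratum
        prefix.mkdir(exist_ok=True)
        bundle.selection.to_frame().to_csv(prefix / "selection.csv")
        bundle.cv_result.mean_coef.to_csv(prefix / "mean_coefficients.csv")
        bundle.cv_result.confusion.to_csv(prefix / "confusion.csv")
        bundle.attribution.to_frame().to_csv(prefix / "attribution.csv", index=False)
        bundle.cluster_metrics.to_csv(prefix / "cluster_metrics.csv")
        summary = {
            "stratum": stratum,
            "n_animals": int(len(sub)),
            "retained_features": list(bundle.selection.retained),
            "accuracy": bundle.cv_result.accuracy,
            "accuracy_sd": bundle.cv_result.accuracy_sd,
            "per_class_mse": {str(k): float(v) for k, v in bundle.cv_result.per_class_mse.items()},
            "seed": config.seed,
        }
        (prefix / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    (out / "input_echo.json").write_text(
        json.dumps({"n_rows": int(len(matrix)), "sim": _config_dict(config.sim)
                    if config.input_path is None else None}, indent=2)
    )
    return bundles
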