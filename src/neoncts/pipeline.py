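"""End-to-end pipeline: simulate -> window -> extract -> cluster -> model.

Orchestrates the full analysis on a synthetic cohort from a single config
mapping, produces an :class:`~neoncts.risk.EvaluationReport`, and records a
local provenance manifest (stage parameters, seeds, artifact digests) so a
rerun with identical inputs is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import build_default_catalog, catalog_to_json
from .clustering import MutualInfoKMedoids, select_representatives, \
    variance_explained
from .features import (FeatureMatrix, apply_catalog, filter_nonviable,
                       robust_sigmoid_normalize, sample_daily,
                       sample_windows_daily, winsorize)
from .risk import (DEMOGRAPHIC_FEATURES, BackwardLogisticRisk,
                   EvaluationReport, cv_predictions,
                   event_rate_threshold_metrics, horizon_auc, univariate_auc)
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort
from .vitals_io import assign_labels, make_windows

log = logging.getLogger(__name__)

PIPELINE_DEFAULTS: dict[str, Any] = {
    "horizon_days": 7,
    "sampling_mode": "random_one_per_day",   # or "daily_mean"
    "sampling_seed": 0,
    "sample_before_extraction": True,
    "n_clusters": 20,
    "n_bins": 10,
    "representative_mode": "top_auc",        # or "medoid"
    "max_features": 5,
    "folds": 10,
    "cv_seed": 0,
    "include_demographics": False,
    "selector": "backward_p",
}


def default_config(**cohort_overrides) -> dict:
    """A complete, valid config mapping (cohort + pipeline sections)."""
    cohort = dataclasses.asdict(CohortConfig())
    cohort.update(cohort_overrides)
    return {"cohort": cohort, "pipeline": dict(PIPELINE_DEFAULTS)}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def validate_config(config: dict) -> list[str]:
    """Return a list of violations (empty means the config is valid)."""
    violations: list[str] = []
    cohort = config.get("cohort")
    if not isinstance(cohort, dict):
        return ["missing 'cohort' section"]
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(cohort) - known
    if unknown:
        violations.append(f"unknown cohort fields: {sorted(unknown)}")
    if "seed" not in cohort:
        violations.append("cohort.seed is mandatory")
    try:
        CohortConfig(**{k: v for k, v in cohort.items() if k in known})
    except Exception as exc:                                # noqa: BLE001
        violations.append(f"cohort: {exc}")
    pipe = config.get("pipeline", {})
    merged = {**PIPELINE_DEFAULTS, **pipe}
    unknown = set(pipe) - set(PIPELINE_DEFAULTS)
    if unknown:
        violations.append(f"unknown pipeline fields: {sorted(unknown)}")
    if merged["sampling_mode"] not in ("random_one_per_day", "daily_mean"):
        violations.append("pipeline.sampling_mode invalid")
    if merged["representative_mode"] not in ("top_auc", "medoid"):
        violations.append("pipeline.representative_mode invalid")
    for key in ("horizon_days", "n_clusters", "n_bins", "max_features",
                "folds"):
        if not (isinstance(merged[key], int) and merged[key] >= 1):
            violations.append(f"pipeline.{key} must be a positive integer")
    for key in ("sampling_seed", "cv_seed"):
        if not isinstance(merged.get(key), int):
            violations.append(f"pipeline.{key} (integer seed) is mandatory")
    if isinstance(merged.get("max_features"), int) and \
            isinstance(merged.get("n_clusters"), int) and \
            merged["max_features"] > merged["n_clusters"]:
        violations.append("pipeline.max_features exceeds candidate count "
                          "(n_clusters)")
    return violations


@dataclass
class RunManifest:
    """Local provenance record: stages, parameters, seeds, file digests."""

    software_version: str = __version__
    stages: list[dict] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)   # path -> sha256
    failed_stage: str | None = None

    def add_stage(self, name: str, **params) -> None:
        self.stages.append({"name": name, "params": params,
                            "finished_at": time.time()})

    def add_artifact(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.artifacts[path.name] = digest

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass
class PipelineResult:
    report: EvaluationReport
    manifest: RunManifest
    matrix: FeatureMatrix
    candidate_ids: list[str]
    selected_ids: list[str]
    cluster_solution: Any
    model: Any
    predictions: pd.DataFrame


def _normalize_for_clustering(values: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for c in values.columns:
        out[c] = robust_sigmoid_normalize(winsorize(values[c].to_numpy()))
    return pd.DataFrame(out, index=values.index)


def _demographic_frame(matrix: FeatureMatrix,
                       outcomes: pd.DataFrame) -> pd.DataFrame:
    table = outcomes.set_index("patient_id")
    pids = matrix.values.index.get_level_values("patient_id")
    demo = table.loc[pids, ["birth_weight_kg", "ga_weeks", "sex", "apgar5"]]
    demo = demo.assign(sex_male=(demo.pop("sex") == "M").astype(float))
    demo.index = matrix.values.index
    return demo[DEMOGRAPHIC_FEATURES].astype(float)


def run_pipeline(
    config: dict,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage in order on one synthetic cohort.

    Stages: simulate, window+label, daily sampling, feature extraction,
    viability filtering, normalization, MI k-medoids clustering,
    representative selection, backward-selected logistic modeling, and
    patient-grouped cross-validated evaluation. Artifacts plus a provenance
    manifest are written under ``out_dir`` when given.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    cohort_cfg = CohortConfig(**config["cohort"])
    pipe = {**PIPELINE_DEFAULTS, **config.get("pipeline", {})}
    manifest = RunManifest()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        series, outcomes = generate_cohort(cohort_cfg)
        manifest.add_stage(stage, seed=cohort_cfg.seed,
                           n_patients=cohort_cfg.n_patients)

        stage = "window"
        windows = []
        for s in series:
            windows.extend(make_windows(s))
        windows = assign_labels(windows, outcomes, pipe["horizon_days"])
        manifest.add_stage(stage, horizon_days=pipe["horizon_days"],
                           n_windows=len(windows))

        stage = "extract"
        catalog = build_default_catalog()
        if pipe["sample_before_extraction"] and \
                pipe["sampling_mode"] == "random_one_per_day":
            windows = sample_windows_daily(windows, pipe["sampling_seed"])
            matrix = apply_catalog(windows, catalog)
        else:
            matrix = apply_catalog(windows, catalog)
            matrix = sample_daily(matrix, pipe["sampling_mode"],
                                  pipe["sampling_seed"])
        manifest.add_stage(stage, n_operations=len(catalog) * 2,
                           sampling_mode=pipe["sampling_mode"],
                           sampling_seed=pipe["sampling_seed"])

        stage = "filter"
        matrix, audit = filter_nonviable(matrix)
        manifest.add_stage(stage,
                           dropped_columns=len(audit.dropped_columns),
                           dropped_rows=len(audit.dropped_rows))

        stage = "cluster"
        n_surviving = matrix.values.shape[1]
        if pipe["n_clusters"] > n_surviving:
            raise ValueError(
                f"n_clusters={pipe['n_clusters']} exceeds the "
                f"{n_surviving} surviving operations")
        normalized = _normalize_for_clustering(matrix.values)
        km = MutualInfoKMedoids(n_clusters=pipe["n_clusters"],
                                n_bins=pipe["n_bins"]).fit(normalized)
        solution = km.solution_
        labels = matrix.labels.to_numpy()
        aucs = {c: univariate_auc(matrix.values[c].to_numpy(), labels)
                for c in matrix.values.columns}
        reps = select_representatives(solution, aucs,
                                      pipe["representative_mode"])
        solution.representative_ids = reps
        solution.variance_explained = variance_explained(normalized, reps)
        manifest.add_stage(stage, k=pipe["n_clusters"],
                           n_bins=pipe["n_bins"],
                           variance_explained=solution.variance_explained)

        stage = "fit"
        X = matrix.values[reps]
        always_keep: tuple[str, ...] = ()
        if pipe["include_demographics"]:
            X = pd.concat([X, _demographic_frame(matrix, outcomes)], axis=1)
            always_keep = tuple(DEMOGRAPHIC_FEATURES)
        model_kwargs = dict(max_features=pipe["max_features"],
                            selector=pipe["selector"],
                            always_keep=always_keep)
        final = BackwardLogisticRisk(**model_kwargs).fit(X, labels)
        manifest.add_stage(stage, candidates=list(X.columns),
                           selected=final.feature_ids_)

        stage = "evaluate"
        pids = matrix.values.index.get_level_values("patient_id").to_numpy()
        if pipe["representative_mode"] == "top_auc":
            # representative choice is label-dependent, so it re-runs
            # inside each training fold over the (label-free) clusters
            X_cv = matrix.values
            if pipe["include_demographics"]:
                X_cv = pd.concat(
                    [X_cv, _demographic_frame(matrix, outcomes)], axis=1)
            preds = cv_predictions(
                X_cv, labels, pids, folds=pipe["folds"],
                seed=pipe["cv_seed"],
                cluster_assignments=solution.assignments, **model_kwargs)
        else:
            preds = cv_predictions(X, labels, pids, folds=pipe["folds"],
                                   seed=pipe["cv_seed"], **model_kwargs)
        from sklearn.metrics import roc_auc_score
        cv_auc_value = float(roc_auc_score(labels, preds))
        dud = matrix.days_until_death.to_numpy()
        horizon_aucs = {d: horizon_auc(preds, labels, dud, d)
                        for d in range(1, pipe["horizon_days"] + 1)}
        thresh = event_rate_threshold_metrics(preds, labels)
        report = EvaluationReport(
            cv_auc=cv_auc_value,
            horizon_aucs=horizon_aucs,
            threshold_metrics={k: thresh[k] for k in
                               ("threshold", "sensitivity", "ppv", "lift")},
            event_rate=thresh["event_rate"],
        )
        manifest.add_stage(stage, folds=pipe["folds"],
                           cv_seed=pipe["cv_seed"], cv_auc=cv_auc_value)
    except Exception:
        manifest.failed_stage = stage
        if out_path is not None:
            (out_path / "manifest.json").write_text(manifest.to_json())
        raise

    predictions = pd.DataFrame({
        "patient_id": matrix.values.index.get_level_values("patient_id"),
        "day_index": matrix.values.index.get_level_values("day_index"),
        "prediction": preds,
        "label": labels,
        "days_until_death": dud,
    })

    if out_path is not None:
        write_cohort(series, outcomes, out_path / "cohort")
        (out_path / "catalog.json").write_text(catalog_to_json(catalog))
        (out_path / "clusters.json").write_text(solution.to_json())
        (out_path / "model.json").write_text(final.model_.to_json())
        (out_path / "report.json").write_text(report.to_json())
        predictions.to_csv(out_path / "predictions.csv", index=False)
        for name in ("catalog.json", "clusters.json", "model.json",
                     "report.json", "predictions.csv"):
            manifest.add_artifact(out_path / name)
        manifest.add_artifact(out_path / "cohort" / "vitals.csv")
        manifest.add_artifact(out_path / "cohort" / "outcomes.csv")
        (out_path / "manifest.json").write_text(manifest.to_json())

    return PipelineResult(
        report=report, manifest=manifest, matrix=matrix,
        candidate_ids=list(X.columns), selected_ids=final.feature_ids_,
        cluster_solution=solution, model=final.model_,
        predictions=predictions,
    )
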