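"""End-to-end pipeline: simulate → extract → stats → classify → report.

Stages communicate only through documented file formats (annotation CSV,
patient-record CSV, metrics CSV, JSON reports), so any stage can also be
run standalone on its declared inputs via the CLI. A run manifest records
the effective configuration, every artifact with its SHA-256 checksum, the
package version and timestamps; under a fixed seed all artifact checksums
are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import write_annotations
from .classify import run_task
from .geometry import METRIC_NAMES, metrics_table
from .simulate import (
    ClassParams,
    SimulationConfig,
    cohort_to_frame,
    default_class_params,
    simulate_feature_cohort,
    simulate_landmark_cohort,
    simulate_rater_replicates,
)
from .stats import (
    correlation_with_ava,
    descriptive_table,
    icc_analysis,
    pairwise_tests_by_metric,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    icc_fraction: float = 0.10
    tasks: tuple[str, ...] = ("binary_significant_AS", "multiclass_severity")
    families: tuple[str, ...] = ("elastic_net_logistic",)
    model_seed: int = 0
    test_fraction: float = 0.2
    collinearity_threshold: float = 0.9
    outdir: Path = Path("leafletmotion-run")
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a YAML/JSON config mirroring the field names."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        cp_raw = sim_raw.pop("class_params", None)
        class_params = default_class_params()
        if cp_raw:
            for sev, spec in cp_raw.items():
                base = class_params[sev]
                params = dict(base.params)
                params.update({k: tuple(v) for k, v in
                               spec.get("params", {}).items()})
                class_params[sev] = ClassParams(
                    severity=sev, n=int(spec.get("n", base.n)), params=params,
                    sex_fraction_female=float(spec.get(
                        "sex_fraction_female", base.sex_fraction_female)))
        sim = SimulationConfig(class_params=class_params, **{
            k: (tuple(v) if k == "leaflet_segment_lengths" else v)
            for k, v in sim_raw.items()})
        if "tasks" in raw:
            raw["tasks"] = tuple(raw["tasks"])
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        if "outdir" in raw:
            raw["outdir"] = Path(raw["outdir"])
        return cls(simulation=sim, **raw)

    def to_snapshot(self) -> dict:
        snap = dataclasses.asdict(self)
        snap["outdir"] = str(self.outdir)
        return snap


@dataclass
class RunManifest:
    config: dict
    artifacts: dict[str, str]        # relative path -> sha256
    package_version: str
    started: str
    finished: str
    stages: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def reproducible_view(self) -> dict:
        """The manifest minus wall-clock fields; identical across reruns
        with the same seed."""
        d = self.to_dict()
        d.pop("started")
        d.pop("finished")
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: RunManifest):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial_manifest = manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(obj: Any):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_full_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write all artifacts under ``config.outdir``.

    Layout: ``data/`` (annotation, patient-record, metrics, ground-truth
    CSVs), ``stats/`` (descriptive table, pairwise tests, ICC, correlation),
    ``models/`` (evaluation reports, ROC points, importance), ``report/``
    (markdown + JSON summary, manifest).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    started = datetime.now(timezone.utc).isoformat()
    outdir = Path(config.outdir)
    for sub in ("data", "stats", "models", "report"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stages: list[str] = []
    manifest = RunManifest(config=config.to_snapshot(), artifacts=artifacts,
                           package_version=__version__, started=started,
                           finished="", stages=stages)

    def register(path: Path) -> None:
        artifacts[str(path.relative_to(outdir))] = _sha256(path)

    summary: dict[str, Any] = {"seed": config.simulation.seed}
    stage = "simulate"
    try:
        cohort = simulate_feature_cohort(config.simulation)
        cohort_df = cohort_to_frame(cohort)
        cohort_path = outdir / "data" / "patient_records.csv"
        cohort_df.to_csv(cohort_path, index=False)
        register(cohort_path)
        stages.append(stage)
        logger.info("stage=%s patients=%d", stage, len(cohort_df))

        stage = "extract"
        geometry_diag = None
        if config.simulation.landmark_mode:
            studies, truths = simulate_landmark_cohort(config.simulation)
            ann_path = outdir / "data" / "annotations.csv"
            write_annotations(studies, ann_path)
            register(ann_path)
            truth_df = pd.DataFrame([t.as_dict() for t in truths])
            truth_df.insert(0, "patient_id", [s.patient_id for s in studies])
            truth_path = outdir / "data" / "ground_truth_metrics.csv"
            truth_df.to_csv(truth_path, index=False)
            register(truth_path)

            replicates = simulate_rater_replicates(
                studies, config.simulation, fraction=config.icc_fraction)
            mdf = metrics_table(list(studies) + list(replicates),
                               correct_rotation=True)
            metrics_path = outdir / "data" / "metrics.csv"
            mdf.to_csv(metrics_path, index=False)
            register(metrics_path)

            recovered = mdf[(mdf.rater_id == "R1") & (mdf.replicate == 1)]
            err = {
                m: float(np.mean(np.abs(recovered[m].to_numpy()
                                        - truth_df[m].to_numpy())))
                for m in METRIC_NAMES
            }
            geometry_diag = {"mean_abs_recovery_error": err,
                             "n_studies": len(studies),
                             "n_replicates": len(replicates)}
            summary["geometry_roundtrip"] = geometry_diag

            icc = icc_analysis(mdf)
            icc_rows = []
            for mode, res in icc.items():
                for metric, r in res["per_metric"].items():
                    icc_rows.append({"mode": mode, "metric": metric,
                                     "icc": r.icc, "ci_low": r.ci_low,
                                     "ci_high": r.ci_high,
                                     "n_subjects": r.n_subjects})
            icc_df = pd.DataFrame(icc_rows)
            icc_path = outdir / "stats" / "icc.csv"
            icc_df.to_csv(icc_path, index=False)
            register(icc_path)
            summary["icc"] = {mode: {"mean_icc": res["mean_icc"],
                                     "n_subjects": res["n_subjects"]}
                              for mode, res in icc.items()}
        stages.append(stage)

        stage = "stats"
        table = descriptive_table(cohort_df)
        table_path = outdir / "stats" / "descriptive_table.csv"
        table.to_csv(table_path, index=False)
        register(table_path)
        pairwise = pairwise_tests_by_metric(cohort_df)
        pw_path = outdir / "stats" / "pairwise_tests.csv"
        pairwise.to_csv(pw_path, index=False)
        register(pw_path)
        corr = correlation_with_ava(cohort_df)
        summary["correlation_with_ava"] = {
            m: {"r": r, "p": p} for m, (r, p) in corr.items()}
        stages.append(stage)
        logger.info("stage=%s rows=%d", stage, len(table))

        stage = "classify"
        model_summaries = []
        for task in config.tasks:
            for family in config.families:
                fitted, report = run_task(
                    cohort_df, task, family, seed=config.model_seed,
                    test_fraction=config.test_fraction,
                    collinearity_threshold=config.collinearity_threshold)
                tag = f"{task}__{family}"
                for cls, pts in report.roc_points.items():
                    roc_path = outdir / "models" / f"roc_{tag}_{cls}.csv"
                    pts.to_csv(roc_path, index=False)
                    register(roc_path)
                if report.importance is not None:
                    imp_path = outdir / "models" / f"importance_{tag}.csv"
                    report.importance.to_csv(imp_path, index=False)
                    register(imp_path)
                cm_path = outdir / "models" / f"confusion_{tag}.csv"
                report.confusion_matrix.to_csv(cm_path)
                register(cm_path)
                entry = report.summary()
                entry["best_params"] = fitted.best_params
                model_summaries.append(entry)
                logger.info("stage=%s %s auc=%.3f acc=%.3f", stage, tag,
                            report.auc, report.accuracy)
        summary["models"] = model_summaries
        stages.append(stage)

        stage = "report"
        summary["descriptive_table"] = table
        summary["pairwise_tests"] = pairwise
        json_path = outdir / "report" / "summary.json"
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, default=_json_default)
        register(json_path)
        md_path = outdir / "report" / "summary.md"
        md_path.write_text(_render_markdown(summary, table, pairwise),
                           encoding="utf-8")
        register(md_path)
        stages.append(stage)
    except Exception as err:  # surfaced with the failing stage name
        manifest.finished = datetime.now(timezone.utc).isoformat()
        raise StageError(stage, err, manifest) from err

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest_path = outdir / "report" / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, default=_json_default)
    return manifest


def _render_markdown(summary: dict, table: pd.DataFrame,
                     pairwise: pd.DataFrame) -> str:
    lines = ["# Leaflet motion analysis report", ""]
    lines += ["## Cohort characteristics", "", table.to_markdown(index=False), ""]
    if "geometry_roundtrip" in summary:
        lines += ["## Geometry round-trip diagnostics", ""]
        for metric, err in summary["geometry_roundtrip"][
                "mean_abs_recovery_error"].items():
            lines.append(f"- {metric}: mean |recovered − truth| = {err:.3g}")
        lines.append("")
    if "icc" in summary:
        lines += ["## Reliability (ICC)", ""]
        for mode, res in summary["icc"].items():
            lines.append(f"- {mode}: mean ICC {res['mean_icc']:.3f} "
                         f"(n = {res['n_subjects']})")
        lines.append("")
    lines += ["## Correlation with aortic valve area", ""]
    for metric, rp in summary.get("correlation_with_ava", {}).items():
        lines.append(f"- {metric}: r = {rp['r']:.2f} (p = {rp['p']:.2g})")
    lines += ["", "## Pairwise group comparisons", "",
              pairwise.to_markdown(index=False), ""]
    lines += ["## Classification", ""]
    for entry in summary.get("models", []):
        lines.append(
            f"- {entry['task']} / {entry['family']}: AUC {entry['auc']:.3f}, "
            f"accuracy {entry['accuracy']:.3f}, sensitivity "
            f"{entry['sensitivity']:.3f}, specificity {entry['specificity']:.3f}")
    lines.append("")
    return "\n".join(lines)
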