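"""End-to-end orchestration: simulate -> preprocess -> features -> select
-> label -> train/evaluate.

The pipeline mirrors the four-stage study design (signal conditioning,
feature generation, statistical feature selection, MLP classification) on a
simulated cohort, with a single global seed making every run reproducible.
Each stage persists its outputs as plain CSV/JSON in the run directory so
any stage can be re-run or inspected in isolation.

Feature vector: the classifier consumes four inputs per subject — the mean
and variance of the selected slope feature on the fistula hand, before and
after dialysis.  The rising slope is the feature the t-test selects on the
reference cohort; when no feature reaches significance the pipeline warns
and keeps all candidates.  Slope values are min–max rescaled to [0, 1]
before summarisation; the default scope pools all beats of the cohort per
feature, which preserves between-subject and between-phase contrasts (a
per-recording scope, which maps every recording onto the same range, is
available but makes phase means uninformative by construction).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from .evaluation import CrossValidationReport, cross_validate
from .labels import patients_frame
from .preprocess import SmootherConfig, detrend, smooth
from .selection import TTestResult, select_features, t_test
from .synthetic import Cohort, CohortSpec, generate_cohort
from .trainers import TrainConfig

logger = logging.getLogger("ppgavf")

__all__ = ["PipelineConfig", "run_pipeline", "extract_cohort_features", "cohort_feature_matrix"]


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    smoother: SmootherConfig = field(default_factory=SmootherConfig)
    n_beats_selected: int = 12
    min_peak_distance: float = 0.4
    rescale_scope: str = "cohort"  # cohort | recording | none
    ttest_variant: str = "paired"
    alpha: float = 0.05
    algorithms: tuple[str, ...] = ("lm", "scg", "rprop")
    cv_folds: int = 5
    cv_repeats: int = 10
    hidden_dim: int = 35
    train: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortSpec(**kwargs["cohort"])
        if "smoother" in kwargs:
            kwargs["smoother"] = SmootherConfig(**kwargs["smoother"])
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        if "algorithms" in kwargs:
            kwargs["algorithms"] = tuple(kwargs["algorithms"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def preprocess_recording(recording, smoother: SmootherConfig | None = None):
    """Condition one recording: robust smoothing, then de-trending."""
    return detrend(smooth(recording, smoother or SmootherConfig()))


def extract_cohort_features(
    cohort: Cohort, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beat-level and summary feature tables for the fistula hand.

    Returns ``(beat_table, summaries)``: the per-beat landmark/slope table
    for every (subject, phase) and the per-subject mean/variance summaries
    of the (optionally rescaled) slope values.
    """
    config = config or PipelineConfig()
    hand = cohort.spec.hd_hand
    rows = []
    for patient in cohort.patients:
        for phase in ("before_HD", "after_HD"):
            rec = cohort.recording(patient.subject_id, hand, phase)
            conditioned = preprocess_recording(rec, config.smoother)
            beats = feat.beat_features(
                conditioned, k=config.n_beats_selected, min_distance=config.min_peak_distance
            )
            rows.append(feat.beat_table(conditioned, beats))
    beat_table = pd.concat(rows, ignore_index=True)

    scaled = beat_table.copy()
    if config.rescale_scope == "cohort":
        for col in ("rs", "fs"):
            scaled[col] = feat.rescale(scaled[col].to_numpy())
    elif config.rescale_scope == "recording":
        for col in ("rs", "fs"):
            scaled[col] = scaled.groupby(["subject_id", "phase"])[col].transform(
                lambda v: feat.rescale(v.to_numpy())
            )
    elif config.rescale_scope != "none":
        raise ValueError(f"unknown rescale_scope {config.rescale_scope!r}")

    summary_rows = []
    for (sid, phase), group in scaled.groupby(["subject_id", "phase"], sort=False):
        for col in ("rs", "fs"):
            s = feat.summarize(group[col].to_numpy(), phase=phase, feature_name=col)
            summary_rows.append(
                {
                    "subject_id": sid,
                    "phase": phase,
                    "feature": col,
                    "mean": s.mean,
                    "variance": s.variance,
                    "n": s.n,
                }
            )
    return beat_table, pd.DataFrame(summary_rows)


def run_feature_selection(
    summaries: pd.DataFrame, variant: str = "paired", alpha: float = 0.05
) -> tuple[dict[str, TTestResult], list[str]]:
    """Before/after t-test per feature on the per-subject mean values."""
    results: dict[str, TTestResult] = {}
    for feature in ("rs", "fs"):
        sub = summaries[summaries["feature"] == feature].pivot(
            index="subject_id", columns="phase", values="mean"
        )
        results[feature] = t_test(
            sub["before_HD"].to_numpy(),
            sub["after_HD"].to_numpy(),
            variant=variant,
            alpha=alpha,
            feature_name=feature,
        )
    selected = select_features(results, alpha)
    if not selected:
        logger.warning("no feature reached significance at alpha=%.3g; keeping all", alpha)
        selected = list(results)
    return results, selected


def cohort_feature_matrix(
    summaries: pd.DataFrame, subject_order: list[str], feature: str = "rs"
) -> np.ndarray:
    """Per-subject classifier inputs: [mean before, mean after, var before, var after]."""
    sub = summaries[summaries["feature"] == feature]
    mean = sub.pivot(index="subject_id", columns="phase", values="mean")
    var = sub.pivot(index="subject_id", columns="phase", values="variance")
    x = np.column_stack(
        [
            mean.loc[subject_order, "before_HD"],
            mean.loc[subject_order, "after_HD"],
            var.loc[subject_order, "before_HD"],
            var.loc[subject_order, "after_HD"],
        ]
    )
    return x


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write reports; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}

    def _stage(name: str):
        logger.info("stage %s", name)
        stages[name] = time.perf_counter()
        return stages[name]

    try:
        _stage("simulate")
        cohort = generate_cohort(config.cohort, config.seed)
        patients = patients_frame(cohort.patients)
        patients.to_csv(outdir / "patients.csv", index=False)

        _stage("features")
        beat_table, summaries = extract_cohort_features(cohort, config)
        beat_table.to_csv(outdir / "beat_features.csv", index=False)
        summaries.to_csv(outdir / "summaries.csv", index=False)

        _stage("select")
        results, selected = run_feature_selection(summaries, config.ttest_variant, config.alpha)
        (outdir / "ttest.json").write_text(
            json.dumps({k: v.to_dict() for k, v in results.items()}, indent=2)
        )

        _stage("evaluate")
        order = [p.subject_id for p in cohort.patients]
        labels = [p.class_label for p in cohort.patients]
        x = cohort_feature_matrix(summaries, order, feature=selected[0])
        reports: list[CrossValidationReport] = []
        for algorithm in config.algorithms:
            cfg = dataclasses.replace(config.train, algorithm=algorithm)
            reports.append(
                cross_validate(
                    x,
                    labels,
                    cfg,
                    k=config.cv_folds,
                    repeats=config.cv_repeats,
                    seed=config.seed,
                    hidden_dim=config.hidden_dim,
                )
            )
        summary = {
            "seed": config.seed,
            "selected_features": selected,
            "ttests": {k: v.to_dict() for k, v in results.items()},
            "class_counts": patients["class"].value_counts().sort_index().to_dict(),
            "metrics": [r.to_dict() for r in reports],
        }
        (outdir / "metrics.json").write_text(json.dumps(summary, indent=2))
        (outdir / "config.json").write_text(json.dumps({"seed": config.seed, **config.to_dict()}, default=str))
        return summary
    except Exception as exc:  # pragma: no cover - error path surfaced to callers
        stage_name = list(stages)[-1] if stages else "setup"
        raise RuntimeError(f"pipeline failed in stage {stage_name!r}: {exc}") from exc
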