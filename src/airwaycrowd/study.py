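"""Study-level model object tying the pipeline stages together.

``CrowdStudy`` holds the raw study inputs (crowd results, expert
references, the task-to-subject map and subject covariates).  ``fit()``
runs validity filtering, measurement, per-task combining and the
correlation analyses, and returns a ``CrowdStudyResults`` carrying the
tables and a text ``summary()``.

The individual stages stay available as standalone functions for scripted
use and for the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .combining import MEASURE_FIELDS, Strategy, combine_dataset
from .evaluation import (
    correlation_table,
    expert_measure_table,
    per_subject_correlations,
    quality_prediction,
    threshold_sweep,
    worker_statistics,
)
from .geometry import ImageFrame
from .io import PipelineConfig
from .measures import DegenerateResultError, ExpertReference, measure_result
from .validity import TaskResult, ValiditySummary, classify_result, tabulate_validity

__all__ = [
    "CrowdStudy",
    "CrowdStudyResults",
    "classify_results_table",
    "measure_results_table",
]

logger = logging.getLogger(__name__)

DEFAULT_STRATEGIES = ("none", "random", "median", "best")


def classify_results_table(
    results: Iterable[TaskResult], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Classify every result; one row per result with status/reason/flag."""
    config = config or PipelineConfig()
    frame = config.frame
    rows = []
    for r in results:
        lab = classify_result(
            r,
            frame,
            default_size=config.default_size,
            size_tolerance=config.size_tolerance,
            corner_fraction=config.corner_fraction,
            marker_size_fraction=config.marker_size_fraction,
        )
        rows.append(
            {
                "result_id": r.result_id,
                "task_id": r.task_id,
                "worker_id": r.worker_id,
                "n_annotations": r.n_annotations,
                "status": lab.status.value,
                "reason": lab.reason.value,
                "no_airway_flag": lab.no_airway_flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "result_id", "task_id", "worker_id", "n_annotations",
            "status", "reason", "no_airway_flag",
        ],
    )


def measure_results_table(
    results: Iterable[TaskResult],
    labels: pd.DataFrame,
    frame: ImageFrame | None = None,
) -> pd.DataFrame:
    """Measure every valid result; one row per valid result, areas in mm^2.

    Degenerate results (the two ellipses have identical areas) are dropped
    with a warning.
    """
    frame = frame or ImageFrame()
    valid_ids = set(labels.loc[labels["status"] == "valid", "result_id"].astype(str))
    rows = []
    for r in results:
        if str(r.result_id) not in valid_ids:
            continue
        try:
            m = measure_result(r, frame)
        except DegenerateResultError as exc:
            logger.warning("dropping degenerate result: %s", exc)
            continue
        rows.append(
            {
                "result_id": r.result_id,
                "task_id": r.task_id,
                "worker_id": r.worker_id,
                **{f: getattr(m, f) for f in MEASURE_FIELDS},
            }
        )
    return pd.DataFrame(
        rows, columns=["result_id", "task_id", "worker_id", *MEASURE_FIELDS]
    )


@dataclass
class CrowdStudy:
    """The study inputs, ready to fit.

    Parameters
    ----------
    results : list of TaskResult
        All crowd submissions.
    experts : list of ExpertReference
        Expert area references (possibly several experts per task).
    tasks : DataFrame, optional
        ``task_id -> subject_id`` map; required for the per-subject and
        quality-prediction analyses.
    subjects : DataFrame, optional
        Subject covariates (CF status, FEV1, FVC, airway count, mean
        generation).
    config : PipelineConfig
        Frame geometry, validity thresholds, combining and evaluation
        options.
    """

    results: list[TaskResult]
    experts: list[ExpertReference]
    tasks: pd.DataFrame | None = None
    subjects: pd.DataFrame | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @classmethod
    def from_csv(
        cls,
        results_path,
        experts_path,
        tasks_path=None,
        subjects_path=None,
        config: PipelineConfig | None = None,
    ) -> "CrowdStudy":
        from . import io

        config = config or PipelineConfig()
        mapping = config.column_mapping or None
        return cls(
            results=io.read_results(results_path, mapping),
            experts=io.read_experts(experts_path, config.frame, mapping),
            tasks=io.read_tasks(tasks_path, mapping) if tasks_path else None,
            subjects=io.read_subjects(subjects_path, mapping) if subjects_path else None,
            config=config,
        )

    @classmethod
    def from_simulation(cls, seed: int, config: PipelineConfig | None = None, **kwargs) -> "CrowdStudy":
        """Build a study from the synthetic generator (see `airwaycrowd.synthetic`)."""
        from .synthetic import simulate_study

        sim = simulate_study(seed, **kwargs)
        return cls(
            results=sim["results"],
            experts=sim["experts"],
            tasks=sim["tasks"],
            subjects=sim["subjects"],
            config=config or PipelineConfig(),
        )

    def fit(
        self,
        strategies: Sequence[str] = DEFAULT_STRATEGIES,
        v: int | None = None,
        seed: int | None = None,
    ) -> "CrowdStudyResults":
        """Run the full analysis and return the results object.

        ``v`` is the minimum number of valid results a task needs to be
        combined; ``seed`` feeds the random combining strategy.  Both
        default to the config values.
        """
        cfg = self.config
        v = cfg.min_valid if v is None else v
        seed = cfg.seed if seed is None else seed
        labels = classify_results_table(self.results, cfg)
        validity = tabulate_validity_from_frame(labels)
        measurements = measure_results_table(self.results, labels, cfg.frame)
        expert_tbl = expert_measure_table(self.experts)

        first_expert = sorted(expert_tbl["expert_id"].unique())[0] if len(expert_tbl) else None
        estimates: dict[str, pd.DataFrame] = {}
        for strat in strategies:
            strat = Strategy(strat)
            expert_meas = None
            if strat is Strategy.BEST:
                if first_expert is None:
                    logger.warning("no expert references: skipping best combining")
                    continue
                expert_meas = expert_tbl[expert_tbl["expert_id"] == first_expert]
            estimates[strat.value] = combine_dataset(
                measurements, strat, seed=seed, expert_measurements=expert_meas, v=v
            )

        correlations = correlation_table(estimates, expert_tbl) if len(expert_tbl) else pd.DataFrame()
        workers = worker_statistics(labels) if len(labels) else None

        per_subject = None
        quality = None
        if (
            self.tasks is not None
            and "median" in estimates
            and len(expert_tbl)
            and not estimates["median"].empty
        ):
            per_subject = per_subject_correlations(
                estimates["median"], expert_tbl, self.tasks, expert_id=cfg.expert_id
            )
            if self.subjects is not None:
                quality = quality_prediction(
                    self.subjects,
                    per_subject.set_index("subject_id")["inner"],
                    alpha=cfg.alpha,
                )
        return CrowdStudyResults(
            study=self,
            labels=labels,
            validity=validity,
            measurements=measurements,
            expert_table=expert_tbl,
            estimates=estimates,
            correlations=correlations,
            worker_stats=workers,
            per_subject=per_subject,
            quality=quality,
            v=v,
            seed=seed,
        )


def tabulate_validity_from_frame(labels: pd.DataFrame) -> ValiditySummary:
    """ValiditySummary from a labels table (status/reason/no_airway_flag)."""
    if labels.empty:
        return ValiditySummary()
    status = labels["status"].value_counts()
    summary = ValiditySummary(
        n_total=int(len(labels)),
        n_valid=int(status.get("valid", 0)),
        n_invalid=int(status.get("invalid", 0)),
        n_multi_pair=int(status.get("multi_pair", 0)),
        n_no_airway=int(labels["no_airway_flag"].sum()),
        reason_counts=labels["reason"].value_counts().to_dict(),
    )
    return summary


@dataclass
class CrowdStudyResults:
    """Fitted study: validity accounting, estimates, correlations, prediction."""

    study: CrowdStudy
    labels: pd.DataFrame
    validity: ValiditySummary
    measurements: pd.DataFrame
    expert_table: pd.DataFrame
    estimates: dict[str, pd.DataFrame]
    correlations: pd.DataFrame
    worker_stats: dict | None
    per_subject: pd.DataFrame | None
    quality: pd.DataFrame | None
    v: int
    seed: int

    def threshold_sweep(self, v_range: Sequence[int], expert_id: str | None = None) -> pd.DataFrame:
        """Median-combined correlations for each minimum-valid threshold v."""
        return threshold_sweep(
            self.measurements, self.expert_table, v_range,
            expert_id=expert_id or self.study.config.expert_id,
        )

    def correlation_matrix(self, expert_id: str | None = None) -> pd.DataFrame:
        """Pivot the correlation reports to the strategy x measure layout."""
        if self.correlations.empty:
            return pd.DataFrame()
        df = self.correlations
        if expert_id is not None:
            df = df[df["expert_id"] == str(expert_id)]
        return df.pivot_table(
            index="strategy", columns="measure", values="rho", aggfunc="first"
        ).round(3)

    def summary(self) -> str:
        """Human-readable study report."""
        val = self.validity
        lines = [
            "Crowd airway annotation study",
            "=" * 33,
            f"results: {val.n_total}  tasks: {self.labels['task_id'].nunique() if len(self.labels) else 0}"
            f"  workers: {self.labels['worker_id'].nunique() if len(self.labels) else 0}",
            (
                f"valid: {val.n_valid} ({val.percent('valid')}%)  "
                f"invalid: {val.n_invalid} ({val.percent('invalid')}%)  "
                f"multi-pair: {val.n_multi_pair} ({val.percent('multi_pair')}%)"
            ),
            f"'no airway' markers: {val.n_no_airway}",
            "",
        ]
        for expert_id in sorted(self.expert_table["expert_id"].unique()) if len(self.expert_table) else []:
            mat = self.correlation_matrix(expert_id)
            if mat.empty:
                continue
            lines.append(f"Pearson correlations vs expert {expert_id} (v={self.v}):")
            lines.append(mat.to_string())
            lines.append("")
        if self.quality is not None:
            adj = self.quality.attrs.get("adjusted_alpha")
            lines.append(
                f"Quality prediction (Spearman, two-sided; adjusted alpha={adj:g}):"
            )
            lines.append(
                self.quality[["characteristic", "rho_s", "p_value", "significant_adjusted"]]
                .round({"rho_s": 3, "p_value": 3})
                .to_string(index=False)
            )
        return "\n".join(lines)
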