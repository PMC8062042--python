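"""Tabular readers/writers and pipeline configuration.

CSV is the single interchange format.  Dialects:

results.csv
    one row per ellipse: ``result_id, task_id, worker_id, cx, cy, a, b,
    rotation, angle_unit`` (angle_unit "rad" or "deg"; degrees are
    converted on read).
tasks.csv
    ``task_id, subject_id``.
experts.csv
    ``task_id, expert_id, inner_area, outer_area, area_unit`` ("mm2" or
    "px2"; pixel areas are converted through the frame scale on read).
subjects.csv
    ``subject_id, has_cf, fev1, fvc, n_airways, mean_generation``.

Real deposited tables may use different column names; the config carries an
optional column mapping applied before parsing, rather than guessing.
Writers never emit NaN silently: missing values become empty cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .geometry import EllipseAnnotation, ImageFrame
from .measures import ExpertReference
from .validity import DEFAULT_SIZE_TOLERANCE, DEFAULT_TOOL_SIZE, TaskResult

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "read_results",
    "write_results",
    "read_experts",
    "write_experts",
    "read_subjects",
    "read_tasks",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("result_id", "task_id", "worker_id", "cx", "cy", "a", "b", "rotation")
EXPERT_COLUMNS = ("task_id", "expert_id", "inner_area", "outer_area")
SUBJECT_COLUMNS = ("subject_id", "has_cf", "fev1", "fvc", "n_airways", "mean_generation")


class SchemaError(ValueError):
    """An input table is missing a required column."""


@dataclass
class PipelineConfig:
    """Everything the pipeline stages need, in one YAML-loadable object."""

    # image frame
    frame_width: float = 500.0
    frame_height: float = 500.0
    mm_per_pixel: float = 0.05508
    # validity thresholds
    default_size: float = DEFAULT_TOOL_SIZE
    size_tolerance: float = DEFAULT_SIZE_TOLERANCE
    corner_fraction: float = 0.2
    marker_size_fraction: float = 0.1
    # combining
    strategy: str = "median"
    min_valid: int = 1
    seed: int = 0
    # evaluation
    expert_id: str | None = None
    alpha: float = 0.05
    adjustment: str = "bonferroni"
    # io
    column_mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.default_size, self.size_tolerance, self.corner_fraction,
               self.marker_size_fraction) <= 0:
            raise ValueError("validity thresholds must be positive")
        if self.strategy not in {"none", "median", "random", "best"}:
            raise ValueError(f"unknown combining strategy {self.strategy!r}")
        if self.adjustment not in {"bonferroni", "none"}:
            raise ValueError(f"unknown adjustment {self.adjustment!r}")

    @property
    def frame(self) -> ImageFrame:
        return ImageFrame(self.frame_width, self.frame_height, self.mm_per_pixel)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _apply_mapping(df: pd.DataFrame, mapping: Mapping[str, str] | None) -> pd.DataFrame:
    # mapping: {file_column -> canonical_column}
    return df.rename(columns=dict(mapping)) if mapping else df


def _require(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_results(
    path: str | Path, column_mapping: Mapping[str, str] | None = None
) -> list[TaskResult]:
    """Read a results table (CSV or JSON records) into TaskResult objects.

    Rows are grouped by ``result_id``; an ``angle_unit`` of "deg"/"degrees"
    triggers conversion to radians.  Malformed rows (non-numeric geometry,
    non-positive axes) are skipped with their line number logged.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path)
    else:
        df = pd.read_csv(path)
    df = _apply_mapping(df, column_mapping)
    _require(df, RESULT_COLUMNS, path)
    if df.empty:
        return []

    results: dict[str, dict] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        blank = all(
            pd.isna(getattr(row, c)) or str(getattr(row, c)).strip() == ""
            for c in ("cx", "cy", "a", "b", "rotation")
        )
        if blank:  # an empty submission (zero annotations), kept as such
            results.setdefault(
                str(row.result_id),
                {"task_id": str(row.task_id), "worker_id": str(row.worker_id),
                 "ellipses": []},
            )
            continue
        try:
            unit = str(getattr(row, "angle_unit", "rad") or "rad").lower()
            rotation = float(row.rotation)
            if unit in {"deg", "degree", "degrees"}:
                rotation = math.radians(rotation)
            ellipse = EllipseAnnotation(
                center_x=float(row.cx),
                center_y=float(row.cy),
                semi_axis_a=float(row.a),
                semi_axis_b=float(row.b),
                rotation=rotation,
            )
        except (TypeError, ValueError) as exc:
            logger.warning("%s line %d: skipping malformed row (%s)", path, pos, exc)
            continue
        key = str(row.result_id)
        rec = results.setdefault(
            key,
            {"task_id": str(row.task_id), "worker_id": str(row.worker_id), "ellipses": []},
        )
        rec["ellipses"].append(ellipse)
    return [
        TaskResult(
            result_id=rid,
            task_id=rec["task_id"],
            worker_id=rec["worker_id"],
            annotations=tuple(rec["ellipses"]),
        )
        for rid, rec in results.items()
    ]


def results_to_frame(results: Iterable[TaskResult]) -> pd.DataFrame:
    """Flatten TaskResults to the one-row-per-ellipse results dialect."""
    rows = []
    for r in results:
        for e in r.annotations:
            rows.append(
                {
                    "result_id": r.result_id,
                    "task_id": r.task_id,
                    "worker_id": r.worker_id,
                    "cx": e.center_x,
                    "cy": e.center_y,
                    "a": e.semi_axis_a,
                    "b": e.semi_axis_b,
                    "rotation": e.rotation,
                    "angle_unit": "rad",
                }
            )
        if not r.annotations:  # keep empty submissions visible in the table
            rows.append(
                {
                    "result_id": r.result_id,
                    "task_id": r.task_id,
                    "worker_id": r.worker_id,
                    "cx": "",
                    "cy": "",
                    "a": "",
                    "b": "",
                    "rotation": "",
                    "angle_unit": "rad",
                }
            )
    return pd.DataFrame(rows, columns=[*RESULT_COLUMNS, "angle_unit"])


def write_results(results: Iterable[TaskResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def read_experts(
    path: str | Path,
    frame: ImageFrame | None = None,
    column_mapping: Mapping[str, str] | None = None,
) -> list[ExpertReference]:
    """Read expert references; pixel-unit areas are converted to mm^2.

    The table declares its units in an ``area_unit`` column ("mm2" default);
    conversion through ``frame.mm_per_pixel`` squared needs a frame.
    """
    path = Path(path)
    df = _apply_mapping(pd.read_csv(path), column_mapping)
    _require(df, EXPERT_COLUMNS, path)
    refs = []
    for row in df.itertuples(index=False):
        unit = str(getattr(row, "area_unit", "mm2") or "mm2").lower()
        inner, outer = float(row.inner_area), float(row.outer_area)
        if unit in {"px2", "pixel2", "pixels2", "px^2"}:
            scale = (frame or ImageFrame()).mm2_per_pixel2
            inner, outer = inner * scale, outer * scale
        refs.append(
            ExpertReference(
                task_id=str(row.task_id),
                expert_id=str(row.expert_id),
                inner_area=inner,
                outer_area=outer,
            )
        )
    return refs


def write_experts(refs: Iterable[ExpertReference], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "task_id": r.task_id,
                "expert_id": r.expert_id,
                "inner_area": r.inner_area,
                "outer_area": r.outer_area,
                "area_unit": "mm2",
            }
        for r in refs
        ]
    ).to_csv(path, index=False)


def read_subjects(
    path: str | Path, column_mapping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    df = _apply_mapping(pd.read_csv(path), column_mapping)
    _require(df, SUBJECT_COLUMNS, path)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_tasks(
    path: str | Path, column_mapping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    df = _apply_mapping(pd.read_csv(path), column_mapping)
    _require(df, ("task_id", "subject_id"), path)
    return df.astype({"task_id": str, "subject_id": str})
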