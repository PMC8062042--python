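"""Per-task aggregation of redundant crowd measurements.

Each task receives many results; after validity filtering the remaining
measurements are combined into one crowd estimate per task by one of three
strategies:

median
    Element-wise median of the inner and outer areas over the valid
    results; diameters, WT, WTR and WAP are recomputed from the median
    areas (not median-combined themselves).
random
    One uniformly drawn valid result — a pessimistic indication of the
    crowd with a single worker per task.
best
    The valid result closest to the expert reference in (inner area,
    outer area) Euclidean distance — an optimistic indication, since it
    peeks at the expert.

Tasks with no valid result produce no estimate; ``filter_min_valid``
additionally drops tasks with fewer than ``v`` valid results.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .measures import AirwayMeasurement

__all__ = [
    "Strategy",
    "CombinedEstimate",
    "combine_median",
    "combine_random",
    "combine_best",
    "filter_min_valid",
    "combine_dataset",
    "MEASURE_FIELDS",
]

MEASURE_FIELDS = (
    "inner_area",
    "outer_area",
    "inner_diameter",
    "outer_diameter",
    "wall_thickness",
    "wtr",
    "wap",
)


class Strategy(str, enum.Enum):
    NONE = "none"
    MEDIAN = "median"
    RANDOM = "random"
    BEST = "best"


@dataclass(frozen=True)
class CombinedEstimate:
    task_id: str
    strategy: Strategy
    n_valid: int
    measurement: AirwayMeasurement

    def __post_init__(self) -> None:
        if self.n_valid < 1:
            raise ValueError("a combined estimate needs at least one valid result")


def _require_nonempty(measurements: Sequence[AirwayMeasurement]) -> None:
    if len(measurements) == 0:
        raise ValueError("no valid measurements: task excluded, no estimate")


def combine_median(
    measurements: Sequence[AirwayMeasurement], task_id: str = ""
) -> CombinedEstimate:
    """Median-combine: median of areas, then derive the wall measures.

    The even-length median is the mean of the two central values (numpy
    convention).  Pairwise ``inner < outer`` guarantees the median inner
    area cannot exceed the median outer area.
    """
    _require_nonempty(measurements)
    inner = float(np.median([m.inner_area for m in measurements]))
    outer = float(np.median([m.outer_area for m in measurements]))
    return CombinedEstimate(
        task_id=task_id,
        strategy=Strategy.MEDIAN,
        n_valid=len(measurements),
        measurement=AirwayMeasurement.from_areas(inner, outer),
    )


def combine_random(
    measurements: Sequence[AirwayMeasurement],
    seed: int | np.random.Generator,
    task_id: str = "",
) -> CombinedEstimate:
    """Pick one valid result uniformly at random (reproducible by seed)."""
    _require_nonempty(measurements)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = int(rng.integers(len(measurements)))
    return CombinedEstimate(
        task_id=task_id,
        strategy=Strategy.RANDOM,
        n_valid=len(measurements),
        measurement=measurements[idx],
    )


def combine_best(
    measurements: Sequence[AirwayMeasurement],
    expert: AirwayMeasurement,
    result_ids: Sequence[str] | None = None,
    task_id: str = "",
) -> CombinedEstimate:
    """Pick the valid result closest to the expert measurement.

    Distance is Euclidean in (inner area, outer area) space; ties break
    deterministically toward the smallest result id (or lowest index when
    ids are not supplied).
    """
    _require_nonempty(measurements)
    if result_ids is not None and len(result_ids) != len(measurements):
        raise ValueError("result_ids must align with measurements")
    dist = np.hypot(
        np.array([m.inner_area for m in measurements]) - expert.inner_area,
        np.array([m.outer_area for m in measurements]) - expert.outer_area,
    )
    best = np.flatnonzero(dist == dist.min())
    if len(best) > 1 and result_ids is not None:
        idx = int(min(best, key=lambda i: str(result_ids[i])))
    else:
        idx = int(best[0])
    return CombinedEstimate(
        task_id=task_id,
        strategy=Strategy.BEST,
        n_valid=len(measurements),
        measurement=measurements[idx],
    )


def filter_min_valid(
    valid_by_task: Mapping[str, Sequence[AirwayMeasurement]] | pd.DataFrame,
    v: int,
) -> Mapping[str, Sequence[AirwayMeasurement]] | pd.DataFrame:
    """Keep only tasks with at least ``v`` valid results.

    Accepts either a mapping ``task_id -> measurements`` or a measurements
    table with a ``task_id`` column, and returns the same kind.
    """
    if v < 1:
        raise ValueError("v must be >= 1")
    if isinstance(valid_by_task, pd.DataFrame):
        counts = valid_by_task.groupby("task_id")["task_id"].transform("size")
        return valid_by_task[counts >= v]
    return {t: ms for t, ms in valid_by_task.items() if len(ms) >= v}


def _row_to_measurement(row: pd.Series) -> AirwayMeasurement:
    return AirwayMeasurement.from_areas(float(row["inner_area"]), float(row["outer_area"]))


def combine_dataset(
    measurements: pd.DataFrame,
    strategy: Strategy | str,
    seed: int | None = None,
    expert_measurements: pd.DataFrame | None = None,
    v: int = 1,
) -> pd.DataFrame:
    """Combine a full measurements table into one estimate per task.

    Parameters
    ----------
    measurements : DataFrame
        Valid-result measurements with columns ``result_id``, ``task_id``
        and the measure fields.
    strategy : Strategy
        ``median``, ``random`` or ``best`` (``none`` is a pass-through that
        keeps every individual result as its own row).
    seed : int, optional
        Required for the random strategy.  One stream serves the whole
        dataset; tasks are visited in sorted task-id order, so the draw
        does not depend on input row order.
    expert_measurements : DataFrame, optional
        Required for ``best``: columns ``task_id``, ``inner_area``,
        ``outer_area`` for one expert.
    v : int
        Minimum number of valid results per task (tasks below are dropped).

    Returns
    -------
    DataFrame with columns ``task_id``, ``strategy``, ``n_valid`` and the
    measure fields, one row per retained task (or per result for ``none``).
    """
    strategy = Strategy(strategy)
    kept = filter_min_valid(measurements, v)
    if strategy is Strategy.NONE:
        out = kept.copy()
        out["strategy"] = Strategy.NONE.value
        out["n_valid"] = kept.groupby("task_id")["task_id"].transform("size")
        cols = ["task_id", "result_id", "strategy", "n_valid", *MEASURE_FIELDS]
        return out[[c for c in cols if c in out.columns]].reset_index(drop=True)

    rng = np.random.default_rng(seed) if strategy is Strategy.RANDOM else None
    expert_by_task: dict[str, AirwayMeasurement] = {}
    if strategy is Strategy.BEST:
        if expert_measurements is None:
            raise ValueError("best combining requires expert measurements")
        for _, row in expert_measurements.iterrows():
            expert_by_task[str(row["task_id"])] = _row_to_measurement(row)

    rows = []
    for task_id, grp in sorted(kept.groupby("task_id"), key=lambda kv: str(kv[0])):
        if "result_id" in grp:  # input row order must not matter
            grp = grp.sort_values("result_id", key=lambda s: s.astype(str))
        ms = [_row_to_measurement(r) for _, r in grp.iterrows()]
        ids = [str(r) for r in grp["result_id"]] if "result_id" in grp else None
        if strategy is Strategy.MEDIAN:
            est = combine_median(ms, task_id=str(task_id))
        elif strategy is Strategy.RANDOM:
            est = combine_random(ms, rng, task_id=str(task_id))
        else:
            expert = expert_by_task.get(str(task_id))
            if expert is None:
                continue  # no reference for this task: no "best" estimate
            est = combine_best(ms, expert, result_ids=ids, task_id=str(task_id))
        rows.append(
            {
                "task_id": est.task_id,
                "strategy": est.strategy.value,
                "n_valid": est.n_valid,
                **{f: getattr(est.measurement, f) for f in MEASURE_FIELDS},
            }
        )
    return pd.DataFrame(
        rows, columns=["task_id", "strategy", "n_valid", *MEASURE_FIELDS]
    )
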