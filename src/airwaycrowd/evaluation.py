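"""Crowd-vs-expert evaluation and subject-level quality prediction.

Covers the reporting side of the study: Pearson correlations between crowd
estimates and expert references for the four measures (inner area, outer
area, WAP, WTR) under each combining strategy; correlation strength bands;
the sweep over the minimum-valid-results threshold; per-worker validity
statistics; and the Spearman analysis relating per-subject crowd quality to
subject characteristics (CF status, FEV1, FVC, airway count, mean airway
generation) with a Bonferroni-adjusted significance threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .combining import MEASURE_FIELDS, Strategy, combine_dataset
from .measures import AirwayMeasurement

__all__ = [
    "SubjectRecord",
    "CorrelationReport",
    "WorkerSummary",
    "pearson",
    "interpret_strength",
    "correlation_table",
    "threshold_sweep",
    "spearman_with_p",
    "spearman_pvalue",
    "bonferroni_threshold",
    "quality_prediction",
    "worker_statistics",
    "expert_measure_table",
    "per_subject_correlations",
    "QUALITY_CHARACTERISTICS",
]

logger = logging.getLogger(__name__)

#: Report-level measures and the measurement columns they map to.
MEASURES = {"inner": "inner_area", "outer": "outer_area", "wap": "wap", "wtr": "wtr"}

#: The five subject characteristics tested against crowd quality.
QUALITY_CHARACTERISTICS = ("has_cf", "fev1", "fvc", "n_airways", "mean_generation")


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject covariates used in quality prediction."""

    subject_id: str
    has_cf: bool
    fev1: float
    fvc: float
    n_airways: int
    mean_generation: float

    def __post_init__(self) -> None:
        if self.n_airways < 1:
            raise ValueError("n_airways must be >= 1")
        if self.fev1 <= 0 or self.fvc <= 0:
            raise ValueError("FEV1 and FVC must be positive")


@dataclass(frozen=True)
class CorrelationReport:
    measure: str
    strategy: str
    expert_id: str
    rho: float
    n_tasks: int
    strength: str


@dataclass(frozen=True)
class WorkerSummary:
    worker_id: str
    n_results: int
    n_valid: int
    n_invalid: int
    n_multi_pair: int

    def __post_init__(self) -> None:
        if self.n_valid + self.n_invalid + self.n_multi_pair != self.n_results:
            raise ValueError("per-worker counts must partition the result count")


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN pairs dropped, constant input -> NaN.

    A constant side leaves the coefficient undefined; it is reported as
    missing (NaN), never coerced to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def interpret_strength(rho: float) -> str:
    """Correlation band: weak [0, 0.3), moderate [0.3, 0.5), strong [0.5, 1].

    Negative coefficients are banded by magnitude (the bands are defined for
    non-negative rho); NaN maps to "undefined".
    """
    if np.isnan(rho):
        return "undefined"
    r = abs(rho)
    if r < 0.3:
        return "weak"
    if r < 0.5:
        return "moderate"
    return "strong"


def expert_measure_table(expert_refs: Iterable) -> pd.DataFrame:
    """Expand expert references into a full per-measure table.

    Accepts ``ExpertReference`` objects or a DataFrame with ``task_id``,
    ``expert_id``, ``inner_area``, ``outer_area``; returns one row per
    (task, expert) with all measure fields derived under the circular-airway
    assumption.
    """
    if isinstance(expert_refs, pd.DataFrame):
        records = expert_refs.to_dict("records")
    else:
        records = [
            {
                "task_id": r.task_id,
                "expert_id": r.expert_id,
                "inner_area": r.inner_area,
                "outer_area": r.outer_area,
            }
            for r in expert_refs
        ]
    rows = []
    for rec in records:
        m = AirwayMeasurement.from_areas(float(rec["inner_area"]), float(rec["outer_area"]))
        rows.append(
            {
                "task_id": str(rec["task_id"]),
                "expert_id": str(rec["expert_id"]),
                **{f: getattr(m, f) for f in MEASURE_FIELDS},
            }
        )
    return pd.DataFrame(rows, columns=["task_id", "expert_id", *MEASURE_FIELDS])


def _paired_rho(crowd: pd.DataFrame, expert: pd.DataFrame, column: str) -> tuple[float, int]:
    merged = crowd.merge(expert, on="task_id", suffixes=("_crowd", "_expert"))
    rho = pearson(merged[f"{column}_crowd"], merged[f"{column}_expert"])
    return rho, len(merged)


def correlation_table(
    estimates_by_strategy: Mapping[str, pd.DataFrame],
    expert_table: pd.DataFrame,
    measures: Sequence[str] = tuple(MEASURES),
) -> pd.DataFrame:
    """Crowd-vs-expert Pearson correlations per (strategy, expert, measure).

    ``estimates_by_strategy`` maps a strategy name to an estimates table
    (the "none" strategy keeps each individual valid result as its own pair,
    reusing the task's expert value).  Also reports every expert-vs-expert
    pair when ``expert_table`` holds more than one expert.  Combinations
    with fewer than two comparable tasks are skipped with a warning.
    """
    experts = sorted(expert_table["expert_id"].unique())
    rows: list[CorrelationReport] = []
    for strategy, est in estimates_by_strategy.items():
        for expert_id in experts:
            etab = expert_table[expert_table["expert_id"] == expert_id]
            for meas in measures:
                col = MEASURES[meas]
                rho, n = _paired_rho(est, etab, col)
                if n < 2:
                    logger.warning(
                        "skipping %s vs expert %s (%s): fewer than 2 pairs",
                        strategy, expert_id, meas,
                    )
                    continue
                rows.append(
                    CorrelationReport(meas, str(strategy), str(expert_id), rho, n,
                                      interpret_strength(rho))
                )
    for i, e1 in enumerate(experts):
        for e2 in experts[i + 1:]:
            t1 = expert_table[expert_table["expert_id"] == e1]
            t2 = expert_table[expert_table["expert_id"] == e2]
            for meas in measures:
                rho, n = _paired_rho(t1, t2, MEASURES[meas])
                if n < 2:
                    continue
                rows.append(
                    CorrelationReport(meas, f"expert_{e1}", str(e2), rho, n,
                                      interpret_strength(rho))
                )
    return pd.DataFrame([r.__dict__ for r in rows])


def threshold_sweep(
    measurements: pd.DataFrame,
    expert_table: pd.DataFrame,
    v_range: Sequence[int],
    expert_id: str | None = None,
    measures: Sequence[str] = tuple(MEASURES),
) -> pd.DataFrame:
    """Median-combined correlation as a function of the min-valid threshold v.

    For each v, tasks with fewer than v valid results are dropped before
    median combining; the retained-task count is reported alongside each
    coefficient.  An empty retained set yields NaN for that v.
    """
    if expert_id is None:
        expert_id = sorted(expert_table["expert_id"].unique())[0]
    etab = expert_table[expert_table["expert_id"] == str(expert_id)]
    rows = []
    for v in v_range:
        est = combine_dataset(measurements, Strategy.MEDIAN, v=int(v))
        for meas in measures:
            if est.empty:
                rho, n = float("nan"), 0
            else:
                rho, n = _paired_rho(est, etab, MEASURES[meas])
            rows.append({"v": int(v), "measure": meas, "rho": rho, "n_tasks": n})
    return pd.DataFrame(rows)


def spearman_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ranks use averages for ties (so a binary covariate such as CF status is
    handled through tied ranks); the p-value comes from
    ``t = rho_s * sqrt((n-2) / (1-rho_s^2))`` on n-2 degrees of freedom.
    All-tied input leaves the coefficient undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho_s = pearson(stats.rankdata(x), stats.rankdata(y))
    return rho_s, spearman_pvalue(rho_s, n)


def spearman_pvalue(rho_s: float, n: int) -> float:
    """Two-sided p for a Spearman coefficient at sample size n (t-approximation)."""
    if abs(rho_s) >= 1.0:
        return 0.0
    t = rho_s * np.sqrt((n - 2) / (1.0 - rho_s ** 2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Per-test significance threshold after Bonferroni adjustment."""
    return alpha / n_comparisons


def quality_prediction(
    subjects: pd.DataFrame,
    quality: pd.Series | Mapping[str, float],
    characteristics: Sequence[str] = QUALITY_CHARACTERISTICS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Relate per-subject crowd quality to subject characteristics.

    ``quality`` maps subject_id to the crowd-vs-expert inner-airway Pearson
    correlation after median combining (the proxy for crowd quality on that
    subject).  Each characteristic is tested with a two-sided Spearman test;
    significance is flagged at the raw ``alpha`` and at the
    Bonferroni-adjusted ``alpha / len(characteristics)``.  Subjects with a
    missing covariate or quality value are dropped with a warning.
    """
    quality = pd.Series(quality)
    quality.index = quality.index.astype(str)
    df = subjects.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["_quality"] = df["subject_id"].map(quality)
    complete = df.dropna(subset=["_quality", *characteristics])
    if len(complete) < len(df):
        logger.warning("dropped %d subject(s) with missing values", len(df) - len(complete))
    adj = bonferroni_threshold(alpha, len(characteristics))
    rows = []
    for char in characteristics:
        rho_s, p = spearman_with_p(
            complete[char].astype(float), complete["_quality"].astype(float)
        )
        rows.append(
            {
                "characteristic": char,
                "rho_s": rho_s,
                "p_value": p,
                "n_subjects": len(complete),
                "significant_raw": bool(p < alpha) if np.isfinite(p) else False,
                "significant_adjusted": bool(p < adj) if np.isfinite(p) else False,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["adjusted_alpha"] = adj
    return out


def worker_statistics(labeled: pd.DataFrame) -> dict:
    """Per-worker validity tallies, cumulative output curve and a linear fit.

    ``labeled`` needs columns ``worker_id`` and ``status`` (one row per
    result).  Returns a dict with

    summaries
        DataFrame of per-worker counts (results, valid, invalid, multi-pair).
    cumulative
        Workers sorted by output (most productive first) with the cumulative
        fraction of all results they account for.
    fit
        Ordinary-least-squares slope and intercept of n_valid against
        n_invalid across workers.
    """
    counts = (
        labeled.groupby("worker_id")["status"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["valid", "invalid", "multi_pair"], fill_value=0)
    )
    summaries = pd.DataFrame(
        {
            "worker_id": counts.index.astype(str),
            "n_results": counts.sum(axis=1).to_numpy(),
            "n_valid": counts["valid"].to_numpy(),
            "n_invalid": counts["invalid"].to_numpy(),
            "n_multi_pair": counts["multi_pair"].to_numpy(),
        }
    ).reset_index(drop=True)

    ordered = summaries.sort_values("n_results", ascending=False, ignore_index=True)
    cumulative = ordered[["worker_id", "n_results"]].copy()
    cumulative["cumulative_fraction"] = (
        cumulative["n_results"].cumsum() / cumulative["n_results"].sum()
    )

    x = summaries["n_invalid"].to_numpy(dtype=float)
    y = summaries["n_valid"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        slope, intercept = float("nan"), float(y.mean())
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
    return {
        "summaries": summaries,
        "cumulative": cumulative,
        "fit": {"slope": slope, "intercept": intercept},
    }


def per_subject_correlations(
    estimates: pd.DataFrame,
    expert_table: pd.DataFrame,
    tasks: pd.DataFrame,
    expert_id: str | None = None,
    measures: Sequence[str] = tuple(MEASURES),
) -> pd.DataFrame:
    """Crowd-vs-expert correlations computed within each subject.

    ``tasks`` maps task_id to subject_id.  Returns one row per subject with
    the task count and a correlation per measure — the layout of the
    per-subject characteristics table.
    """
    if expert_id is None:
        expert_id = sorted(expert_table["expert_id"].unique())[0]
    etab = expert_table[expert_table["expert_id"] == str(expert_id)]
    tasks = tasks.copy()
    tasks["task_id"] = tasks["task_id"].astype(str)
    est = estimates.copy()
    est["task_id"] = est["task_id"].astype(str)
    merged = est.merge(etab, on="task_id", suffixes=("_crowd", "_expert")).merge(
        tasks[["task_id", "subject_id"]], on="task_id"
    )
    rows = []
    for subject_id, grp in merged.groupby("subject_id"):
        row = {"subject_id": str(subject_id), "n_tasks": len(grp)}
        for meas in measures:
            col = MEASURES[meas]
            row[meas] = pearson(grp[f"{col}_crowd"], grp[f"{col}_expert"])
        rows.append(row)
    return pd.DataFrame(rows).sort_values("subject_id", ignore_index=True)
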