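"""Synthetic cohort, crowd and expert simulation.

Emulates the statistical structure of a crowdsourced airway-annotation
study: a cohort of subjects each contributing a set of airway tasks, a
population of several hundred workers with heavy-tailed productivity, 20
redundant results per task, and the observed invalid-result modes — the
single "no airway" corner circle, unresized default circles, lone sloppy
ellipses, non-overlapping or random (spam) submissions, and multi-pair
results.

Worker noise is multiplicative on the ellipse radii (relative outlining
error), not additive on areas: relative error is the natural model for an
outlining task, and it lets the noise amplification of the ratio measures
(WAP, WTR) emerge from the geometry instead of being injected.

Every public operation takes an explicit seed; one master seed derives
independent per-stream sub-seeds deterministically.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import EllipseAnnotation, ImageFrame
from .measures import ExpertReference
from .validity import DEFAULT_TOOL_SIZE, TaskResult

__all__ = [
    "Behavior",
    "WorkerProfile",
    "GroundTruthAirway",
    "CohortConfig",
    "CrowdConfig",
    "generate_cohort",
    "generate_workers",
    "simulate_crowd",
    "simulate_experts",
    "simulate_study",
    "DEFAULT_BEHAVIOR_MIXTURE",
]


class Behavior(str, enum.Enum):
    CAREFUL = "careful"
    NO_AIRWAY_PRONE = "no_airway_prone"
    NON_RESIZER = "non_resizer"
    SLOPPY_SINGLE = "sloppy_single"
    SPAMMER = "spammer"


#: Default behavior mixture.  Chosen so the valid-result share lands in the
#: low-forties regime (invalid share in the high fifties, multi-pair around
#: 3%), matching the magnitude reported in crowdsourced airway annotation.
DEFAULT_BEHAVIOR_MIXTURE: dict[Behavior, float] = {
    Behavior.CAREFUL: 0.43,
    Behavior.NO_AIRWAY_PRONE: 0.12,
    Behavior.NON_RESIZER: 0.16,
    Behavior.SLOPPY_SINGLE: 0.14,
    Behavior.SPAMMER: 0.15,
}

#: Ellipse-count distribution for spam submissions; the >=4 tail is what
#: produces multi-pair exclusions (0.15 spam share x 0.20 tail = 3%).
_SPAM_COUNTS = np.array([1, 2, 3, 4, 5])
_SPAM_COUNT_PROBS = np.array([0.30, 0.30, 0.20, 0.15, 0.05])


@dataclass(frozen=True)
class WorkerProfile:
    """One simulated crowd worker.

    ``noise_scale`` is the relative (log-normal sigma) outlining error on
    ellipse radii; ``center_jitter`` the placement error in pixels;
    ``productivity`` the worker's relative propensity to pick up tasks
    (heavy-tailed across the population).
    """

    worker_id: str
    behavior: Behavior
    noise_scale: float = 0.10
    center_jitter: float = 3.0
    productivity: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.productivity < 1:
            raise ValueError("productivity must be >= 1")


@dataclass(frozen=True)
class GroundTruthAirway:
    """True geometry of one airway task.

    Radii are in mm (equivalent-circle convention); ``eccentricity`` is the
    minor/major axis ratio of the drawn ellipses; ``difficulty`` in [0, 1]
    modulates how often workers fail to see the airway.
    """

    task_id: str
    subject_id: str
    true_inner_radius: float
    true_wall_thickness: float
    eccentricity: float = 1.0
    difficulty: float = 0.5

    def __post_init__(self) -> None:
        if self.true_inner_radius <= 0 or self.true_wall_thickness <= 0:
            raise ValueError("radii must be positive")
        if not 0 < self.eccentricity <= 1:
            raise ValueError("eccentricity (axis ratio) must be in (0, 1]")

    @property
    def true_outer_radius(self) -> float:
        return self.true_inner_radius + self.true_wall_thickness

    @property
    def true_inner_area(self) -> float:
        return math.pi * self.true_inner_radius ** 2

    @property
    def true_outer_area(self) -> float:
        return math.pi * self.true_outer_radius ** 2

    @property
    def true_wtr(self) -> float:
        # WT / d_o with d_o = 2 * (r_i + WT); always in (0, 0.5).
        return self.true_wall_thickness / (2.0 * self.true_outer_radius)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings.

    Defaults target a study of 24 subjects and roughly a thousand tasks in
    total (tasks per subject uniform on the given range).  Inner radii are
    log-normal around ~1.4 mm with sigma 0.4 (airway calibres spanning
    several generations); the wall is ~30% of the lumen radius with 5%
    relative spread, which keeps the implied WTR inside (0, 0.5) by
    construction.  ``difficulty_effect`` optionally couples CF status to
    task difficulty (zero by default: no planted subject-level effect).
    """

    n_subjects: int = 24
    tasks_per_subject: tuple[int, int] = (20, 66)
    inner_radius_log_mean: float = math.log(1.4)
    inner_radius_log_sigma: float = 0.4
    wall_fraction_mean: float = 0.30
    wall_fraction_sigma: float = 0.05
    min_axis_ratio: float = 0.8
    cf_prevalence: float = 0.5
    difficulty_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.tasks_per_subject
        if not (1 <= lo <= hi):
            raise ValueError("tasks_per_subject must be an increasing positive range")
        if self.wall_fraction_mean <= 0:
            raise ValueError("wall_fraction_mean must be positive")


@dataclass(frozen=True)
class CrowdConfig:
    """Crowd-level generator settings (worker population and redundancy)."""

    n_workers: int = 577
    results_per_task: int = 20
    behavior_mixture: Mapping[Behavior, float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_MIXTURE)
    )
    careful_noise_mean: float = 0.10
    careful_noise_sigma: float = 0.03
    productivity_log_sigma: float = 1.3
    default_tool_size: float = DEFAULT_TOOL_SIZE

    def __post_init__(self) -> None:
        if self.results_per_task < 1:
            raise ValueError("results_per_task must be >= 1")
        if self.n_workers < self.results_per_task:
            raise ValueError("need at least results_per_task distinct workers")
        if not self.behavior_mixture:
            raise ValueError("behavior mixture must be non-empty")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(
    seed: int, config: CohortConfig | None = None
) -> tuple[list[GroundTruthAirway], pd.DataFrame]:
    """Generate ground-truth airways and the subject covariate table.

    Returns the task-level truth and a subjects DataFrame with columns
    ``subject_id, has_cf, fev1, fvc, n_airways, mean_generation`` (FEV1 and
    FVC as percent of predicted, airway generation averaged per subject).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    truth: list[GroundTruthAirway] = []
    subject_rows = []
    lo, hi = config.tasks_per_subject
    for s in range(config.n_subjects):
        subject_id = f"S{s:02d}"
        n_tasks = int(rng.integers(lo, hi + 1))
        has_cf = bool(rng.random() < config.cf_prevalence)
        fev1 = float(np.clip(rng.normal(88.0, 18.0), 40.0, 140.0))
        fvc = float(np.clip(rng.normal(97.0, 17.0), 50.0, 140.0))
        mean_generation = float(np.clip(rng.normal(6.5, 0.8), 3.0, 10.0))
        subject_rows.append(
            {
                "subject_id": subject_id,
                "has_cf": int(has_cf),
                "fev1": round(fev1, 1),
                "fvc": round(fvc, 1),
                "n_airways": n_tasks,
                "mean_generation": round(mean_generation, 2),
            }
        )
        for t in range(n_tasks):
            r_i = float(
                rng.lognormal(config.inner_radius_log_mean, config.inner_radius_log_sigma)
            )
            wall_frac = float(
                np.clip(
                    rng.normal(config.wall_fraction_mean, config.wall_fraction_sigma),
                    0.05,
                    0.95,
                )
            )
            difficulty = float(rng.beta(2.0, 2.0))
            if config.difficulty_effect != 0.0:
                difficulty = float(
                    np.clip(
                        difficulty + config.difficulty_effect * (has_cf - 0.5), 0.0, 1.0
                    )
                )
            truth.append(
                GroundTruthAirway(
                    task_id=f"{subject_id}_T{t:03d}",
                    subject_id=subject_id,
                    true_inner_radius=r_i,
                    true_wall_thickness=wall_frac * r_i,
                    eccentricity=float(rng.uniform(config.min_axis_ratio, 1.0)),
                    difficulty=difficulty,
                )
            )
    return truth, pd.DataFrame(subject_rows)


def _quota_assignment(n: int, mixture: Mapping[Behavior, float]) -> list[Behavior]:
    """Assign behaviors to n ranked slots, tracking the target shares at
    every prefix (largest-deficit quota method).

    Workers are ranked by productivity before assignment, so each
    productivity stratum carries the configured mixture: with a heavy-tailed
    productivity distribution, an i.i.d. assignment would make the
    productivity-weighted behavior shares (and hence the realized
    valid-result fraction) strongly seed-dependent.
    """
    names = list(mixture)
    shares = np.array([mixture[b] for b in names], dtype=float)
    shares = shares / shares.sum()
    assigned = np.zeros(len(names))
    out: list[Behavior] = []
    for i in range(n):
        deficit = shares * (i + 1) - assigned
        j = int(np.argmax(deficit))
        assigned[j] += 1
        out.append(names[j])
    return out


def generate_workers(seed: int, config: CrowdConfig | None = None) -> list[WorkerProfile]:
    """Generate the worker population: heavy-tailed productivity, mixed behavior."""
    config = config or CrowdConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = config.n_workers
    productivity = 1.0 + rng.lognormal(0.0, config.productivity_log_sigma, size=n)
    noise = np.clip(
        rng.normal(config.careful_noise_mean, config.careful_noise_sigma, size=n),
        0.02,
        0.30,
    )
    jitter = rng.uniform(1.0, 5.0, size=n)
    order = np.argsort(-productivity)  # most productive first
    behaviors = _quota_assignment(n, config.behavior_mixture)
    workers = [None] * n
    for rank, idx in enumerate(order):
        workers[idx] = WorkerProfile(
            worker_id=f"W{idx:04d}",
            behavior=behaviors[rank],
            noise_scale=float(noise[idx]),
            center_jitter=float(jitter[idx]),
            productivity=float(productivity[idx]),
        )
    return list(workers)


def _truth_ellipse_axes(radius_px: float, axis_ratio: float) -> tuple[float, float]:
    # Semi-axes preserving the equivalent-circle area pi * r^2.
    return radius_px / math.sqrt(axis_ratio), radius_px * math.sqrt(axis_ratio)


def _careful_pair(
    truth: GroundTruthAirway,
    worker: WorkerProfile,
    frame: ImageFrame,
    rng: np.random.Generator,
) -> tuple[EllipseAnnotation, EllipseAnnotation]:
    cx = frame.width / 2.0 + rng.normal(0.0, worker.center_jitter)
    cy = frame.height / 2.0 + rng.normal(0.0, worker.center_jitter)
    theta = float(rng.uniform(0.0, math.pi))
    sigma = worker.noise_scale
    ellipses = []
    for radius_mm in (truth.true_inner_radius, truth.true_outer_radius):
        a, b = _truth_ellipse_axes(radius_mm / frame.mm_per_pixel, truth.eccentricity)
        ellipses.append(
            EllipseAnnotation(
                center_x=cx + rng.normal(0.0, worker.center_jitter),
                center_y=cy + rng.normal(0.0, worker.center_jitter),
                semi_axis_a=a * float(rng.lognormal(0.0, sigma)),
                semi_axis_b=b * float(rng.lognormal(0.0, sigma)),
                rotation=theta,
            )
        )
    return ellipses[0], ellipses[1]


def _corner_marker(frame: ImageFrame, rng: np.random.Generator) -> EllipseAnnotation:
    r = float(rng.uniform(5.0, 12.0))
    cx = float(np.clip(0.94 * frame.width + rng.normal(0.0, 3.0),
                       0.85 * frame.width, frame.width - r))
    cy = float(np.clip(0.06 * frame.height + rng.normal(0.0, 3.0),
                       r, 0.15 * frame.height))
    return EllipseAnnotation(cx, cy, r, r, 0.0)


def _default_circle(
    frame: ImageFrame, size: float, rng: np.random.Generator
) -> EllipseAnnotation:
    # The unresized tool circle, dragged into place but never resized.
    wobble = float(rng.uniform(-0.005, 0.005))
    r = size * (1.0 + wobble)
    return EllipseAnnotation(
        frame.width / 2.0 + rng.normal(0.0, 15.0),
        frame.height / 2.0 + rng.normal(0.0, 15.0),
        r,
        r,
        0.0,
    )


def _spam_ellipses(
    frame: ImageFrame, rng: np.random.Generator
) -> tuple[EllipseAnnotation, ...]:
    k = int(rng.choice(_SPAM_COUNTS, p=_SPAM_COUNT_PROBS))
    out = []
    for _ in range(k):
        out.append(
            EllipseAnnotation(
                float(rng.uniform(0.1, 0.9) * frame.width),
                float(rng.uniform(0.1, 0.9) * frame.height),
                float(rng.uniform(5.0, 120.0)),
                float(rng.uniform(5.0, 120.0)),
                float(rng.uniform(0.0, math.pi)),
            )
        )
    return tuple(out)


def simulate_crowd(
    truth: Sequence[GroundTruthAirway],
    workers: Sequence[WorkerProfile],
    seed: int,
    results_per_task: int = 20,
    frame: ImageFrame | None = None,
    default_tool_size: float = DEFAULT_TOOL_SIZE,
) -> tuple[list[TaskResult], pd.DataFrame]:
    """Simulate the crowd: ``results_per_task`` distinct workers per task.

    Workers are drawn per task with probability proportional to
    productivity, which produces the heavy-tailed per-worker output counts
    seen in real crowds.  Emission per behavior:

    * careful — two concentric noisy ellipses around the truth;
    * no_airway_prone — the top-right corner marker, with probability
      increasing in task difficulty (0.8 + 0.2 * difficulty), otherwise a
      careful pair;
    * non_resizer — two unresized default circles dragged onto the airway;
    * sloppy_single — one resized ellipse on the airway, never the pair;
    * spammer — 1 to 5 random ellipses anywhere in the frame.

    Returns the results and a log with one row per result: worker behavior,
    the emitted mode, and the validity label the generator intends
    (``expected_status``/``expected_reason``, empty for spam, whose label
    depends on its random geometry).
    """
    if not workers:
        raise ValueError("worker list must be non-empty")
    frame = frame or ImageFrame()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    prod = np.array([w.productivity for w in workers], dtype=float)
    prob = prod / prod.sum()
    results: list[TaskResult] = []
    log_rows = []
    rid = 0
    for task in truth:
        chosen = rng.choice(len(workers), size=results_per_task, replace=False, p=prob)
        for widx in chosen:
            worker = workers[int(widx)]
            mode = worker.behavior
            if worker.behavior is Behavior.NO_AIRWAY_PRONE:
                p_marker = 0.8 + 0.2 * task.difficulty
                if rng.random() >= p_marker:
                    mode = Behavior.CAREFUL

            expected_status, expected_reason, no_airway = "", "", False
            if mode is Behavior.CAREFUL:
                annotations = _careful_pair(task, worker, frame, rng)
                expected_status, expected_reason = "valid", "ok"
            elif mode is Behavior.NO_AIRWAY_PRONE:
                annotations = (_corner_marker(frame, rng),)
                expected_status, expected_reason = "invalid", "wrong_ellipse_count"
                no_airway = True
            elif mode is Behavior.NON_RESIZER:
                annotations = (
                    _default_circle(frame, default_tool_size, rng),
                    _default_circle(frame, default_tool_size, rng),
                )
                expected_status, expected_reason = "invalid", "not_resized"
            elif mode is Behavior.SLOPPY_SINGLE:
                inner, _ = _careful_pair(task, worker, frame, rng)
                annotations = (inner,)
                expected_status, expected_reason = "invalid", "wrong_ellipse_count"
            else:  # spammer: expected label undetermined
                annotations = _spam_ellipses(frame, rng)

            result_id = f"R{rid:06d}"
            rid += 1
            results.append(
                TaskResult(
                    result_id=result_id,
                    task_id=task.task_id,
                    worker_id=worker.worker_id,
                    annotations=tuple(annotations),
                )
            )
            log_rows.append(
                {
                    "result_id": result_id,
                    "task_id": task.task_id,
                    "worker_id": worker.worker_id,
                    "behavior": worker.behavior.value,
                    "emitted_mode": mode.value,
                    "expected_status": expected_status,
                    "expected_reason": expected_reason,
                    "expected_no_airway": no_airway,
                }
            )
    return results, pd.DataFrame(log_rows)


def simulate_experts(
    truth: Sequence[GroundTruthAirway],
    seed: int,
    expert_noise_scale: float = 0.05,
    n_experts: int = 2,
) -> list[ExpertReference]:
    """Simulate expert area measurements with multiplicative log-normal noise.

    Each expert measures every task's true inner and outer area with
    independent relative error of the given scale.  Two experts allow the
    expert-vs-expert correlation row of the report.
    """
    if n_experts < 1:
        raise ValueError("n_experts must be >= 1")
    if expert_noise_scale < 0:
        raise ValueError("expert noise scale must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    refs: list[ExpertReference] = []
    for expert in range(1, n_experts + 1):
        for task in truth:
            inner = task.true_inner_area * float(rng.lognormal(0.0, expert_noise_scale))
            outer = task.true_outer_area * float(rng.lognormal(0.0, expert_noise_scale))
            if inner >= outer:  # extreme draws on thin walls: keep ordering
                inner = 0.95 * outer
            refs.append(
                ExpertReference(
                    task_id=task.task_id,
                    expert_id=str(expert),
                    inner_area=inner,
                    outer_area=outer,
                )
            )
    return refs


def simulate_study(
    seed: int,
    cohort_config: CohortConfig | None = None,
    crowd_config: CrowdConfig | None = None,
    frame: ImageFrame | None = None,
    expert_noise_scale: float = 0.05,
    n_experts: int = 2,
) -> dict:
    """Run the full generator: cohort, workers, crowd results and experts.

    Returns a dict with keys ``truth``, ``subjects``, ``tasks``, ``workers``,
    ``results``, ``log``, ``experts``, ``frame``.  Sub-streams are derived
    from the master seed, so a seed fully determines the study.
    """
    crowd_config = crowd_config or CrowdConfig()
    rng_cohort, rng_workers, rng_crowd, rng_experts = (
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(4)
    )
    frame = frame or ImageFrame()
    truth, subjects = generate_cohort(rng_cohort, cohort_config)
    workers = generate_workers(rng_workers, crowd_config)
    results, log = simulate_crowd(
        truth,
        workers,
        rng_crowd,
        results_per_task=crowd_config.results_per_task,
        frame=frame,
        default_tool_size=crowd_config.default_tool_size,
    )
    experts = simulate_experts(
        truth, rng_experts, expert_noise_scale=expert_noise_scale, n_experts=n_experts
    )
    tasks = pd.DataFrame(
        {"task_id": [t.task_id for t in truth], "subject_id": [t.subject_id for t in truth]}
    )
    return {
        "truth": truth,
        "subjects": subjects,
        "tasks": tasks,
        "workers": workers,
        "results": results,
        "log": log,
        "experts": experts,
        "frame": frame,
    }
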