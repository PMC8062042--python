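"""Validity filtering of crowd results.

A result (one worker's submission for one task) is kept only when it
consists of exactly two resized, overlapping ellipses.  Everything else is
excluded before measurement:

* wrong ellipse count (including the single "no airway" corner marker),
* unresized ellipses (the annotation tool starts from a default circle;
  a submission that leaves it untouched carries no measurement),
* two ellipses that do not overlap,
* results with multiple pairs of ellipses (>= 4 annotations), excluded as a
  separate category rather than folded into the wrong-count invalids.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .geometry import EllipseAnnotation, ImageFrame, is_corner_marker, ellipses_overlap

__all__ = [
    "Status",
    "Reason",
    "TaskResult",
    "ValidityLabel",
    "ValiditySummary",
    "classify_result",
    "tabulate_validity",
]

#: Default tool size (pixels) of the unresized annotation circle and the
#: relative tolerance for recognizing it.  Both are configuration: the
#: interface's actual default radius is not documented.
DEFAULT_TOOL_SIZE = 50.0
DEFAULT_SIZE_TOLERANCE = 0.02


class Status(str, enum.Enum):
    VALID = "valid"
    INVALID = "invalid"
    MULTI_PAIR = "multi_pair"


class Reason(str, enum.Enum):
    OK = "ok"
    WRONG_ELLIPSE_COUNT = "wrong_ellipse_count"
    NOT_RESIZED = "not_resized"
    NOT_OVERLAPPING = "not_overlapping"
    MULTIPLE_PAIRS = "multiple_pairs"


@dataclass(frozen=True)
class TaskResult:
    """One worker's submission for one task: an ordered list of ellipses."""

    result_id: str
    task_id: str
    worker_id: str
    annotations: tuple[EllipseAnnotation, ...] = ()

    @property
    def n_annotations(self) -> int:
        return len(self.annotations)


@dataclass(frozen=True)
class ValidityLabel:
    """Classification of one result.

    ``no_airway_flag`` marks the single-annotation invalids where the lone
    ellipse is the "no airway visible" corner marker; it never accompanies a
    valid or multi-pair status.
    """

    status: Status
    reason: Reason
    no_airway_flag: bool = False

    def __post_init__(self) -> None:
        if (self.status is Status.VALID) != (self.reason is Reason.OK):
            raise ValueError("status 'valid' if and only if reason 'ok'")
        if self.no_airway_flag and self.status is not Status.INVALID:
            raise ValueError("no_airway_flag only applies to invalid results")


def _is_unresized_default(
    e: EllipseAnnotation, default_size: float, tol: float
) -> bool:
    """A default circle: both semi-axes within ``tol`` of ``default_size``.

    That condition already forces near-circularity (both axes close to the
    same value), so shape and size are checked in one go.
    """
    lo, hi = default_size * (1.0 - tol), default_size * (1.0 + tol)
    return lo <= e.semi_axis_a <= hi and lo <= e.semi_axis_b <= hi


def classify_result(
    r: TaskResult,
    frame: ImageFrame | None = None,
    default_size: float = DEFAULT_TOOL_SIZE,
    size_tolerance: float = DEFAULT_SIZE_TOLERANCE,
    corner_fraction: float = 0.2,
    marker_size_fraction: float = 0.1,
) -> ValidityLabel:
    """Assign exactly one validity label to a result.

    Decision order:

    1. four or more annotations -> ``multi_pair`` (multiple pairs of
       ellipses; three annotations are a wrong count, not a pair-and-a-half);
    2. annotation count != 2 -> invalid, wrong ellipse count, with the
       no-airway flag set when the single annotation is a corner marker;
    3. one or both ellipses still the unresized default circle -> invalid,
       not resized (a default circle carries no measurement, so one
       unresized ellipse already spoils the pair);
    4. the two ellipses do not overlap -> invalid, not overlapping;
    5. otherwise valid.
    """
    frame = frame or ImageFrame()
    n = r.n_annotations
    if n >= 4:
        return ValidityLabel(Status.MULTI_PAIR, Reason.MULTIPLE_PAIRS)
    if n != 2:
        no_airway = n == 1 and is_corner_marker(
            r.annotations[0], frame, corner_fraction, marker_size_fraction
        )
        return ValidityLabel(
            Status.INVALID, Reason.WRONG_ELLIPSE_COUNT, no_airway_flag=no_airway
        )
    e1, e2 = r.annotations
    if _is_unresized_default(e1, default_size, size_tolerance) or _is_unresized_default(
        e2, default_size, size_tolerance
    ):
        return ValidityLabel(Status.INVALID, Reason.NOT_RESIZED)
    if not ellipses_overlap(e1, e2):
        return ValidityLabel(Status.INVALID, Reason.NOT_OVERLAPPING)
    return ValidityLabel(Status.VALID, Reason.OK)


@dataclass
class ValiditySummary:
    """Counts and percentages of validity statuses over a result set.

    Percentages are computed on the full result count and rounded to one
    decimal for reporting (`percent`); exact fractions are available through
    `fraction`.
    """

    n_total: int = 0
    n_valid: int = 0
    n_invalid: int = 0
    n_multi_pair: int = 0
    n_no_airway: int = 0
    reason_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_valid + self.n_invalid + self.n_multi_pair != self.n_total:
            raise ValueError("status counts must partition the total")

    def fraction(self, status: Status | str) -> float:
        if self.n_total == 0:
            return float("nan")
        return self._count(status) / self.n_total

    def percent(self, status: Status | str) -> float:
        """Share of ``status`` in percent, rounded to one decimal."""
        return round(100.0 * self.fraction(status), 1)

    def _count(self, status: Status | str) -> int:
        status = Status(status)
        return {
            Status.VALID: self.n_valid,
            Status.INVALID: self.n_invalid,
            Status.MULTI_PAIR: self.n_multi_pair,
        }[status]


def tabulate_validity(labels: Iterable[ValidityLabel]) -> ValiditySummary:
    """Tally validity labels into a summary; empty input gives an empty summary."""
    summary = ValiditySummary()
    reasons: dict[str, int] = {}
    for lab in labels:
        summary.n_total += 1
        if lab.status is Status.VALID:
            summary.n_valid += 1
        elif lab.status is Status.INVALID:
            summary.n_invalid += 1
        else:
            summary.n_multi_pair += 1
        if lab.no_airway_flag:
            summary.n_no_airway += 1
        reasons[lab.reason.value] = reasons.get(lab.reason.value, 0) + 1
    summary.reason_counts = reasons
    return summary
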