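"""Airway measures: inner/outer area, wall thickness, WTR and WAP.

Given the lumen (inner) and outer-wall ellipses of a valid result, or an
expert's recorded areas, the measures are

    d   = 2*sqrt(area/pi)          equivalent-circle diameter
    WT  = (d_o - d_i) / 2          wall thickness
    WTR = WT / d_o                 wall thickness ratio (dimensionless)
    WAP = (a_o - a_i)/a_o * 100    wall area percentage

Both crowd and expert diameters are equivalent-circle diameters derived
from areas: the expert records only areas, so crowd-vs-expert comparison
assumes circular airways, and using the same convention for the crowd keeps
the two sides on the same footing.  All stored lengths are millimetres and
areas mm^2; WTR and WAP are scale-free, so the unit choice cannot affect any
downstream correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import ImageFrame, ellipse_area, equivalent_diameter
from .validity import TaskResult

__all__ = [
    "AirwayMeasurement",
    "ExpertReference",
    "DegenerateResultError",
    "InvalidReferenceError",
    "measure_result",
    "measure_expert",
]


class DegenerateResultError(ValueError):
    """The two ellipses of a result have indistinguishable areas."""


class InvalidReferenceError(ValueError):
    """An expert reference violates inner_area < outer_area."""


@dataclass(frozen=True)
class AirwayMeasurement:
    """Inner/outer areas (mm^2), diameters (mm) and derived wall measures."""

    inner_area: float
    outer_area: float
    inner_diameter: float
    outer_diameter: float
    wall_thickness: float
    wtr: float
    wap: float

    @classmethod
    def from_areas(cls, inner_area: float, outer_area: float) -> "AirwayMeasurement":
        """Build the full measurement from the two areas (mm^2).

        Requires 0 < inner_area < outer_area; an exact tie is rejected as
        degenerate rather than silently ordered.
        """
        if not 0 < inner_area:
            raise InvalidReferenceError(f"inner area must be positive, got {inner_area}")
        if inner_area == outer_area:
            raise DegenerateResultError("inner and outer areas are identical")
        if inner_area > outer_area:
            raise InvalidReferenceError(
                f"inner area {inner_area} exceeds outer area {outer_area}"
            )
        d_i = equivalent_diameter(inner_area)
        d_o = equivalent_diameter(outer_area)
        wt = (d_o - d_i) / 2.0
        return cls(
            inner_area=inner_area,
            outer_area=outer_area,
            inner_diameter=d_i,
            outer_diameter=d_o,
            wall_thickness=wt,
            wtr=wt / d_o,
            wap=(outer_area - inner_area) / outer_area * 100.0,
        )


@dataclass(frozen=True)
class ExpertReference:
    """Expert's recorded inner and outer areas (mm^2) for one task."""

    task_id: str
    expert_id: str
    inner_area: float
    outer_area: float

    def __post_init__(self) -> None:
        if not self.inner_area < self.outer_area:
            raise InvalidReferenceError(
                f"expert reference for task {self.task_id}: inner area "
                f"{self.inner_area} not below outer area {self.outer_area}"
            )


def measure_result(r: TaskResult, frame: ImageFrame | None = None) -> AirwayMeasurement:
    """Measure a valid result (exactly two overlapping, resized ellipses).

    The smaller-area ellipse is taken as the lumen and the larger as the
    outer wall (the worker interface does not label them); areas are
    converted from pixel^2 to mm^2 through the frame scale.
    """
    frame = frame or ImageFrame()
    if r.n_annotations != 2:
        raise ValueError(
            f"measure_result requires exactly 2 annotations, got {r.n_annotations}"
        )
    areas_px = sorted(ellipse_area(e) for e in r.annotations)
    if areas_px[0] == areas_px[1]:
        raise DegenerateResultError(
            f"result {r.result_id}: the two ellipses have equal areas"
        )
    scale = frame.mm2_per_pixel2
    return AirwayMeasurement.from_areas(areas_px[0] * scale, areas_px[1] * scale)


def measure_expert(ref: ExpertReference) -> AirwayMeasurement:
    """Measure an expert reference with the same formulas as the crowd."""
    return AirwayMeasurement.from_areas(ref.inner_area, ref.outer_area)
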