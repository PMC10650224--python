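"""Per-cell nuclear shape descriptors and patient-level aggregation.

All descriptors rest on the elliptic-nucleus assumption: a nucleus of
measured area ``A`` and long axis ``L = 2·r1`` is modelled as an ellipse,
so its semi-short axis follows from the ellipse-area relation

    A = π · r1 · r2                                  (small axis = 2·r2)

and its volume from a prolate-style ellipsoid whose two remaining axes both
equal the small axis,

    V = (4/3) · π · r1 · r2²  =  (2/3) · A · (2·r2).

Two dimensionless dysmorphism grades compare the measured perimeter with
ideal reference perimeters:

* acyclicity  = P / (2·√(π·A))          (circle of equal area),
* anellipticity = P / (2π·√((r1²+r2²)/2))   (root-mean-square ellipse
  perimeter approximation for the fitted axes).

Cytoplasm is quantified either per cell (cell area minus nuclear area) or
from pooled regions where cell borders are not individually evaluable, and
the mean internuclear distance follows from a square-tiling packing
argument as √(mean cell area).
"""

from __future__ import annotations

import math
import statistics
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .model import CellMeasurement, Finding, PatientSample, RegionMeasurement

__all__ = [
    "SelectionPolicy",
    "CellMorphometrics",
    "PatientMorphometrics",
    "PARAMETER_NAMES",
    "select_nuclei",
    "small_axis_from_area",
    "axis_ratio",
    "ellipsoid_volume",
    "acyclicity_grade",
    "ellipse_perimeter_rms",
    "anellipticity_grade",
    "nc_ratio_per_cell",
    "nc_ratio_pooled",
    "mean_internuclear_distance",
    "cell_morphometrics",
    "patient_morphometrics",
]

#: the nine patient-level parameters, in report order
PARAMETER_NAMES: tuple[str, ...] = (
    "mean_nuclear_area",
    "nc_ratio",
    "axis_ratio",
    "acyclicity",
    "mean_internuclear_distance",
    "long_axis",
    "small_axis",
    "mean_nuclear_volume",
    "anellipticity",
)

EllipsePerimeterMode = Literal["rms", "code-compat"]
AggregationMode = Literal["per_cell", "from_means"]


class GeometryError(ValueError):
    """Raised when a measurement combination is geometrically impossible."""


class SelectionPolicy(BaseModel):
    """Rule excluding small nuclei before aggregation.

    Small nuclear profiles may be off-plane caps of larger nuclei, so only
    nuclei whose area exceeds ``fraction`` times a reference area are kept.
    The reference is the mean area of the largest nuclei (top decile by
    area) or the single largest area.
    """

    model_config = ConfigDict(frozen=True)

    fraction: float = Field(default=0.5, gt=0.0, lt=1.0)
    reference: Literal["max_area", "mean_top_decile"] = "mean_top_decile"


def select_nuclei(
    cells: Sequence[CellMeasurement],
    policy: SelectionPolicy | None = None,
) -> list[CellMeasurement]:
    """Keep nuclei larger than ``fraction`` × the reference area.

    Order is preserved. With the default policy the reference area is the
    mean area of the top decile (at least one cell) of nuclei by area.
    """
    if len(cells) == 0:
        raise ValueError("select_nuclei requires at least one cell")
    policy = policy or SelectionPolicy()
    areas = sorted((c.nucleus_area for c in cells), reverse=True)
    if policy.reference == "max_area":
        ref = areas[0]
    else:
        k = max(1, len(areas) // 10)
        ref = sum(areas[:k]) / k
    threshold = policy.fraction * ref
    return [c for c in cells if c.nucleus_area > threshold]


def small_axis_from_area(nucleus_area: float, long_axis: float) -> float:
    """Small axis 2·r2 of the ellipse with this area and long axis."""
    if nucleus_area <= 0 or long_axis <= 0:
        raise GeometryError("nucleus_area and long_axis must be positive")
    r1 = long_axis / 2.0
    r2 = nucleus_area / (math.pi * r1)
    if r2 > r1 * (1.0 + 1e-9):
        raise GeometryError(
            f"area {nucleus_area:g} µm² is too large for long axis "
            f"{long_axis:g} µm (small axis would exceed the long axis)"
        )
    return 2.0 * min(r2, r1)


def axis_ratio(long_axis: float, small_axis: float) -> float:
    """Ratio of long to small axis, ≥ 1."""
    if small_axis <= 0:
        raise GeometryError("small_axis must be positive")
    if small_axis > long_axis * (1.0 + 1e-9):
        raise GeometryError("small_axis exceeds long_axis")
    return max(long_axis / small_axis, 1.0)


def ellipsoid_volume(nucleus_area: float, long_axis: float) -> float:
    """Nuclear volume under the ellipsoid model, µm³.

    The ellipsoid has one axis equal to the long axis and the other two
    equal to the elliptically derived small axis:
    V = (4/3)·π·r1·r2², identically (2/3)·A·(2·r2).
    """
    r1 = long_axis / 2.0
    r2 = small_axis_from_area(nucleus_area, long_axis) / 2.0
    return (4.0 / 3.0) * math.pi * r1 * r2 * r2


def acyclicity_grade(nucleus_perimeter: float, nucleus_area: float) -> float:
    """Perimeter over the perimeter of the circle of equal area.

    Equals 1 for a circle and exceeds 1 for any other simple closed contour
    (isoperimetric inequality); grows with nuclear folding.
    """
    if nucleus_perimeter <= 0 or nucleus_area <= 0:
        raise GeometryError("perimeter and area must be positive")
    return nucleus_perimeter / (2.0 * math.sqrt(math.pi * nucleus_area))


def ellipse_perimeter_rms(
    semi_long: float, semi_short: float, mode: EllipsePerimeterMode = "rms"
) -> float:
    """Root-mean-square approximation of an ellipse perimeter.

    ``2π·√((r1²+r2²)/2)``, an upper bound on the true arc length; exact for
    circles.  ``mode="code-compat"`` reproduces a published code variant
    that omits the square root (dimensionally a length², kept for audit
    only).
    """
    if semi_long <= 0 or semi_short <= 0:
        raise GeometryError("semi-axes must be positive")
    if semi_short > semi_long * (1.0 + 1e-9):
        raise GeometryError("semi_short exceeds semi_long")
    mean_sq = (semi_long**2 + semi_short**2) / 2.0
    if mode == "code-compat":
        return 2.0 * math.pi * mean_sq
    return 2.0 * math.pi * math.sqrt(mean_sq)


def anellipticity_grade(
    nucleus_perimeter: float,
    semi_long: float,
    semi_short: float,
    mode: EllipsePerimeterMode = "rms",
) -> float:
    """Perimeter over the RMS-approximated perimeter of the fitted ellipse.

    Close to 1 for a smooth elliptic nucleus (slightly below, since the RMS
    formula overestimates the true arc length) and larger for folded
    contours.
    """
    if nucleus_perimeter <= 0:
        raise GeometryError("perimeter must be positive")
    return nucleus_perimeter / ellipse_perimeter_rms(semi_long, semi_short, mode)


def nc_ratio_per_cell(nucleus_area: float, cell_area: float) -> float:
    """Nucleus-to-cytoplasm area ratio A / (cell_area − A)."""
    if nucleus_area <= 0:
        raise GeometryError("nucleus_area must be positive")
    if cell_area <= nucleus_area:
        raise GeometryError(
            f"cell_area {cell_area:g} µm² must exceed nucleus_area "
            f"{nucleus_area:g} µm²"
        )
    return nucleus_area / (cell_area - nucleus_area)


def nc_ratio_pooled(region: RegionMeasurement, mean_nucleus_area: float) -> float:
    """N/C ratio of a pooled region with uniformly shared cytoplasm.

    Each of the ``n`` counted nuclei is taken to have the mean nuclear
    area; the region's cytoplasm (region area minus n·Ā) is split evenly.
    """
    n = region.nucleus_count
    cytoplasm = region.region_area - n * mean_nucleus_area
    if cytoplasm <= 0:
        raise GeometryError(
            f"region {region.region_id!r}: area {region.region_area:g} µm² "
            f"does not exceed {n} × mean nuclear area {mean_nucleus_area:g} µm²"
        )
    return mean_nucleus_area / (cytoplasm / n)


def mean_internuclear_distance(mean_cell_area: float) -> float:
    """√(mean cell area): the side of the square tile holding one nucleus."""
    if mean_cell_area <= 0:
        raise GeometryError("mean_cell_area must be positive")
    return math.sqrt(mean_cell_area)


class CellMorphometrics(BaseModel):
    """Derived shape descriptors of a single nucleus."""

    model_config = ConfigDict(frozen=True)

    cell_id: str
    semi_long_axis: float
    semi_short_axis: float
    small_axis: float
    axis_ratio: float
    nuclear_volume: float
    acyclicity: float
    anellipticity: float
    nc_ratio: Optional[float] = None


class PatientMorphometrics(BaseModel):
    """The nine patient-level morphometric parameters.

    ``nc_ratio`` and ``mean_internuclear_distance`` are ``None`` when no
    cytoplasm information (per-cell areas or pooled regions) is available.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    mean_nuclear_area: float = Field(gt=0)
    nc_ratio: Optional[float] = Field(default=None, gt=0)
    axis_ratio: float = Field(ge=1.0)
    acyclicity: float = Field(gt=0)
    mean_internuclear_distance: Optional[float] = Field(default=None, gt=0)
    long_axis: float = Field(gt=0)
    small_axis: float = Field(gt=0)
    mean_nuclear_volume: float = Field(gt=0)
    anellipticity: float = Field(gt=0)
    aggregation_mode: AggregationMode = "per_cell"
    n_cells_used: int = 0
    findings: tuple[Finding, ...] = ()

    def parameter(self, name: str) -> Optional[float]:
        if name not in PARAMETER_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def cell_morphometrics(
    cell: CellMeasurement, ellipse_perimeter: EllipsePerimeterMode = "rms"
) -> CellMorphometrics:
    """All derived descriptors for one measured nucleus."""
    small = small_axis_from_area(cell.nucleus_area, cell.nucleus_long_axis)
    r1 = cell.nucleus_long_axis / 2.0
    r2 = small / 2.0
    nc = (
        nc_ratio_per_cell(cell.nucleus_area, cell.cell_area)
        if cell.cell_area is not None
        else None
    )
    return CellMorphometrics(
        cell_id=cell.cell_id,
        semi_long_axis=r1,
        semi_short_axis=r2,
        small_axis=small,
        axis_ratio=axis_ratio(cell.nucleus_long_axis, small),
        nuclear_volume=ellipsoid_volume(cell.nucleus_area, cell.nucleus_long_axis),
        acyclicity=acyclicity_grade(cell.nucleus_perimeter, cell.nucleus_area),
        anellipticity=anellipticity_grade(
            cell.nucleus_perimeter, r1, r2, ellipse_perimeter
        ),
        nc_ratio=nc,
    )


def _per_cell_cell_areas(
    cells: Sequence[CellMeasurement], regions: Sequence[RegionMeasurement]
) -> list[float]:
    """Whole-cell areas: measured per cell, or region area split per nucleus."""
    areas = [c.cell_area for c in cells if c.cell_area is not None]
    covered = {c.cell_id for c in cells if c.cell_area is not None}
    for region in regions:
        if region.member_cell_ids and set(region.member_cell_ids) <= covered:
            continue  # region duplicates individually measured cells
        areas.extend([region.region_area / region.nucleus_count] * region.nucleus_count)
    return areas


def patient_morphometrics(
    sample: PatientSample,
    mode: AggregationMode = "per_cell",
    policy: SelectionPolicy | None = None,
    ellipse_perimeter: EllipsePerimeterMode = "rms",
) -> PatientMorphometrics:
    """Aggregate a patient's cells into the nine panel parameters.

    ``per_cell`` computes every descriptor for each selected cell and
    averages the descriptors; ``from_means`` averages the raw measurements
    first and applies each descriptor once to the means, matching a
    mean-input calculation.  The two agree exactly on homogeneous samples
    and differ by Jensen gaps on heterogeneous ones.
    """
    selected = select_nuclei(sample.cells, policy)
    findings: list[Finding] = []
    if not selected:  # pragma: no cover - policy guarantees ≥1 by construction
        raise ValueError("selection policy removed every cell")

    cell_areas = _per_cell_cell_areas(selected, sample.regions)
    mean_area = statistics.fmean(c.nucleus_area for c in selected)

    nc: Optional[float]
    distance: Optional[float]
    if mode == "from_means":
        mean_perimeter = statistics.fmean(c.nucleus_perimeter for c in selected)
        mean_long = statistics.fmean(c.nucleus_long_axis for c in selected)
        small = small_axis_from_area(mean_area, mean_long)
        r1, r2 = mean_long / 2.0, small / 2.0
        ratio = axis_ratio(mean_long, small)
        volume = ellipsoid_volume(mean_area, mean_long)
        acyc = acyclicity_grade(mean_perimeter, mean_area)
        anell = anellipticity_grade(mean_perimeter, r1, r2, ellipse_perimeter)
        long_axis_val = mean_long
    else:
        per_cell = [cell_morphometrics(c, ellipse_perimeter) for c in selected]
        small = statistics.fmean(m.small_axis for m in per_cell)
        ratio = statistics.fmean(m.axis_ratio for m in per_cell)
        volume = statistics.fmean(m.nuclear_volume for m in per_cell)
        acyc = statistics.fmean(m.acyclicity for m in per_cell)
        anell = statistics.fmean(m.anellipticity for m in per_cell)
        long_axis_val = statistics.fmean(c.nucleus_long_axis for c in selected)

    if cell_areas:
        mean_cell_area = statistics.fmean(cell_areas)
        distance = mean_internuclear_distance(mean_cell_area)
        if mode == "from_means":
            nc = nc_ratio_per_cell(mean_area, mean_cell_area)
        else:
            per_cell_nc = [
                nc_ratio_per_cell(c.nucleus_area, c.cell_area)
                for c in selected
                if c.cell_area is not None
            ]
            pooled_nc: list[float] = []
            for region in sample.regions:
                # every cell of a pooled region shares the same ratio, so the
                # per-cell average weights the region by its nucleus count
                pooled_nc.extend(
                    [nc_ratio_pooled(region, mean_area)] * region.nucleus_count
                )
            nc = statistics.fmean(per_cell_nc + pooled_nc)
    else:
        nc = None
        distance = None
        findings.append(
            Finding(
                level="warning",
                code="no_cytoplasm_data",
                message=(
                    "no per-cell cell areas and no pooled regions; N/C ratio "
                    "and mean internuclear distance are unavailable"
                ),
                subject=sample.patient_id,
            )
        )

    return PatientMorphometrics(
        patient_id=sample.patient_id,
        mean_nuclear_area=mean_area,
        nc_ratio=nc,
        axis_ratio=ratio,
        acyclicity=acyc,
        mean_internuclear_distance=distance,
        long_axis=long_axis_val,
        small_axis=small,
        mean_nuclear_volume=volume,
        anellipticity=anell,
        aggregation_mode=mode,
        n_cells_used=len(selected),
        findings=tuple(findings),
    )
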