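"""Domain types for nuclear-morphometry measurement data.

The measurement model mirrors what whole-slide annotation software exports
for a manually annotated tumor region: per-nucleus area, perimeter and long
axis (all in micrometres), optionally the area of the whole cell when the
cellular membrane is evaluable, and pooled region measurements (region area
plus nucleus count) when it is not.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "PixelCalibration",
    "CellMeasurement",
    "RegionMeasurement",
    "MetastasisStatus",
    "PatientSample",
    "CohortDataset",
    "Finding",
]

#: relative slack on the elliptic area bound, covering float round-off only
_AREA_BOUND_RTOL = 1e-9


class PixelCalibration(BaseModel):
    """Isotropic pixel size used to convert pixel measurements to µm."""

    model_config = ConfigDict(frozen=True)

    microns_per_pixel: float = Field(gt=0.0)


class CellMeasurement(BaseModel):
    """Raw measurements of one tumor-cell nucleus, in micrometres.

    Attributes
    ----------
    nucleus_area : float
        Nuclear cross-section area A, µm².
    nucleus_perimeter : float
        Nuclear contour perimeter P, µm.
    nucleus_long_axis : float
        Long (major) axis of the nucleus, µm; equals 2·r1 under the
        elliptic-nucleus assumption.
    cell_area : float, optional
        Whole-cell area, µm², when the cellular border is individually
        evaluable; ``None`` when cytoplasm must be quantified from pooled
        regions instead.
    """

    model_config = ConfigDict(frozen=True)

    cell_id: str
    nucleus_area: float = Field(gt=0.0)
    nucleus_perimeter: float = Field(gt=0.0)
    nucleus_long_axis: float = Field(gt=0.0)
    cell_area: Optional[float] = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _check_geometry(self) -> "CellMeasurement":
        # An ellipse with this long axis can hold at most π·(L/2)² of area;
        # more would force the small axis past the long one.
        bound = math.pi * (self.nucleus_long_axis / 2.0) ** 2
        if self.nucleus_area > bound * (1.0 + _AREA_BOUND_RTOL):
            raise ValueError(
                f"cell {self.cell_id!r}: nucleus_area {self.nucleus_area:g} µm² "
                f"exceeds the elliptic bound π·(long_axis/2)² = {bound:g} µm²"
            )
        if self.cell_area is not None and self.cell_area <= self.nucleus_area:
            raise ValueError(
                f"cell {self.cell_id!r}: cell_area {self.cell_area:g} µm² must "
                f"exceed nucleus_area {self.nucleus_area:g} µm²"
            )
        return self


class RegionMeasurement(BaseModel):
    """A pooled region used when individual cell borders are not evaluable.

    The cytoplasm of the region is treated as uniformly distributed over the
    counted nuclei, so only the region area and the nucleus count are needed.
    """

    model_config = ConfigDict(frozen=True)

    region_id: str
    region_area: float = Field(gt=0.0)
    nucleus_count: int = Field(gt=0)
    member_cell_ids: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check_count(self) -> "RegionMeasurement":
        if self.member_cell_ids and len(self.member_cell_ids) != self.nucleus_count:
            raise ValueError(
                f"region {self.region_id!r}: nucleus_count {self.nucleus_count} "
                f"does not match {len(self.member_cell_ids)} member cell ids"
            )
        return self


class MetastasisStatus(str, Enum):
    """Bone-metastasis outcome label of a patient."""

    bone_metastasis = "bone_metastasis"
    no_bone_metastasis = "no_bone_metastasis"
    unknown = "unknown"


class PatientSample(BaseModel):
    """All measured cells (and optional pooled regions) of one patient."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    metastasis_status: MetastasisStatus = MetastasisStatus.unknown
    cells: tuple[CellMeasurement, ...] = Field(min_length=1)
    regions: tuple[RegionMeasurement, ...] = ()


class CohortDataset(BaseModel):
    """A set of patient samples analysed together."""

    model_config = ConfigDict(frozen=True)

    patients: tuple[PatientSample, ...] = ()
    provenance: str = ""

    @model_validator(mode="after")
    def _check_unique_ids(self) -> "CohortDataset":
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_ids: {dupes}")
        return self


class Finding(BaseModel):
    """A validation or processing finding; findings are data, not exceptions."""

    model_config = ConfigDict(frozen=True)

    level: str = Field(pattern="^(warning|error)$")
    code: str
    message: str
    subject: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.code}: {self.message}"
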