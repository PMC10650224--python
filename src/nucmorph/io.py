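"""Measurement-table ingestion and scored-report serialization.

Reads per-cell measurement tables exported by whole-slide annotation
software (QuPath-style detection exports by default, arbitrary headers via
a column map), converts pixel units to µm when a calibration is supplied,
and writes per-patient reports with the nine parameters, per-criterion
flags, the satisfied-criteria count and the risk tier.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from pydantic import ValidationError

from .model import (
    CellMeasurement,
    CohortDataset,
    Finding,
    MetastasisStatus,
    PatientSample,
    PixelCalibration,
    RegionMeasurement,
)
from .morphometry import PARAMETER_NAMES
from .scoring import CRITERION_NAMES, CriteriaResult

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "read_measurement_csv",
    "read_cohort_csv",
    "read_region_csv",
    "write_cohort_csv",
    "validate_sample",
    "write_report",
    "read_report",
]

#: logical field -> header, defaults matching QuPath detection exports
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "cell_id": "Object ID",
    "nucleus_area": "Nucleus: Area",
    "nucleus_perimeter": "Nucleus: Perimeter",
    "nucleus_long_axis": "Nucleus: Max diameter",
    "cell_area": "Cell: Area",
    "patient_id": "Image",
    "metastasis_status": "Metastasis status",
}

#: expected cell count per representative area; outside is a warning only
CELL_COUNT_RANGE = (60, 100)


class MeasurementTableError(ValueError):
    """A measurement table cannot be ingested as configured."""


def _resolve_columns(
    df: pd.DataFrame, column_map: Optional[Mapping[str, str]]
) -> dict[str, str]:
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    required = ("cell_id", "nucleus_area", "nucleus_perimeter", "nucleus_long_axis")
    missing = [cmap[f] for f in required if cmap[f] not in df.columns]
    if missing:
        raise MeasurementTableError(
            f"required column(s) missing from table: {missing}; "
            f"present: {list(df.columns)}"
        )
    return cmap


def _scale_factors(
    units: str, calibration: Optional[PixelCalibration]
) -> tuple[float, float]:
    """(length factor, area factor) converting table units to µm, µm²."""
    if units == "um":
        return 1.0, 1.0
    if units == "px":
        if calibration is None:
            raise MeasurementTableError(
                "units='px' requires a PixelCalibration to convert to µm"
            )
        s = calibration.microns_per_pixel
        return s, s * s
    raise MeasurementTableError(f"unknown units {units!r}; use 'um' or 'px'")


def _rows_to_cells(
    df: pd.DataFrame,
    cmap: Mapping[str, str],
    length_scale: float,
    area_scale: float,
) -> list[CellMeasurement]:
    cells = []
    has_cell_area = cmap["cell_area"] in df.columns
    for _, row in df.iterrows():
        cell_id = str(row[cmap["cell_id"]])
        raw_cell_area = row[cmap["cell_area"]] if has_cell_area else None
        if raw_cell_area is not None and (
            pd.isna(raw_cell_area) or raw_cell_area == ""
        ):
            raw_cell_area = None
        try:
            cells.append(
                CellMeasurement(
                    cell_id=cell_id,
                    nucleus_area=float(row[cmap["nucleus_area"]]) * area_scale,
                    nucleus_perimeter=float(row[cmap["nucleus_perimeter"]])
                    * length_scale,
                    nucleus_long_axis=float(row[cmap["nucleus_long_axis"]])
                    * length_scale,
                    cell_area=(
                        float(raw_cell_area) * area_scale
                        if raw_cell_area is not None
                        else None
                    ),
                )
            )
        except (ValidationError, TypeError, ValueError) as exc:
            raise MeasurementTableError(
                f"invalid measurement row for cell {cell_id!r}: {exc}"
            ) from exc
    return cells


def read_measurement_csv(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    calibration: Optional[PixelCalibration] = None,
    units: str = "um",
    patient_id: Optional[str] = None,
    metastasis_status: MetastasisStatus = MetastasisStatus.unknown,
    regions: Sequence[RegionMeasurement] = (),
) -> PatientSample:
    """Read one patient's per-cell measurement table.

    Lengths are read in µm by default; ``units="px"`` converts with the
    supplied calibration (areas by its square).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    cmap = _resolve_columns(df, column_map)
    length_scale, area_scale = _scale_factors(units, calibration)
    cells = _rows_to_cells(df, cmap, length_scale, area_scale)
    if not cells:
        raise MeasurementTableError(f"{path}: table contains no measurement rows")
    return PatientSample(
        patient_id=patient_id or path.stem,
        metastasis_status=metastasis_status,
        cells=tuple(cells),
        regions=tuple(regions),
    )


def read_cohort_csv(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    calibration: Optional[PixelCalibration] = None,
    units: str = "um",
) -> CohortDataset:
    """Read a multi-patient measurement table grouped by a patient column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    cmap = _resolve_columns(df, column_map)
    if cmap["patient_id"] not in df.columns:
        raise MeasurementTableError(
            f"cohort table needs a patient column {cmap['patient_id']!r}"
        )
    length_scale, area_scale = _scale_factors(units, calibration)
    patients = []
    for pid, group in df.groupby(cmap["patient_id"], sort=False):
        status = MetastasisStatus.unknown
        if cmap["metastasis_status"] in group.columns:
            raw = str(group[cmap["metastasis_status"]].iloc[0])
            try:
                status = MetastasisStatus(raw)
            except ValueError as exc:
                raise MeasurementTableError(
                    f"patient {pid!r}: unknown metastasis status {raw!r}"
                ) from exc
        patients.append(
            PatientSample(
                patient_id=str(pid),
                metastasis_status=status,
                cells=tuple(_rows_to_cells(group, cmap, length_scale, area_scale)),
            )
        )
    return CohortDataset(patients=tuple(patients), provenance=str(path))


def read_region_csv(path: str | Path) -> list[RegionMeasurement]:
    """Read a pooled-region table (region_id, region_area, nucleus_count)."""
    df = pd.read_csv(path)
    required = {"region_id", "region_area", "nucleus_count"}
    if not required <= set(df.columns):
        raise MeasurementTableError(
            f"region table must have columns {sorted(required)}"
        )
    return [
        RegionMeasurement(
            region_id=str(row.region_id),
            region_area=float(row.region_area),
            nucleus_count=int(row.nucleus_count),
        )
        for row in df.itertuples()
    ]


def write_cohort_csv(cohort: CohortDataset, path: str | Path) -> pd.DataFrame:
    """Write a cohort as one measurement table, readable by
    :func:`read_cohort_csv` with the default column map."""
    path = Path(path)
    rows = []
    for patient in cohort.patients:
        for cell in patient.cells:
            rows.append(
                {
                    DEFAULT_COLUMN_MAP["patient_id"]: patient.patient_id,
                    DEFAULT_COLUMN_MAP["metastasis_status"]: (
                        patient.metastasis_status.value
                    ),
                    DEFAULT_COLUMN_MAP["cell_id"]: cell.cell_id,
                    DEFAULT_COLUMN_MAP["nucleus_area"]: cell.nucleus_area,
                    DEFAULT_COLUMN_MAP["nucleus_perimeter"]: cell.nucleus_perimeter,
                    DEFAULT_COLUMN_MAP["nucleus_long_axis"]: cell.nucleus_long_axis,
                    DEFAULT_COLUMN_MAP["cell_area"]: cell.cell_area,
                }
            )
    df = pd.DataFrame.from_records(
        rows,
        columns=[
            DEFAULT_COLUMN_MAP[k]
            for k in (
                "patient_id",
                "metastasis_status",
                "cell_id",
                "nucleus_area",
                "nucleus_perimeter",
                "nucleus_long_axis",
                "cell_area",
            )
        ],
    )
    df.to_csv(path, index=False)
    return df


def validate_sample(sample: PatientSample) -> list[Finding]:
    """Collect warnings and errors about a sample without mutating it.

    Re-checks the per-cell geometric invariants (so objects built without
    validation are still caught), the pooled-region bookkeeping, the
    recommended 60–100 cell count, and the availability of cytoplasm data.
    """
    findings: list[Finding] = []
    lo, hi = CELL_COUNT_RANGE
    n = len(sample.cells)
    if n < lo:
        findings.append(
            Finding(
                level="warning",
                code="cell_count_low",
                message=f"cell count {n} below the recommended {lo}",
                subject=sample.patient_id,
            )
        )
    elif n > hi:
        findings.append(
            Finding(
                level="warning",
                code="cell_count_high",
                message=f"cell count {n} above the recommended {hi}",
                subject=sample.patient_id,
            )
        )

    for cell in sample.cells:
        bound = math.pi * (cell.nucleus_long_axis / 2.0) ** 2
        if min(cell.nucleus_area, cell.nucleus_perimeter, cell.nucleus_long_axis) <= 0:
            findings.append(
                Finding(
                    level="error",
                    code="non_positive_measurement",
                    message=f"cell {cell.cell_id!r} has a non-positive measurement",
                    subject=sample.patient_id,
                )
            )
        elif cell.nucleus_area > bound * (1.0 + 1e-9):
            findings.append(
                Finding(
                    level="error",
                    code="area_exceeds_elliptic_bound",
                    message=(
                        f"cell {cell.cell_id!r}: area {cell.nucleus_area:g} µm² "
                        f"exceeds π·(long_axis/2)² = {bound:g} µm²"
                    ),
                    subject=sample.patient_id,
                )
            )
        if cell.cell_area is not None and cell.cell_area <= cell.nucleus_area:
            findings.append(
                Finding(
                    level="error",
                    code="cell_smaller_than_nucleus",
                    message=(
                        f"cell {cell.cell_id!r}: cell_area {cell.cell_area:g} µm² "
                        f"does not exceed nucleus_area {cell.nucleus_area:g} µm²"
                    ),
                    subject=sample.patient_id,
                )
            )

    by_id = {c.cell_id: c for c in sample.cells}
    for region in sample.regions:
        members = [by_id[i] for i in region.member_cell_ids if i in by_id]
        nuclear_sum = sum(c.nucleus_area for c in members)
        if members and region.region_area <= nuclear_sum:
            findings.append(
                Finding(
                    level="error",
                    code="region_smaller_than_nuclei",
                    message=(
                        f"region {region.region_id!r}: area {region.region_area:g} "
                        f"µm² does not exceed member nuclear area {nuclear_sum:g} µm²"
                    ),
                    subject=sample.patient_id,
                )
            )

    if not sample.regions and all(c.cell_area is None for c in sample.cells):
        findings.append(
            Finding(
                level="warning",
                code="no_cytoplasm_data",
                message=(
                    "no cell areas and no pooled regions: N/C ratio and "
                    "internuclear distance will be unavailable"
                ),
                subject=sample.patient_id,
            )
        )
    return findings


def _result_record(result: CriteriaResult) -> dict:
    record: dict = {"patient_id": result.patient_id}
    record["metastasis_status"] = result.metastasis_status.value
    pm = result.morphometrics
    for name in PARAMETER_NAMES:
        value = pm.parameter(name) if pm is not None else None
        record[name] = round(value, 3) if value is not None else None
    for name in CRITERION_NAMES:
        record[f"crit_{name}"] = bool(result.flags[name])
    record["axis_ratio_flag"] = bool(result.axis_ratio_flag)
    record["n_cr"] = int(result.n_cr)
    record["risk"] = result.risk
    return record


def write_report(
    results: Sequence[CriteriaResult], path: str | Path
) -> pd.DataFrame:
    """Write a scored-cohort report (CSV, or JSON for a .json path).

    Parameters are formatted to three decimals; criterion flags, the
    satisfied-criteria count and the risk tier are written per patient.
    Returns the report table.
    """
    path = Path(path)
    records = [_result_record(r) for r in results]
    columns = list(
        _result_record(_EMPTY_RESULT).keys()  # stable header, even when empty
    )
    df = pd.DataFrame.from_records(records, columns=columns)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        df.to_csv(path, index=False)
    return df


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame.from_records(json.loads(path.read_text()))
    return pd.read_csv(path)


_EMPTY_RESULT = CriteriaResult(
    patient_id="",
    flags={name: False for name in CRITERION_NAMES},
    n_cr=0,
    risk="low",
    axis_ratio_flag=False,
)
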