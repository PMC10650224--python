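"""Cut-off panel evaluation and three-tier bone-metastasis risk scoring.

Eight counted criteria compare the patient-level parameters against fixed
cut-offs, each with a strict inequality in the metastasis-like direction
(small, dense, folded nuclei):

======================  =========  =========
parameter               direction  cut-off
======================  =========  =========
mean nuclear area       <          55 µm²
N/C ratio               >          1.1
acyclicity grade        >          1.145
internuclear distance   <          10.5 µm
long axis               <          9 µm
small axis              <          7 µm
mean nuclear volume     <          200 µm³
anellipticity grade     >          1.14
======================  =========  =========

The axis ratio (> 1.2) is derivative of the two axes, so it is reported
but never counted.  The satisfied-criteria count ``n_cr`` maps to risk
tiers: high for n_cr ≥ 6, intermediate for 3–5, low for ≤ 2.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import CohortDataset, Finding, MetastasisStatus
from .morphometry import (
    AggregationMode,
    EllipsePerimeterMode,
    PatientMorphometrics,
    SelectionPolicy,
    patient_morphometrics,
)

__all__ = [
    "CriteriaPanel",
    "CriteriaResult",
    "CRITERION_NAMES",
    "evaluate_criteria",
    "risk_category",
    "score_cohort",
]

#: the eight counted criteria, in panel order
CRITERION_NAMES: tuple[str, ...] = (
    "area",
    "nc_ratio",
    "acyclicity",
    "distance",
    "long_axis",
    "small_axis",
    "volume",
    "anellipticity",
)

RiskTier = Literal["high", "intermediate", "low"]


class CriteriaPanel(BaseModel):
    """Cut-off values of the morphometric panel; all overridable.

    ``distance_max`` defaults to 10.5 µm; a stricter 9.5 µm variant exists
    in part of the source literature and can be set explicitly.
    """

    model_config = ConfigDict(frozen=True)

    area_max: float = Field(default=55.0, gt=0)  # µm²
    nc_min: float = Field(default=1.1, gt=0)
    acyclicity_min: float = Field(default=1.145, gt=0)
    distance_max: float = Field(default=10.5, gt=0)  # µm
    long_axis_max: float = Field(default=9.0, gt=0)  # µm
    small_axis_max: float = Field(default=7.0, gt=0)  # µm
    volume_max: float = Field(default=200.0, gt=0)  # µm³
    anellipticity_min: float = Field(default=1.14, gt=0)
    axis_ratio_min: float = Field(default=1.2, gt=0)  # auxiliary, uncounted


class CriteriaResult(BaseModel):
    """Outcome of the panel for one patient."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    flags: dict[str, bool]
    n_cr: int = Field(ge=0, le=8)
    risk: RiskTier
    axis_ratio_flag: bool
    metastasis_status: MetastasisStatus = MetastasisStatus.unknown
    morphometrics: Optional[PatientMorphometrics] = None
    findings: tuple[Finding, ...] = ()

    @model_validator(mode="after")
    def _check_consistency(self) -> "CriteriaResult":
        if set(self.flags) != set(CRITERION_NAMES):
            raise ValueError("flags must cover exactly the eight panel criteria")
        if self.n_cr != sum(self.flags.values()):
            raise ValueError("n_cr must equal the number of true flags")
        if self.risk != risk_category(self.n_cr):
            raise ValueError("risk tier inconsistent with n_cr")
        return self


def risk_category(n_cr: int) -> RiskTier:
    """Map the satisfied-criteria count to a risk tier."""
    if not 0 <= n_cr <= 8:
        raise ValueError(f"n_cr must be in 0..8, got {n_cr}")
    if n_cr > 5:
        return "high"
    if n_cr > 2:
        return "intermediate"
    return "low"


def evaluate_criteria(
    pm: PatientMorphometrics, panel: CriteriaPanel | None = None
) -> CriteriaResult:
    """Apply the cut-off panel to one patient's parameters.

    Comparisons are strict; a parameter sitting exactly at its cut-off does
    not satisfy the criterion.  Missing N/C ratio or internuclear distance
    evaluates false and is flagged with a warning finding.
    """
    panel = panel or CriteriaPanel()
    findings = list(pm.findings)

    flags = {
        "area": pm.mean_nuclear_area < panel.area_max,
        "nc_ratio": pm.nc_ratio is not None and pm.nc_ratio > panel.nc_min,
        "acyclicity": pm.acyclicity > panel.acyclicity_min,
        "distance": (
            pm.mean_internuclear_distance is not None
            and pm.mean_internuclear_distance < panel.distance_max
        ),
        "long_axis": pm.long_axis < panel.long_axis_max,
        "small_axis": pm.small_axis < panel.small_axis_max,
        "volume": pm.mean_nuclear_volume < panel.volume_max,
        "anellipticity": pm.anellipticity > panel.anellipticity_min,
    }
    for name, value in (
        ("nc_ratio", pm.nc_ratio),
        ("distance", pm.mean_internuclear_distance),
    ):
        if value is None:
            findings.append(
                Finding(
                    level="warning",
                    code="missing_criterion_input",
                    message=f"criterion {name!r} evaluated false: parameter missing",
                    subject=pm.patient_id,
                )
            )

    n_cr = sum(flags.values())
    return CriteriaResult(
        patient_id=pm.patient_id,
        flags=flags,
        n_cr=n_cr,
        risk=risk_category(n_cr),
        axis_ratio_flag=pm.axis_ratio > panel.axis_ratio_min,
        morphometrics=pm,
        findings=tuple(findings),
    )


def score_cohort(
    cohort: CohortDataset,
    panel: CriteriaPanel | None = None,
    mode: AggregationMode = "per_cell",
    policy: SelectionPolicy | None = None,
    ellipse_perimeter: EllipsePerimeterMode = "rms",
) -> list[CriteriaResult]:
    """Select → aggregate → evaluate → categorize every patient.

    Per-patient failures become error findings on a low-information result
    rather than aborting the cohort; the pipeline is deterministic.
    """
    results: list[CriteriaResult] = []
    for patient in cohort.patients:
        try:
            pm = patient_morphometrics(
                patient, mode=mode, policy=policy, ellipse_perimeter=ellipse_perimeter
            )
        except (ValueError, ArithmeticError) as exc:
            results.append(
                CriteriaResult(
                    patient_id=patient.patient_id,
                    flags={name: False for name in CRITERION_NAMES},
                    n_cr=0,
                    risk="low",
                    axis_ratio_flag=False,
                    metastasis_status=patient.metastasis_status,
                    findings=(
                        Finding(
                            level="error",
                            code="patient_failed",
                            message=str(exc),
                            subject=patient.patient_id,
                        ),
                    ),
                )
            )
            continue
        result = evaluate_criteria(pm, panel)
        results.append(
            result.model_copy(update={"metastasis_status": patient.metastasis_status})
        )
    return results
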