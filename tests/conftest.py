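import math

import pytest
from hypothesis import HealthCheck, settings

from nucmorph.model import (
    CellMeasurement,
    MetastasisStatus,
    PatientSample,
    PixelCalibration,
)
from nucmorph.morphometry import PatientMorphometrics

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

# published group-level parameter profiles (bone-metastasis vs control)
METASTASIS_PROFILE = dict(
    mean_nuclear_area=42.583,
    nc_ratio=1.405,
    axis_ratio=1.323,
    acyclicity=1.175,
    mean_internuclear_distance=8.574,
    long_axis=8.411,
    small_axis=6.404,
    mean_nuclear_volume=181.023,
    anellipticity=1.151,
)
CONTROL_PROFILE = dict(
    mean_nuclear_area=64.718,
    nc_ratio=0.561,
    axis_ratio=1.268,
    acyclicity=1.145,
    mean_internuclear_distance=12.871,
    long_axis=10.630,
    small_axis=8.115,
    mean_nuclear_volume=347.615,
    anellipticity=1.126,
)


@pytest.fixture
def metastasis_pm() -> PatientMorphometrics:
    return PatientMorphometrics(patient_id="met-group", **METASTASIS_PROFILE)


@pytest.fixture
def control_pm() -> PatientMorphometrics:
    return PatientMorphometrics(patient_id="ctl-group", **CONTROL_PROFILE)


@pytest.fixture
def calibration() -> PixelCalibration:
    return PixelCalibration(microns_per_pixel=0.1)


def make_cell(
    cell_id: str = "c1",
    area: float = 42.583,
    perimeter: float = 27.181,
    long_axis: float = 8.411,
    cell_area: float | None = 72.893,
) -> CellMeasurement:
    """A cell matching the bone-metastasis mean profile by default.

    The perimeter is reconstructed from the published acyclicity grade:
    P = 1.175 · 2·sqrt(π·42.583) ≈ 27.181 µm.
    """
    return CellMeasurement(
        cell_id=cell_id,
        nucleus_area=area,
        nucleus_perimeter=perimeter,
        nucleus_long_axis=long_axis,
        cell_area=cell_area,
    )


def homogeneous_sample(
    n_cells: int = 80,
    patient_id: str = "p1",
    status: MetastasisStatus = MetastasisStatus.unknown,
    **cell_kwargs,
) -> PatientSample:
    return PatientSample(
        patient_id=patient_id,
        metastasis_status=status,
        cells=tuple(
            make_cell(cell_id=f"c{i}", **cell_kwargs) for i in range(n_cells)
        ),
    )


def circle_cell(cell_id: str = "circ", radius: float = 5.0) -> CellMeasurement:
    return CellMeasurement(
        cell_id=cell_id,
        nucleus_area=math.pi * radius**2,
        nucleus_perimeter=2.0 * math.pi * radius,
        nucleus_long_axis=2.0 * radius,
    )
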