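"""Per-cell shape descriptors and patient-level aggregation."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ellipe

from nucmorph.model import PatientSample, RegionMeasurement
from nucmorph.morphometry import (
    GeometryError,
    SelectionPolicy,
    acyclicity_grade,
    anellipticity_grade,
    axis_ratio,
    cell_morphometrics,
    ellipse_perimeter_rms,
    ellipsoid_volume,
    mean_internuclear_distance,
    nc_ratio_per_cell,
    nc_ratio_pooled,
    patient_morphometrics,
    select_nuclei,
    small_axis_from_area,
)

from conftest import circle_cell, homogeneous_sample, make_cell


def true_ellipse_perimeter(r1: float, r2: float) -> float:
    """Independent oracle: complete elliptic integral of the second kind."""
    return 4.0 * r1 * ellipe(1.0 - (r2 / r1) ** 2)


class TestSelectNuclei:
    def test_threshold_from_top_decile(self):
        cells = [make_cell(cell_id=str(a), area=a, long_axis=20.0,
                           cell_area=None)
                 for a in (100, 90, 80, 40, 30)]
        kept = select_nuclei(cells, SelectionPolicy())
        # top decile of 5 cells is the single largest (area 100);
        # threshold 50 keeps the three largest, in original order
        assert [c.cell_id for c in kept] == ["100", "90", "80"]

    def test_max_area_reference(self):
        cells = [make_cell(cell_id=str(a), area=a, long_axis=20.0,
                           cell_area=None)
                 for a in (100, 60, 49)]
        kept = select_nuclei(
            cells, SelectionPolicy(reference="max_area", fraction=0.5)
        )
        assert [c.cell_id for c in kept] == ["100", "60"]

    def test_equal_areas_all_kept(self):
        cells = [make_cell(cell_id=str(i)) for i in range(10)]
        assert len(select_nuclei(cells)) == 10

    def test_single_cell_kept(self):
        assert len(select_nuclei([make_cell()])) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_nuclei([])


class TestSmallAxis:
    @pytest.mark.parametrize(
        "area,long_axis,expected",
        [
            (42.583, 8.411, 6.446),        # published metastasis-group means
            (math.pi * 25.0, 10.0, 10.0),  # circle r=5
            (math.pi * 5 * 2.5, 10.0, 5.0),  # ellipse r1=5, r2=2.5
        ],
    )
    def test_examples(self, area, long_axis, expected):
        assert small_axis_from_area(area, long_axis) == pytest.approx(
            expected, abs=5e-4
        )

    def test_area_too_large_raises(self):
        with pytest.raises(GeometryError):
            small_axis_from_area(50.0, 4.0)

    @given(
        r1=st.floats(0.5, 50.0),
        r2_frac=st.floats(0.05, 1.0),
    )
    def test_inverts_ellipse_area(self, r1, r2_frac):
        r2 = r1 * r2_frac
        area = math.pi * r1 * r2
        assert small_axis_from_area(area, 2 * r1) == pytest.approx(
            2 * r2, rel=1e-9
        )


class TestAxisRatio:
    @pytest.mark.parametrize(
        "long,small,expected",
        [(10.0, 10.0, 1.0), (8.411, 6.446, 1.305), (10.0, 5.0, 2.0)],
    )
    def test_examples(self, long, small, expected):
        assert axis_ratio(long, small) == pytest.approx(expected, abs=5e-4)

    def test_small_above_long_raises(self):
        with pytest.raises(GeometryError):
            axis_ratio(5.0, 6.0)


class TestEllipsoidVolume:
    @pytest.mark.parametrize(
        "area,long_axis,expected",
        [
            (math.pi, 2.0, 4.0 * math.pi / 3.0),  # unit sphere
            (42.583, 8.411, 182.997),
            (math.pi * 5 * 2.5, 10.0, (4 / 3) * math.pi * 5 * 2.5**2),
        ],
    )
    def test_examples(self, area, long_axis, expected):
        assert ellipsoid_volume(area, long_axis) == pytest.approx(
            expected, abs=5e-3
        )

    @given(
        r1=st.floats(0.5, 50.0),
        r2_frac=st.floats(0.05, 1.0),
    )
    def test_closed_form_identity(self, r1, r2_frac):
        """V = (2/3) · A · small_axis for every admissible (A, L)."""
        area = math.pi * r1 * (r1 * r2_frac)
        long_axis = 2 * r1
        small = small_axis_from_area(area, long_axis)
        assert ellipsoid_volume(area, long_axis) == pytest.approx(
            (2.0 / 3.0) * area * small, rel=1e-9
        )


class TestAcyclicity:
    def test_circle_is_one(self):
        assert acyclicity_grade(2 * math.pi, math.pi) == pytest.approx(1.0)

    def test_square_closed_form(self):
        # square of side 2: P=8, A=4 -> 2/sqrt(pi)
        assert acyclicity_grade(8.0, 4.0) == pytest.approx(
            2.0 / math.sqrt(math.pi), rel=1e-12
        )

    def test_metastasis_profile_reconstruction(self):
        perimeter = 1.175 * 2.0 * math.sqrt(math.pi * 42.583)
        assert acyclicity_grade(perimeter, 42.583) == pytest.approx(1.175)

    @given(
        n=st.integers(3, 40),
        radius=st.floats(1.0, 20.0),
    )
    def test_regular_polygons_at_least_one(self, n, radius):
        """Isoperimetric inequality on exactly known convex shapes."""
        perimeter = 2 * n * radius * math.sin(math.pi / n)
        area = 0.5 * n * radius**2 * math.sin(2 * math.pi / n)
        assert acyclicity_grade(perimeter, area) >= 1.0


class TestAnellipticity:
    def test_circle_is_one(self):
        assert anellipticity_grade(2 * math.pi, 1.0, 1.0) == pytest.approx(1.0)

    def test_exact_ellipse_below_one(self):
        # RMS approximation overestimates the true arc length, so a perfect
        # ellipse grades slightly below 1
        p_true = true_ellipse_perimeter(2.0, 1.0)
        assert p_true == pytest.approx(9.6884, abs=2e-4)
        grade = anellipticity_grade(p_true, 2.0, 1.0)
        assert grade == pytest.approx(0.9752, abs=2e-4)
        assert grade < 1.0

    def test_rms_perimeter_matches_grade_one(self):
        p_rms = 2 * math.pi * math.sqrt((4.0 + 1.0) / 2.0)
        assert p_rms == pytest.approx(9.9346, abs=1e-3)
        assert anellipticity_grade(p_rms, 2.0, 1.0) == pytest.approx(1.0)

    @given(
        r1=st.floats(1.0, 20.0),
        r2_frac=st.floats(0.2, 1.0),
    )
    def test_rms_is_upper_bound_on_true_perimeter(self, r1, r2_frac):
        r2 = r1 * r2_frac
        assert ellipse_perimeter_rms(r1, r2) >= true_ellipse_perimeter(
            r1, r2
        ) * (1 - 1e-12)

    def test_code_compat_variant_drops_the_root(self):
        assert ellipse_perimeter_rms(2.0, 1.0, mode="code-compat") == (
            pytest.approx(2 * math.pi * 2.5)
        )


class TestNCRatio:
    @pytest.mark.parametrize(
        "nucleus,cell,expected",
        [(30.0, 60.0, 1.0), (42.583, 72.893, 1.405), (10.0, 110.0, 0.1)],
    )
    def test_per_cell(self, nucleus, cell, expected):
        assert nc_ratio_per_cell(nucleus, cell) == pytest.approx(
            expected, abs=5e-4
        )

    def test_cell_not_larger_raises(self):
        with pytest.raises(GeometryError):
            nc_ratio_per_cell(50.0, 50.0)

    @pytest.mark.parametrize(
        "region_area,n,mean_area,expected",
        [(300.0, 3, 50.0, 1.0), (150.0, 1, 50.0, 0.5), (437.36, 6, 42.583, 1.405)],
    )
    def test_pooled(self, region_area, n, mean_area, expected):
        region = RegionMeasurement(
            region_id="r", region_area=region_area, nucleus_count=n
        )
        assert nc_ratio_pooled(region, mean_area) == pytest.approx(
            expected, abs=2e-3
        )

    def test_pooled_region_too_small_raises(self):
        region = RegionMeasurement(region_id="r", region_area=100.0, nucleus_count=3)
        with pytest.raises(GeometryError):
            nc_ratio_pooled(region, 50.0)


class TestInternuclearDistance:
    @pytest.mark.parametrize(
        "mean_cell_area,expected",
        [(100.0, 10.0), (72.893, 8.538), (110.25, 10.5)],
    )
    def test_examples(self, mean_cell_area, expected):
        assert mean_internuclear_distance(mean_cell_area) == pytest.approx(
            expected, abs=5e-4
        )

    def test_non_positive_raises(self):
        with pytest.raises(GeometryError):
            mean_internuclear_distance(0.0)


class TestPatientAggregation:
    def test_modes_agree_on_homogeneous_sample(self):
        sample = homogeneous_sample(70)
        per_cell = patient_morphometrics(sample, mode="per_cell")
        from_means = patient_morphometrics(sample, mode="from_means")
        for name in (
            "mean_nuclear_area", "nc_ratio", "axis_ratio", "acyclicity",
            "mean_internuclear_distance", "long_axis", "small_axis",
            "mean_nuclear_volume", "anellipticity",
        ):
            assert per_cell.parameter(name) == pytest.approx(
                from_means.parameter(name), rel=1e-9
            ), name

    def test_from_means_composition(self):
        pm = patient_morphometrics(homogeneous_sample(60), mode="from_means")
        assert pm.small_axis == pytest.approx(6.446, abs=5e-4)
        assert pm.mean_nuclear_volume == pytest.approx(182.997, abs=5e-3)

    def test_circles_give_unit_grades(self):
        sample = PatientSample(
            patient_id="circles",
            cells=(circle_cell("a"), circle_cell("b")),
        )
        pm = patient_morphometrics(sample)
        assert pm.acyclicity == pytest.approx(1.0)
        assert pm.axis_ratio == pytest.approx(1.0)
        assert pm.anellipticity == pytest.approx(1.0)

    def test_missing_cytoplasm_reported_as_none_with_warning(self):
        sample = homogeneous_sample(60, cell_area=None)
        pm = patient_morphometrics(sample)
        assert pm.nc_ratio is None
        assert pm.mean_internuclear_distance is None
        assert any(f.code == "no_cytoplasm_data" for f in pm.findings)

    def test_pooled_regions_supply_cytoplasm(self):
        cells = tuple(
            make_cell(cell_id=f"c{i}", cell_area=None) for i in range(60)
        )
        # region sized for exactly the published N/C: 6 cells, each with
        # cytoplasm A/1.405
        region_area = 6 * 42.583 * (1 + 1 / 1.405)
        sample = PatientSample(
            patient_id="pooled",
            cells=cells,
            regions=(
                RegionMeasurement(
                    region_id="r1", region_area=region_area, nucleus_count=6
                ),
            ),
        )
        pm = patient_morphometrics(sample)
        assert pm.nc_ratio == pytest.approx(1.405, rel=1e-6)
        assert pm.mean_internuclear_distance == pytest.approx(
            math.sqrt(region_area / 6), rel=1e-9
        )

    @given(scale=st.floats(0.2, 5.0))
    def test_scale_covariance(self, scale):
        """Scaling lengths by k scales areas k², volumes k³ and leaves the
        dimensionless descriptors unchanged."""
        base = make_cell()
        scaled = make_cell(
            area=base.nucleus_area * scale**2,
            perimeter=base.nucleus_perimeter * scale,
            long_axis=base.nucleus_long_axis * scale,
            cell_area=base.cell_area * scale**2,
        )
        m0 = cell_morphometrics(base)
        m1 = cell_morphometrics(scaled)
        assert m1.small_axis == pytest.approx(m0.small_axis * scale, rel=1e-9)
        assert m1.nuclear_volume == pytest.approx(
            m0.nuclear_volume * scale**3, rel=1e-9
        )
        for name in ("axis_ratio", "acyclicity", "anellipticity", "nc_ratio"):
            assert getattr(m1, name) == pytest.approx(
                getattr(m0, name), rel=1e-9
            ), name
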