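import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdukinetics.geometry import (
    CompartmentEnsemble,
    ParameterError,
    make_capsule_cell,
    make_cylinder,
    make_sphere,
    match_ensemble,
    sa_v_fold_factor,
)

NM3_PER_UM3 = 1e9
NM2_PER_UM2 = 1e6


class TestShapes:
    @pytest.mark.parametrize(
        "diameter,area_nm2,volume_nm3",
        [
            (140.0, 6.1575e4, 1.4368e6),  # the modelled MCP
            (2.0, 4 * math.pi, 4 * math.pi / 3),  # unit radius
        ],
    )
    def test_sphere_area_volume(self, diameter, area_nm2, volume_nm3):
        g = make_sphere(diameter)
        assert g.area_per_compartment * NM2_PER_UM2 == pytest.approx(area_nm2, rel=1e-4)
        assert g.volume_per_compartment * NM3_PER_UM3 == pytest.approx(volume_nm3, rel=1e-4)

    def test_cylinder_lateral_only(self):
        g = make_cylinder(50.0, 2500.0)
        assert g.area_per_compartment * NM2_PER_UM2 == pytest.approx(3.9270e5, rel=1e-4)
        assert g.volume_per_compartment * NM3_PER_UM3 == pytest.approx(4.9087e6, rel=1e-4)

    def test_cylinder_with_end_caps(self):
        g = make_cylinder(50.0, 2500.0, include_end_area=True)
        assert g.area_per_compartment * NM2_PER_UM2 == pytest.approx(3.9663e5, rel=1e-3)
        assert g.area_ends * NM2_PER_UM2 == pytest.approx(2 * math.pi * 625, rel=1e-6)

    @pytest.mark.parametrize(
        "ctor,args",
        [
            (make_sphere, (0.0,)),
            (make_sphere, (-1.0,)),
            (make_cylinder, (50.0, 0.0)),
            (make_cylinder, (0.0, 2500.0)),
        ],
    )
    def test_degenerate_dimensions_rejected(self, ctor, args):
        with pytest.raises(ParameterError):
            ctor(*args)

    def test_capsule_cell(self):
        c = make_capsule_cell(0.5, 2.5)
        r, body = 0.5, 1.5
        assert c.cell_volume == pytest.approx(
            math.pi * r**2 * body + 4 / 3 * math.pi * r**3
        )
        assert c.membrane_area == pytest.approx(
            2 * math.pi * r * body + 4 * math.pi * r**2
        )


class TestMatching:
    @pytest.fixture()
    def base(self):
        return CompartmentEnsemble(make_sphere(140.0), 15.0)

    @pytest.fixture()
    def mt(self):
        return make_cylinder(50.0, 2500.0)

    def test_equal_volume_count_and_area_fold(self, base, mt):
        matched = match_ensemble(base, mt, "equal_volume")
        assert matched.count == pytest.approx(4.390, abs=5e-3)
        assert matched.total_volume == pytest.approx(base.total_volume, rel=1e-12)
        fold = matched.total_area / base.total_area
        assert fold == pytest.approx(1.87, abs=5e-3)
        assert round(fold, 1) == 1.9

    def test_equal_area_count_and_concentration_fold(self, base, mt):
        matched = match_ensemble(base, mt, "equal_area")
        assert matched.count == pytest.approx(2.352, abs=5e-3)
        assert matched.total_area == pytest.approx(base.total_area, rel=1e-12)
        conc_fold = base.total_volume / matched.total_volume
        assert conc_fold == pytest.approx(1.87, abs=5e-3)
        assert round(conc_fold, 1) == 1.9

    def test_fixed_count_identity(self, base):
        same = match_ensemble(base, base.geometry, "fixed_count", count=base.count)
        assert same.count == base.count
        assert same.total_area == base.total_area

    def test_fixed_count_requires_count(self, base, mt):
        with pytest.raises(ParameterError):
            match_ensemble(base, mt, "fixed_count")

    @given(
        r_s=st.floats(1.0, 500.0),
        r_c=st.floats(1.0, 500.0),
        count=st.floats(1.0, 100.0),
        length=st.floats(100.0, 10000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_equal_volume_fold_matches_closed_form(self, r_s, r_c, count, length):
        """Area fold under equal-volume matching equals 2 r_s / (3 r_c)."""
        base = CompartmentEnsemble(make_sphere(2 * r_s), count)
        matched = match_ensemble(base, make_cylinder(2 * r_c, length), "equal_volume")
        fold = matched.total_area / base.total_area
        assert fold == pytest.approx(sa_v_fold_factor(r_s / 1e3, r_c / 1e3), rel=1e-9)

    @given(r_s=st.floats(1.0, 500.0), r_c=st.floats(1.0, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_area_and_volume_folds_are_reciprocal(self, r_s, r_c):
        base = CompartmentEnsemble(make_sphere(2 * r_s), 15.0)
        cyl = make_cylinder(2 * r_c, 2500.0)
        area_fold = match_ensemble(base, cyl, "equal_volume").total_area / base.total_area
        vol_fold = match_ensemble(base, cyl, "equal_area").total_volume / base.total_volume
        assert area_fold * vol_fold == pytest.approx(1.0, rel=1e-9)

    def test_fold_symmetry_point(self):
        # 2 r_s = 3 r_c makes sphere and lateral cylinder folds cancel
        assert sa_v_fold_factor(3.0, 2.0) == pytest.approx(1.0)
        assert sa_v_fold_factor(1.5 * 7.0, 7.0) == pytest.approx(1.0)

    def test_printed_dimensions_give_1p87(self):
        assert sa_v_fold_factor(70.0, 25.0) == pytest.approx(1.8667, abs=1e-4)
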