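"""Melanosome geometry, grid enumeration and unit-cell slicing."""

import math

import numpy as np
import pytest

from iridisim.structures import (
    Melanosome,
    MelanosomeKind,
    Packing,
    PhotonicCrystalSpec,
    classify_rod,
    cross_section_fractions,
    derived_metrics,
    enumerate_grid,
    grid_from_csv,
    grid_to_csv,
    keratin_spacing,
    read_structure_database,
    total_depth,
    vertical_period,
)


def _rod(d, d_air=0.0, kind=None):
    if kind is None:
        kind = (
            MelanosomeKind.HOLLOW_ROD
            if d_air
            else (
                MelanosomeKind.THIN_SOLID_ROD
                if d < 190
                else MelanosomeKind.THICK_SOLID_ROD
            )
        )
    return Melanosome(kind, d, d_air)


class TestMelanosomeInvariants:
    def test_solid_kinds_require_zero_air(self):
        with pytest.raises(ValueError):
            Melanosome(MelanosomeKind.THIN_SOLID_ROD, 100.0, d_air=20.0)

    def test_hollow_kinds_require_air_core(self):
        with pytest.raises(ValueError):
            Melanosome(MelanosomeKind.HOLLOW_ROD, 200.0, d_air=0.0)

    def test_air_core_smaller_than_diameter(self):
        with pytest.raises(ValueError):
            Melanosome(MelanosomeKind.HOLLOW_ROD, 200.0, d_air=200.0)

    def test_platelets_must_be_wider_than_tall(self):
        with pytest.raises(ValueError):
            Melanosome(MelanosomeKind.SOLID_PLATELET, 100.0, l_melsom=100.0)
        m = Melanosome(MelanosomeKind.SOLID_PLATELET, 100.0, l_melsom=240.0)
        assert m.l_melsom == 240.0

    def test_rods_default_width_to_diameter(self):
        assert _rod(150.0).l_melsom == 150.0


@pytest.mark.parametrize(
    "m,expected",
    [
        (_rod(200.0), dict(mt=200.0, hollowness=0.0, flatness=1.0)),
        (_rod(200.0, 100.0), dict(mt=50.0, hollowness=0.5, flatness=1.0)),
        (
            Melanosome(MelanosomeKind.HOLLOW_PLATELET, 135.0, 0.26 * 135.0, 2.4 * 135.0),
            dict(mt=49.95, hollowness=0.26, flatness=2.4),
        ),
    ],
)
def test_derived_metrics(m, expected):
    got = derived_metrics(m)
    for key, val in expected.items():
        assert got[key] == pytest.approx(val)


def test_keratin_spacing():
    spec = PhotonicCrystalSpec(_rod(190.0), Packing.LAMINAR, a=300.0, c=10.0)
    assert keratin_spacing(spec) == pytest.approx(110.0)
    touching = PhotonicCrystalSpec(_rod(200.0, 100.0), Packing.LAMINAR, a=200.0, c=0.0)
    assert keratin_spacing(touching) == 0.0
    with pytest.raises(ValueError):
        PhotonicCrystalSpec(_rod(300.0), Packing.LAMINAR, a=200.0, c=0.0)


@pytest.mark.parametrize(
    "d,expected",
    [
        (100.0, MelanosomeKind.THIN_SOLID_ROD),
        (200.0, MelanosomeKind.THICK_SOLID_ROD),
        (190.0, MelanosomeKind.THICK_SOLID_ROD),
    ],
)
def test_classify_rod(d, expected):
    assert classify_rod(d) is expected


def test_classify_rod_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_rod(0.0)


class TestGridEnumeration:
    @pytest.mark.parametrize(
        "kind,count",
        [
            ("thin_solid_rod", 900),
            ("thick_solid_rod", 900),
            ("hollow_rod", 900),
            ("solid_platelet", 450),
            ("hollow_platelet", 450),
        ],
    )
    def test_counts(self, kind, count):
        assert len(enumerate_grid(kind)) == count

    def test_platelet_doubling_switch(self):
        assert len(enumerate_grid("solid_platelet", duplicate_laminar=True)) == 900
        # rods are unaffected by the switch
        assert len(enumerate_grid("thin_solid_rod", duplicate_laminar=True)) == 900

    def test_deterministic_and_order_stable(self):
        a = enumerate_grid("hollow_rod")
        b = enumerate_grid("hollow_rod")
        assert a == b

    def test_all_layers_default_four_and_invariants_hold(self):
        for spec in enumerate_grid("hollow_platelet"):
            assert spec.n_layers == 4
            assert 0 < spec.relative_spacing <= 0.5
            assert keratin_spacing(spec) >= 0

    def test_derived_kinds_have_thin_layers_across_grid(self):
        # every hollow / platelet structure in the grids has mt < 190 nm
        for kind in ("hollow_rod", "solid_platelet", "hollow_platelet"):
            for spec in enumerate_grid(kind):
                assert derived_metrics(spec.melanosome)["mt"] < 190.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid("porous_rod")


class TestCrossSection:
    def test_cortex_is_pure_keratin(self):
        spec = PhotonicCrystalSpec(_rod(200.0), Packing.LAMINAR, a=300.0, c=100.0)
        f = cross_section_fractions(spec, 50.0)
        assert f == {"f_mel": 0.0, "f_air": 0.0, "f_ker": 1.0}

    def test_touching_solid_rod_center_fills_period(self):
        spec = PhotonicCrystalSpec(_rod(200.0), Packing.LAMINAR, a=200.0, c=0.0)
        f = cross_section_fractions(spec, 100.0)  # centre of first rod layer
        assert f["f_mel"] == pytest.approx(1.0)

    def test_hollow_rod_center_chords(self):
        spec = PhotonicCrystalSpec(_rod(200.0, 100.0), Packing.LAMINAR, a=200.0, c=0.0)
        f = cross_section_fractions(spec, 100.0)
        assert f["f_mel"] == pytest.approx(0.5)
        assert f["f_air"] == pytest.approx(0.5)

    def test_depth_out_of_range_rejected(self):
        spec = PhotonicCrystalSpec(_rod(200.0), Packing.LAMINAR, a=300.0, c=0.0)
        with pytest.raises(ValueError):
            cross_section_fractions(spec, total_depth(spec) + 1.0)

    def test_fractions_sum_to_one_everywhere(self):
        spec = PhotonicCrystalSpec(
            Melanosome(MelanosomeKind.HOLLOW_PLATELET, 150.0, 60.0, 360.0),
            Packing.LAMINAR, a=280.0, c=40.0,
        )
        for z in np.linspace(0, total_depth(spec), 57):
            f = cross_section_fractions(spec, z)
            assert f["f_mel"] + f["f_air"] + f["f_ker"] == pytest.approx(1.0)
            assert all(v >= -1e-12 for v in f.values())

    @pytest.mark.parametrize(
        "m,packing,a",
        [
            (_rod(200.0), Packing.LAMINAR, 320.0),
            (_rod(200.0, 90.0), Packing.LAMINAR, 280.0),
            (_rod(180.0, 70.0), Packing.HEXAGONAL, 260.0),
            (
                Melanosome(MelanosomeKind.HOLLOW_PLATELET, 140.0, 56.0, 336.0),
                Packing.LAMINAR,
                300.0,
            ),
        ],
    )
    def test_integrated_melanin_area_matches_analytic(self, m, packing, a):
        """Slicing at 1 nm reproduces the melanosome cross-section area."""
        spec = PhotonicCrystalSpec(m, packing, a=a, c=0.0, n_layers=1)
        period = m.l_melsom if m.kind.is_platelet else m.d_melsom
        vp = vertical_period(spec)
        zs = np.arange(0.5, vp, 1.0)
        area = sum(
            cross_section_fractions(spec, z)["f_mel"] * period for z in zs
        )
        expected = math.pi * (m.d_melsom / 2) * (m.l_melsom / 2)
        if m.kind.is_hollow:
            l_air = m.l_melsom * m.d_air / m.d_melsom
            expected -= math.pi * (m.d_air / 2) * (l_air / 2)
        assert area == pytest.approx(expected, rel=0.005)

    def test_hexagonal_rejected_for_platelets(self):
        m = Melanosome(MelanosomeKind.SOLID_PLATELET, 100.0, l_melsom=240.0)
        with pytest.raises(ValueError):
            PhotonicCrystalSpec(m, Packing.HEXAGONAL, a=250.0, c=0.0)

    def test_hexagonal_vertical_period(self):
        spec = PhotonicCrystalSpec(_rod(180.0, 70.0), Packing.HEXAGONAL, a=260.0, c=0.0)
        assert vertical_period(spec) == pytest.approx(260.0 * math.sqrt(3) / 2)
        assert total_depth(spec) == pytest.approx(4 * 260.0 * math.sqrt(3) / 2)


def test_grid_csv_round_trip(tmp_path):
    specs = enumerate_grid("hollow_rod")[:25]
    path = tmp_path / "grid.csv"
    grid_to_csv(specs, path)
    back = grid_from_csv(path)
    assert len(back) == len(specs)
    for a, b in zip(specs, back):
        assert a.melanosome.kind is b.melanosome.kind
        assert a.packing is b.packing
        assert a.n_layers == b.n_layers
        assert b.melanosome.d_melsom == pytest.approx(a.melanosome.d_melsom, rel=1e-12)
        assert b.melanosome.d_air == pytest.approx(a.melanosome.d_air, rel=1e-12, abs=1e-12)
        assert b.a == pytest.approx(a.a, rel=1e-12)
        assert b.c == pytest.approx(a.c, rel=1e-12)


def test_read_structure_database_with_column_map(tmp_path):
    path = tmp_path / "db.csv"
    path.write_text(
        "taxon,type,diam\nGallus_gallus,hollow_rod,210.5\nPavo_cristatus,thin_solid_rod,120\n"
    )
    df = read_structure_database(
        path, column_map={"species": "taxon", "kind": "type", "d_melsom": "diam"}
    )
    assert list(df["species"]) == ["Gallus_gallus", "Pavo_cristatus"]
    assert df["d_melsom"].iloc[0] == pytest.approx(210.5)
    with pytest.raises(ValueError):
        read_structure_database(path)
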