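"""Zone densities, count extrapolation and colony totals."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guanofe.census import (
    ClassMismatchError,
    IncompleteCensusError,
    InvalidGeometryError,
    WrongCRSError,
    ZoneCensus,
    complete_census,
    extrapolate_count,
    polygon_area,
    total_census,
    zone_density,
)
from guanofe.quantities import UncertainQuantity as UQ


class TestPolygonArea:
    def test_unit_square(self):
        out = polygon_area([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert out.value == pytest.approx(1.0)
        assert out.sd == 0 and out.unit == "m2"

    def test_grz_scale_rectangle(self):
        # 100 m × 43.56 m: the zone area consistent with 2265 birds at
        # 0.52 ind/m2
        out = polygon_area([(0, 0), (100, 0), (100, 43.56), (0, 43.56)])
        assert out.value == pytest.approx(4356.0)

    def test_degenerate_two_point_ring(self):
        with pytest.raises(InvalidGeometryError):
            polygon_area([(0, 0), (1, 1)])

    def test_self_intersecting_bowtie(self):
        with pytest.raises(InvalidGeometryError):
            polygon_area([(0, 0), (10, 10), (10, 0), (0, 10)])

    def test_lonlat_footprint_flagged(self):
        # a ~50 m colony zone expressed in degrees near Deception Island
        ring = [(-60.726, -62.992), (-60.7255, -62.992),
                (-60.7255, -62.9915), (-60.726, -62.9915)]
        with pytest.raises(WrongCRSError):
            polygon_area(ring)

    def test_geojson_mapping_accepted(self):
        gj = {"type": "Polygon",
              "coordinates": [[(0, 0), (1000, 0), (1000, 500), (0, 500), (0, 0)]]}
        assert polygon_area(gj).value == pytest.approx(5e5)


class TestZoneDensity:
    def test_grz_density(self):
        d = zone_density(UQ(2265, 159, "ind"), UQ(4356, 0, "m2"))
        assert d.value == pytest.approx(0.52, abs=0.005)
        assert d.unit == "ind/m2"

    def test_oz_density(self):
        d = zone_density(UQ(1853, 130, "ind"), UQ(66179, 0, "m2"))
        assert d.value == pytest.approx(0.028, abs=0.0005)

    def test_zero_count(self):
        d = zone_density(UQ(0, 0, "ind"), UQ(100, 0, "m2"))
        assert d.value == 0 and d.sd == 0


class TestExtrapolation:
    def test_grz_extrapolation(self):
        n = extrapolate_count(UQ(0.52, 0.03, "ind/m2"), UQ(14637, 0, "m2"))
        assert n.value == pytest.approx(7611, rel=0.001)

    def test_oz_extrapolation(self):
        n = extrapolate_count(UQ(0.028, 0.01, "ind/m2"), UQ(178429, 0, "m2"))
        assert n.value == pytest.approx(4996, rel=0.001)

    def test_zero_density(self):
        assert extrapolate_count(UQ(0, 0, "ind/m2"), UQ(1e4, 0, "m2")).value == 0

    def test_cross_class_transfer_rejected(self):
        with pytest.raises(ClassMismatchError):
            extrapolate_count(UQ(0.52, 0.03, "ind/m2"), UQ(1e4, 0, "m2"),
                              source_class="GRZ", target_class="OZ")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(count=st.floats(1, 1e5), area=st.floats(1, 1e6),
           sd=st.floats(0, 100))
    def test_density_extrapolation_round_trip(self, count, area, sd):
        a = UQ(area, 0, "m2")
        c = UQ(count, sd, "ind")
        back = extrapolate_count(zone_density(c, a), a)
        assert back.value == pytest.approx(count, rel=1e-9)
        assert back.sd == pytest.approx(sd, rel=1e-9, abs=1e-12)


class TestTotals:
    def test_reported_colony_total(self, printed_zones):
        total = total_census(printed_zones)
        assert total.value == 16725

    def test_single_zone_identity(self, printed_zones):
        assert total_census(printed_zones[:1]).value == 2265

    def test_quadrature_of_two_zones(self, printed_zones):
        total = total_census(printed_zones[:2])
        assert total.value == 4118
        assert total.sd == pytest.approx(math.hypot(159, 130))

    def test_permutation_invariance(self, printed_zones):
        fwd = total_census(printed_zones)
        rev = total_census(printed_zones[::-1])
        assert fwd.value == rev.value and fwd.sd == pytest.approx(rev.sd)

    def test_additive_over_partition(self, printed_zones):
        whole = total_census(printed_zones)
        parts = (total_census(printed_zones[:2]).value
                 + total_census(printed_zones[2:]).value)
        assert whole.value == pytest.approx(parts)

    def test_missing_count_rejected(self, printed_zones):
        zones = printed_zones[:1] + [
            ZoneCensus("EXTRA", "OZ", UQ(100, 0, "m2"))]
        with pytest.raises(IncompleteCensusError):
            total_census(zones)


class TestCompleteCensus:
    def test_classwise_density_transfer(self):
        zones = [
            ZoneCensus("S_GRZ", "GRZ", UQ(4356, 0, "m2"), UQ(2265, 159, "ind")),
            ZoneCensus("S_OZ", "OZ", UQ(66179, 0, "m2"), UQ(1853, 130, "ind")),
            ZoneCensus("U_GRZ", "GRZ", UQ(14637, 0, "m2")),
            ZoneCensus("U_OZ", "OZ", UQ(178429, 0, "m2")),
        ]
        done = {z.zone_id: z for z in complete_census(zones)}
        assert done["U_GRZ"].count.value == pytest.approx(7611, rel=0.001)
        assert done["U_OZ"].count.value == pytest.approx(4996, rel=0.001)
        assert round(total_census(list(done.values())).value) == 16725

    def test_unsurveyed_class_without_source_rejected(self):
        zones = [
            ZoneCensus("S_GRZ", "GRZ", UQ(4356, 0, "m2"), UQ(2265, 159, "ind")),
            ZoneCensus("U_OZ", "OZ", UQ(178429, 0, "m2")),
        ]
        with pytest.raises(IncompleteCensusError):
            complete_census(zones)
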