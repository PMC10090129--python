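"""Synthetic colonies: determinism, construction invariants, estimator recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from guanofe.census import ZoneCensus, complete_census, total_census
from guanofe.accumulation import guano_mass_from_census
from guanofe.discharge import WaterCompartment, release_efficiency, water_fe_inventory
from guanofe.quantities import InvalidConfigurationError, UncertainQuantity as UQ
from guanofe.synthetic_data import (
    SyntheticColonyConfig,
    simulate_colony,
    simulate_discharge_observation,
)


def zones_from_frame(df: pd.DataFrame) -> list[ZoneCensus]:
    out = []
    for r in df.itertuples():
        count = None if pd.isna(r.count) else UQ(r.count, r.count_sd, "ind")
        out.append(ZoneCensus(r.zone_id, r.zone_class,
                              UQ(r.area_m2, 0, "m2"), count))
    return out


def estimate_release_fraction(df: pd.DataFrame, truth: dict,
                              cfg: SyntheticColonyConfig):
    """The full estimation chain a survey would go through."""
    total = total_census(complete_census(zones_from_frame(df)))
    pool = guano_mass_from_census(total, cfg.breeding_days, cfg.guano_params)
    comp = WaterCompartment(
        surface_area=UQ(cfg.water_surface_m2, 0, "m2"),
        mean_depth=UQ(cfg.water_depth_m, 0, "m"),
        fe_conc=UQ(truth["water_fe_conc_mg_per_L"], 0, "mg/L"))
    eff = release_efficiency(water_fe_inventory(comp), pool.fe_mass)
    return eff.value, total, pool


class TestSimulateColony:
    def test_fixed_seed_reproduces_exactly(self):
        cfg = SyntheticColonyConfig()
        a, ta = simulate_colony(cfg, seed=5)
        b, tb = simulate_colony(cfg, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert ta == tb

    def test_different_seeds_differ(self):
        cfg = SyntheticColonyConfig()
        a, _ = simulate_colony(cfg, seed=5)
        b, _ = simulate_colony(cfg, seed=6)
        assert not a["count"].dropna().equals(b["count"].dropna())

    def test_zero_detection_error_gives_true_counts(self):
        cfg = SyntheticColonyConfig(detection_error_sd=0.0)
        df, truth = simulate_colony(cfg, seed=2)
        surveyed = df.dropna(subset=["count"])
        for r in surveyed.itertuples():
            assert r.count == pytest.approx(truth["zone_counts"][r.zone_id])

    def test_reproduces_field_scale_grz_count(self):
        # GRZ density 0.52 on a 4356 m2 zone carries ~2265 birds
        cfg = SyntheticColonyConfig(
            n_zones={"GRZ": 1}, true_density={"GRZ": 0.52},
            area_range_m2={"GRZ": (4356.0, 4356.0)},
            detection_error_sd=0.0, unsurveyed_fraction=0.0)
        _, truth = simulate_colony(cfg, seed=0)
        assert truth["zone_counts"]["GRZ_0"] == pytest.approx(0.52 * 4356)

    def test_some_zones_withheld_for_extrapolation(self):
        df, _ = simulate_colony(SyntheticColonyConfig(), seed=9)
        assert df["count"].isna().any() and df["count"].notna().any()

    def test_negative_density_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            SyntheticColonyConfig(true_density={"GRZ": -0.1, "OZ": 0.01})


class TestDischargeObservation:
    def test_inverts_to_reported_scale(self):
        conc = simulate_discharge_observation(
            UQ(506, 0, "kg"), 0.0514, surface_area_m2=4e4, mean_depth_m=2.0)
        assert conc.value == pytest.approx(0.325, abs=0.001)

    def test_zero_fraction(self):
        conc = simulate_discharge_observation(
            UQ(506, 0, "kg"), 0.0, surface_area_m2=4e4, mean_depth_m=2.0)
        assert conc.value == 0

    def test_round_trip_is_machine_exact(self):
        pool = UQ(321.7, 0, "kg")
        conc = simulate_discharge_observation(
            pool, 0.0713, surface_area_m2=3e4, mean_depth_m=1.5)
        comp = WaterCompartment(surface_area=UQ(3e4, 0, "m2"),
                                mean_depth=UQ(1.5, 0, "m"), fe_conc=conc)
        eff = release_efficiency(water_fe_inventory(comp), pool)
        assert eff.value == pytest.approx(0.0713, rel=1e-12)

    def test_zero_volume_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            simulate_discharge_observation(UQ(1, 0, "kg"), 0.1,
                                           surface_area_m2=0.0, mean_depth_m=2)


@pytest.fixture(scope="module")
def replicates():
    """200 simulated colonies pushed through the full estimation chain."""
    cfg = SyntheticColonyConfig()
    rows = []
    for i in range(200):
        df, truth = simulate_colony(cfg, seed=i)
        eff, total, pool = estimate_release_fraction(df, truth, cfg)
        rows.append({
            "eff_err": eff - truth["release_fraction"],
            "total_err": total.value - truth["total_count"],
            "pool_covered": abs(pool.fe_mass.to("kg").value
                                - truth["pool_fe_kg"])
            <= pool.fe_mass.to("kg").sd,
        })
    return pd.DataFrame(rows)


class TestParameterRecovery:
    """Normal-theory checks of the full estimation chain on 200 colonies."""

    def test_release_fraction_unbiased(self, replicates):
        err = replicates["eff_err"].to_numpy()
        se = err.std(ddof=1) / np.sqrt(len(err))
        assert abs(err.mean()) < 2 * se

    def test_census_total_unbiased(self, replicates):
        err = replicates["total_err"].to_numpy()
        se = err.std(ddof=1) / np.sqrt(len(err))
        assert abs(err.mean()) < 2 * se

    def test_pool_interval_coverage_near_nominal(self, replicates):
        coverage = replicates["pool_covered"].mean()
        assert 0.62 <= coverage <= 0.74


def test_census_estimator_unbiased_over_500_detections():
    """Mean extrapolated total over 500 simulated detections matches truth."""
    cfg = dataclasses.replace(SyntheticColonyConfig())
    errs = []
    for i in range(500):
        df, truth = simulate_colony(cfg, seed=10_000 + i)
        total = total_census(complete_census(zones_from_frame(df)))
        errs.append(total.value - truth["total_count"])
    errs = np.asarray(errs)
    se = errs.std(ddof=1) / np.sqrt(len(errs))
    assert abs(errs.mean()) < 2 * se
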