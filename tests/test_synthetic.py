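"""Generator contracts: determinism, injected-trend calibration, ranges."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from medseas.config import InvalidConfigError, GroupSpec, ScenarioConfig
from medseas.regions import period_windows
from medseas.synthetic import (
    gen_coastal_stretches,
    gen_foodweb_outputs,
    gen_habitat_layers,
    gen_ocean_fields,
    gen_recreation_layers,
    gen_survey_hauls,
    window_factors,
)

from conftest import tiny_config


def _window_means(field: xr.DataArray, kind: str):
    return [
        float(field.isel(time=np.flatnonzero(p.contains(field["time"].values))).mean())
        for p in period_windows(kind)
    ]


class TestDeterminism:
    def test_same_config_same_seed_identical(self):
        cfg = tiny_config(noise_sd=0.05)
        a, b = gen_ocean_fields(cfg), gen_ocean_fields(cfg)
        xr.testing.assert_identical(a, b)
        pd.testing.assert_frame_equal(gen_foodweb_outputs(cfg), gen_foodweb_outputs(cfg))
        pd.testing.assert_frame_equal(gen_survey_hauls(cfg), gen_survey_hauls(cfg))
        pd.testing.assert_frame_equal(
            gen_coastal_stretches(cfg)[0], gen_coastal_stretches(cfg)[0]
        )
        xr.testing.assert_identical(
            gen_recreation_layers(cfg)[0], gen_recreation_layers(cfg)[0]
        )
        xr.testing.assert_identical(gen_habitat_layers(cfg)[0], gen_habitat_layers(cfg)[0])

    def test_different_seeds_differ(self):
        a = gen_foodweb_outputs(tiny_config(seed=1, noise_sd=0.05))
        b = gen_foodweb_outputs(tiny_config(seed=2, noise_sd=0.05))
        assert not a.equals(b)


class TestOceanFields:
    def test_exact_multiplicative_ppr_trend(self):
        cfg = tiny_config(trend_spec={"ppr": 0.5}, base_ppr=2.0)
        ppr = gen_ocean_fields(cfg)["ppr"]
        means = _window_means(ppr, "biogeochemistry")
        assert means[0] == pytest.approx(2.0)
        assert means[2] == pytest.approx(3.0)

    def test_eke_trend_applies_to_kinetic_energy(self):
        # scaling speed by sqrt(1+t) must scale KE by exactly 1+t
        cfg = tiny_config(trend_spec={"eke": 0.3}, spatial_amp=0.3)
        ds = gen_ocean_fields(cfg)
        ke = 0.5 * (ds["u"] ** 2 + ds["v"] ** 2)
        means = _window_means(ke, "biogeochemistry")
        assert means[2] / means[0] == pytest.approx(1.3, rel=1e-9)

    def test_noisy_trend_recovered_within_tolerance(self):
        # Monte-Carlo calibration on >= 1000 sea cells
        cfg = ScenarioConfig(
            seed=3, noise_sd=0.05, nlat=25, nlon=50, n_land_rows=5,
            trend_spec={"ppr": 0.5},
        )
        means = _window_means(gen_ocean_fields(cfg)["ppr"], "biogeochemistry")
        assert means[2] / means[0] - 1 == pytest.approx(0.5, abs=0.05)

    def test_units_and_masking(self):
        cfg = tiny_config()
        ds = gen_ocean_fields(cfg)
        assert ds["ppr"].attrs["units"] == "mmolN m-2 d-1"
        land = ~cfg.sea_mask()
        assert np.isnan(ds["u"].values[:, land]).all()
        assert (ds["ppr"].values[:, cfg.sea_mask()] >= 0).all()

    def test_nonpositive_grid_rejected(self):
        with pytest.raises(InvalidConfigError):
            ScenarioConfig(nlat=0)


class TestFoodWeb:
    def test_exact_hake_biomass_trend(self):
        cfg = tiny_config(trend_spec={"biomass_hake": -0.4})
        df = gen_foodweb_outputs(cfg)
        hake = df[(df["group"] == "hake") & (df["sub_basin"] == "Western")]
        first = hake[hake["year"] < 1970]["biomass"].mean()
        last = hake[hake["year"] >= 2000]["biomass"].mean()
        assert last / first == pytest.approx(0.6, rel=1e-9)

    def test_catch_bounded_by_exploitation(self):
        cfg = tiny_config(noise_sd=0.1, trend_spec={"catch": 0.5, "biomass_hake": -0.4})
        df = gen_foodweb_outputs(cfg)
        assert (df["catch"] <= cfg.max_exploitation * df["biomass"] + 1e-12).all()

    def test_trophic_level_constant_per_group(self):
        df = gen_foodweb_outputs(tiny_config(noise_sd=0.05))
        assert (df.groupby("group")["trophic_level"].nunique() == 1).all()

    def test_trophic_level_out_of_range_rejected(self):
        bad = [
            GroupSpec("pilchard_anchovy", 3.1, True, 6.0, 0.25),
            GroupSpec("hake", 4.7, True, 1.2, 0.25),
            GroupSpec("a", 2.0, True, 1.0, 0.2),
            GroupSpec("b", 2.0, True, 1.0, 0.2),
        ]
        with pytest.raises(InvalidConfigError):
            ScenarioConfig(groups=bad)


class TestCoastalStretches:
    def test_688_units_three_years(self):
        df, features = gen_coastal_stretches(tiny_config(), n_units=688)
        assert len(df) == 688 * 3
        assert len(features) == 688

    def test_attributes_within_declared_ranges(self):
        df, _ = gen_coastal_stretches(tiny_config(noise_sd=0.05), n_units=50)
        assert df["geomorphology"].between(1, 5).all()
        assert df["emerged_habitat"].between(1, 5).all()
        assert df["submerged_habitat"].between(1, 5).all()
        for col in (
            "slope_deg", "wave_height_m", "storm_surge_m", "tidal_range_m",
            "slr_mm_yr", "residents", "artificial_km2", "cultural_sites",
        ):
            assert (df[col] >= 0).all()

    def test_population_growth_propagates_exactly(self):
        cfg = tiny_config(trend_spec={"cp_demand": 0.2})
        df, _ = gen_coastal_stretches(cfg, n_units=10)
        first = df[df["year"] == 1990].set_index("id")
        last = df[df["year"] == 2010].set_index("id")
        ratio = last["residents"] / first["residents"]
        assert ratio.to_numpy() == pytest.approx(np.full(10, 1.2))


class TestRecreationLayers:
    def test_component_rasters_bounded(self):
        ds, _ = gen_recreation_layers(tiny_config(noise_sd=0.1))
        for name in (
            "land_suitability", "natural_features", "water_proximity", "green_urban",
            "coast_geomorph", "eco_status", "transparency",
        ):
            values = ds[name].values
            valid = values[np.isfinite(values)]
            assert ((valid >= 0) & (valid <= 1)).all()
        assert (ds["dist_roads"].values[np.isfinite(ds["dist_roads"].values)] >= 0).all()

    def test_lau_count_and_coastal_contact(self):
        cfg = tiny_config(n_lau=4)
        _, laus = gen_recreation_layers(cfg)
        assert len(laus) == 4
        for lau in laus:
            assert lau.coastal
            # every polygon spans down to the coastline latitude
            assert lau.polygon.bounds[1] == pytest.approx(cfg.coast_lat)


class TestHabitatLayers:
    def test_masked_cell_has_no_layers(self):
        cfg = tiny_config()
        ds, _ = gen_habitat_layers(cfg)
        land = ~cfg.sea_mask()
        assert np.isnan(ds["sst"].values[:, land]).all()
        assert np.isnan(ds["depth"].values[land]).all()

    def test_envelope_intervals_non_empty(self):
        _, envelopes = gen_habitat_layers(tiny_config())
        for env in envelopes.values():
            for lo, hi in env.intervals.values():
                assert lo <= hi

    def test_too_few_days_rejected(self):
        with pytest.raises(InvalidConfigError):
            gen_habitat_layers(tiny_config(days_per_period=10))


class TestSurveyHauls:
    def test_exact_decline_ratio(self):
        cfg = tiny_config()
        df = gen_survey_hauls(cfg, decline=-0.44)
        west = df[df["sub_basin"] == "Western"]
        first = west[west["year"] <= 2005]["recruit_biomass"].mean()
        last = west[west["year"] >= 2009]["recruit_biomass"].mean()
        assert last / first == pytest.approx(0.56, rel=1e-9)

    def test_eastern_sparse_flag(self):
        df = gen_survey_hauls(tiny_config(eastern_sparse=True))
        east = df[df["sub_basin"] == "Eastern"]
        for p in period_windows("hk_bmi"):
            assert len(east[east["year"].between(p.start, p.end)]) < 5

    def test_biomass_nonnegative(self):
        df = gen_survey_hauls(tiny_config(noise_sd=0.3))
        assert (df["recruit_biomass"] >= 0).all()


class TestConfigValidation:
    def test_trend_at_minus_one_rejected(self):
        with pytest.raises(InvalidConfigError):
            tiny_config(trend_spec={"ppr": -1.0})

    def test_unknown_trend_key_rejected(self):
        with pytest.raises(InvalidConfigError):
            tiny_config(trend_spec={"chlorophyll": 0.1})

    def test_window_factors_shape(self):
        assert window_factors(0.3) == pytest.approx([1.0, 1.15, 1.3])

    def test_yaml_round_trip(self, tmp_path):
        cfg = tiny_config(noise_sd=0.02)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        loaded = ScenarioConfig.from_yaml(tmp_path / "cfg.yaml")
        assert loaded == cfg
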