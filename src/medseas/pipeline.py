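"""End-to-end orchestration: generate inputs, compute every indicator,
classify trends and flag sustainability concerns."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import food_provision, lifecycle, recreation, water_purification
from .coastal_protection import score_stretches
from .config import ScenarioConfig
from .regions import (
    BASIN_NAMES,
    IndicatorValue,
    SubBasin,
    period_windows,
)
from .synthetic import (
    COASTAL_YEARS,
    gen_coastal_stretches,
    gen_foodweb_outputs,
    gen_habitat_layers,
    gen_ocean_fields,
    gen_recreation_layers,
    gen_survey_hauls,
    scenario_basins,
)
from .trends import build_indicator_table, sustainability_flags, trends_matrix


@dataclass
class SyntheticData:
    """Everything the indicator stages consume, in memory."""

    ocean: xr.Dataset
    foodweb: pd.DataFrame
    stretches: pd.DataFrame
    stretch_features: list
    recreation: xr.Dataset
    laus: list
    habitat: xr.Dataset
    envelopes: dict
    hauls: pd.DataFrame
    basins: dict = field(default_factory=dict)


@dataclass
class ScenarioResult:
    table: pd.DataFrame
    matrix: pd.DataFrame
    flags: list


def generate_all(cfg: ScenarioConfig) -> SyntheticData:
    """Run every generator for one scenario."""
    stretches, features = gen_coastal_stretches(cfg)
    rec, laus = gen_recreation_layers(cfg)
    habitat, envelopes = gen_habitat_layers(cfg)
    return SyntheticData(
        ocean=gen_ocean_fields(cfg),
        foodweb=gen_foodweb_outputs(cfg),
        stretches=stretches,
        stretch_features=features,
        recreation=rec,
        laus=laus,
        habitat=habitat,
        envelopes=envelopes,
        hauls=gen_survey_hauls(cfg),
        basins=scenario_basins(cfg),
    )


def _food_indicators(data: SyntheticData) -> list[IndicatorValue]:
    out = []
    for j, period in enumerate(period_windows("foodweb")):
        for basin in BASIN_NAMES:
            out.append(
                food_provision.biomass_indicator(
                    data.foodweb, ["pilchard_anchovy"], basin, period, j, code="BM_PA"
                )
            )
            out.append(
                food_provision.biomass_indicator(
                    data.foodweb, ["hake"], basin, period, j, code="BM_HK"
                )
            )
            out.append(
                food_provision.catch_indicator(
                    data.foodweb, ["pilchard_anchovy", "hake"], basin, period, j
                )
            )
            out.append(
                food_provision.trophic_level_of_catch(data.foodweb, basin, period, j)
            )
    return out


def _water_indicators(data: SyntheticData, anomaly: bool = False) -> list[IndicatorValue]:
    out = []
    ds = data.ocean
    for j, period in enumerate(period_windows("biogeochemistry")):
        for basin in data.basins.values():
            out.append(
                water_purification.eke_indicator(
                    ds["u"], ds["v"], basin, period, j, anomaly=anomaly
                )
            )
            out.append(water_purification.ppr_indicator(ds["ppr"], basin, period, j))
            out.append(water_purification.sed_indicator(ds["sed"], basin, period, j))
    return out


def _coastal_indicators(data: SyntheticData) -> list[IndicatorValue]:
    scores = score_stretches(data.stretches)
    out = []
    for j, year in enumerate(COASTAL_YEARS):
        for basin in BASIN_NAMES:
            sub = scores[(scores["year"] == year) & (scores["sub_basin"] == basin)]
            for code in ("CPcap", "CPsup", "CPdem"):
                value = float(sub[code].mean()) if len(sub) else float("nan")
                out.append(
                    IndicatorValue.from_code(code, basin, str(year), j, value)
                )
    return out


def _lifecycle_indicators(cfg: ScenarioConfig, data: SyntheticData) -> list[IndicatorValue]:
    out = []
    species_codes = {"bluefin_tuna_spawning": "BFThab", "hake_nursery": "HKhab"}
    for j, period in enumerate(period_windows("lifecycle")):
        for basin in data.basins.values():
            for species, code in species_codes.items():
                out.append(
                    lifecycle.habitat_capacity_indicator(
                        data.habitat, data.envelopes[species], basin, period, code, j
                    )
                )
    for j, period in enumerate(period_windows("hk_bmi")):
        for basin in BASIN_NAMES:
            out.append(lifecycle.recruit_biomass_index(data.hauls, basin, period, j))
    return out


def lau_rpi_table(cfg: ScenarioConfig, data: SyntheticData) -> pd.DataFrame:
    """Per-LAU, per-year terrestrial/marine/combined RPI plus zone."""
    sea = cfg.sea_mask()
    rec = data.recreation
    rows = []
    for lau in data.laus:
        zone = recreation.accessibility_zone(
            recreation.aggregate_lau(
                rec["dist_roads"].values, lau, sea, cfg.n_land_rows, cfg.rec_cell_km, "land"
            ),
            recreation.aggregate_lau(
                rec["dist_residential"].values,
                lau,
                sea,
                cfg.n_land_rows,
                cfg.rec_cell_km,
                "land",
            ),
            cfg.zone_threshold_roads_km,
            cfg.zone_threshold_residential_km,
        )
        for j, year in enumerate(COASTAL_YEARS):
            snap = rec.sel(year=year)
            terr_means = {
                name: recreation.aggregate_lau(
                    snap[name].values, lau, sea, cfg.n_land_rows, cfg.rec_cell_km, "land"
                )
                for name in recreation.TERRESTRIAL_COMPONENTS
            }
            mar_means = {
                name: recreation.aggregate_lau(
                    snap[name].values,
                    lau,
                    sea,
                    cfg.n_land_rows,
                    cfg.rec_cell_km,
                    "marine",
                )
                for name in recreation.MARINE_COMPONENTS
            }
            terr = recreation.terrestrial_rpi(terr_means)
            mar = recreation.marine_component(mar_means)
            rows.append(
                {
                    "lau": lau.id,
                    "sub_basin": lau.sub_basin,
                    "year": year,
                    "period_index": j,
                    "terrestrial": terr,
                    "marine": mar,
                    "rpi": float(recreation.combined_rpi(terr, mar)),
                    "zone": int(zone),
                }
            )
    return pd.DataFrame(rows)


def _recreation_indicators(cfg: ScenarioConfig, data: SyntheticData) -> list[IndicatorValue]:
    table = lau_rpi_table(cfg, data)
    # tertile bounds pooled over all LAU-years so levels are comparable in time
    levels = recreation.rpi_tertile(table["rpi"].to_numpy())
    table = table.assign(
        level=levels, ros=recreation.ros_class(levels, table["zone"].to_numpy())
    )
    out = []
    for j, year in enumerate(COASTAL_YEARS):
        for basin in BASIN_NAMES:
            sub = table[(table["year"] == year) & (table["sub_basin"] == basin)]
            rpi = float(sub["rpi"].mean()) if len(sub) else float("nan")
            ros = float(sub["ros"].mean()) if len(sub) else float("nan")
            out.append(IndicatorValue.from_code("RPI", basin, str(year), j, rpi))
            out.append(IndicatorValue.from_code("ROS", basin, str(year), j, ros))
    return out


def compute_indicators(
    cfg: ScenarioConfig, data: SyntheticData | None = None
) -> list[IndicatorValue]:
    """All indicator values for one scenario (generating inputs if needed)."""
    data = data if data is not None else generate_all(cfg)
    if not data.basins:
        data.basins = scenario_basins(cfg)
    values: list[IndicatorValue] = []
    values += _food_indicators(data)
    values += _water_indicators(data)
    values += _coastal_indicators(data)
    values += _lifecycle_indicators(cfg, data)
    values += _recreation_indicators(cfg, data)
    return values


def run_scenario(
    cfg: ScenarioConfig,
    taus: dict[str, float] | None = None,
    data: SyntheticData | None = None,
) -> ScenarioResult:
    """Full pipeline: inputs -> indicators -> trend matrix -> flags."""
    table = build_indicator_table(compute_indicators(cfg, data))
    matrix = trends_matrix(table, taus)
    return ScenarioResult(table, matrix, sustainability_flags(matrix))
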