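"""Seeded generators for every input the indicator pipeline consumes.

The generators emulate the *data regime* of the upstream models — gridded
hydrodynamic/biogeochemical fields, annual food-web outputs, a coastal
operational-unit attribute table, recreation component rasters with LAU
polygons, daily habitat layers with species envelopes, and trawl-haul
records — without solving any of the upstream physics or ecology.

Two properties make the pipeline testable:

* **Determinism** — a fixed :class:`~medseas.config.ScenarioConfig` (seed
  included) yields byte-identical outputs on every call.
* **Calibration** — each ``trend_spec`` entry is a relative change injected
  multiplicatively between the first and last assessment window (the middle
  window sits halfway).  With ``noise_sd = 0`` the matching downstream
  indicator recovers the injected change exactly; with noise it recovers it
  in expectation.

Noise is multiplicative lognormal (unit mean) for strictly positive
quantities and additive Gaussian for signed ones (current components), so
sign constraints survive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString

from .config import InvalidConfigError, ScenarioConfig
from .coastal_protection import segment_coastline
from .lifecycle import HabitatEnvelope
from .recreation import LAUnit
from .regions import BASIN_NAMES, basin_of_point, make_subbasin_masks, period_windows

# independent random streams per generator, derived from the scenario seed
_STREAMS = {
    "ocean": 1,
    "foodweb": 2,
    "coast": 3,
    "recreation": 4,
    "habitat": 5,
    "hauls": 6,
}

COASTAL_YEARS = (1990, 2000, 2010)

DEFAULT_ENVELOPES = {
    "bluefin_tuna_spawning": HabitatEnvelope(
        "bluefin_tuna_spawning",
        {"sst": (23.0, 28.0), "front_index": (0.2, 1.0), "depth": (0.0, 3000.0)},
    ),
    "hake_nursery": HabitatEnvelope(
        "hake_nursery",
        {"sst": (11.0, 18.0), "front_index": (0.1, 1.0), "depth": (20.0, 1000.0)},
    ),
}

# stylised in-envelope / out-of-envelope layer values (see docs/methods.md)
_SST_TUNA, _SST_HAKE, _SST_NONE = 25.5, 14.5, 5.0
_FRONT_ON, _FRONT_OFF = 0.6, 0.02


def _rng(cfg: ScenarioConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stream]])


def window_factors(trend: float) -> np.ndarray:
    """Multiplicative factors for the three windows: 1, 1 + t/2, 1 + t."""
    return np.array([1.0, 1.0 + trend / 2.0, 1.0 + trend])


def _lognormal_noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    """Unit-mean multiplicative noise with relative spread ``sd``."""
    if sd == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(sd * sd))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, shape))


def _smooth_pattern(rng: np.random.Generator, shape) -> np.ndarray:
    """Smooth spatial pattern scaled to max |.| = 1."""
    raw = gaussian_filter(rng.normal(size=shape), sigma=2.0, mode="wrap")
    peak = np.abs(raw).max()
    return raw / peak if peak > 0 else raw


def _monthly_axis(periods) -> tuple[np.ndarray, np.ndarray]:
    """Fractional-year time axis and window index for monthly sampling."""
    times, widx = [], []
    for j, p in enumerate(periods):
        for year in range(p.start, p.end + 1):
            for m in range(12):
                times.append(year + (m + 0.5) / 12.0)
                widx.append(j)
    return np.array(times), np.array(widx)


def scenario_basins(cfg: ScenarioConfig):
    """The four sub-basins of the configured grid."""
    return make_subbasin_masks(
        cfg.lat_centers(),
        cfg.lon_centers(),
        cfg.sea_mask(),
        cfg.basin_boundaries,
        cfg.adriatic_lon,
        cfg.adriatic_lat,
        cfg.cell_area_km2,
    )


# ---------------------------------------------------------------------------
# (a) gridded ocean / biogeochemistry fields
# ---------------------------------------------------------------------------
def gen_ocean_fields(cfg: ScenarioConfig) -> xr.Dataset:
    """Monthly surface currents (u, v), primary production and sediment
    detritus over the three decadal windows, land cells masked.

    The injected ``eke`` trend scales current *speed* by sqrt(1 + t) so the
    kinetic energy — the downstream indicator — changes by exactly (1 + t).
    """
    rng = _rng(cfg, "ocean")
    periods = period_windows("biogeochemistry")
    times, widx = _monthly_axis(periods)
    sea = cfg.sea_mask()
    shape = (cfg.nlat, cfg.nlon)

    u_base = cfg.base_speed * _smooth_pattern(rng, shape)
    v_base = cfg.base_speed * _smooth_pattern(rng, shape)
    ppr_pat = _smooth_pattern(rng, shape)
    sed_pat = _smooth_pattern(rng, shape)
    ppr_base = np.clip(
        cfg.base_ppr * (1.0 + cfg.spatial_amp * ppr_pat), 0.05 * cfg.base_ppr, None
    )
    sed_base = np.clip(
        cfg.base_sed * (1.0 + cfg.spatial_amp * sed_pat), 0.05 * cfg.base_sed, None
    )

    f_cur = np.sqrt(window_factors(cfg.trend_spec.get("eke", 0.0)))[widx]
    f_ppr = window_factors(cfg.trend_spec.get("ppr", 0.0))[widx]
    f_sed = window_factors(cfg.trend_spec.get("sed", 0.0))[widx]

    nt = times.size
    u = u_base[None, :, :] * f_cur[:, None, None]
    v = v_base[None, :, :] * f_cur[:, None, None]
    ppr = ppr_base[None, :, :] * f_ppr[:, None, None]
    sed = sed_base[None, :, :] * f_sed[:, None, None]
    if cfg.noise_sd > 0:
        u = u + rng.normal(0.0, cfg.noise_sd * cfg.base_speed, (nt, *shape))
        v = v + rng.normal(0.0, cfg.noise_sd * cfg.base_speed, (nt, *shape))
        ppr = ppr * _lognormal_noise(rng, cfg.noise_sd, (nt, *shape))
        sed = sed * _lognormal_noise(rng, cfg.noise_sd, (nt, *shape))

    land = ~sea
    for arr in (u, v, ppr, sed):
        arr[:, land] = np.nan

    coords = {"time": times, "lat": cfg.lat_centers(), "lon": cfg.lon_centers()}
    dims = ("time", "lat", "lon")
    ds = xr.Dataset(
        {
            "u": (dims, u, {"units": "m s-1"}),
            "v": (dims, v, {"units": "m s-1"}),
            "ppr": (dims, ppr, {"units": "mmolN m-2 d-1"}),
            "sed": (dims, sed, {"units": "mmolN m-2"}),
        },
        coords=coords,
    )
    ds.attrs["description"] = "synthetic monthly surface fields"
    return ds


# ---------------------------------------------------------------------------
# (b) food-web outputs
# ---------------------------------------------------------------------------
def gen_foodweb_outputs(cfg: ScenarioConfig) -> pd.DataFrame:
    """Annual biomass/catch per functional group, sub-basin and year.

    Catch is bounded by ``max_exploitation * biomass`` in every record.
    Trophic levels are constant per group, so with all catches sharing the
    same injected trend the trophic level of the catch stays exactly stable.
    """
    names = {g.name for g in cfg.groups}
    if not {"pilchard_anchovy", "hake"} <= names or len(names) < 4:
        raise InvalidConfigError(
            "food web needs pilchard_anchovy, hake and at least 2 other groups"
        )
    rng = _rng(cfg, "foodweb")
    periods = period_windows("foodweb")
    years, widx = [], []
    for j, p in enumerate(periods):
        for y in range(p.start, p.end + 1):
            years.append(y)
            widx.append(j)
    years, widx = np.array(years), np.array(widx)
    f_cat = window_factors(cfg.trend_spec.get("catch", 0.0))[widx]

    rows = []
    for basin in BASIN_NAMES:
        for g in cfg.groups:
            basin_factor = rng.uniform(0.7, 1.3)
            f_bio = window_factors(cfg.trend_spec.get(f"biomass_{g.name}", 0.0))[widx]
            biomass = (
                g.base_biomass
                * basin_factor
                * f_bio
                * _lognormal_noise(rng, cfg.noise_sd, years.size)
            )
            catch_raw = (
                g.exploitation
                * g.base_biomass
                * basin_factor
                * f_cat
                * _lognormal_noise(rng, cfg.noise_sd, years.size)
            )
            catch = np.minimum(catch_raw, cfg.max_exploitation * biomass)
            for y, bm, ct in zip(years, biomass, catch):
                rows.append(
                    {
                        "group": g.name,
                        "sub_basin": basin,
                        "year": int(y),
                        "biomass": bm,
                        "catch": ct,
                        "trophic_level": g.trophic_level,
                        "retained": g.retained,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# (c) coastal-stretch attribute table
# ---------------------------------------------------------------------------
def gen_coastal_stretches(
    cfg: ScenarioConfig, n_units: int | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Operational-unit attributes for the three coastal-protection years.

    Returns the attribute table (one row per unit per year) and GeoJSON-style
    features for the unit geometries along the synthetic coastline.
    Geomorphology and slope are treated as static physiography; habitat
    protection scores follow the ``cp_capacity`` trend, oceanographic forcing
    the ``cp_exposure`` trend and socio-economic attributes the ``cp_demand``
    trend.
    """
    n_units = n_units if n_units is not None else cfg.n_units
    rng = _rng(cfg, "coast")
    coast_km = cfg.nlon * cfg.cell_km
    line = LineString([(0.0, 0.0), (coast_km, 0.0)])
    if n_units is None:
        segments = segment_coastline(line, cfg.coast_target_km)
        n_units = len(segments)
    else:
        if n_units < 2:
            raise InvalidConfigError("n_units must be >= 2")
        edges = np.linspace(0.0, coast_km, n_units + 1)
        segments = [
            LineString([(a, 0.0), (b, 0.0)]) for a, b in zip(edges[:-1], edges[1:])
        ]

    lon_span = cfg.lon_max - cfg.lon_min
    mids = [seg.interpolate(0.5, normalized=True).x for seg in segments]
    lons = [cfg.lon_min + (m / coast_km) * lon_span for m in mids]
    # classify at the latitude of the first sea row next to the coast
    sea_lat = cfg.coast_lat - 0.5 * (cfg.lat_max - cfg.lat_min) / cfg.nlat
    basins = [
        basin_of_point(lo, sea_lat, cfg.basin_boundaries, cfg.adriatic_lon, cfg.adriatic_lat)
        for lo in lons
    ]

    base = {
        "geomorphology": rng.integers(1, 6, n_units).astype(float),
        "slope_deg": rng.uniform(0.5, 30.0, n_units),
        "emerged_habitat": rng.uniform(2.0, 4.0, n_units),
        "submerged_habitat": rng.uniform(2.0, 4.0, n_units),
        "wave_height_m": rng.uniform(0.5, 3.0, n_units),
        "storm_surge_m": rng.uniform(0.2, 1.5, n_units),
        "tidal_range_m": rng.uniform(0.1, 1.0, n_units),
        "slr_mm_yr": rng.uniform(0.5, 4.0, n_units),
        "residents": rng.uniform(200.0, 50000.0, n_units),
        "artificial_km2": rng.uniform(0.5, 30.0, n_units),
        "cultural_sites": rng.uniform(0.0, 20.0, n_units),
    }
    f_cap = window_factors(cfg.trend_spec.get("cp_capacity", 0.0))
    f_exp = window_factors(cfg.trend_spec.get("cp_exposure", 0.0))
    f_dem = window_factors(cfg.trend_spec.get("cp_demand", 0.0))
    trended = {
        "emerged_habitat": (f_cap, (1.0, 5.0)),
        "submerged_habitat": (f_cap, (1.0, 5.0)),
        "wave_height_m": (f_exp, None),
        "storm_surge_m": (f_exp, None),
        "tidal_range_m": (f_exp, None),
        "slr_mm_yr": (f_exp, None),
        "residents": (f_dem, None),
        "artificial_km2": (f_dem, None),
        "cultural_sites": (f_dem, None),
    }

    rows = []
    for j, year in enumerate(COASTAL_YEARS):
        for i in range(n_units):
            row = {"id": f"OU{i:04d}", "year": year, "sub_basin": basins[i]}
            for attr, values in base.items():
                value = values[i]
                if attr in trended:
                    factors, clip = trended[attr]
                    value = value * factors[j] * _lognormal_noise(
                        rng, cfg.noise_sd, ()
                    )
                    if clip is not None:
                        value = float(np.clip(value, *clip))
                row[attr] = float(value)
            rows.append(row)

    features = []
    for i, seg in enumerate(segments):
        coords = [
            [cfg.lon_min + (x / coast_km) * lon_span, cfg.coast_lat] for x, _ in seg.coords
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {"id": f"OU{i:04d}", "sub_basin": basins[i]},
            }
        )
    return pd.DataFrame(rows), features


# ---------------------------------------------------------------------------
# (d) recreation component rasters + LAU polygons
# ---------------------------------------------------------------------------
def gen_recreation_layers(cfg: ScenarioConfig) -> tuple[xr.Dataset, list[LAUnit]]:
    """Component rasters for the three recreation years and the coastal LAUs.

    Scored components live in [0, 1] (terrestrial ones on land cells, marine
    ones on sea cells, the rest NaN); distance layers are km >= 0 and static.
    Each LAU owns a contiguous block of longitude columns, so every polygon
    touches the synthetic coastline.
    """
    rng = _rng(cfg, "recreation")
    sea = cfg.sea_mask()
    land = ~sea
    shape = (cfg.nlat, cfg.nlon)
    years = np.array(COASTAL_YEARS)
    f_rpi = window_factors(cfg.trend_spec.get("rpi", 0.0))

    from .recreation import MARINE_COMPONENTS, TERRESTRIAL_COMPONENTS

    data = {}
    for name in TERRESTRIAL_COMPONENTS + MARINE_COMPONENTS:
        base = rng.uniform(0.2, 0.8, shape)
        field = np.empty((3, *shape))
        for j in range(3):
            field[j] = np.clip(
                base * f_rpi[j] * _lognormal_noise(rng, cfg.noise_sd, shape), 0.0, 1.0
            )
        domain = land if name in TERRESTRIAL_COMPONENTS else sea
        field[:, ~domain] = np.nan
        data[name] = (("year", "lat", "lon"), field, {"units": "score"})

    # LAU blocks of longitude columns
    col_blocks = np.array_split(np.arange(cfg.nlon), cfg.n_lau)
    lons = cfg.lon_centers()
    dlon = (cfg.lon_max - cfg.lon_min) / cfg.nlon
    laus = []
    for k, cols in enumerate(col_blocks):
        lo = lons[cols[0]] - dlon / 2
        hi = lons[cols[-1]] + dlon / 2
        from shapely.geometry import box

        poly = box(lo, cfg.coast_lat, hi, cfg.lat_max)
        basin = basin_of_point(
            (lo + hi) / 2,
            cfg.coast_lat,
            cfg.basin_boundaries,
            cfg.adriatic_lon,
            cfg.adriatic_lat,
        )
        laus.append(LAUnit(f"LAU{k:03d}", int(cols[0]), int(cols[-1]) + 1, poly, basin))

    # distances: per-LAU base level + per-cell jitter, static over years
    dist_roads = np.full(shape, np.nan)
    dist_res = np.full(shape, np.nan)
    for lau in laus:
        cols = slice(lau.col_start, lau.col_stop)
        base_r = rng.uniform(1.0, 12.0)
        base_d = rng.uniform(2.0, 18.0)
        ncols = lau.col_stop - lau.col_start
        dist_roads[:, cols] = base_r + rng.uniform(0.0, 3.0, (cfg.nlat, ncols))
        dist_res[:, cols] = base_d + rng.uniform(0.0, 3.0, (cfg.nlat, ncols))
    data["dist_roads"] = (("lat", "lon"), dist_roads, {"units": "km"})
    data["dist_residential"] = (("lat", "lon"), dist_res, {"units": "km"})

    ds = xr.Dataset(
        {k: xr.DataArray(v[1], dims=v[0], attrs=v[2]) for k, v in data.items()},
        coords={"year": years, "lat": cfg.lat_centers(), "lon": cfg.lon_centers()},
    )
    return ds, laus


# ---------------------------------------------------------------------------
# (e) daily habitat layers + envelopes
# ---------------------------------------------------------------------------
def gen_habitat_layers(
    cfg: ScenarioConfig, envelopes: dict[str, HabitatEnvelope] | None = None
) -> tuple[xr.Dataset, dict[str, HabitatEnvelope]]:
    """Daily SST / front-index layers plus a static depth layer.

    Each sea cell carries designed per-species favourability probabilities;
    the ``bft_hab`` / ``hk_hab`` trends scale those probabilities between the
    first and last window.  With ``noise_sd = 0`` the favourable days are a
    deterministic count (first k days of the window); with noise each day is
    drawn independently.  The SST envelopes of the two species are disjoint,
    so one temperature field can encode both.
    """
    if cfg.days_per_period < 30:
        raise InvalidConfigError("need at least 30 days per period")
    envelopes = envelopes or DEFAULT_ENVELOPES
    rng = _rng(cfg, "habitat")
    periods = period_windows("lifecycle")
    sea = cfg.sea_mask()
    shape = (cfg.nlat, cfg.nlon)
    n = cfg.days_per_period

    p_bft = rng.uniform(0.15, 0.35, shape)
    p_hk = rng.uniform(0.15, 0.35, shape)
    depth = np.where(sea, rng.uniform(50.0, 2500.0, shape), np.nan)
    f_b = window_factors(cfg.trend_spec.get("bft_hab", 0.0))
    f_h = window_factors(cfg.trend_spec.get("hk_hab", 0.0))

    times = []
    sst = np.empty((3 * n, *shape))
    front = np.empty((3 * n, *shape))
    t = 0
    for j, p in enumerate(periods):
        span = p.end - p.start + 1
        pb = np.clip(p_bft * f_b[j], 0.0, 1.0)
        ph = np.clip(p_hk * f_h[j], 0.0, 1.0 - pb)
        if cfg.noise_sd == 0:
            k_b = np.rint(pb * n)
            k_h = np.rint(ph * n)
        for d in range(n):
            times.append(p.start + span * (d + 0.5) / n)
            if cfg.noise_sd == 0:
                is_tuna = d < k_b
                is_hake = (~is_tuna) & (d < k_b + k_h)
            else:
                draw = rng.random(shape)
                is_tuna = draw < pb
                is_hake = (~is_tuna) & (draw < pb + ph)
            sst_day = np.where(is_tuna, _SST_TUNA, np.where(is_hake, _SST_HAKE, _SST_NONE))
            front_day = np.where(is_tuna | is_hake, _FRONT_ON, _FRONT_OFF)
            sst[t] = np.where(sea, sst_day, np.nan)
            front[t] = np.where(sea, front_day, np.nan)
            t += 1

    ds = xr.Dataset(
        {
            "sst": (("time", "lat", "lon"), sst, {"units": "degC"}),
            "front_index": (("time", "lat", "lon"), front, {"units": "dimensionless"}),
            "depth": (("lat", "lon"), depth, {"units": "m"}),
        },
        coords={
            "time": np.array(times),
            "lat": cfg.lat_centers(),
            "lon": cfg.lon_centers(),
        },
    )
    return ds, envelopes


# ---------------------------------------------------------------------------
# (f) trawl-haul records
# ---------------------------------------------------------------------------
def gen_survey_hauls(cfg: ScenarioConfig, decline: float | None = None) -> pd.DataFrame:
    """Trawl hauls with recruit biomass (kg km-2) per basin and survey year.

    ``decline`` is the relative change of the expected basin mean between
    the first and last survey window (default: the ``hk_bmi`` trend).  With
    ``eastern_sparse`` the Eastern basin gets fewer than 5 hauls per window,
    emulating its data-poor series.
    """
    decline = cfg.trend_spec.get("hk_bmi", 0.0) if decline is None else decline
    if decline <= -1:
        raise InvalidConfigError("decline must be > -1")
    rng = _rng(cfg, "hauls")
    periods = period_windows("hk_bmi")
    factors = window_factors(decline)
    basins = scenario_basins(cfg)
    lat, lon = cfg.lat_centers(), cfg.lon_centers()
    dlat = (cfg.lat_max - cfg.lat_min) / cfg.nlat
    dlon = (cfg.lon_max - cfg.lon_min) / cfg.nlon

    rows = []
    for name in BASIN_NAMES:
        cells = np.argwhere(basins[name].mask)
        basin_factor = rng.uniform(0.8, 1.2)
        n = cfg.hauls_per_basin
        if cfg.eastern_sparse and name == "Eastern":
            n = 3
        for j, p in enumerate(periods):
            picks = cells[rng.integers(0, len(cells), n)]
            yrs = rng.integers(p.start, p.end + 1, n)
            biomass = (
                cfg.base_recruit_biomass
                * basin_factor
                * factors[j]
                * _lognormal_noise(rng, cfg.noise_sd, n)
            )
            for (r, c), y, bm in zip(picks, yrs, biomass):
                rows.append(
                    {
                        "lon": lon[c] + rng.uniform(-0.4, 0.4) * dlon,
                        "lat": lat[r] + rng.uniform(-0.4, 0.4) * dlat,
                        "year": int(y),
                        "recruit_biomass": float(bm),
                        "sub_basin": name,
                    }
                )
    return pd.DataFrame(rows)
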