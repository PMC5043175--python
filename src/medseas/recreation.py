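"""Recreation capacity (RPI) and flow (ROS) for coastal administrative units.

The Recreation Potential Indicator combines a terrestrial sub-index (land
suitability, natural features, water proximity, green urban areas) and a
marine sub-index (coastal geomorphology, ecological status of coastal
waters, water transparency), each an equal-weight mean of its components,
joined 50/50.  The Recreation Opportunity Spectrum cross-tabulates the RPI
level (tertiles: low/medium/high) with an accessibility zoning (remote /
proximal / high access from distances to roads and residential areas) into
nine classes; (medium, proximal) is class 5 and (high, high access) class 9.

Reporting units are coastal Local Administrative Units (LAUs): terrestrial
variables are averaged over each unit's land cells and marine variables over
the sea cells within 10 km of its coast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from shapely.geometry import Polygon

log = logging.getLogger(__name__)

TERRESTRIAL_COMPONENTS = (
    "land_suitability",
    "natural_features",
    "water_proximity",
    "green_urban",
)
MARINE_COMPONENTS = ("coast_geomorph", "eco_status", "transparency")

ZONE_REMOTE, ZONE_PROXIMAL, ZONE_HIGH_ACCESS = 1, 2, 3
LEVEL_LOW, LEVEL_MEDIUM, LEVEL_HIGH = 1, 2, 3


@dataclass
class LAUnit:
    """A coastal municipality-level reporting polygon.

    On the stylised grid each unit owns a contiguous block of longitude
    columns; only units touching the coastline are retained (all generated
    units do, by construction).
    """

    id: str
    col_start: int
    col_stop: int  # exclusive
    polygon: Polygon
    sub_basin: str
    coastal: bool = True


def _component_mean(arrays: dict, names: tuple) -> xr.DataArray | np.ndarray:
    missing = [n for n in names if n not in arrays]
    if missing:
        raise ValueError(f"missing recreation component(s): {missing}")
    stack = [arrays[n] for n in names]
    return sum(stack) / len(stack)


def terrestrial_rpi(components: dict) -> xr.DataArray | np.ndarray:
    """Equal-weight mean of the four terrestrial components, in [0, 1]."""
    return _component_mean(components, TERRESTRIAL_COMPONENTS)


def marine_component(components: dict) -> xr.DataArray | np.ndarray:
    """Equal-weight mean of the three marine components, in [0, 1]."""
    return _component_mean(components, MARINE_COMPONENTS)


def combined_rpi(terrestrial, marine):
    """50% terrestrial + 50% marine recreation potential."""
    t, m = np.asarray(terrestrial, dtype=float), np.asarray(marine, dtype=float)
    if t.shape != m.shape:
        raise ValueError("terrestrial and marine RPI rasters differ in shape")
    return 0.5 * t + 0.5 * m


def accessibility_zone(
    dist_roads, dist_residential, roads_km: float = 5.0, residential_km: float = 10.0
):
    """Zone 1 (remote), 2 (proximal) or 3 (high access) from two distances.

    Remote = far from both roads and residential areas; high access = near
    both; anything else is proximal.
    """
    if roads_km <= 0 or residential_km <= 0:
        raise ValueError("zone thresholds must be positive")
    dr = np.asarray(dist_roads, dtype=float)
    dd = np.asarray(dist_residential, dtype=float)
    if (dr < 0).any() or (dd < 0).any():
        raise ValueError("distances must be non-negative")
    near_roads = dr <= roads_km
    near_res = dd <= residential_km
    zone = np.full(dr.shape, ZONE_PROXIMAL, dtype=int)
    zone[~near_roads & ~near_res] = ZONE_REMOTE
    zone[near_roads & near_res] = ZONE_HIGH_ACCESS
    return zone if zone.shape else int(zone)


def rpi_tertile(values, bounds: tuple[float, float] | None = None):
    """Classify RPI values into tertile levels 1 (low) / 2 (medium) / 3 (high).

    Boundaries default to the empirical 33.3/66.7 percentiles of the input;
    a value exactly at a boundary falls in the lower class.  A constant
    input degenerates to all-medium (logged).
    """
    v = np.asarray(values, dtype=float)
    if bounds is None:
        finite = v[np.isfinite(v)]
        if np.unique(finite).size < 3:
            if np.unique(finite).size == 1:
                log.warning("rpi_tertile: constant input, returning all medium")
                return np.full(v.shape, LEVEL_MEDIUM, dtype=int)
            raise ValueError("need at least 3 distinct values for tertiles")
        bounds = tuple(np.percentile(finite, [100 / 3, 200 / 3]))
    q1, q2 = bounds
    return (1 + (v > q1).astype(int) + (v > q2).astype(int)).astype(int)


def ros_class(level, zone):
    """Cross-tabulate RPI level with accessibility zone into classes 1..9.

    class = 3 * (level - 1) + zone — a bijection over the nine combinations
    with (medium, proximal) -> 5 and (high, high access) -> 9.
    """
    lv = np.asarray(level, dtype=int)
    zn = np.asarray(zone, dtype=int)
    if ((lv < 1) | (lv > 3)).any() or ((zn < 1) | (zn > 3)).any():
        raise ValueError("level and zone must lie in 1..3")
    out = 3 * (lv - 1) + zn
    return out if out.shape else int(out)


def lau_cell_mask(
    lau: LAUnit,
    sea_mask: np.ndarray,
    n_land_rows: int,
    cell_km: float,
    domain: str,
    offshore_km: float = 10.0,
) -> np.ndarray:
    """Boolean cell mask of a LAU's terrestrial or offshore footprint.

    ``domain="land"`` selects the unit's land cells; ``domain="marine"`` the
    sea cells in its longitude block whose centre lies within ``offshore_km``
    of the coast (rows counted from the land/sea boundary).
    """
    nlat, _ = sea_mask.shape
    mask = np.zeros_like(sea_mask)
    mask[:, lau.col_start : lau.col_stop] = True
    if domain == "land":
        return mask & ~sea_mask
    if domain != "marine":
        raise ValueError("domain must be 'land' or 'marine'")
    coast_row = nlat - n_land_rows  # first land row; sea rows are below it
    rows = np.arange(nlat)
    dist = (coast_row - 1 - rows + 0.5) * cell_km  # distance of sea-row centres
    near = (dist >= 0) & (dist <= offshore_km)
    return mask & sea_mask & near[:, None]


def aggregate_lau(
    raster: np.ndarray | xr.DataArray,
    lau: LAUnit,
    sea_mask: np.ndarray,
    n_land_rows: int,
    cell_km: float,
    domain: str,
    offshore_km: float = 10.0,
) -> float:
    """Mean of a raster over one LAU's land (or <=10 km offshore) cells."""
    cells = lau_cell_mask(lau, sea_mask, n_land_rows, cell_km, domain, offshore_km)
    values = np.asarray(raster, dtype=float)[cells]
    values = values[np.isfinite(values)]
    if values.size == 0:
        log.warning("aggregate_lau: no %s cells for unit %s", domain, lau.id)
        return float("nan")
    return float(values.mean())
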