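"""Sub-basin partition, assessment periods and spatial aggregation.

The Mediterranean is reported on four sub-basins (Western, Adriatic, Central,
Eastern).  Here they are stylised as two longitude splits plus a rectangular
Adriatic carve-out that takes precedence over the longitude bands, because
the real Adriatic is not a longitude band.  Every service model is assessed
on three time windows that depend on the model type (decadal windows for the
food-web and biogeochemical models, single years for the coastal-protection
and recreation models, multi-year blocks for the habitat models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

log = logging.getLogger(__name__)

BASIN_NAMES = ("Western", "Adriatic", "Central", "Eastern")

# Decadal windows are concretised as full decades (1960-1969 etc.).
MODEL_PERIODS: dict[str, list[tuple[str, int, int]]] = {
    "foodweb": [("1960s", 1960, 1969), ("1980s", 1980, 1989), ("2000s", 2000, 2009)],
    "biogeochemistry": [
        ("1960s", 1960, 1969),
        ("1980s", 1980, 1989),
        ("2000s", 2000, 2009),
    ],
    "coastal_protection": [("1990", 1990, 1990), ("2000", 2000, 2000), ("2010", 2010, 2010)],
    "recreation": [("1990", 1990, 1990), ("2000", 2000, 2000), ("2010", 2010, 2010)],
    "lifecycle": [("2003-05", 2003, 2005), ("2006-09", 2006, 2009), ("2010-12", 2010, 2012)],
    # The recruit-biomass survey series stops in 2011, so its windows differ
    # from the habitat-map windows.
    "hk_bmi": [("2003-05", 2003, 2005), ("2006-08", 2006, 2008), ("2009-11", 2009, 2011)],
}


@dataclass(frozen=True)
class Period:
    """A labelled assessment window, inclusive of both end years."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"period {self.label}: start > end")

    def contains(self, t: float | np.ndarray) -> np.ndarray:
        """True for fractional-year times falling inside the window."""
        return (np.asarray(t) >= self.start) & (np.asarray(t) < self.end + 1)


def period_windows(model_kind: str) -> list[Period]:
    """Return the three assessment windows for a model type."""
    try:
        spec = MODEL_PERIODS[model_kind]
    except KeyError:
        raise KeyError(
            f"unknown model kind {model_kind!r}; one of {sorted(MODEL_PERIODS)}"
        ) from None
    return [Period(*p) for p in spec]


@dataclass
class SubBasin:
    name: str
    mask: np.ndarray          # boolean (nlat, nlon), True on basin sea cells
    area_km2: float

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError(f"basin {self.name} has non-positive area")


def make_subbasin_masks(
    lat: np.ndarray,
    lon: np.ndarray,
    sea_mask: np.ndarray,
    boundaries: tuple[float, float],
    adriatic_lon: tuple[float, float],
    adriatic_lat: tuple[float, float],
    cell_area_km2: float,
) -> dict[str, SubBasin]:
    """Partition the sea cells into the four named sub-basins.

    ``boundaries`` are the two longitude splits Western|Central|Eastern; the
    Adriatic box wins over the band it sits in.  The result is checked to be
    a partition (disjoint and exhaustive over sea cells).
    """
    b1, b2 = boundaries
    if not b1 < b2:
        raise ValueError("boundaries must be strictly increasing")
    lon2d, lat2d = np.meshgrid(lon, lat)
    adr = (
        sea_mask
        & (lon2d >= adriatic_lon[0])
        & (lon2d <= adriatic_lon[1])
        & (lat2d >= adriatic_lat[0])
        & (lat2d <= adriatic_lat[1])
    )
    west = sea_mask & (lon2d < b1) & ~adr
    cent = sea_mask & (lon2d >= b1) & (lon2d < b2) & ~adr
    east = sea_mask & (lon2d >= b2) & ~adr
    masks = {"Western": west, "Adriatic": adr, "Central": cent, "Eastern": east}
    total = sum(m.astype(int) for m in masks.values())
    if not np.array_equal(total, sea_mask.astype(int)):
        raise ValueError("sub-basin definitions do not partition the sea cells")
    return {
        name: SubBasin(name, m, float(m.sum()) * cell_area_km2)
        for name, m in masks.items()
    }


def basin_of_point(
    lon: float,
    lat: float,
    boundaries: tuple[float, float],
    adriatic_lon: tuple[float, float],
    adriatic_lat: tuple[float, float],
) -> str:
    """Classify a single lon/lat point with the same precedence rule."""
    if (
        adriatic_lon[0] <= lon <= adriatic_lon[1]
        and adriatic_lat[0] <= lat <= adriatic_lat[1]
    ):
        return "Adriatic"
    b1, b2 = boundaries
    if lon < b1:
        return "Western"
    if lon < b2:
        return "Central"
    return "Eastern"


def select_period(field_: xr.DataArray, period: Period) -> xr.DataArray:
    """Restrict a (time, ...) field to one assessment window."""
    if "time" not in field_.dims:
        return field_
    keep = period.contains(field_["time"].values)
    return field_.isel(time=np.flatnonzero(keep))


def aggregate(
    field_: xr.DataArray,
    basin: SubBasin,
    period: Period | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Area-weighted time-mean of a gridded field over one basin and window.

    Masked (NaN) cells are excluded; time steps are weighted uniformly within
    the window and cells by ``weights`` (uniform by default, matching equal
    per-cell areas).  An empty selection yields NaN and a log entry rather
    than an exception, so missing cells propagate as flagged values.
    """
    if period is not None:
        field_ = select_period(field_, period)
        if "time" in field_.dims and field_.sizes["time"] == 0:
            log.warning("aggregate: no time steps in %s for %s", period.label, basin.name)
            return float("nan")
    values = field_.values
    mask = basin.mask
    if values.ndim == 2:
        sel = values[mask]
        w = np.ones(mask.sum()) if weights is None else np.asarray(weights)[mask]
    else:
        sel = values[:, mask].reshape(-1)
        w1 = np.ones(mask.sum()) if weights is None else np.asarray(weights)[mask]
        w = np.tile(w1, values.shape[0])
    good = np.isfinite(sel)
    if not good.any():
        log.warning("aggregate: empty selection for basin %s", basin.name)
        return float("nan")
    return float(np.average(sel[good], weights=w[good]))


# ---------------------------------------------------------------------------
# Indicator registry: code -> (service, cascade level, units)
# ---------------------------------------------------------------------------
INDICATOR_REGISTRY: dict[str, tuple[str, str, str]] = {
    "BM_PA": ("food_provisioning", "capacity", "t km-2"),
    "BM_HK": ("food_provisioning", "capacity", "t km-2"),
    "Cat": ("food_provisioning", "flow", "t km-2 yr-1"),
    "TLC": ("food_provisioning", "flow", "dimensionless"),
    "EKE": ("water_purification", "capacity", "m2 s-2"),
    "PPR": ("water_purification", "flow", "mmolN m-2 d-1"),
    "Sed": ("water_purification", "flow", "mmolN m-2"),
    "CPcap": ("coastal_protection", "capacity", "dimensionless"),
    "CPsup": ("coastal_protection", "flow", "dimensionless"),
    "CPdem": ("coastal_protection", "benefit", "dimensionless"),
    "BFThab": ("lifecycle_maintenance", "capacity", "%"),
    "HKhab": ("lifecycle_maintenance", "capacity", "%"),
    "HKBMI": ("lifecycle_maintenance", "flow", "kg km-2"),
    "RPI": ("recreation", "capacity", "dimensionless"),
    "ROS": ("recreation", "flow", "class"),
}


@dataclass
class IndicatorValue:
    """One indicator value for one sub-basin and one assessment period."""

    service: str
    cascade_level: str
    indicator: str
    sub_basin: str
    period: str
    period_index: int
    value: float
    units: str
    reliable: bool = True

    @classmethod
    def from_code(
        cls,
        code: str,
        sub_basin: str,
        period: str,
        period_index: int,
        value: float,
        reliable: bool = True,
    ) -> "IndicatorValue":
        service, level, units = INDICATOR_REGISTRY[code]
        return cls(service, level, code, sub_basin, period, period_index, value, units, reliable)
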