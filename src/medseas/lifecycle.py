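"""Lifecycle-maintenance indicators: habitat suitability and recruit biomass.

Capacity is the relative frequency of occurrence of favourable habitat —
the share of assessed days on which a cell meets *all* the environmental
requirements of a species (a hard conjunction of closed intervals, one per
variable).  Two species are tracked: bluefin tuna spawning habitat and
European hake nursery habitat.

Flow is an empirical index: the mean biomass of hake recruits observed in
trawl hauls (kg km-2).  Basins with fewer hauls than ``min_hauls`` keep
their value but are flagged unreliable, mirroring the data-poor Eastern
basin, and classify as "undefined" downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .regions import IndicatorValue, Period, SubBasin, aggregate, select_period


@dataclass(frozen=True)
class HabitatEnvelope:
    """Closed per-variable intervals defining a species' suitable conditions."""

    species: str
    intervals: dict  # variable name -> (lower, upper), closed on both ends

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("envelope must constrain at least one variable")
        for var, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise ValueError(f"empty interval for {var}: ({lo}, {hi})")


def favourable_mask(layers: xr.Dataset, envelope: HabitatEnvelope) -> xr.DataArray:
    """Daily 0/1 favourability with NaN where any constrained layer is missing.

    A cell-day is favourable iff every constrained variable lies inside its
    closed interval (boundary values count as inside).  Static layers such as
    depth broadcast across the time axis.
    """
    ok = None
    valid = None
    for var, (lo, hi) in envelope.intervals.items():
        if var not in layers:
            raise ValueError(f"missing layer {var!r} required by envelope")
        layer = layers[var]
        inside = (layer >= lo) & (layer <= hi)
        notnan = layer.notnull()
        ok = inside if ok is None else ok & inside
        valid = notnan if valid is None else valid & notnan
    ok, valid = xr.broadcast(ok, valid)
    return xr.where(valid, ok.astype(float), np.nan)


def habitat_frequency(daily_mask: xr.DataArray) -> xr.DataArray:
    """Percent of assessed days that were favourable, per cell.

    Days with missing data are excluded from the denominator; cells with
    zero assessed days come out as NaN.
    """
    assessed = daily_mask.notnull().sum("time")
    favourable = daily_mask.sum("time", skipna=True)
    freq = 100.0 * favourable / assessed.where(assessed > 0)
    freq.attrs["units"] = "%"
    return freq


def habitat_capacity_indicator(
    layers: xr.Dataset,
    envelope: HabitatEnvelope,
    basin: SubBasin,
    period: Period,
    code: str,
    period_index: int = 0,
    weights: np.ndarray | None = None,
) -> IndicatorValue:
    """Basin mean habitat frequency (%) within one assessment window."""
    window = layers.isel(time=np.flatnonzero(period.contains(layers["time"].values)))
    freq = habitat_frequency(favourable_mask(window, envelope))
    value = aggregate(freq, basin, None, weights)
    return IndicatorValue.from_code(code, basin.name, period.label, period_index, value)


def recruit_biomass_index(
    hauls: pd.DataFrame,
    basin: str,
    period: Period,
    period_index: int = 0,
    min_hauls: int = 5,
) -> IndicatorValue:
    """Mean recruit biomass (kg km-2) over the basin's hauls in the window."""
    sub = hauls[
        (hauls["sub_basin"] == basin)
        & hauls["year"].between(period.start, period.end)
    ]
    if sub.empty:
        return IndicatorValue.from_code(
            "HKBMI", basin, period.label, period_index, float("nan"), reliable=False
        )
    value = float(sub["recruit_biomass"].mean())
    return IndicatorValue.from_code(
        "HKBMI", basin, period.label, period_index, value, reliable=len(sub) >= min_hauls
    )
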