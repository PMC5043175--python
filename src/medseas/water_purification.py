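"""Water-purification indicators from gridded hydrodynamic/biogeochemical
fields.

Capacity is the kinetic energy of surface currents (dispersal of pollutants),
KE = 1/2 (u^2 + v^2) in m2 s-2.  Flow is the nutrient uptake by primary
production (PPR, mmolN m-2 d-1, short term) and the detritus burial into the
sediment (Sed, mmolN m-2, long term).

The default kinetic-energy indicator uses the total currents; an eddy
(anomaly) variant subtracting the per-cell period-mean current before
squaring is available via ``anomaly=True``, since the source text does not
state which convention its maps used.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .regions import IndicatorValue, Period, SubBasin, aggregate, select_period


def kinetic_energy(u: xr.DataArray, v: xr.DataArray) -> xr.DataArray:
    """Per-cell, per-step kinetic energy 1/2 (u^2 + v^2), m2 s-2."""
    if u.sizes != v.sizes or list(u.dims) != list(v.dims):
        raise ValueError("u and v must be co-registered (same dims and sizes)")
    for d in u.dims:
        if d in u.coords and not np.array_equal(u[d].values, v[d].values):
            raise ValueError(f"u and v axes differ on {d!r}")
    ke = 0.5 * (u * u + v * v)
    ke.attrs["units"] = "m2 s-2"
    return ke


def eke_indicator(
    u: xr.DataArray,
    v: xr.DataArray,
    basin: SubBasin,
    period: Period,
    period_index: int = 0,
    weights: np.ndarray | None = None,
    anomaly: bool = False,
) -> IndicatorValue:
    """Basin/period mean kinetic energy of surface currents — capacity."""
    usel, vsel = select_period(u, period), select_period(v, period)
    if anomaly and "time" in usel.dims:
        usel = usel - usel.mean("time")
        vsel = vsel - vsel.mean("time")
    value = aggregate(kinetic_energy(usel, vsel), basin, None, weights)
    return IndicatorValue.from_code("EKE", basin.name, period.label, period_index, value)


def ppr_indicator(
    ppr: xr.DataArray,
    basin: SubBasin,
    period: Period,
    period_index: int = 0,
    weights: np.ndarray | None = None,
) -> IndicatorValue:
    """Basin/period mean primary-production nutrient uptake — flow."""
    value = aggregate(ppr, basin, period, weights)
    return IndicatorValue.from_code("PPR", basin.name, period.label, period_index, value)


def sed_indicator(
    sed: xr.DataArray,
    basin: SubBasin,
    period: Period,
    period_index: int = 0,
    weights: np.ndarray | None = None,
) -> IndicatorValue:
    """Basin/period mean sediment detritus burial — flow."""
    value = aggregate(sed, basin, period, weights)
    return IndicatorValue.from_code("Sed", basin.name, period.label, period_index, value)
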