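"""Coastal flood and erosion protection scoring on ~30 km operational units.

The coastline is segmented into operational units on which four scores are
computed per year:

* ``CPcap`` — natural capacity: geomorphology, slope, and the protection
  level of emerged and submerged habitats (all normalised, weighted mean).
* ``CPexp`` — exposure: wave height, storm surge, tidal range and relative
  sea-level rise (higher = more exposed).
* ``CPsup`` — supply (service flow): capacity discounted by exposure,
  ``CPsup = CPcap * (1 - CPexp)``.
* ``CPdem`` — demand (service benefit): residents, artificial surface and
  cultural sites.

All scores live in [0, 1].  Min-max normalisation pools the three assessment
years by default so that inter-year trends remain meaningful; per-year
normalisation is available behind a flag.  Human-made defence structures are
out of scope — only natural features count as ecosystem service.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from shapely.geometry import LineString
from shapely.ops import substring

log = logging.getLogger(__name__)

#: attribute -> (score family, direction) used by :func:`score_stretches`.
#: Direction "direct" means larger raw value -> larger normalised score.
ATTRIBUTE_ROLES = {
    "geomorphology": ("capacity", "direct"),
    "slope_deg": ("capacity", "direct"),      # flatter -> less protective
    "emerged_habitat": ("capacity", "direct"),
    "submerged_habitat": ("capacity", "direct"),
    "wave_height_m": ("exposure", "direct"),
    "storm_surge_m": ("exposure", "direct"),
    "tidal_range_m": ("exposure", "direct"),
    "slr_mm_yr": ("exposure", "direct"),
    "residents": ("demand", "direct"),
    "artificial_km2": ("demand", "direct"),
    "cultural_sites": ("demand", "direct"),
}


def segment_coastline(
    line: LineString, target_length_km: float = 30.0, merge_fraction: float = 0.5
) -> list[LineString]:
    """Cut a coastline polyline into contiguous ~target-length units.

    Cuts fall every ``target_length_km`` along the line; a terminal stub
    shorter than ``merge_fraction * target`` is merged into the previous
    unit.  Coordinates are interpreted in km.
    """
    length = line.length
    if length <= 0:
        raise ValueError("coastline has zero length")
    breaks = list(np.arange(0.0, length, target_length_km)) + [length]
    if len(breaks) > 2 and breaks[-1] - breaks[-2] < merge_fraction * target_length_km:
        del breaks[-2]
    return [substring(line, a, b) for a, b in zip(breaks[:-1], breaks[1:])]


def normalize_minmax(values, direction: str = "direct") -> np.ndarray:
    """Scale values to [0, 1] by the observed min/max.

    ``direction="inverse"`` flips the scale.  A constant input degenerates to
    0.5 everywhere (midpoint convention, logged) rather than NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot normalise an empty input")
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        log.warning("normalize_minmax: constant input, returning midpoint 0.5")
        out = np.full_like(v, 0.5)
    else:
        out = (v - lo) / (hi - lo)
    return 1.0 - out if direction == "inverse" else out


def _weighted_mean(components: dict[str, np.ndarray], weights: dict[str, float] | None) -> np.ndarray:
    names = list(components)
    if weights is None:
        w = np.full(len(names), 1.0 / len(names))
    else:
        w = np.array([weights[n] for n in names], dtype=float)
        total = w.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            log.warning("weights sum to %.4f; renormalising", total)
            w = w / total
    stacked = np.stack([np.asarray(components[n], dtype=float) for n in names])
    return np.tensordot(w, stacked, axes=1)


def cp_capacity(
    geomorphology, slope, emerged_habitat, submerged_habitat, weights=None
) -> np.ndarray:
    """Weighted mean of the four normalised protective components."""
    return _weighted_mean(
        {
            "geomorphology": geomorphology,
            "slope_deg": slope,
            "emerged_habitat": emerged_habitat,
            "submerged_habitat": submerged_habitat,
        },
        weights,
    )


def cp_exposure(wave_height, storm_surge, tidal_range, slr, weights=None) -> np.ndarray:
    """Weighted mean of the four normalised exposure components."""
    return _weighted_mean(
        {
            "wave_height_m": wave_height,
            "storm_surge_m": storm_surge,
            "tidal_range_m": tidal_range,
            "slr_mm_yr": slr,
        },
        weights,
    )


def cp_demand(residents, artificial_km2, cultural_sites, weights=None) -> np.ndarray:
    """Weighted mean of the three normalised demand components — benefit."""
    return _weighted_mean(
        {
            "residents": residents,
            "artificial_km2": artificial_km2,
            "cultural_sites": cultural_sites,
        },
        weights,
    )


def cp_supply(cpcap, cpexp) -> np.ndarray:
    """Supply = capacity discounted by exposure: CPcap * (1 - CPexp)."""
    cap = np.asarray(cpcap, dtype=float)
    exp_ = np.asarray(cpexp, dtype=float)
    if ((cap < 0) | (cap > 1) | (exp_ < 0) | (exp_ > 1)).any():
        raise ValueError("CPcap and CPexp must lie in [0, 1]")
    return cap * (1.0 - exp_)


def score_stretches(
    stretches: pd.DataFrame,
    weights: dict[str, dict[str, float]] | None = None,
    per_year_norm: bool = False,
) -> pd.DataFrame:
    """Score an operational-unit attribute table across all years.

    Returns one row per (id, year) with CPcap, CPexp, CPsup, CPdem in [0, 1].
    Normalisation bounds pool all years unless ``per_year_norm`` is set.
    """
    weights = weights or {}
    df = stretches.copy()
    norm: dict[str, np.ndarray] = {}
    for attr, (family, direction) in ATTRIBUTE_ROLES.items():
        if per_year_norm:
            norm[attr] = (
                df.groupby("year")[attr]
                .transform(lambda s: normalize_minmax(s.to_numpy(), direction))
                .to_numpy()
            )
        else:
            norm[attr] = normalize_minmax(df[attr].to_numpy(), direction)
    cap = cp_capacity(
        norm["geomorphology"],
        norm["slope_deg"],
        norm["emerged_habitat"],
        norm["submerged_habitat"],
        weights.get("capacity"),
    )
    exp_ = cp_exposure(
        norm["wave_height_m"],
        norm["storm_surge_m"],
        norm["tidal_range_m"],
        norm["slr_mm_yr"],
        weights.get("exposure"),
    )
    dem = cp_demand(
        norm["residents"],
        norm["artificial_km2"],
        norm["cultural_sites"],
        weights.get("demand"),
    )
    out = pd.DataFrame(
        {
            "id": df["id"].to_numpy(),
            "year": df["year"].to_numpy(),
            "CPcap": cap,
            "CPexp": exp_,
            "CPsup": cp_supply(cap, exp_),
            "CPdem": dem,
        }
    )
    if "sub_basin" in df.columns:
        out["sub_basin"] = df["sub_basin"].to_numpy()
    return out
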