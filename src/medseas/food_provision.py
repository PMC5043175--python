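"""Food-provisioning indicators from food-web model outputs.

Capacity is the standing biomass of the commercially dominant groups
(pilchard + anchovy together, and hake); flow is the catch of the same
groups plus the trophic level of the catch (TLC) over all retained groups.
A declining TLC is the classic "fishing down the food web" signal.

Records are annual per-group, per-basin densities; within an assessment
period annual values are averaged (not summed), so indicators stay per-year
densities whatever the window length.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .regions import IndicatorValue, Period

FOODWEB_COLUMNS = [
    "group",
    "sub_basin",
    "year",
    "biomass",
    "catch",
    "trophic_level",
    "retained",
]


def read_foodweb_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FOODWEB_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"food-web table missing columns: {sorted(missing)}")
    return df


def _select(records: pd.DataFrame, basin: str, period: Period) -> pd.DataFrame:
    return records[
        (records["sub_basin"] == basin)
        & records["year"].between(period.start, period.end)
    ]


def _group_density_indicator(
    records: pd.DataFrame,
    groups: list[str],
    basin: str,
    period: Period,
    period_index: int,
    column: str,
    code: str,
    combine: str = "sum",
) -> IndicatorValue:
    if not groups:
        raise ValueError("group list must be non-empty")
    sub = _select(records, basin, period)
    sub = sub[sub["group"].isin(groups)]
    if sub.empty:
        return IndicatorValue.from_code(code, basin, period.label, period_index, float("nan"))
    yearly = sub.groupby("year")[column].agg(combine)
    return IndicatorValue.from_code(code, basin, period.label, period_index, float(yearly.mean()))


def biomass_indicator(
    records: pd.DataFrame,
    groups: list[str],
    basin: str,
    period: Period,
    period_index: int = 0,
    code: str = "BM_PA",
    combine: str = "sum",
) -> IndicatorValue:
    """Mean annual summed biomass (t km-2) of the named groups — capacity.

    ``combine`` may be set to ``"mean"`` for an average across groups instead
    of the default sum (relevant for the joint pilchard + anchovy group).
    """
    return _group_density_indicator(
        records, groups, basin, period, period_index, "biomass", code, combine
    )


def catch_indicator(
    records: pd.DataFrame,
    groups: list[str],
    basin: str,
    period: Period,
    period_index: int = 0,
    combine: str = "sum",
) -> IndicatorValue:
    """Mean annual summed catch (t km-2 yr-1) of the named groups — flow."""
    return _group_density_indicator(
        records, groups, basin, period, period_index, "catch", "Cat", combine
    )


def trophic_level_of_catch(
    records: pd.DataFrame,
    basin: str,
    period: Period,
    period_index: int = 0,
) -> IndicatorValue:
    """Catch-weighted mean trophic level of all retained groups — flow.

    TLC = sum_i TL_i * Y_i / sum_i Y_i over retained records with positive
    catch, pooled across the years of the period.  Zero total retained catch
    yields a missing value.
    """
    sub = _select(records, basin, period)
    sub = sub[sub["retained"] & (sub["catch"] > 0)]
    total = float(sub["catch"].sum())
    if total == 0.0:
        return IndicatorValue.from_code("TLC", basin, period.label, period_index, float("nan"))
    tlc = float((sub["trophic_level"] * sub["catch"]).sum() / total)
    return IndicatorValue.from_code("TLC", basin, period.label, period_index, tlc)
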