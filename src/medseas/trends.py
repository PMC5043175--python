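"""Tidy indicator table, endpoint trend classification and the
sustainability (arrow) matrix.

A trend compares the first and last assessment periods: the relative change
r = (v3 - v1)/|v1| classifies as *stable* when |r| < tau, *increase* when
r >= tau, *decrease* when r <= -tau, and *undefined* when any period is
missing or unreliable.  The middle period does not enter the classification
(the arrows compare endpoint states); it is reported as part of the tidy
table.  Tau defaults to 5%, except recreation where small fluctuations are
explicitly treated as stable at the 1% level.

A (service, basin) cell is flagged as a sustainability concern when its
capacity decreases while its flow or benefit increases — the ecosystem is
delivering more from a shrinking base.
"""

from __future__ import annotations

import logging
from collections import Counter

import pandas as pd

from .regions import IndicatorValue

log = logging.getLogger(__name__)

INCREASE, DECREASE, STABLE, UNDEFINED = "increase", "decrease", "stable", "undefined"
CASCADE_ORDER = ("capacity", "flow", "benefit")

#: CSV rendering of the arrow matrix
ARROW_SYMBOLS = {INCREASE: "up", DECREASE: "down", STABLE: "stable", UNDEFINED: "na"}


def default_taus() -> dict[str, float]:
    return {"default": 0.05, "recreation": 0.01}


def classify_trend(v1: float, v2: float, v3: float, tau: float = 0.05) -> str:
    """Classify the endpoint change of a three-period series."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if any(pd.isna(v) for v in (v1, v2, v3)):
        return UNDEFINED
    if v1 == 0:
        if v3 == 0:
            return STABLE
        log.warning("classify_trend: v1 = 0, falling back to absolute change")
        r = v3 - v1
    else:
        r = (v3 - v1) / abs(v1)
    if abs(r) < tau:
        return STABLE
    return INCREASE if r > 0 else DECREASE


def build_indicator_table(values: list[IndicatorValue]) -> pd.DataFrame:
    """Assemble a tidy table with one row per
    (service, cascade_level, indicator, sub_basin, period)."""
    rows = [
        {
            "service": v.service,
            "cascade_level": v.cascade_level,
            "indicator": v.indicator,
            "sub_basin": v.sub_basin,
            "period": v.period,
            "period_index": v.period_index,
            "value": v.value,
            "units": v.units,
            "reliable": v.reliable,
        }
        for v in values
    ]
    table = pd.DataFrame(rows)
    key = ["service", "cascade_level", "indicator", "sub_basin", "period"]
    dup = table.duplicated(subset=key)
    if dup.any():
        raise ValueError(f"duplicate indicator keys:\n{table.loc[dup, key]}")
    return table.sort_values(key + ["period_index"]).reset_index(drop=True)


def completeness_report(table: pd.DataFrame) -> pd.DataFrame:
    """Cells that are missing (NaN) or flagged unreliable."""
    bad = table[table["value"].isna() | ~table["reliable"]]
    return bad[["service", "indicator", "sub_basin", "period", "value", "reliable"]]


def _series_symbol(group: pd.DataFrame, tau: float) -> str:
    g = group.sort_values("period_index")
    if len(g) != 3 or not g["reliable"].all():
        return UNDEFINED
    v1, v2, v3 = g["value"].tolist()
    return classify_trend(v1, v2, v3, tau)


def trends_matrix(table: pd.DataFrame, taus: dict[str, float] | None = None) -> pd.DataFrame:
    """One trend symbol per (service, cascade_level, sub_basin).

    Multiple indicators at the same cascade level (e.g. the two biomass
    indicators for food capacity) are combined by majority; ties give
    *undefined*.
    """
    taus = {**default_taus(), **(taus or {})}
    records = []
    for (service, level, basin), group in table.groupby(
        ["service", "cascade_level", "sub_basin"], sort=False
    ):
        tau = taus.get(service, taus["default"])
        symbols = [
            _series_symbol(ind_group, tau)
            for _, ind_group in group.groupby("indicator", sort=False)
        ]
        counts = Counter(symbols).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            symbol = UNDEFINED
        else:
            symbol = counts[0][0]
        records.append(
            {
                "service": service,
                "cascade_level": level,
                "sub_basin": basin,
                "symbol": symbol,
            }
        )
    matrix = pd.DataFrame(records)
    matrix["cascade_level"] = pd.Categorical(
        matrix["cascade_level"], categories=CASCADE_ORDER, ordered=True
    )
    return matrix.sort_values(["service", "cascade_level", "sub_basin"]).reset_index(
        drop=True
    )


def sustainability_flags(matrix: pd.DataFrame) -> list[tuple[str, str]]:
    """(service, basin) cells with decreasing capacity but rising flow or
    benefit — the points of special concern."""
    flags = []
    for (service, basin), group in matrix.groupby(["service", "sub_basin"], sort=False):
        by_level = dict(zip(group["cascade_level"].astype(str), group["symbol"]))
        if by_level.get("capacity") == DECREASE and (
            by_level.get("flow") == INCREASE or by_level.get("benefit") == INCREASE
        ):
            flags.append((service, basin))
    return sorted(flags)


def render_arrow_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Wide service x basin table with {up, down, stable, na} symbols."""
    wide = matrix.assign(symbol=matrix["symbol"].map(ARROW_SYMBOLS)).pivot_table(
        index=["service", "cascade_level"],
        columns="sub_basin",
        values="symbol",
        aggfunc="first",
        observed=True,
    )
    return wide.reset_index()
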