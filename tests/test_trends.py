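"""Trend classification, indicator table assembly and sustainability flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from medseas.regions import IndicatorValue
from medseas.trends import (
    DECREASE,
    INCREASE,
    STABLE,
    UNDEFINED,
    build_indicator_table,
    classify_trend,
    completeness_report,
    render_arrow_matrix,
    sustainability_flags,
    trends_matrix,
)

finite = st.floats(-1e6, 1e6, allow_nan=False)


class TestClassifyTrend:
    def test_sub_threshold_change_is_stable(self):
        # a 0.5% endpoint change under a 1% threshold counts as stable
        assert classify_trend(100, 100, 100.5, tau=0.01) == STABLE

    def test_forty_percent_rise_is_increase(self):
        assert classify_trend(10, 12, 14, tau=0.05) == INCREASE

    def test_six_percent_drop_is_decrease(self):
        assert classify_trend(10, 9, 9.4, tau=0.05) == DECREASE

    def test_missing_period_undefined(self):
        assert classify_trend(10, np.nan, 12) == UNDEFINED

    def test_zero_baseline_absolute_fallback(self, caplog):
        with caplog.at_level("WARNING"):
            assert classify_trend(0.0, 0.1, 0.2, tau=0.05) == INCREASE
        assert "absolute" in caplog.text
        assert classify_trend(0.0, 0.0, 0.0) == STABLE

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            classify_trend(1, 2, 3, tau=0.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        v1=st.floats(-1e3, 1e3).filter(lambda x: abs(x) > 1e-3),
        v2=finite,
        v3=st.floats(-1e3, 1e3),
        tau=st.floats(0.001, 0.5),
    )
    def test_antisymmetry_of_the_endpoint_change(self, v1, v2, v3, tau):
        # reflecting the endpoint across the baseline negates the relative
        # change exactly, so increase <-> decrease and stable stays fixed
        r = (v3 - v1) / abs(v1)
        assume(abs(abs(r) - tau) > 1e-6)  # keep away from the threshold ulp
        fwd = classify_trend(v1, v2, v3, tau)
        rev = classify_trend(v1, v2, 2 * v1 - v3, tau)
        mapping = {INCREASE: DECREASE, DECREASE: INCREASE, STABLE: STABLE}
        assert rev == mapping[fwd]

    def test_swapping_endpoints_flips_direction(self):
        # swapping v1 and v3 can never keep the same non-stable symbol
        for v1, v3 in [(10, 14), (14, 10), (2, 1.9), (100, 105)]:
            fwd = classify_trend(v1, 0, v3, tau=0.05)
            rev = classify_trend(v3, 0, v1, tau=0.05)
            if fwd == INCREASE:
                assert rev != INCREASE
            if fwd == DECREASE:
                assert rev != DECREASE

    def test_tau_limits(self):
        assert classify_trend(10, 11, 12, tau=1e9) == STABLE
        assert classify_trend(10, 11, 12, tau=1e-12) == INCREASE
        assert classify_trend(12, 11, 10, tau=1e-12) == DECREASE


def iv(code, basin, idx, value, reliable=True, period=None):
    return IndicatorValue.from_code(
        code, basin, period or f"t{idx + 1}", idx, value, reliable
    )


class TestIndicatorTable:
    def test_duplicate_keys_rejected(self):
        values = [iv("PPR", "Western", 0, 1.0), iv("PPR", "Western", 0, 2.0)]
        with pytest.raises(ValueError, match="duplicate"):
            build_indicator_table(values)

    def test_round_trip_csv(self, tmp_path):
        values = [iv("PPR", b, j, j + 1.0) for b in ("Western", "Eastern") for j in range(3)]
        table = build_indicator_table(values)
        path = tmp_path / "table.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table)

    def test_completeness_report_flags_unreliable_and_missing(self):
        values = [
            iv("HKBMI", "Eastern", 0, 5.0, reliable=False),
            iv("HKBMI", "Western", 0, np.nan),
            iv("HKBMI", "Central", 0, 5.0),
        ]
        report = completeness_report(build_indicator_table(values))
        assert set(report["sub_basin"]) == {"Eastern", "Western"}


def _series(code, basin, v1, v2, v3, reliable=True):
    return [iv(code, basin, j, v, reliable) for j, v in enumerate((v1, v2, v3))]


class TestTrendsMatrix:
    def test_all_flat_scenario_all_stable(self):
        values = []
        for code in ("PPR", "Sed", "EKE"):
            for basin in ("Western", "Eastern"):
                values += _series(code, basin, 5.0, 5.0, 5.0)
        matrix = trends_matrix(build_indicator_table(values))
        assert (matrix["symbol"] == STABLE).all()

    def test_conflicting_capacity_indicators_tie_to_undefined(self):
        values = _series("BM_PA", "Western", 10, 11, 13) + _series(
            "BM_HK", "Western", 10, 9, 7
        )
        matrix = trends_matrix(build_indicator_table(values))
        row = matrix[matrix["cascade_level"] == "capacity"].iloc[0]
        assert row["symbol"] == UNDEFINED

    def test_agreeing_indicators_keep_majority(self):
        values = _series("BM_PA", "Western", 10, 11, 13) + _series(
            "BM_HK", "Western", 10, 12, 14
        )
        matrix = trends_matrix(build_indicator_table(values))
        row = matrix[matrix["cascade_level"] == "capacity"].iloc[0]
        assert row["symbol"] == INCREASE

    def test_unreliable_series_classifies_undefined(self):
        values = _series("HKBMI", "Eastern", 10, 8, 6, reliable=False)
        matrix = trends_matrix(build_indicator_table(values))
        assert matrix["symbol"].iloc[0] == UNDEFINED

    def test_recreation_uses_one_percent_threshold(self):
        values = _series("RPI", "Western", 1.0, 0.999, 0.995)
        matrix = trends_matrix(build_indicator_table(values))
        assert matrix["symbol"].iloc[0] == STABLE
        # the same 0.5% drop on a default-threshold service is also stable,
        # but a 3% drop flips only under the default tau
        values = _series("PPR", "Western", 1.0, 0.99, 0.97)
        assert trends_matrix(build_indicator_table(values))["symbol"].iloc[0] == STABLE
        values = _series("RPI", "Eastern", 1.0, 0.99, 0.97)
        assert trends_matrix(build_indicator_table(values))["symbol"].iloc[0] == DECREASE


class TestSustainabilityFlags:
    def _matrix(self, cap, flow, ben=None):
        rows = [
            {"service": "s", "cascade_level": "capacity", "sub_basin": "W", "symbol": cap},
            {"service": "s", "cascade_level": "flow", "sub_basin": "W", "symbol": flow},
        ]
        if ben is not None:
            rows.append(
                {"service": "s", "cascade_level": "benefit", "sub_basin": "W", "symbol": ben}
            )
        return pd.DataFrame(rows)

    def test_decreasing_capacity_rising_benefit_flagged(self):
        assert sustainability_flags(self._matrix(DECREASE, STABLE, INCREASE)) == [("s", "W")]

    def test_rising_capacity_not_flagged(self):
        assert sustainability_flags(self._matrix(INCREASE, INCREASE)) == []

    def test_everything_falling_not_flagged(self):
        assert sustainability_flags(self._matrix(DECREASE, DECREASE, STABLE)) == []


def test_arrow_matrix_rendering():
    values = _series("PPR", "Western", 1.0, 1.2, 1.5) + _series(
        "PPR", "Eastern", 1.0, 0.9, 0.7
    )
    wide = render_arrow_matrix(trends_matrix(build_indicator_table(values)))
    row = wide.iloc[0]
    assert row["Western"] == "up" and row["Eastern"] == "down"
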