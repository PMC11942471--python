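"""Indicator formulas, bounds, and table-style summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effi.errors import DataConsistencyError
from effi.indicators import (
    INDICATORS,
    compute_indicators,
    efr_heatmap_matrix,
    format_summary,
    summarize,
)

COLS = (
    "births_le14",
    "births_15_19",
    "aff_women_10_14",
    "aff_women_15_19",
    "aff_women_total",
    "aff_indigenous",
    "aff_migrant",
    "aff_subsidized",
    "dv_total",
    "dv_women_male_perp",
    "dv_children_le18",
    "deaths_total",
    "deaths_suicide",
    "deaths_homicide_le19",
)


def counts_frame(**overrides):
    base = {
        "births_le14": 2,
        "births_15_19": 30,
        "aff_women_10_14": 1000,
        "aff_women_15_19": 1000,
        "aff_women_total": 20000,
        "aff_indigenous": 5000,
        "aff_migrant": 500,
        "aff_subsidized": 10000,
        "dv_total": 100,
        "dv_women_male_perp": 30,
        "dv_children_le18": 0,
        "deaths_total": 1000,
        "deaths_suicide": 5,
        "deaths_homicide_le19": 25,
    }
    base.update(overrides)
    idx = pd.MultiIndex.from_tuples([("D01", 2020)], names=["department", "year"])
    return pd.DataFrame({c: [float(base[c])] for c in COLS}, index=idx)


def test_hand_computed_indicator_values():
    out = compute_indicators(
        counts_frame(aff_indigenous=5000, aff_migrant=600, aff_subsidized=10000,
                     aff_women_total=20000)
    ).iloc[0]
    assert out["PIW"] == pytest.approx(25.0)
    assert out["PMW"] == pytest.approx(3.0)
    assert out["PSW"] == pytest.approx(50.0)
    assert out["IFR"] == pytest.approx(2.0)
    assert out["AFR"] == pytest.approx(30.0)
    assert out["EFR"] == pytest.approx(16.0)  # (2+30)/2000*1000
    assert out["DVAW"] == pytest.approx(300.0)
    assert out["DVAC"] == pytest.approx(0.0)
    assert out["SR"] == pytest.approx(5.0)
    assert out["CHR"] == pytest.approx(25.0)


def test_share_example_migrant_subsidized():
    out = compute_indicators(
        counts_frame(aff_migrant=3, aff_subsidized=60, aff_women_total=120,
                     aff_indigenous=0)
    ).iloc[0]
    assert out["PMW"] == pytest.approx(2.5)
    assert out["PSW"] == pytest.approx(50.0)
    assert out["PIW"] == pytest.approx(0.0)


def test_dv_scale_is_configurable():
    df = counts_frame()
    per_1000 = compute_indicators(df, dv_scale=1000).iloc[0]["DVAW"]
    per_100 = compute_indicators(df, dv_scale=100).iloc[0]["DVAW"]
    assert per_1000 == pytest.approx(300.0)
    assert per_100 == pytest.approx(30.0)


def test_zero_denominators_give_missing_not_zero():
    out = compute_indicators(
        counts_frame(
            aff_women_total=0, aff_indigenous=0, aff_migrant=0, aff_subsidized=0,
            dv_total=0, dv_women_male_perp=0, dv_children_le18=0,
            deaths_total=0, deaths_suicide=0, deaths_homicide_le19=0,
        )
    ).iloc[0]
    for ind in ("PIW", "PMW", "PSW", "DVAW", "DVAC", "SR", "CHR"):
        assert np.isnan(out[ind]), ind
    # positive denominators with zero numerators are data, not missing
    zeros = compute_indicators(counts_frame(births_le14=0, births_15_19=0)).iloc[0]
    assert zeros["IFR"] == 0.0 and zeros["AFR"] == 0.0 and zeros["EFR"] == 0.0


def test_subgroup_exceeding_total_is_consistency_error():
    with pytest.raises(DataConsistencyError, match="PIW"):
        compute_indicators(counts_frame(aff_indigenous=30000))
    with pytest.raises(DataConsistencyError, match="DVAW"):
        compute_indicators(counts_frame(dv_women_male_perp=200))


@given(
    st.integers(1, 10_000),
    st.integers(0, 10_000),
    st.integers(0, 500),
    st.integers(2, 20),
)
@settings(max_examples=60, deadline=None)
def test_scale_equivariance_and_share_bounds(total, subgroup, births, factor):
    subgroup = min(subgroup, total)
    base = counts_frame(
        aff_women_total=total,
        aff_indigenous=subgroup,
        aff_migrant=0,
        aff_subsidized=min(subgroup, total),
        births_le14=births,
        births_15_19=births,
        aff_women_10_14=total,
        aff_women_15_19=total,
    )
    scaled = base * factor
    a = compute_indicators(base)
    b = compute_indicators(scaled)
    pd.testing.assert_frame_equal(a, b)
    piw = a.iloc[0]["PIW"]
    assert 0.0 <= piw <= 100.0


@given(st.integers(0, 50), st.integers(0, 2000), st.integers(1, 5000), st.integers(1, 5000))
@settings(max_examples=60, deadline=None)
def test_efr_between_ifr_and_afr(b14, b19, n14, n19):
    out = compute_indicators(
        counts_frame(
            births_le14=b14, births_15_19=b19, aff_women_10_14=n14, aff_women_15_19=n19
        )
    ).iloc[0]
    lo, hi = sorted([out["IFR"], out["AFR"]])
    assert lo - 1e-9 <= out["EFR"] <= hi + 1e-9


def _series_panel(values):
    idx = pd.MultiIndex.from_product(
        [["D01"], range(2019, 2019 + len(values))], names=["department", "year"]
    )
    return pd.DataFrame({"PIW": list(values)}, index=idx, dtype=float)


@pytest.mark.parametrize(
    "values, expected",
    [
        ((10, 20, 30, 40), "25 (10; 40)"),
        ((5,), "5 (5; 5)"),
        ((0, 0, 0, 0), "0 (0; 0)"),
    ],
)
def test_summary_formatting(values, expected):
    s = format_summary(summarize(_series_panel(values)))
    assert s.loc["D01", "PIW"] == expected


def test_summary_all_missing_marked_unavailable():
    s = format_summary(summarize(_series_panel((np.nan, np.nan))))
    assert s.loc["D01", "PIW"] == "NA"


def test_summary_order_invariant():
    stats = summarize(_series_panel((3, 1, 4, 1)))
    assert (
        stats[("PIW", "min")].iloc[0]
        <= stats[("PIW", "median")].iloc[0]
        <= stats[("PIW", "max")].iloc[0]
    )


def test_efr_heatmap_sorted_by_last_year(indicator_panel):
    mat = efr_heatmap_matrix(indicator_panel)
    last = mat.columns.max()
    vals = mat[last].to_numpy()
    assert (np.diff(vals[~np.isnan(vals)]) <= 1e-12).all()


def test_indicator_panel_columns_and_bounds(indicator_panel):
    assert list(indicator_panel.columns) == list(INDICATORS)
    for col, hi in [("PIW", 100), ("PMW", 100), ("PSW", 100),
                    ("DVAW", 1000), ("DVAC", 1000), ("SR", 1000), ("CHR", 1000)]:
        v = indicator_panel[col].dropna()
        assert ((v >= 0) & (v <= hi)).all(), col
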