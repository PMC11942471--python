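"""The ten department-year indicators and their table-style summaries.

Four indicator families are computed from the harmonized counts:

* structural inequality — PIW, PMW, PSW: indigenous / migrant / subsidized
  affiliated women as a percentage of all affiliated women;
* early fertility — IFR, AFR, EFR: births to mothers <=14 / 15-19 / <=19 per
  1000 affiliated women in the matching age band (10-14 / 15-19 / 10-19);
* domestic violence — DVAW, DVAC: reported cases against women (male
  perpetrator) / against children <=18 as a share of all reported cases,
  per-1000 by default (see ``dv_scale``);
* violent deaths — SR, CHR: suicides / homicides of persons <=19 per 1000
  reported deaths.

Rates are missing (NaN), never 0, when their denominator is zero; a subgroup
count exceeding its total is a data-consistency error.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .errors import DataConsistencyError
from .io import HarmonizedPanel

INDICATORS = ("PIW", "PMW", "PSW", "IFR", "AFR", "EFR", "DVAW", "DVAC", "SR", "CHR")

#: Candidate risk predictors for the fragility index (fertility outcomes excluded).
RISK_INDICATORS = ("PIW", "PMW", "PSW", "DVAW", "DVAC", "CHR")
FERTILITY_INDICATORS = ("IFR", "AFR", "EFR")

PanelLike = Union[HarmonizedPanel, pd.DataFrame]


def _counts(panel: PanelLike) -> pd.DataFrame:
    return panel.data if isinstance(panel, HarmonizedPanel) else panel


def _ratio(
    num: pd.Series, den: pd.Series, scale: float, name: str, subset: bool = True
) -> pd.Series:
    """num/den*scale with NaN where den==0.

    With ``subset=True`` (shares: the numerator counts a subgroup of the
    denominator) a numerator exceeding its total is a data-consistency
    error.  Fertility rates set ``subset=False``: births are not a subset
    of affiliations, so no such bound applies.
    """
    bad = subset & (num > den) & num.notna() & den.notna()
    if bad.any():
        cell = bad.idxmax()
        raise DataConsistencyError(
            f"{name}: subgroup count exceeds total at {cell}: "
            f"{num[cell]} > {den[cell]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den * scale
    out[den == 0] = np.nan
    return out.rename(name)


def affiliation_shares(panel: PanelLike) -> pd.DataFrame:
    """PIW/PMW/PSW: subgroup affiliated women over total affiliated women x 100."""
    d = _counts(panel)
    total = d["aff_women_total"]
    return pd.concat(
        [
            _ratio(d["aff_indigenous"], total, 100.0, "PIW"),
            _ratio(d["aff_migrant"], total, 100.0, "PMW"),
            _ratio(d["aff_subsidized"], total, 100.0, "PSW"),
        ],
        axis=1,
    )


def fertility_rates(panel: PanelLike) -> pd.DataFrame:
    """IFR/AFR/EFR: births per 1000 affiliated women in the matching age band."""
    d = _counts(panel)
    ifr = _ratio(d["births_le14"], d["aff_women_10_14"], 1000.0, "IFR", subset=False)
    afr = _ratio(d["births_15_19"], d["aff_women_15_19"], 1000.0, "AFR", subset=False)
    efr = _ratio(
        d["births_le14"] + d["births_15_19"],
        d["aff_women_10_14"] + d["aff_women_15_19"],
        1000.0,
        "EFR",
        subset=False,
    )
    return pd.concat([ifr, afr, efr], axis=1)


def violence_shares(panel: PanelLike, scale: float = 1000.0) -> pd.DataFrame:
    """DVAW/DVAC: domestic-violence subgroup cases over all reported cases.

    Default scale is per-1000: the printed formula scale (x100) is
    inconsistent with the magnitudes the reference tables report, which are
    only compatible with a per-1000 share (see docs/methods.md).
    """
    d = _counts(panel)
    total = d["dv_total"]
    return pd.concat(
        [
            _ratio(d["dv_women_male_perp"], total, scale, "DVAW"),
            _ratio(d["dv_children_le18"], total, scale, "DVAC"),
        ],
        axis=1,
    )


def death_rates(panel: PanelLike) -> pd.DataFrame:
    """SR/CHR: suicides and homicides of <=19-year-olds per 1000 reported deaths."""
    d = _counts(panel)
    total = d["deaths_total"]
    return pd.concat(
        [
            _ratio(d["deaths_suicide"], total, 1000.0, "SR"),
            _ratio(d["deaths_homicide_le19"], total, 1000.0, "CHR"),
        ],
        axis=1,
    )


def compute_indicators(panel: PanelLike, dv_scale: float = 1000.0) -> pd.DataFrame:
    """All ten indicators, indexed by (department, year)."""
    parts = [
        affiliation_shares(panel),
        fertility_rates(panel),
        violence_shares(panel, scale=dv_scale),
        death_rates(panel),
    ]
    out = pd.concat(parts, axis=1)
    return out[list(INDICATORS)]


def summarize(indicator_panel: pd.DataFrame) -> pd.DataFrame:
    """Median/min/max per department and indicator over the study years.

    Missing years are ignored; an all-missing series yields NaN statistics
    (rendered as unavailable by :func:`format_summary`).
    """
    grouped = indicator_panel.groupby(level="department")
    stats = pd.concat(
        {"median": grouped.median(), "min": grouped.min(), "max": grouped.max()},
        axis=1,
    )
    # columns -> (indicator, stat)
    stats = stats.swaplevel(axis=1).sort_index(axis=1)
    return stats


def _fmt(x: float) -> str:
    if pd.isna(x):
        return "NA"
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-0") else "0"


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Render a summary as "median (min; max)" strings, one column per indicator."""
    indicators = summary.columns.get_level_values(0).unique()
    out = {}
    for ind in indicators:
        med, lo, hi = (summary[(ind, s)] for s in ("median", "min", "max"))
        out[ind] = [
            "NA" if pd.isna(m) else f"{_fmt(m)} ({_fmt(a)}; {_fmt(b)})"
            for m, a, b in zip(med, lo, hi)
        ]
    return pd.DataFrame(out, index=summary.index)


def efr_heatmap_matrix(indicator_panel: pd.DataFrame) -> pd.DataFrame:
    """Department x year EFR matrix, rows sorted descending by the last year's EFR."""
    mat = indicator_panel["EFR"].unstack("year")
    last = mat.columns.max()
    return mat.sort_values(by=last, ascending=False)
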