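"""Z-score standardization, relative fertility changes, and dataset segmentation.

The index construction works on standardized indicators, Z = (X - mu)/sigma
with the population sigma, pooled per indicator over all department-years so
that the longitudinal dataset sits on one scale.  The outcome side uses the
relative percent change of each fertility rate across a configured year pair
(default 2020 -> 2021: conceptions during the first pandemic year becoming
maternities the next), standardized across departments.

Segmentation produces the two datasets the modelling stage consumes:

* longitudinal — standardized risk indicators for every department-year,
  with the fertility indicators explicitly excluded (they define the
  outcome, not the predictors);
* aggregated — one row per department: period-averaged standardized risk
  indicators over the index window plus the delta outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    ConfigError,
    CoverageError,
    DegenerateScaleWarning,
    ExclusionWarning,
    InsufficientDataError,
    YearRangeError,
)
from .indicators import FERTILITY_INDICATORS, RISK_INDICATORS

#: Default candidate predictor set: the six risk indicators plus the suicide
#: rate, which the fitted models treat as a seventh candidate predictor.
DEFAULT_PREDICTORS: tuple[str, ...] = RISK_INDICATORS + ("SR",)

DELTA_OUTCOMES = ("dIFR", "dAFR", "dEFR")
Z_DELTA_OUTCOMES = ("Z_dIFR", "Z_dAFR", "Z_dEFR")


class ZScoreStandardizer(BaseEstimator, TransformerMixin):
    """Column-wise z-score transformer with population sigma by default.

    Missing values are excluded from mu/sigma and propagate through
    ``transform``.  A zero-variance column is transformed to all zeros with a
    :class:`DegenerateScaleWarning` instead of dividing by zero.

    Parameters
    ----------
    ddof : int
        Delta degrees of freedom for sigma; 0 (population) matches the plain
        sigma of the index definition, 1 gives the sample convention.
    """

    def __init__(self, ddof: int = 0):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        n_obs = X.notna().sum(axis=0)
        short = n_obs[n_obs < 2]
        if len(short):
            raise InsufficientDataError(
                f"columns with fewer than 2 non-missing values: {list(short.index)}"
            )
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0).to_numpy(dtype=float)
        self.scale_ = X.std(axis=0, ddof=self.ddof).to_numpy(dtype=float)
        self.degenerate_ = self.scale_ == 0.0
        if self.degenerate_.any():
            cols = list(np.asarray(X.columns)[self.degenerate_])
            warnings.warn(
                f"sigma = 0 for column(s) {cols}; standardized values forced to 0",
                DegenerateScaleWarning,
                stacklevel=2,
            )
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        scale = np.where(self.degenerate_, 1.0, self.scale_)
        Z = (X - self.mean_) / scale
        Z.loc[:, self.degenerate_] = Z.loc[:, self.degenerate_] * 0.0
        return Z

    def params_frame(self) -> pd.DataFrame:
        """mu/sigma used per column, for the reproducibility sidecar."""
        return pd.DataFrame(
            {"mu": self.mean_, "sigma": self.scale_}, index=self.feature_names_in_
        )


def zscore(values, ddof: int = 0):
    """Standardize one vector; returns ``(z, mu, sigma)``.

    Population sigma by default; NaNs are excluded from mu/sigma and
    propagate.  A constant vector returns all zeros with a degeneracy
    warning; fewer than two non-missing values is an error.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    scaler = ZScoreStandardizer(ddof=ddof).fit(s.to_frame("x"))
    z = scaler.transform(s.to_frame("x"))["x"].to_numpy()
    return z, float(scaler.mean_[0]), float(scaler.scale_[0])


def relative_change(
    indicator_panel: pd.DataFrame,
    indicator: str,
    from_year: int,
    to_year: int,
) -> pd.Series:
    """Per-department relative percent change of one indicator between two years.

    delta = (value_to - value_from) / value_from * 100.  A zero or missing
    baseline yields NaN with an exclusion warning naming the departments.
    """
    years = set(indicator_panel.index.get_level_values("year"))
    for y in (from_year, to_year):
        if y not in years:
            raise YearRangeError(f"year {y} not in panel years {sorted(years)}")
    v0 = indicator_panel.xs(from_year, level="year")[indicator]
    v1 = indicator_panel.xs(to_year, level="year")[indicator]
    zero_base = (v0 == 0) & v1.notna()
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (v1 - v0) / v0 * 100.0
    delta[v0 == 0] = np.nan
    if zero_base.any():
        warnings.warn(
            f"{indicator} {from_year}->{to_year}: zero baseline, excluded "
            f"departments {sorted(v0.index[zero_base])}",
            ExclusionWarning,
            stacklevel=2,
        )
    return delta.rename(f"d{indicator}")


def delta_outcomes(
    indicator_panel: pd.DataFrame,
    from_year: int = 2020,
    to_year: int = 2021,
) -> pd.DataFrame:
    """Relative changes of IFR/AFR/EFR per department, raw and standardized."""
    deltas = pd.concat(
        [
            relative_change(indicator_panel, ind, from_year, to_year)
            for ind in FERTILITY_INDICATORS
        ],
        axis=1,
    )
    out = deltas.copy()
    for ind in FERTILITY_INDICATORS:
        z, _, _ = zscore(deltas[f"d{ind}"].to_numpy())
        out[f"Z_d{ind}"] = z
    return out


@dataclass
class SegmentedDatasets:
    """The longitudinal predictor dataset and aggregated outcome dataset."""

    longitudinal: pd.DataFrame  # (department, year) x standardized predictors
    aggregated: pd.DataFrame  # department x (predictors + delta outcomes)
    predictors: tuple[str, ...]
    standardization: pd.DataFrame  # mu/sigma per predictor
    effi_window: tuple[int, int]
    delta_years: tuple[int, int]


def segment(
    indicator_panel: pd.DataFrame,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    effi_window: tuple[int, int] = (2019, 2021),
    delta_years: tuple[int, int] = (2020, 2021),
    pool: str = "pooled",
    max_missing_fraction: float = 0.5,
) -> SegmentedDatasets:
    """Build the longitudinal and aggregated datasets from the indicator panel.

    Predictors are standardized over the pool of all department-years
    (``pool="pooled"``) or within each year (``pool="by_year"``); the
    aggregated predictors are the per-department means of the standardized
    values over ``effi_window``.  Aborts with :class:`CoverageError` when the
    delta year-pair is unusable for more than ``max_missing_fraction`` of
    departments.
    """
    predictors = tuple(predictors)
    overlap = set(predictors) & set(FERTILITY_INDICATORS)
    if overlap:
        raise ConfigError(
            f"fertility indicators cannot be predictors: {sorted(overlap)}"
        )
    years = sorted(set(indicator_panel.index.get_level_values("year")))
    for y in (*effi_window, *delta_years):
        if y not in years:
            raise YearRangeError(f"year {y} outside panel years {years}")

    X = indicator_panel[list(predictors)]
    if pool == "pooled":
        scaler = ZScoreStandardizer().fit(X)
        longitudinal = scaler.transform(X)
        params = scaler.params_frame()
    elif pool == "by_year":
        parts, mus, sigmas = [], [], []
        for y in years:
            sub = X.xs(y, level="year", drop_level=False)
            sc = ZScoreStandardizer().fit(sub)
            parts.append(sc.transform(sub))
            mus.append(sc.mean_)
            sigmas.append(sc.scale_)
        longitudinal = pd.concat(parts).sort_index()
        params = pd.DataFrame(
            {"mu": np.mean(mus, axis=0), "sigma": np.mean(sigmas, axis=0)},
            index=list(predictors),
        )
    else:
        raise ValueError(f"unknown pool mode {pool!r}")

    lo, hi = effi_window
    in_window = longitudinal.index.get_level_values("year").to_series().between(lo, hi)
    window_rows = longitudinal[in_window.to_numpy()]
    aggregated = window_rows.groupby(level="department").mean()

    raw_deltas = pd.concat(
        [
            relative_change(indicator_panel, ind, *delta_years)
            for ind in FERTILITY_INDICATORS
        ],
        axis=1,
    )
    usable = raw_deltas["dEFR"].notna()
    if usable.mean() < 1.0 - max_missing_fraction:
        raise CoverageError(
            f"delta pair {delta_years} usable for only {int(usable.sum())} of "
            f"{len(usable)} departments"
        )
    deltas = raw_deltas.copy()
    for ind in FERTILITY_INDICATORS:
        z, _, _ = zscore(raw_deltas[f"d{ind}"].to_numpy())
        deltas[f"Z_d{ind}"] = z
    aggregated = aggregated.join(deltas)
    return SegmentedDatasets(
        longitudinal=longitudinal,
        aggregated=aggregated,
        predictors=predictors,
        standardization=params,
        effi_window=effi_window,
        delta_years=delta_years,
    )
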