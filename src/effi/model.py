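"""Composite-index aggregation and GLM-based predictor refinement.

The fragility index for department *d* is a weighted sum of its
period-averaged standardized risk indicators,

    FFI_d = sum_i w_i * Z_{i,d},

with equal weights w_i = 1/k over the k retained indicators by default.
The retained set comes from a Gaussian/identity GLM with backward
elimination: predictors whose two-sided t-test p-value exceeds ``alpha``
are dropped one at a time (largest p first) until every remaining p-value
is at or below ``alpha``.  Goodness of fit is reported as
pseudo-R^2 = 1 - residual deviance / null deviance.

Two outcome conventions are offered by :func:`build_effi`:

* ``delta_outcome`` (recommended) — regress the standardized relative change
  in the early fertility rate (Z_dEFR by default) on the candidate
  indicators, prune, then aggregate the retained set;
* ``circular_composite`` — regress the equal-weight composite of the candidate
  indicators on those same indicators, prune, and re-aggregate.  The first
  stage is circular by construction (the outcome is an exact linear
  combination of the predictors, so pseudo-R^2 = 1); it is provided to
  reproduce that published convention and is flagged in the logs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    ConfigError,
    ConstantPredictorWarning,
    EmptyModelWarning,
    ExclusionWarning,
    InsufficientDataError,
    RankDeficiencyError,
)
from .standardize import DEFAULT_PREDICTORS, SegmentedDatasets

log = logging.getLogger(__name__)

FAMILIES = {
    "gaussian": sm.families.Gaussian,
    "poisson": sm.families.Poisson,
    "gamma": sm.families.Gamma,
    "binomial": sm.families.Binomial,
}


@dataclass
class GLMFit:
    """One fitted GLM: coefficient table, deviances and pseudo-R^2."""

    outcome: str
    family: str
    n: int
    df_resid: float
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    null_deviance: float
    deviance: float
    pseudo_r2: float

    @property
    def predictors(self) -> list[str]:
        return [t for t in self.params.index if t != "const"]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "std_err": self.bse,
                "t": self.tvalues,
                "p_value": self.pvalues,
            }
        )


def _check_design(X: pd.DataFrame) -> pd.DataFrame:
    """Drop constant columns (with warning); raise on a singular design."""
    if X.shape[1] == 0:
        return X
    const = X.std(axis=0, ddof=0) == 0
    if const.any():
        warnings.warn(
            f"dropping constant predictor column(s): {list(X.columns[const])}",
            ConstantPredictorWarning,
            stacklevel=3,
        )
        X = X.loc[:, ~const]
    if X.shape[1] == 0:
        return X
    design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        involved = []
        for j, col in enumerate(X.columns):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                involved.append(col)
        raise RankDeficiencyError(involved or list(X.columns))
    return X


def fit_glm(
    y,
    X: pd.DataFrame | None = None,
    family: str = "gaussian",
    outcome: str = "y",
) -> GLMFit:
    """Fit a GLM of ``y`` on ``X`` with an intercept.

    The default Gaussian/identity family reports two-sided t-test p-values
    with residual degrees of freedom (equivalent to OLS inference); other
    families use the usual large-sample z tests.  Rows with any missing
    value are dropped; constant predictor columns are dropped with a
    warning; a singular design raises :class:`RankDeficiencyError`.
    """
    if family not in FAMILIES:
        raise ConfigError(f"unknown GLM family {family!r}; known: {sorted(FAMILIES)}")
    y = pd.Series(y).astype(float)
    if X is None:
        X = pd.DataFrame(index=y.index)
    X = pd.DataFrame(X).astype(float)
    keep_rows = y.notna() & X.notna().all(axis=1)
    if not keep_rows.all():
        warnings.warn(
            f"dropping {int((~keep_rows).sum())} row(s) with missing values",
            ExclusionWarning,
            stacklevel=2,
        )
    y, X = y[keep_rows], X.loc[keep_rows]
    X = _check_design(X)
    n, p = len(y), X.shape[1]
    if n <= p + 1:
        raise InsufficientDataError(
            f"n = {n} observations cannot support {p} predictors plus intercept"
        )
    design = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, design, family=FAMILIES[family]())
    res = model.fit(use_t=(family == "gaussian"))
    null_dev = float(res.null_deviance)
    dev = float(res.deviance)
    pseudo = 1.0 - dev / null_dev if null_dev > 0 else np.nan
    return GLMFit(
        outcome=outcome,
        family=family,
        n=n,
        df_resid=float(res.df_resid),
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        null_deviance=null_dev,
        deviance=dev,
        pseudo_r2=pseudo,
    )


@dataclass
class PruneResult:
    retained: list[str]
    fit: GLMFit
    audit: pd.DataFrame  # one row per elimination step


def prune_predictors(
    y,
    X: pd.DataFrame,
    alpha: float = 0.05,
    keep: Sequence[str] = (),
    family: str = "gaussian",
    outcome: str = "y",
) -> PruneResult:
    """Backward elimination: repeatedly drop the worst predictor above ``alpha``.

    At each step the predictor with the largest p-value exceeding ``alpha``
    (and not in ``keep``) is removed and the model refit; the loop stops when
    every remaining droppable predictor satisfies p <= alpha.  The audit
    trail records each drop with its p-value and the deviance / pseudo-R^2
    before and after.  If every predictor is eliminated an intercept-only
    fit is returned with :class:`EmptyModelWarning`.
    """
    current = list(X.columns)
    keep = set(keep)
    unknown = keep - set(current)
    if unknown:
        raise ConfigError(f"keep-list names absent from predictors: {sorted(unknown)}")
    rows = []
    fit = fit_glm(y, X[current], family=family, outcome=outcome)
    step = 0
    while True:
        droppable = {
            c: fit.pvalues[c]
            for c in fit.predictors
            if c not in keep and fit.pvalues[c] > alpha
        }
        if not droppable:
            break
        worst = max(droppable, key=droppable.get)
        current = [c for c in current if c != worst]
        new_fit = fit_glm(
            y, X[current] if current else None, family=family, outcome=outcome
        )
        step += 1
        rows.append(
            {
                "step": step,
                "dropped": worst,
                "p_value": droppable[worst],
                "deviance_before": fit.deviance,
                "deviance_after": new_fit.deviance,
                "pseudo_r2_before": fit.pseudo_r2,
                "pseudo_r2_after": new_fit.pseudo_r2,
            }
        )
        fit = new_fit
        if not current:
            warnings.warn(
                "all predictors eliminated; returning intercept-only fit",
                EmptyModelWarning,
                stacklevel=2,
            )
            break
    audit = pd.DataFrame(
        rows,
        columns=[
            "step",
            "dropped",
            "p_value",
            "deviance_before",
            "deviance_after",
            "pseudo_r2_before",
            "pseudo_r2_after",
        ],
    )
    return PruneResult(retained=list(fit.predictors), fit=fit, audit=audit)


class BackwardEliminationGLM(BaseEstimator, RegressorMixin):
    """sklearn-style wrapper around :func:`prune_predictors`.

    Parameters
    ----------
    alpha : float
        Significance threshold for retaining a predictor.
    keep : sequence of str
        Predictors never dropped regardless of p-value.
    family : str
        GLM family name (default ``"gaussian"``).

    Attributes (after ``fit``)
    --------------------------
    retained_ : list of predictors surviving elimination
    coef_, intercept_, pvalues_ : final-model estimates
    fit_ : the final :class:`GLMFit`
    audit_ : elimination audit trail
    """

    def __init__(self, alpha: float = 0.05, keep: Sequence[str] = (), family: str = "gaussian"):
        self.alpha = alpha
        self.keep = keep
        self.family = family

    def fit(self, X, y):
        X = pd.DataFrame(X)
        result = prune_predictors(
            y, X, alpha=self.alpha, keep=self.keep, family=self.family
        )
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.retained_ = result.retained
        self.fit_ = result.fit
        self.audit_ = result.audit
        self.intercept_ = float(result.fit.params.get("const", 0.0))
        self.coef_ = result.fit.params.drop("const", errors="ignore").to_numpy()
        self.pvalues_ = result.fit.pvalues.drop("const", errors="ignore")
        return self

    def predict(self, X):
        X = pd.DataFrame(X)
        return self.intercept_ + X[self.retained_].to_numpy() @ self.coef_


@dataclass
class IndexWeights:
    """Weights over the retained indicators; ``mode`` records their origin."""

    weights: dict[str, float]
    mode: str = "equal"

    @classmethod
    def equal(cls, indicators: Sequence[str]) -> "IndexWeights":
        k = len(indicators)
        return cls(weights={i: 1.0 / k for i in indicators}, mode="equal")

    @classmethod
    def from_glm(cls, fit: GLMFit) -> "IndexWeights":
        return cls(
            weights={c: float(fit.params[c]) for c in fit.predictors},
            mode="glm_coefficients",
        )


@dataclass
class EFFIScores:
    """Per-department composite index with the weights and window used."""

    scores: pd.Series
    weights: IndexWeights
    window: tuple[int, int] | None = None

    def ranking(self) -> pd.DataFrame:
        out = self.scores.sort_values(ascending=False).to_frame("EFFI")
        out["rank"] = np.arange(1, len(out) + 1)
        return out


def aggregate_index(
    aggregated: pd.DataFrame,
    weights: IndexWeights | Mapping[str, float] | Sequence[str],
    window: tuple[int, int] | None = None,
) -> EFFIScores:
    """FFI_d = sum_i w_i Z_{i,d} over the retained indicators.

    ``weights`` may be an :class:`IndexWeights`, a plain mapping, or a list of
    indicator names (interpreted as equal weights).  Departments missing any
    retained indicator are excluded with a warning.
    """
    if isinstance(weights, IndexWeights):
        w = weights
    elif isinstance(weights, Mapping):
        w = IndexWeights(weights=dict(weights), mode="custom")
    else:
        w = IndexWeights.equal(list(weights))
    if not w.weights:
        raise ConfigError("no indicators to aggregate")
    absent = [c for c in w.weights if c not in aggregated.columns]
    if absent:
        raise ConfigError(f"weights name indicators absent from data: {absent}")
    if not all(np.isfinite(list(w.weights.values()))):
        raise ConfigError("weights must be finite")
    cols = list(w.weights)
    Z = aggregated[cols]
    complete = Z.notna().all(axis=1)
    if not complete.all():
        warnings.warn(
            f"excluding departments with missing indicators: "
            f"{sorted(Z.index[~complete])}",
            ExclusionWarning,
            stacklevel=2,
        )
    scores = (Z[complete] * pd.Series(w.weights)).sum(axis=1).rename("EFFI")
    return EFFIScores(scores=scores, weights=w, window=window)


@dataclass
class EFFIResult:
    """Everything :func:`build_effi` produces for one run."""

    scores: EFFIScores
    glm: GLMFit
    weights: IndexWeights
    retained: list[str]
    audit: pd.DataFrame
    first_stage: GLMFit | None = None
    mode: str = "delta_outcome"


def build_effi(
    segmented: SegmentedDatasets,
    mode: str = "delta_outcome",
    outcome: str = "Z_dEFR",
    alpha: float = 0.05,
    keep: Sequence[str] = (),
    weight_mode: str = "equal",
    family: str = "gaussian",
) -> EFFIResult:
    """Refine the predictor set and aggregate the fragility index.

    ``delta_outcome`` prunes against the standardized fertility-change
    outcome; ``circular_composite`` prunes against the equal-weight composite of
    the candidate indicators themselves (circular first stage, logged).
    """
    agg = segmented.aggregated
    X = agg[list(segmented.predictors)]
    first_stage = None
    if mode == "delta_outcome":
        y = agg[outcome]
    elif mode == "circular_composite":
        log.warning(
            "circular_composite mode regresses the equal-weight composite on its own "
            "components; the first-stage fit is circular (pseudo-R^2 = 1) and "
            "should not be read as predictive performance"
        )
        y = X.mean(axis=1).rename("composite")
        first_stage = fit_glm(y, X, family=family, outcome="composite")
        outcome = "composite"
    else:
        raise ConfigError(f"unknown mode {mode!r}")

    pruned = prune_predictors(
        y, X, alpha=alpha, keep=keep, family=family, outcome=outcome
    )
    retained = pruned.retained
    if not retained:
        warnings.warn(
            "no predictors retained; index scores set to 0 for all departments",
            EmptyModelWarning,
            stacklevel=2,
        )
        scores = EFFIScores(
            scores=pd.Series(0.0, index=agg.index, name="EFFI"),
            weights=IndexWeights(weights={}, mode=weight_mode),
            window=segmented.effi_window,
        )
        return EFFIResult(
            scores=scores,
            glm=pruned.fit,
            weights=scores.weights,
            retained=[],
            audit=pruned.audit,
            first_stage=first_stage,
            mode=mode,
        )

    if weight_mode == "equal":
        weights = IndexWeights.equal(retained)
    elif weight_mode == "glm_coefficients":
        weights = IndexWeights.from_glm(pruned.fit)
    else:
        raise ConfigError(f"unknown weight mode {weight_mode!r}")
    scores = aggregate_index(agg, weights, window=segmented.effi_window)
    return EFFIResult(
        scores=scores,
        glm=pruned.fit,
        weights=weights,
        retained=retained,
        audit=pruned.audit,
        first_stage=first_stage,
        mode=mode,
    )
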