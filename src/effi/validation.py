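"""Rank-correlation validation of the fragility index.

The construct-validity check is Spearman's rank correlation between the
composite index and the standardized relative changes in the fertility rates.
A positive rho supports the index (more fragile departments saw larger
post-pandemic fertility increases); |rho| below a small threshold means no
detectable link; a clearly negative rho contradicts the framework.

rho is computed as the Pearson correlation of average (tie-adjusted) ranks.
Two-sided p-values use the exact permutation distribution of rho when the
paired sample is small (n < 10) and the t approximation with n - 2 degrees
of freedom otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedCorrelationError

SUPPORTS, NO_LINK, CONTRADICTS = (
    "supports_validity",
    "no_link",
    "contradicts_framework",
)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact_permutation" | "t_approximation"


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    rho: float
    p_value: float
    n: int
    interpretation: str


@lru_cache(maxsize=None)
def _permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        raise UndefinedCorrelationError("zero rank variance in one of the vectors")
    return float((rxc * ryc).sum() / denom)


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided p over all n! permutations of one rank vector."""
    n = len(rx)
    perms = _permutations(n)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    rhos = (ryc[perms] @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(x, y, exact_threshold: int = 10) -> SpearmanResult:
    """Spearman rank correlation with pairwise deletion of missing entries.

    Ties receive average (fractional) ranks.  ``exact_threshold`` is the
    sample size below which the exact permutation p-value is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = _rank_corr(rx, ry)
    if n < exact_threshold:
        return SpearmanResult(rho, _exact_p(rx, ry, rho), n, "exact_permutation")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, p, n, "t_approximation")


def interpret(rho: float, threshold: float = 0.1) -> str:
    if abs(rho) < threshold:
        return NO_LINK
    return SUPPORTS if rho > 0 else CONTRADICTS


def validate_index(
    effi_scores: pd.Series,
    deltas: pd.DataFrame,
    threshold: float = 0.1,
    outcomes: tuple[str, ...] = ("Z_dIFR", "Z_dAFR", "Z_dEFR"),
) -> list[CorrelationResult]:
    """Correlate the index with each standardized fertility-change outcome."""
    results = []
    for col in outcomes:
        joined = pd.concat([effi_scores.rename("EFFI"), deltas[col]], axis=1).dropna()
        r = spearman(joined["EFFI"], joined[col])
        results.append(
            CorrelationResult(
                pair=f"EFFI~{col}",
                rho=r.rho,
                p_value=r.p_value,
                n=r.n,
                interpretation=interpret(r.rho, threshold),
            )
        )
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": r.pair,
                "rho": r.rho,
                "p_value": r.p_value,
                "n": r.n,
                "interpretation": r.interpretation,
            }
            for r in results
        ]
    )


def scatter_data(
    effi_scores: pd.Series,
    deltas: pd.DataFrame,
    outcomes: tuple[str, ...] = ("Z_dIFR", "Z_dAFR", "Z_dEFR"),
) -> pd.DataFrame:
    """Per-department points and ranks behind the validation scatter matrix."""
    out = pd.concat([effi_scores.rename("EFFI"), deltas[list(outcomes)]], axis=1)
    for col in ("EFFI", *outcomes):
        vals = out[col]
        ranks = pd.Series(
            stats.rankdata(vals.dropna(), method="average"),
            index=vals.dropna().index,
        )
        out[f"rank_{col}"] = ranks
    return out
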