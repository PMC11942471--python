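"""GLM fitting, backward elimination and index aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from effi.errors import (
    ConfigError,
    ConstantPredictorWarning,
    EmptyModelWarning,
    ExclusionWarning,
    InsufficientDataError,
    RankDeficiencyError,
)
from effi.model import (
    BackwardEliminationGLM,
    IndexWeights,
    aggregate_index,
    build_effi,
    fit_glm,
    prune_predictors,
)
from effi.standardize import segment


def _design(n=33, k=3, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((n, k)), columns=[f"x{i}" for i in range(k)]
    )


# --- aggregation -----------------------------------------------------------

def _agg(values, cols):
    return pd.DataFrame([values], columns=cols, index=pd.Index(["D01"], name="department"))


@pytest.mark.parametrize(
    "z, weights, expected",
    [
        ((1.0, 1.0, 1.0), None, 1.0),  # equal weights
        ((2.0, -2.0), None, 0.0),  # symmetry
        ((0.5, -1.0, 2.0), (0.2, 0.3, 0.5), 0.8),  # hand dot product
    ],
)
def test_aggregate_index_examples(z, weights, expected):
    cols = [f"x{i}" for i in range(len(z))]
    w = cols if weights is None else dict(zip(cols, weights))
    scores = aggregate_index(_agg(z, cols), w)
    assert scores.scores.iloc[0] == pytest.approx(expected)


def test_aggregate_index_rejects_bad_weights():
    Z = _agg((1.0, 2.0), ["a", "b"])
    with pytest.raises(ConfigError, match="absent"):
        aggregate_index(Z, {"a": 0.5, "zzz": 0.5})
    with pytest.raises(ConfigError, match="finite"):
        aggregate_index(Z, {"a": np.inf, "b": 0.5})


def test_aggregate_index_excludes_incomplete_departments():
    Z = pd.DataFrame(
        {"a": [1.0, np.nan], "b": [0.0, 1.0]},
        index=pd.Index(["D01", "D02"], name="department"),
    )
    with pytest.warns(ExclusionWarning, match="D02"):
        scores = aggregate_index(Z, ["a", "b"])
    assert list(scores.scores.index) == ["D01"]


@given(
    st.lists(st.floats(-10, 10), min_size=3, max_size=3),
    st.lists(st.floats(-10, 10), min_size=3, max_size=3),
    st.floats(-5, 5),
    st.floats(-5, 5),
)
@settings(max_examples=50, deadline=None)
def test_aggregate_index_linearity(z1, z2, a, b):
    cols = ["x0", "x1", "x2"]
    w = {"x0": 0.2, "x1": 0.3, "x2": 0.5}
    s1 = aggregate_index(_agg(z1, cols), w).scores.iloc[0]
    s2 = aggregate_index(_agg(z2, cols), w).scores.iloc[0]
    combo = [a * u + b * v for u, v in zip(z1, z2)]
    s = aggregate_index(_agg(combo, cols), w).scores.iloc[0]
    assert s == pytest.approx(a * s1 + b * s2, rel=1e-9, abs=1e-9)


# --- GLM fitting -----------------------------------------------------------

def test_fit_glm_exact_relationship():
    X = _design(n=33, k=3, seed=1)
    y = X["x0"]  # outcome equals one predictor exactly
    fit = fit_glm(y, X)
    assert fit.params["x0"] == pytest.approx(1.0, abs=1e-10)
    assert fit.pseudo_r2 == pytest.approx(1.0, abs=1e-10)


def test_fit_glm_matches_closed_form():
    rng = np.random.default_rng(5)
    X = _design(n=25, k=4, seed=5)
    y = X @ np.array([1.0, -2.0, 0.0, 0.5]) + rng.standard_normal(25)
    fit = fit_glm(y, X)
    D = np.column_stack([np.ones(25), X])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-10)
    resid = y - D @ beta
    assert fit.deviance == pytest.approx(float(resid @ resid), abs=1e-8)


def test_fit_glm_drops_constant_column():
    X = _design(n=20, k=2, seed=2)
    X["c"] = 3.0
    with pytest.warns(ConstantPredictorWarning, match="c"):
        fit = fit_glm(X["x0"] + 0.1 * X["x1"], X)
    assert "c" not in fit.params.index


def test_fit_glm_singular_design_raises():
    X = _design(n=20, k=2, seed=3)
    X["dup"] = X["x0"] * 2.0
    with pytest.raises(RankDeficiencyError) as err:
        fit_glm(X["x1"], X)
    assert {"x0", "dup"} <= set(err.value.columns)


def test_fit_glm_needs_enough_rows():
    X = _design(n=4, k=3, seed=4)
    with pytest.raises(InsufficientDataError):
        fit_glm(X["x0"], X)


def test_fit_glm_unknown_family():
    X = _design()
    with pytest.raises(ConfigError):
        fit_glm(X["x0"], X, family="tweedie")


# --- pruning ---------------------------------------------------------------

def test_prune_alpha_one_is_identity():
    X = _design(n=30, k=4, seed=6)
    y = np.random.default_rng(6).standard_normal(30)
    result = prune_predictors(y, X, alpha=1.0)
    assert result.retained == list(X.columns)
    assert result.audit.empty


def test_prune_recovers_true_effects():
    """Strong/strong/null design: the null predictor is dropped."""
    rng = np.random.default_rng(7)
    X = _design(n=200, k=3, seed=7)
    y = 5.0 * X["x0"] - 5.0 * X["x1"] + rng.standard_normal(200)
    result = prune_predictors(y, X, alpha=0.05)
    assert result.retained == ["x0", "x1"]
    assert result.audit["dropped"].tolist() == ["x2"]


def test_prune_keep_list_retains_nonsignificant():
    rng = np.random.default_rng(8)
    X = _design(n=40, k=3, seed=8)
    y = 3.0 * X["x0"] + rng.standard_normal(40)
    free = prune_predictors(y, X, alpha=0.05)
    kept = prune_predictors(y, X, alpha=0.05, keep=["x2"])
    assert "x2" not in free.retained
    assert "x2" in kept.retained
    assert kept.fit.pvalues["x2"] > 0.05


def test_prune_keep_unknown_name_errors():
    X = _design()
    with pytest.raises(ConfigError):
        prune_predictors(X["x0"], X, keep=["nope"])


def test_prune_all_eliminated_warns_intercept_only():
    rng = np.random.default_rng(9)
    X = _design(n=30, k=2, seed=9)
    y = rng.standard_normal(30)
    with pytest.warns(EmptyModelWarning):
        result = prune_predictors(y, X, alpha=1e-6)
    assert result.retained == []
    assert result.fit.pseudo_r2 == pytest.approx(0.0, abs=1e-12)


def test_prune_deviance_monotone_along_path():
    rng = np.random.default_rng(10)
    X = _design(n=30, k=6, seed=10)
    y = rng.standard_normal(30)
    import warnings as w

    with w.catch_warnings():
        w.simplefilter("ignore")
        result = prune_predictors(y, X, alpha=0.5)
    audit = result.audit
    assert (audit["deviance_after"] >= audit["deviance_before"] - 1e-10).all()


def test_backward_elimination_estimator():
    rng = np.random.default_rng(11)
    X = _design(n=120, k=3, seed=11)
    y = 2.0 * X["x0"] + rng.standard_normal(120)
    est = BackwardEliminationGLM(alpha=0.05)
    assert clone(est).get_params() == est.get_params()
    est.fit(X, y)
    assert est.retained_ == ["x0"]
    pred = est.predict(X)
    assert np.corrcoef(pred, y)[0, 1] > 0.8


# --- build_effi ------------------------------------------------------------

def test_circular_composite_first_stage_saturated(indicator_panel):
    seg = segment(indicator_panel)
    result = build_effi(seg, mode="circular_composite")
    assert result.first_stage is not None
    assert result.first_stage.pseudo_r2 == pytest.approx(1.0, abs=1e-12)


def test_build_effi_equal_weights_sum_to_one(indicator_panel):
    seg = segment(indicator_panel)
    result = build_effi(seg)
    if result.retained:
        assert sum(result.weights.weights.values()) == pytest.approx(1.0)
        k = len(result.retained)
        assert all(w == pytest.approx(1.0 / k) for w in result.weights.weights.values())


def test_build_effi_glm_coefficient_weights(indicator_panel):
    seg = segment(indicator_panel)
    result = build_effi(seg, weight_mode="glm_coefficients")
    for name, w in result.weights.weights.items():
        assert w == pytest.approx(float(result.glm.params[name]))


def test_build_effi_unknown_mode(indicator_panel):
    seg = segment(indicator_panel)
    with pytest.raises(ConfigError):
        build_effi(seg, mode="bayes")


def test_index_weights_equal_mode():
    w = IndexWeights.equal(["a", "b", "c", "d"])
    assert w.mode == "equal"
    assert all(v == pytest.approx(0.25) for v in w.weights.values())
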