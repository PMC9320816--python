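import numpy as np
import pandas as pd
import pytest

from rollgait.errors import DegenerateStatisticError
from rollgait.models import (
    VifGatedRegressor,
    cohens_d,
    cohens_d_from_summary,
    fit_model,
    mae,
    paired_t,
    vif,
)


def _toy_table(X, y=None, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    if y is not None:
        df["y"] = y
    return df, names


def test_vif_orthogonal_features_all_one(rng):
    X = rng.normal(size=(200, 4))
    Q, _ = np.linalg.qr(X - X.mean(axis=0))
    report = vif(Q)
    assert np.allclose(report.vif_values, 1.0, atol=1e-10)
    assert not report.multicollinear


def test_vif_duplicate_column_is_infinite():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    X = np.column_stack([x, x, rng.normal(size=50)])
    report = vif(X)
    assert np.isinf(report.vif_values[0]) and np.isinf(report.vif_values[1])
    assert report.multicollinear
    assert set(report.flagged) >= {"x0", "x1"}


def test_vif_matches_brute_force_r_squared(rng):
    # two columns with correlation ~0.9 plus an independent one
    n = 300
    z = rng.normal(size=n)
    x1 = z + 0.48 * rng.normal(size=n)
    x2 = z + 0.48 * rng.normal(size=n)
    x3 = rng.normal(size=n)
    X = np.column_stack([x1, x2, x3])
    report = vif(X)
    for j in range(3):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        r2 = 1 - resid @ resid / np.sum((X[:, j] - X[:, j].mean()) ** 2)
        assert report.vif_values[j] == pytest.approx(1.0 / (1.0 - r2), rel=1e-9)


def test_vif_cross_checked_against_statsmodels(rng):
    statsmodels = pytest.importorskip("statsmodels.stats.outliers_influence")
    n = 120
    z = rng.normal(size=n)
    X = np.column_stack([z + 0.5 * rng.normal(size=n), z + 0.5 * rng.normal(size=n), rng.normal(size=n)])
    Xc = X - X.mean(axis=0)
    report = vif(Xc)
    design = np.column_stack([np.ones(n), Xc])
    for j in range(3):
        sm_vif = statsmodels.variance_inflation_factor(design, j + 1)
        assert report.vif_values[j] == pytest.approx(sm_vif, rel=1e-8)


def test_orthogonal_features_fit_linear_with_univariate_slopes(rng):
    n = 100
    X = rng.normal(size=(n, 3))
    Q, _ = np.linalg.qr(X - X.mean(axis=0))
    y = Q @ np.array([1.0, -2.0, 0.5]) + 0.3
    table, names = _toy_table(Q, y)
    model = fit_model(table, "y", names)
    assert model.model_type_ == "linear"
    for j, name in enumerate(names):
        slope = (Q[:, j] @ (y - y.mean())) / (Q[:, j] @ Q[:, j])
        assert model.coef_[j] == pytest.approx(slope, abs=1e-10)


def test_duplicate_feature_takes_ridge_path(rng):
    x = rng.normal(size=60)
    X = np.column_stack([x, x + 1e-9 * rng.normal(size=60), rng.normal(size=60)])
    y = x + rng.normal(size=60)
    table, names = _toy_table(X, y)
    model = fit_model(table, "y", names)
    assert model.model_type_ == "ridge"
    assert model.ridge_lambda_ > 0
    assert model.vif_report_.multicollinear


def test_extreme_ridge_penalty_shrinks_to_outcome_mean(rng):
    x = rng.normal(size=50)
    X = np.column_stack([x, x])  # force the ridge path
    y = 2.0 * x + 5.0
    table, names = _toy_table(X, y)
    model = fit_model(table, "y", names, ridge_grid=[1e12])
    assert np.allclose(model.coef_, 0.0, atol=1e-6)
    assert model.intercept_ == pytest.approx(y.mean(), rel=1e-6)
    pred = model.predict(table[names])
    assert np.allclose(pred, y.mean(), atol=1e-4)


def test_mae_basic_cases():
    assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert mae(np.array([1.05, 2.05]), np.array([1.0, 2.0])) == pytest.approx(0.05)
    assert mae([0.1, 0.2, 0.3], [0.2, 0.2, 0.2]) == pytest.approx(0.2 / 3, abs=1e-12)
    with pytest.raises(ValueError):
        mae([1.0], [1.0, 2.0])


def test_cohens_d_reproduces_reported_effect_sizes():
    assert cohens_d_from_summary(0.3585, 0.3593, 0.1513) == pytest.approx(0.0053, abs=5e-5)
    assert cohens_d_from_summary(0.0215, 0.0216, 0.0090) == pytest.approx(0.0111, abs=5e-5)


def test_cohens_d_identical_series_is_zero(rng):
    x = rng.normal(size=20)
    assert cohens_d(x, x) == 0.0


def test_cohens_d_undefined_for_constant_actual():
    with pytest.raises(DegenerateStatisticError):
        cohens_d([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])


def test_cohens_d_signed_option(rng):
    actual = np.array([1.0, 2.0, 3.0])
    predicted = actual + 1.0
    assert cohens_d(actual, predicted, signed=True) == pytest.approx(-1.0)
    assert cohens_d(actual, predicted) == pytest.approx(1.0)


def test_paired_t_zero_mean_symmetric_differences():
    actual = np.array([1.0, 0.0, 1.0, 0.0])
    predicted = np.array([0.0, 1.0, 0.0, 1.0])
    t, p = paired_t(actual, predicted)
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_paired_t_matches_hand_arithmetic():
    actual = np.array([1.2, 0.8, 1.5, 1.1, 0.9])
    predicted = np.array([1.0, 1.0, 1.2, 1.0, 1.0])
    diff = actual - predicted
    t_expected = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
    t, p = paired_t(actual, predicted)
    assert t == pytest.approx(t_expected, rel=1e-12)
    assert 0.0 < p < 1.0


def test_paired_t_degenerate_on_identical_series(rng):
    x = rng.normal(size=10)
    with pytest.raises(DegenerateStatisticError):
        paired_t(x, x)


def test_vif_gated_regressor_is_sklearn_compatible(rng):
    from sklearn.base import clone

    model = VifGatedRegressor(ridge_grid=[0.1, 1.0])
    params = model.get_params()
    assert params["ridge_grid"] == [0.1, 1.0]
    clone(model)  # get_params/set_params round trip
    X = rng.normal(size=(30, 3))
    y = X @ np.array([1.0, 0.5, -0.2])
    model.fit(X, y)
    assert model.coef_.shape == (3,)
    assert np.allclose(model.predict(X), y, atol=1e-8)
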