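import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rollgait.registry import FEATURE_NAMES
from rollgait.selection import (
    ElasticNetSelector,
    FTestSelector,
    LassoSelector,
    RReliefFSelector,
    f_test_rank,
    lasso_rank,
    relieff_rank,
    selection_frequency,
)


def _orthonormal_design(rng, n=24, p=4):
    """Zero-mean columns with X'X = I."""
    X = rng.normal(size=(n, p))
    X = X - X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    Q = Q - Q.mean(axis=0)
    Q, _ = np.linalg.qr(Q)  # re-orthonormalize after centering
    return Q


def _random_table(rng, n=40, y=None):
    X = rng.normal(size=(n, 60))
    X = X - X.mean(axis=0)
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df["peak_com_excursion"] = rng.normal(size=n) if y is None else y
    df["subject"] = [f"S{i}" for i in range(n)]
    df["condition"] = 0.0
    return df


def test_lasso_matches_soft_threshold_on_orthonormal_design(rng):
    X = _orthonormal_design(rng)
    b = np.array([2.0, -1.0, 0.4, 0.0])
    y = X @ b
    y = y - y.mean()
    lam = 0.6
    sel = LassoSelector(lam=lam, standardize=False).fit(X, y)
    ols = X.T @ y  # since X'X = I
    expected = np.sign(ols) * np.maximum(np.abs(ols) - lam / 2.0, 0.0)
    assert np.allclose(sel.coef_, expected, atol=1e-6)


def test_lasso_at_zero_penalty_equals_least_squares(rng):
    X = rng.normal(size=(30, 6))
    y = rng.normal(size=30)
    sel = LassoSelector(lam=0.0, standardize=False).fit(X, y)
    A = np.column_stack([np.ones(30), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    assert np.allclose(sel.coef_, beta[1:], atol=1e-6)
    assert sel.intercept_ == pytest.approx(beta[0], abs=1e-6)


def test_lasso_full_shrinkage_above_lambda_max(rng):
    X = rng.normal(size=(30, 5))
    X = X - X.mean(axis=0)
    y = rng.normal(size=30)
    y = y - y.mean()
    lam_max = 2.0 * np.max(np.abs(X.T @ y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = LassoSelector(lam=lam_max * 1.01, standardize=False).fit(X, y)
    assert np.allclose(sel.coef_, 0.0)
    assert len(sel.ranking_) == 0


def test_lasso_objective_no_worse_than_zero_vector(rng):
    X = rng.normal(size=(40, 8))
    y = rng.normal(size=40)
    lam = 5.0
    sel = LassoSelector(lam=lam, standardize=False).fit(X, y)
    resid = y - X @ sel.coef_ - sel.intercept_
    obj = resid @ resid + lam * np.abs(sel.coef_).sum()
    obj_zero = np.sum((y - y.mean()) ** 2)  # best zero-coefficient model
    assert obj <= obj_zero + 1e-9


def test_elastic_net_alpha_one_reduces_to_lasso(rng):
    X = rng.normal(size=(30, 6))
    y = X[:, 0] * 1.5 - X[:, 3] + rng.normal(size=30)
    lam = 2.0
    lasso = LassoSelector(lam=lam, standardize=False).fit(X, y)
    enet = ElasticNetSelector(alpha=1.0, lam=lam, standardize=False).fit(X, y)
    assert np.allclose(lasso.coef_, enet.coef_, atol=1e-8)
    assert np.array_equal(lasso.ranking_, enet.ranking_)


def test_ridge_limit_keeps_all_coefficients_nonzero(rng):
    X = rng.normal(size=(40, 6))
    y = X @ rng.normal(size=6) + rng.normal(size=40)
    sel = ElasticNetSelector(alpha=0.0, lam=3.0, standardize=False).fit(X, y)
    assert np.all(np.abs(sel.coef_) > 0)
    assert len(sel.ranking_) == 6


def test_elastic_net_matches_brute_force_grid(rng):
    """Objective at the solver's solution beats a dense coefficient grid."""
    X = rng.normal(size=(25, 3))
    X = X - X.mean(axis=0)
    true = np.array([1.0, -0.5, 0.0])
    y = X @ true + 0.1 * rng.normal(size=25)
    y = y - y.mean()
    lam, alpha = 4.0, 0.5

    def objective(beta):
        r = y - X @ beta
        return r @ r + lam * (alpha * np.abs(beta).sum() + (1 - alpha) * (beta @ beta) / 2.0)

    sel = ElasticNetSelector(alpha=alpha, lam=lam, standardize=False).fit(X, y)
    grid = np.linspace(-1.5, 1.5, 41)
    best = min(
        objective(np.array([b0, b1, b2])) for b0 in grid for b1 in grid for b2 in grid
    )
    assert objective(sel.coef_) <= best + 1e-4


def test_f_test_perfect_feature_ranks_first(rng):
    y = rng.normal(size=40)
    table = _random_table(rng, 40, y=y)
    table["aM"] = y  # exact copy of the outcome
    res = f_test_rank(table, "peak_com_excursion")
    assert res.ranked_features[0] == "aM"
    assert res.scores["aM"] < 1e-20  # p-value numerically zero


def test_f_test_orthogonal_feature_has_near_zero_f():
    x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0] * 4)
    y = np.array([1.0, -1.0, 0.0, -1.0, 1.0] * 4)  # uncorrelated with x
    sel = FTestSelector().fit(x.reshape(-1, 1), y)
    assert sel.f_statistic_[0] == pytest.approx(0.0, abs=1e-12)


def test_f_test_matches_hand_computed_anova():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.1, 2.9, 4.2, 4.8, 6.1])
    n = 5
    r = np.corrcoef(x, y)[0, 1]
    f_expected = r**2 * (n - 2) / (1 - r**2)
    p_expected = stats.f.sf(f_expected, 1, n - 2)
    sel = FTestSelector().fit(x.reshape(-1, 1), y)
    assert sel.f_statistic_[0] == pytest.approx(f_expected, rel=1e-10)
    assert sel.pvalues_[0] == pytest.approx(p_expected, rel=1e-10)


def test_f_test_constant_feature_ranks_last(rng):
    X = rng.normal(size=(20, 3))
    X[:, 1] = 7.0
    y = X[:, 0] + rng.normal(size=20)
    sel = FTestSelector().fit(X, y)
    assert sel.pvalues_[1] == 1.0
    assert sel.ranking_[-1] == 1


def _naive_rrelieff(X, y, k, sigma):
    """Independent loop-based RReliefF for oracle comparison."""
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xn = (X - X.min(axis=0)) / span
    yn = (y - y.min()) / (y.max() - y.min())
    w = np.array([np.exp(-((r / sigma) ** 2)) for r in range(1, k + 1)])
    w = w / w.sum()
    n_dy, n_df, n_dydf = 0.0, np.zeros(p), np.zeros(p)
    for i in range(n):
        d = [(sum(abs(Xn[i] - Xn[j])), j) for j in range(n) if j != i]
        d.sort(key=lambda t: t[0])
        for rank, (_, j) in enumerate(d[:k]):
            dy = abs(yn[i] - yn[j])
            n_dy += w[rank] * dy
            for f in range(p):
                df = abs(Xn[i, f] - Xn[j, f])
                n_df[f] += w[rank] * df
                n_dydf[f] += w[rank] * dy * df
    return n_dydf / n_dy - (n_df - n_dydf) / (n - n_dy)


def test_rrelieff_matches_naive_loop_oracle(rng):
    X = rng.normal(size=(6, 2))
    y = rng.normal(size=6)
    sel = RReliefFSelector(n_neighbors=2, sigma=20.0).fit(X, y)
    expected = _naive_rrelieff(X, y, k=2, sigma=20.0)
    assert np.allclose(sel.scores_, expected, atol=1e-12)


def test_rrelieff_copy_of_outcome_beats_noise(rng):
    n = 200
    y = rng.normal(size=n)
    X = np.column_stack([y, rng.normal(size=n)])
    sel = RReliefFSelector(n_neighbors=10).fit(X, y)
    assert sel.scores_[0] > sel.scores_[1]
    assert abs(sel.scores_[1]) < 0.1  # pure-noise weight near zero
    assert sel.ranking_[0] == 0


def test_rrelieff_weights_bounded(rng):
    X = rng.normal(size=(50, 8))
    y = rng.normal(size=50)
    sel = RReliefFSelector().fit(X, y)
    assert np.all(sel.scores_ >= -1.0) and np.all(sel.scores_ <= 1.0)


def test_rrelieff_handles_duplicate_rows(rng):
    X = np.vstack([np.ones((5, 3)), np.zeros((5, 3))])
    y = np.concatenate([np.ones(5), np.zeros(5)])
    sel = RReliefFSelector(n_neighbors=3).fit(X, y)
    assert np.all(np.isfinite(sel.scores_))


def test_rrelieff_constant_response_gives_zero_weights(rng):
    X = rng.normal(size=(20, 4))
    sel = RReliefFSelector().fit(X, np.full(20, 3.0))
    assert np.allclose(sel.scores_, 0.0)


def test_rankings_invariant_to_rescaling_one_feature(rng):
    y = None
    table = _random_table(rng, 50)
    table["peak_com_excursion"] = (
        1.5 * table["aM"] + 0.8 * table["vST"] + 0.2 * rng.normal(size=50)
    )
    scaled = table.copy()
    scaled["aM"] = scaled["aM"] * 1000.0

    f1 = f_test_rank(table, "peak_com_excursion").ranked_features
    f2 = f_test_rank(scaled, "peak_com_excursion").ranked_features
    assert f1 == f2

    r1 = relieff_rank(table, "peak_com_excursion").ranked_features
    r2 = relieff_rank(scaled, "peak_com_excursion").ranked_features
    assert r1 == r2

    l1 = lasso_rank(table, "peak_com_excursion", seed=0).ranked_features
    l2 = lasso_rank(scaled, "peak_com_excursion", seed=0).ranked_features
    assert l1 == l2


def test_selector_transform_keeps_top_features(rng):
    X = rng.normal(size=(30, 10))
    y = 2.0 * X[:, 4] + rng.normal(size=30) * 0.1
    sel = FTestSelector(n_features_to_select=3).fit(X, y)
    Xt = sel.transform(X)
    assert Xt.shape == (30, 3)
    assert sel.get_support()[4]


def test_selection_frequency_single_iteration_equals_single_run(rng):
    table = _random_table(rng, 40)
    table["peak_com_excursion"] = 2.0 * table["aM"] + 0.1 * rng.normal(size=40)
    from rollgait.validation import make_splits

    splits = make_splits(40, 1, 0.7, np.random.default_rng(5))
    freq = selection_frequency(
        table, "peak_com_excursion", "f_test", n_iterations=1, splits=splits
    )
    train = table.iloc[splits[0][0]]
    single = f_test_rank(train, "peak_com_excursion")
    assert freq.ranked_features == single.ranked_features[:10]
    assert all(freq.scores[f] == 1.0 for f in freq.ranked_features)


def test_selection_frequency_deterministic_under_seed(rng):
    table = _random_table(rng, 40)
    a = selection_frequency(table, "peak_com_excursion", "f_test", n_iterations=5, seed=7)
    b = selection_frequency(table, "peak_com_excursion", "f_test", n_iterations=5, seed=7)
    assert a.ranked_features == b.ranked_features
    assert a.scores == b.scores


def test_empty_lasso_selection_warns(rng):
    X = rng.normal(size=(30, 5))
    y = rng.normal(size=30)
    with pytest.warns(UserWarning, match="zero"):
        sel = LassoSelector(lam=1e6, standardize=False).fit(X, y)
    assert len(sel.ranking_) == 0
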