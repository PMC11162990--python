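import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ngdwi.modeling import (build_combined_model, fit_logistic,
                            lasso_lambda_max, lasso_select, prune_redundant,
                            significant_features, spearman_rho)


def _informative_data(seed=0, n=200, p=6):
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.5
    X = rng.standard_normal((n, p))
    X[:, 0] += 2.0 * y            # strongly informative column
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(p)]), y.astype(int)


def test_full_shrinkage_gives_empty_selection():
    X, y = _informative_data()
    # force every grid point to lambda_max: nothing can enter the model
    sel = lasso_select(X, y, seed=0, n_lambda=3, lambda_min_ratio=1.0)
    assert sel.selected == ()
    assert sel.lambda_used == pytest.approx(lasso_lambda_max(X, y))


def test_informative_column_selected():
    X, y = _informative_data(seed=3)
    sel = lasso_select(X, y, seed=3)
    assert "x0" in sel.selected


def test_selection_deterministic_given_seed():
    X, y = _informative_data(seed=5)
    s1 = lasso_select(X, y, seed=42)
    s2 = lasso_select(X, y, seed=42)
    assert s1.selected == s2.selected
    assert s1.lambda_used == s2.lambda_used


def test_single_class_rejected():
    X, _ = _informative_data()
    with pytest.raises(ValueError):
        lasso_select(X, np.zeros(len(X), int))


def test_lasso_approaches_unpenalized_fit_as_lambda_vanishes():
    """With a negligible penalty the L1 path endpoint matches the
    maximum-likelihood logistic coefficients (standardized scale)."""
    rng = np.random.default_rng(8)
    n = 400
    X = rng.standard_normal((n, 3))
    eta = 0.8 * X[:, 0] - 0.5 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    from sklearn.linear_model import LogisticRegression
    Xs = (X - X.mean(0)) / X.std(0)
    lam = lasso_lambda_max(Xs, y) * 1e-6
    tiny = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                              C=1.0 / (n * lam), max_iter=5000, tol=1e-10,
                              intercept_scaling=100.0).fit(Xs, y)
    ml = fit_logistic(Xs, y)
    np.testing.assert_allclose(tiny.coef_[0], ml.coefficients, atol=1e-3)


def test_intercept_only_closed_form():
    y = np.array([1] * 30 + [0] * 70)
    model = fit_logistic(np.empty((100, 0)), y)
    assert model.intercept == pytest.approx(math.log(0.3 / 0.7), rel=1e-6)


def test_binary_predictor_log_odds_ratio():
    """2×2 table (20,10;10,20): slope is the log odds ratio log 4."""
    x = np.array([0] * 30 + [1] * 30, float)
    y = np.concatenate([np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)])
    model = fit_logistic(x[:, None], y.astype(int))
    assert abs(model.coefficients[0]) == pytest.approx(math.log(4.0),
                                                       rel=1e-5)


def test_null_wald_rejection_rate():
    """y independent of X: p < 0.05 in about 5% of coefficients."""
    rng = np.random.default_rng(21)
    hits = total = 0
    for _ in range(40):
        X = rng.standard_normal((500, 5))
        y = (rng.random(500) < 0.5).astype(int)
        m = fit_logistic(X, y)
        hits += int(np.sum(m.p_values < 0.05))
        total += 5
    assert 0.01 <= hits / total <= 0.12


def test_perfect_separation_flagged():
    x = np.concatenate([-1 - np.arange(10.0), 1 + np.arange(10.0)])
    y = (x > 0).astype(int)
    with pytest.warns(UserWarning, match="separation"):
        model = fit_logistic(x[:, None], y)
    assert model.separation
    assert np.all(np.isfinite(model.coefficients))


def test_significant_features_thresholding():
    m = fit_logistic(*_informative_data(seed=2)[:2])
    sig = significant_features(m, alpha=0.05)
    assert set(sig) <= set(m.feature_names)
    assert "x0" in sig
    assert sig == [n for n, p in zip(m.feature_names, m.p_values) if p < 0.05]


def test_spearman_examples():
    x = np.linspace(-2, 2, 20)
    assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
    assert spearman_rho(x, -x) == pytest.approx(-1.0)
    # hand ranks, rho = 1 − 6·Σd²/(n(n²−1)):
    # y=[2,1,4,3,5]: d²=(1,1,1,1,0) → 1 − 24/120 = 0.8
    assert spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)
    # y=[2,3,1,4,5]: d²=(1,1,4,0,0) → 1 − 36/120 = 0.7
    assert spearman_rho([1, 2, 3, 4, 5], [2, 3, 1, 4, 5]) == pytest.approx(0.7)


def test_spearman_degenerate():
    assert np.isnan(spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
    with pytest.raises(ValueError):
        spearman_rho([1.0, 2.0], [1.0, 2.0])


def _corr_frame(rng, n=100):
    z = rng.standard_normal(n)
    return pd.DataFrame({
        "a": z + 0.05 * rng.standard_normal(n),
        "b": z + 0.05 * rng.standard_normal(n),
        "c": z + 0.05 * rng.standard_normal(n),
        "d": rng.standard_normal(n),
    })


def test_prune_drops_lower_icc_duplicate(rng):
    df = pd.DataFrame({"a": np.arange(30.0), "b": np.arange(30.0)})
    spec = prune_redundant(["a", "b"], df, {"a": 0.95, "b": 0.90})
    assert spec.selected == ("a",)
    assert spec.audit[0][0] == "b"


def test_prune_keeps_uncorrelated(rng):
    df = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
    spec = prune_redundant(list("abc"), df, dict(a=0.9, b=0.9, c=0.9))
    assert set(spec.selected) == set("abc")
    assert spec.audit == ()


def test_prune_missing_icc_named():
    df = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
    with pytest.raises(ValueError, match="b"):
        prune_redundant(["a", "b"], df, {"a": 0.9})


def test_prune_against_brute_force(rng):
    """Survivors satisfy the threshold; compare against exhaustive search
    over drop orders for a mutually correlated triple."""
    df = _corr_frame(rng)
    iccs = {"a": 0.95, "b": 0.85, "c": 0.90, "d": 0.99}
    thr = 0.70
    spec = prune_redundant(list("abcd"), df, iccs, thr)

    def ok(subset):
        return all(abs(spearman_rho(df[f], df[g])) <= thr
                   for f, g in itertools.combinations(subset, 2))

    # no surviving pair exceeds the threshold
    assert ok(spec.selected)
    # brute force: keeping any larger subset containing the survivors fails
    best = max((s for r in range(1, 5)
                for s in itertools.combinations("abcd", r) if ok(s)),
               key=len)
    assert len(spec.selected) == len(best)
    # the greedy rule keeps the highest-ICC member of the correlated triple
    assert "a" in spec.selected and "d" in spec.selected


def test_combined_model_single_feature_equals_univariate(rng):
    X, y = _informative_data(seed=9)
    spec, combined = build_combined_model({"M": ["x0"]}, X, {"x0": 0.9}, y)
    uni = fit_logistic(X[["x0"]], y, feature_names=["x0"])
    assert spec.selected == ("x0",)
    np.testing.assert_allclose(combined.coefficients, uni.coefficients,
                               rtol=1e-8)


def test_combined_model_two_independent_signals():
    rng = np.random.default_rng(17)
    n = 300
    x0 = rng.standard_normal(n)
    x1 = rng.standard_normal(n)
    eta = 1.2 * x0 + 1.2 * x1
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame({"f0": x0, "f1": x1,
                       "noise": rng.standard_normal(n)})
    spec, model = build_combined_model({"A": ["f0"], "B": ["f1"]}, df,
                                       {"f0": 0.9, "f1": 0.9}, y)
    assert set(spec.selected) == {"f0", "f1"}
    assert all(p < 0.05 for p in model.p_values)


def test_combined_model_empty_pool_raises(rng):
    X, y = _informative_data()
    with pytest.raises(ValueError):
        build_combined_model({"A": []}, X, {}, y)
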