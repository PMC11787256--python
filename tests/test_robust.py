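"""Huber M-estimation and detection-logistic fits against oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from evpdiet.robust import DetectionLogistic, HuberConfig, HuberRegression


def _clean_data(n=200, seed=0, noise=0.5):
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.normal(0, 1, n), rng.normal(0, 2, n)])
    y = 2.0 + 1.5 * X[:, 0] - 0.7 * X[:, 1] + rng.normal(0, noise, n)
    return X, y


def test_huber_matches_ols_on_clean_gaussian_data():
    X, y = _clean_data()
    huber = HuberRegression().fit(X, y)
    ols = sm.OLS(y, sm.add_constant(X)).fit()
    assert np.abs(huber.params_ - ols.params).max() < 0.01


def test_huber_limit_c_infinity_is_ols():
    X, y = _clean_data(n=120, seed=3)
    huber = HuberRegression(c=1e6).fit(X, y)
    ols = sm.OLS(y, sm.add_constant(X)).fit()
    np.testing.assert_allclose(huber.params_, ols.params, rtol=1e-6)


def test_huber_matches_statsmodels_rlm():
    X, y = _clean_data(n=150, seed=9)
    y[::17] += 8.0  # some gross outliers
    mine = HuberRegression().fit(X, y)
    ref = sm.RLM(y, sm.add_constant(X),
                 M=sm.robust.norms.HuberT(t=1.345)).fit(scale_est="mad", cov="H1")
    np.testing.assert_allclose(mine.params_, ref.params, atol=1e-7)
    np.testing.assert_allclose(mine.bse_, ref.bse, rtol=1e-6)


def test_huber_matches_frozen_mass_rlm_fit():
    """Frozen oracle: MASS::rlm(k=1.345, scale.est='MAD') on the same draws."""
    rng = np.random.default_rng(42)
    n = 80
    X = np.column_stack([rng.normal(0, 1, n), rng.normal(0, 2, n)])
    y = 1.0 + 0.5 * X[:, 0] - 1.2 * X[:, 1] + rng.standard_t(3, n)
    mine = HuberRegression().fit(X, y)
    mass_coef = [1.1355943991, 0.6354412128, -1.4684541070]
    mass_se = [0.1603637208, 0.2072846860, 0.0851293156]
    np.testing.assert_allclose(mine.params_, mass_coef, atol=2e-5)
    np.testing.assert_allclose(mine.bse_, mass_se, rtol=1e-3)


def test_huber_bounds_single_gross_outlier():
    rng = np.random.default_rng(1)
    n = 50
    x = rng.normal(0, 1, n)
    y = 1.0 + 2.0 * x + rng.normal(0, 1, n)
    clean_ols = sm.OLS(y, sm.add_constant(x)).fit().params[1]
    y_out = y.copy()
    y_out[0] += 100.0
    dirty_ols = sm.OLS(y_out, sm.add_constant(x)).fit().params[1]
    huber = HuberRegression().fit(x[:, None], y_out).coef_[0]
    ols_shift = abs(dirty_ols - clean_ols)
    assert abs(huber - clean_ols) < 0.1 * ols_shift


def test_huber_permutation_invariance():
    X, y = _clean_data(n=60, seed=4)
    perm = np.random.default_rng(5).permutation(60)
    a = HuberRegression().fit(X, y)
    b = HuberRegression().fit(X[perm], y[perm])
    np.testing.assert_allclose(a.params_, b.params_, atol=1e-10)


def test_constant_outcome_is_degenerate():
    import pandas as pd

    from evpdiet.associations import fit_robust_linear

    rng = np.random.default_rng(2)
    df = pd.DataFrame({"y": 2.0, "x": rng.normal(0, 1, 30)})
    with pytest.raises(ValueError, match="degenerate"):
        fit_robust_linear(df, "y", "x", covariates=())


def test_huber_rank_deficient_and_invalid_inputs():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 30)
    X = np.column_stack([x, 2 * x])
    with pytest.raises(ValueError, match="rank deficient"):
        HuberRegression().fit(X, rng.normal(0, 1, 30),
                              feature_names=["a", "a_times_2"])
    with pytest.raises(ValueError, match="n > p"):
        HuberRegression().fit(np.ones((3, 4)), np.ones(3))
    with pytest.raises(ValueError, match="missing"):
        HuberRegression().fit(np.array([[1.0], [np.nan], [2.0], [3.0]]),
                              np.ones(4))


def test_huber_perfect_fit_is_exact():
    x = np.arange(20, dtype=float)
    model = HuberRegression().fit(x[:, None], 3.0 + 2.0 * x)
    assert model.scale_ == 0.0
    np.testing.assert_allclose(model.params_, [3.0, 2.0], atol=1e-10)


def test_huber_config_validation():
    with pytest.raises(ValueError):
        HuberConfig(c=0)
    with pytest.raises(ValueError):
        HuberConfig(tol=-1)


def test_logistic_balanced_intercept_is_zero():
    y = np.array([0.0, 1.0] * 30)
    x = np.zeros((60, 1))
    x[:, 0] = np.tile([1.0, 1.0, -1.0, -1.0], 15)
    model = DetectionLogistic().fit(x, y)
    assert model.intercept_ == pytest.approx(0.0, abs=1e-8)


def test_logistic_recovers_planted_log_odds():
    rng = np.random.default_rng(11)
    est = []
    for _ in range(30):
        x = rng.normal(0, 1, 1000)
        p = 1 / (1 + np.exp(-(0.2 + 0.5 * x)))
        y = (rng.random(1000) < p).astype(float)
        est.append(DetectionLogistic().fit(x[:, None], y).coef_[0])
    assert abs(np.mean(est) - 0.5) < 0.1


def test_logistic_null_wald_p_uniform():
    """Under exposure independent of outcome, Wald p-values are uniform."""
    from scipy.stats import kstest

    rng = np.random.default_rng(13)
    pvals = []
    for _ in range(200):
        x = rng.normal(0, 1, 500)
        y = (rng.random(500) < 0.4).astype(float)
        pvals.append(DetectionLogistic().fit(x[:, None], y).pvalues_[1])
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_logistic_flags_separation_and_rejects_single_class():
    x = np.linspace(-2, 2, 40)
    y = (x > 0).astype(float)
    model = DetectionLogistic().fit(x[:, None], y)
    assert not model.converged_
    assert model.note_ != ""
    with pytest.raises(ValueError, match="single-class"):
        DetectionLogistic().fit(x[:, None], np.ones(40))
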