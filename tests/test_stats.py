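"""Model-quality criteria against independent oracles."""

import math

import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import (
    confusion_matrix,
    matthews_corrcoef,
    mean_absolute_error,
    mean_squared_error,
)

from cwqsar.errors import DegenerateDataError, UndefinedStatisticError
from cwqsar.stats import (
    cccp,
    cii,
    classification_stats,
    iic,
    lin_ccc,
    loo_influence,
    pearson_r,
    q2_loo,
    regression_stats,
)


def brute_force_loo(x, y):
    """O(n^2) reference: recompute Pearson r after deleting each point."""
    r_all = scipy.stats.pearsonr(x, y).statistic
    out = np.empty(len(x))
    for k in range(len(x)):
        xs = np.delete(x, k)
        ys = np.delete(y, k)
        out[k] = scipy.stats.pearsonr(xs, ys).statistic - r_all
    return out


def test_loo_influence_matches_bruteforce_many_instances(rng):
    for _ in range(60):
        n = int(rng.integers(4, 51))
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n)
        fast = loo_influence(x, y)
        assert np.max(np.abs(fast - brute_force_loo(x, y))) < 1e-10


def test_loo_influence_collinear_is_zero():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = 2 * x + 1
    assert np.allclose(loo_influence(x, y), 0.0, atol=1e-12)


def test_loo_influence_outlier_is_opponent(rng):
    x = np.arange(10.0)
    y = x.copy()
    y[4] += 25.0  # gross outlier off a perfect line
    delta = loo_influence(x, y)
    assert delta[4] > 0
    assert delta[4] == max(delta)


def test_loo_influence_errors():
    with pytest.raises(DegenerateDataError):
        loo_influence([1, 2, 3], [1, 2, 3])
    with pytest.raises(DegenerateDataError):
        # deleting the only distinct x value leaves a constant vector
        loo_influence([1.0, 1.0, 1.0, 5.0], [1.0, 2.0, 3.0, 4.0])


def test_loo_influence_on_r2_sign_convention(rng):
    x = rng.normal(size=12)
    y = 0.9 * x + 0.2 * rng.normal(size=12)
    d_r = loo_influence(x, y)
    d_r2 = loo_influence(x, y, on_r2=True)
    # r is positive here, so r and r2 influences agree in sign
    assert np.all(np.sign(d_r) == np.sign(d_r2))


def test_cii_and_cccp_arithmetic():
    delta = np.array([0.1, -0.2, 0.05])
    assert cii(delta) == pytest.approx(1 - 0.15, abs=1e-12)
    assert cccp(delta) == pytest.approx(1 - 0.15 / 0.2, abs=1e-12)
    no_opponents = np.array([-0.1, -0.05, 0.0])
    assert cii(no_opponents) == 1.0
    assert cccp(no_opponents) == 1.0
    balanced = np.array([0.3, -0.3])
    assert cccp(balanced) == pytest.approx(0.0, abs=1e-12)
    assert cccp(delta, literal_ratio=True) == pytest.approx(0.75, abs=1e-12)


def test_cccp_requires_supporters():
    with pytest.raises(UndefinedStatisticError):
        cccp(np.array([0.1, 0.2, 0.0]))


def test_cii_cccp_permutation_invariant(rng):
    x = rng.normal(size=12)
    y = x + rng.normal(size=12)
    delta = loo_influence(x, y)
    perm = rng.permutation(12)
    assert cii(delta[perm]) == pytest.approx(cii(delta), abs=1e-14)
    assert cccp(delta[perm]) == pytest.approx(cccp(delta), abs=1e-14)


def test_cii_cccp_from_bruteforce_deltas_match_fast_path(rng):
    x = rng.normal(size=12)
    y = 0.5 * x + rng.normal(size=12)
    fast = loo_influence(x, y)
    brute = brute_force_loo(x, y)
    assert cii(fast) == pytest.approx(cii(brute), abs=1e-10)
    assert cccp(fast) == pytest.approx(cccp(brute), abs=1e-10)


def test_iic_ratio_and_conventions(rng):
    obs = rng.normal(size=20)
    pred = obs + rng.normal(scale=0.3, size=20)
    r = pearson_r(obs, pred)
    resid = obs - pred
    mae_neg = np.abs(resid[resid < 0]).mean()
    mae_pos = resid[resid >= 0].mean()
    expected = r * min(mae_neg, mae_pos) / max(mae_neg, mae_pos)
    assert iic(obs, pred) == pytest.approx(expected, abs=1e-12)
    # exact fit: IIC equals r by the equal-MAE convention
    x = np.arange(5.0)
    assert iic(x, x) == pytest.approx(1.0)
    # one-sided residuals are undefined
    with pytest.raises(UndefinedStatisticError):
        iic(x, x - 1.0)


def test_iic_symmetric_residuals_give_r():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    pred = x + np.array([0.5, -0.5, 0.5, -0.5])
    assert iic(x, pred) == pytest.approx(pearson_r(x, pred), abs=1e-12)


def test_regression_stats_perfect_and_shifted():
    x = np.array([1.0, 2.0, 4.0, 7.0, 9.0])
    st = regression_stats(x, x)
    assert st.r2 == pytest.approx(1.0)
    assert st.ccc == pytest.approx(1.0)
    assert st.rmse == 0.0 and st.mae == 0.0
    assert st.q2 == pytest.approx(1.0)
    assert math.isinf(st.f)
    assert st.cii == 1.0
    shifted = regression_stats(x, x + 3.0)
    assert shifted.r2 == pytest.approx(1.0)
    assert shifted.ccc < 1.0


def test_regression_stats_against_independent_formulas(rng):
    obs = rng.normal(size=20)
    pred = 0.8 * obs + rng.normal(scale=0.4, size=20)
    st = regression_stats(obs, pred)
    r = scipy.stats.pearsonr(obs, pred).statistic
    assert st.r2 == pytest.approx(r**2, abs=1e-10)
    assert st.rmse == pytest.approx(
        math.sqrt(mean_squared_error(obs, pred)), abs=1e-10
    )
    assert st.mae == pytest.approx(mean_absolute_error(obs, pred), abs=1e-10)
    assert st.f == pytest.approx(st.r2 * 18 / (1 - st.r2), abs=1e-8)
    # Lin's CCC from its definition
    sx, sy = obs.var(), pred.var()
    ccc = 2 * np.cov(obs, pred, bias=True)[0, 1] / (
        sx + sy + (obs.mean() - pred.mean()) ** 2
    )
    assert st.ccc == pytest.approx(ccc, abs=1e-10)
    # Q2 by explicitly refitting with each point held out
    press = 0.0
    for k in range(20):
        xs = np.delete(pred, k)
        ys = np.delete(obs, k)
        b1, b0 = np.polyfit(xs, ys, 1)
        press += (obs[k] - (b0 + b1 * pred[k])) ** 2
    assert st.q2 == pytest.approx(1 - press / ((obs - obs.mean()) ** 2).sum(), abs=1e-10)
    assert st.iic == pytest.approx(iic(obs, pred), abs=1e-12)
    assert st.cccp == pytest.approx(cccp(loo_influence(obs, pred)), abs=1e-12)


def test_lin_ccc_range(rng):
    obs = rng.normal(size=30)
    pred = -obs
    assert -1.0 <= lin_ccc(obs, pred) <= 1.0


def test_q2_requires_variance():
    with pytest.raises(DegenerateDataError):
        q2_loo([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])


def test_classification_stats_examples():
    perfect = classification_stats([0, 1, 0, 1], [0, 1, 0, 1])
    assert (
        perfect.sensitivity,
        perfect.specificity,
        perfect.accuracy,
        perfect.mcc,
    ) == (1.0, 1.0, 1.0, 1.0)
    all_pos = classification_stats([0, 0, 1, 1], [1, 1, 1, 1])
    assert all_pos.sensitivity == 1.0
    assert all_pos.specificity == 0.0
    assert all_pos.accuracy == 0.5
    assert not all_pos.mcc_defined


def test_classification_stats_against_sklearn(rng):
    actual = rng.integers(0, 2, size=60)
    actual[:2] = [0, 1]  # both classes present
    predicted = np.where(rng.random(60) < 0.8, actual, 1 - actual)
    st = classification_stats(actual, predicted)
    tn, fp, fn, tp = confusion_matrix(actual, predicted).ravel()
    assert st.sensitivity == pytest.approx(tp / (tp + fn))
    assert st.specificity == pytest.approx(tn / (tn + fp))
    assert st.accuracy == pytest.approx((tp + tn) / 60)
    assert st.mcc == pytest.approx(matthews_corrcoef(actual, predicted), abs=1e-10)


def test_classification_stats_errors():
    with pytest.raises(DegenerateDataError):
        classification_stats([1, 1, 1], [0, 1, 1])
    with pytest.raises(DegenerateDataError):
        classification_stats([0, 1, 2], [0, 1, 1])
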