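"""Estimators against independent oracles, reduction identities and
invariances."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrkit.estimators import (
    EstimatorConfig,
    MODE_GRID_POINTS,
    ivw,
    mr_egger,
    ratio_estimates,
    run_all_estimators,
    wald_ratio,
    weighted_median,
    weighted_median_point,
    weighted_mode,
    weighted_mode_point,
)

from conftest import make_instruments


# ---------------------------------------------------------------- Wald ratio

@pytest.mark.parametrize(
    ("bx", "by", "sy", "estimate", "se"),
    [
        (0.1, 0.02, 0.01, 0.2, 0.1),
        (-0.1, 0.02, 0.01, -0.2, 0.1),  # |beta_exp| in the SE
        (0.1, 0.0, 0.01, 0.0, 0.1),
    ],
)
def test_wald_ratio(bx, by, sy, estimate, se):
    inst = make_instruments([bx], [0.01], [by], [sy])[0]
    r = wald_ratio(inst)
    assert r.estimate == pytest.approx(estimate)
    assert r.se == pytest.approx(se)
    if by == 0.0:
        assert r.pval == pytest.approx(1.0)


def test_wald_ratio_zero_exposure_effect_is_domain_error():
    inst = make_instruments([0.0], [0.01], [0.02], [0.01])[0]
    with pytest.raises(ValueError):
        wald_ratio(inst)


# ------------------------------------------------------------------- IVW

def test_ivw_with_single_instrument_equals_wald_ratio():
    inst = make_instruments([0.13], [0.02], [0.031], [0.008])
    r_ivw, r_wald = ivw(inst), wald_ratio(inst[0])
    assert r_ivw.estimate == r_wald.estimate
    assert r_ivw.se == r_wald.se
    assert r_ivw.ci_low == r_wald.ci_low and r_ivw.ci_high == r_wald.ci_high


def test_ivw_perfect_homogeneity_no_inflation():
    bx = np.array([0.1, 0.2, 0.4])
    inst = make_instruments(bx, [0.01] * 3, 0.5 * bx, [0.01, 0.02, 0.03])
    r = ivw(inst)
    assert r.estimate == pytest.approx(0.5)
    assert r.q_statistic == pytest.approx(0.0, abs=1e-20)
    assert r.q_pval == pytest.approx(1.0)
    fixed = ivw(inst, random_effects=False)
    assert r.se == fixed.se  # inflation floor at 1


def test_ivw_matches_zero_intercept_wls_oracle():
    bx = np.array([0.1, 0.2, 0.3])
    by = np.array([0.01, 0.04, 0.09])
    sy = np.array([0.01, 0.01, 0.01])
    inst = make_instruments(bx, [0.01] * 3, by, sy)
    oracle = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
    r = ivw(inst)
    assert r.estimate == pytest.approx(oracle.params[0], rel=1e-12)


def test_ivw_empty_input_is_usage_error():
    with pytest.raises(ValueError):
        ivw([])


def test_ivw_random_effects_never_below_fixed_effect_se():
    rng = np.random.default_rng(10)
    bx = rng.uniform(0.05, 0.3, 20)
    by = 0.3 * bx + rng.normal(0, 0.05, 20)
    inst = make_instruments(bx, [0.01] * 20, by, [0.01] * 20)
    assert ivw(inst).se >= ivw(inst, random_effects=False).se


# ------------------------------------------------------------------ MR-Egger

def test_egger_exact_linear_data():
    bx = np.array([0.1, 0.15, 0.2, 0.3])
    inst = make_instruments(bx, [0.01] * 4, 0.3 * bx, [0.01] * 4)
    r = mr_egger(inst)
    assert r.estimate == pytest.approx(0.3, abs=1e-12)
    assert r.intercept == pytest.approx(0.0, abs=1e-12)


def test_egger_exact_affine_data_recovers_intercept():
    bx = np.array([0.1, 0.15, 0.2, 0.3])
    inst = make_instruments(bx, [0.01] * 4, 0.05 + 0.3 * bx, [0.01] * 4)
    r = mr_egger(inst)
    assert r.estimate == pytest.approx(0.3, abs=1e-12)
    assert r.intercept == pytest.approx(0.05, abs=1e-12)


def test_egger_orients_instruments_to_positive_exposure_effect():
    bx = np.array([0.1, -0.15, 0.2, -0.3, 0.12])
    by = 0.05 * np.sign(bx) + 0.3 * bx  # pleiotropy on the oriented scale
    inst = make_instruments(bx, [0.01] * 5, by, [0.01] * 5)
    r = mr_egger(inst)
    assert r.estimate == pytest.approx(0.3, abs=1e-12)
    assert r.intercept == pytest.approx(0.05, abs=1e-12)


def test_egger_matches_weighted_regression_oracle():
    """Slope, intercept, SEs and p agree with a statsmodels WLS fit using
    the same orientation rule (over-dispersed fixture, so the scale floor
    is inactive on both routes)."""
    rng = np.random.default_rng(42)
    k = 10
    bx = rng.uniform(-0.3, 0.3, k)
    sy = np.full(k, 0.05)
    by = 0.05 * np.sign(bx) + 0.25 * bx + rng.normal(0, 0.15, k)
    inst = make_instruments(bx, [0.01] * k, by, sy)

    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    oracle = sm.WLS(y, sm.add_constant(x), weights=1.0 / sy**2).fit()
    assert oracle.mse_resid > 1.0  # floor inactive; SEs comparable

    r = mr_egger(inst)
    assert r.estimate == pytest.approx(oracle.params[1], rel=1e-10)
    assert r.intercept == pytest.approx(oracle.params[0], rel=1e-10)
    assert r.se == pytest.approx(oracle.bse[1], rel=1e-10)
    assert r.intercept_se == pytest.approx(oracle.bse[0], rel=1e-10)
    assert r.pval == pytest.approx(oracle.pvalues[1], rel=1e-10)
    assert r.intercept_pval == pytest.approx(oracle.pvalues[0], rel=1e-10)


def test_egger_requires_three_instruments():
    inst = make_instruments([0.1, 0.2], [0.01] * 2, [0.03, 0.06], [0.01] * 2)
    with pytest.raises(ValueError):
        mr_egger(inst)


def test_egger_uses_t_distribution_with_k_minus_2_df():
    bx = np.array([0.1, 0.2, 0.3])
    by = np.array([0.02, 0.07, 0.08])
    inst = make_instruments(bx, [0.01] * 3, by, [0.01] * 3)
    r = mr_egger(inst)
    assert r.pval == pytest.approx(2 * stats.t.sf(abs(r.estimate / r.se), 1))


# ------------------------------------------------------------ weighted median

def test_weighted_median_degenerate_distribution():
    inst = make_instruments([0.1, 0.2, 0.3], [0.01] * 3,
                            [0.07, 0.14, 0.21], [0.01, 0.05, 0.02])
    r = weighted_median(inst, n_boot=50, seed=0)
    assert r.estimate == pytest.approx(0.7)


def test_weighted_median_symmetric_equal_weights():
    # theta = (0.1, 0.5, 0.9) with equal weights
    bx = np.array([0.1, 0.1, 0.1])
    by = np.array([0.01, 0.05, 0.09])
    inst = make_instruments(bx, [0.01] * 3, by, [0.01] * 3)
    r = weighted_median(inst, n_boot=50, seed=0)
    assert r.estimate == pytest.approx(0.5)


def _weighted_median_oracle(theta, w, tol=1e-13):
    """Bisection on the interpolated mid-cumulative-weight function."""
    order = np.argsort(theta)
    th, ww = np.asarray(theta)[order], np.asarray(w)[order]
    s = (np.cumsum(ww) - ww / 2.0) / ww.sum()

    def s_of(t):  # piecewise-linear cumulative-weight function
        return np.interp(t, th, s, left=s[0], right=s[-1])

    lo, hi = th[0], th[-1]
    if s_of(lo) >= 0.5:
        return lo
    if s_of(hi) <= 0.5:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if s_of(mid) < 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def test_weighted_median_matches_cumulative_weight_oracle():
    rng = np.random.default_rng(3)
    bx = rng.uniform(0.05, 0.3, 5)
    by = 0.4 * bx + rng.normal(0, 0.03, 5)
    sy = rng.uniform(0.005, 0.05, 5)
    theta, _, w = ratio_estimates(make_instruments(bx, [0.01] * 5, by, sy))
    assert weighted_median_point(theta, w) == pytest.approx(
        _weighted_median_oracle(theta, w), abs=1e-10)


def test_weighted_median_bootstrap_is_seeded():
    inst = make_instruments([0.1, 0.2, 0.3, 0.15], [0.01] * 4,
                            [0.03, 0.05, 0.1, 0.04], [0.01] * 4)
    a = weighted_median(inst, n_boot=200, seed=7)
    b = weighted_median(inst, n_boot=200, seed=7)
    assert a == b
    c = weighted_median(inst, n_boot=200, seed=8)
    assert c.se != a.se


# -------------------------------------------------------------- weighted mode

def test_weighted_mode_point_mass():
    inst = make_instruments([0.1, 0.2, 0.5], [0.01] * 3,
                            [0.04, 0.08, 0.2], [0.01] * 3)
    r = weighted_mode(inst, n_boot=50, seed=0)
    assert r.estimate == pytest.approx(0.4)


def test_weighted_mode_resists_low_weight_outlier():
    bx = np.array([0.2, 0.2, 0.2, 0.01])
    by = np.array([0.10, 0.102, 0.098, 0.05])  # cluster at ~0.5, outlier at 5
    sy = np.array([0.005, 0.005, 0.005, 0.05])
    inst = make_instruments(bx, [0.01] * 4, by, sy)
    r = weighted_mode(inst, n_boot=50, seed=0)
    assert 0.4 < r.estimate < 0.6


def test_weighted_mode_matches_dense_grid_density_oracle():
    """Argmax equals an independently coded kernel-density evaluation on
    the estimator's defined grid (explicit Python loops, math.exp)."""
    rng = np.random.default_rng(11)
    bx = rng.uniform(0.05, 0.3, 7)
    by = 0.35 * bx + rng.normal(0, 0.02, 7)
    sy = rng.uniform(0.005, 0.03, 7)
    theta, _, w = ratio_estimates(make_instruments(bx, [0.01] * 7, by, sy))

    k = len(theta)
    sd = np.std(theta, ddof=1)
    iqr = np.percentile(theta, 75) - np.percentile(theta, 25)
    h = 0.9 * min(sd, iqr / 1.34) * k ** (-0.2)
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, MODE_GRID_POINTS)
    wn = w / w.sum()
    best_x, best_d = None, -1.0
    for x in grid:
        d = sum(wn[j] * math.exp(-0.5 * ((x - theta[j]) / h) ** 2) for j in range(k))
        if d > best_d:
            best_x, best_d = x, d
    assert weighted_mode_point(theta, w) == pytest.approx(best_x, abs=1e-12)


def test_weighted_mode_identical_ratios_returns_common_value():
    theta = np.array([0.4, 0.4, 0.4])
    assert weighted_mode_point(theta, np.ones(3)) == 0.4


def test_weighted_mode_requires_positive_bandwidth_factor():
    inst = make_instruments([0.1, 0.2, 0.3], [0.01] * 3,
                            [0.04, 0.08, 0.1], [0.01] * 3)
    with pytest.raises(ValueError):
        weighted_mode(inst, bandwidth_factor=0.0, n_boot=10, seed=0)


# ------------------------------------------------------------ invariances

def _point_estimates(inst):
    theta, _, w = ratio_estimates(inst)
    return {
        "ivw": ivw(inst).estimate,
        "egger": mr_egger(inst).estimate,
        "median": weighted_median_point(theta, w),
        "mode": weighted_mode_point(theta, w),
    }


def test_estimators_equivariant_under_joint_sign_flip():
    rng = np.random.default_rng(5)
    k = 8
    bx = rng.uniform(0.05, 0.3, k)
    by = 0.3 * bx + rng.normal(0, 0.02, k)
    sy = rng.uniform(0.01, 0.03, k)
    base = _point_estimates(make_instruments(bx, [0.01] * k, by, sy))
    flip = np.where(rng.random(k) < 0.5, -1.0, 1.0)
    flipped = _point_estimates(make_instruments(bx * flip, [0.01] * k, by * flip, sy))
    for key in base:
        assert flipped[key] == pytest.approx(base[key], rel=1e-12), key


@pytest.mark.parametrize("c", [0.1, 3.0])
def test_uniform_outcome_se_scaling_leaves_points_unchanged(c):
    rng = np.random.default_rng(6)
    k = 6
    bx = rng.uniform(0.05, 0.3, k)
    by = 0.3 * bx + rng.normal(0, 0.02, k)
    sy = rng.uniform(0.01, 0.03, k)
    a = make_instruments(bx, [0.01] * k, by, sy)
    b = make_instruments(bx, [0.01] * k, by, sy * c)
    assert ivw(b).estimate == pytest.approx(ivw(a).estimate, rel=1e-12)
    assert mr_egger(b).estimate == pytest.approx(mr_egger(a).estimate, rel=1e-12)


# ------------------------------------------------------------ run_all

def test_run_all_gates_methods_by_instrument_count():
    inst = make_instruments([0.1, 0.2], [0.01] * 2, [0.03, 0.06], [0.01] * 2)
    results = run_all_estimators(inst, EstimatorConfig(seed=1))
    methods = [r.method for r in results]
    assert methods.count("ivw") == 1
    assert methods.count("wald_ratio") == 2
    assert not {"egger", "weighted_median", "weighted_mode"} & set(methods)


def test_run_all_is_deterministic_given_seed():
    rng = np.random.default_rng(9)
    k = 6
    bx = rng.uniform(0.05, 0.3, k)
    by = 0.3 * bx + rng.normal(0, 0.02, k)
    inst = make_instruments(bx, [0.01] * k, by, [0.02] * k)
    config = EstimatorConfig(seed=123, n_boot=100)
    assert run_all_estimators(inst, config) == run_all_estimators(inst, config)


def test_run_all_methods_agree_on_exact_homogeneous_data():
    bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
    inst = make_instruments(bx, [0.01] * 5, 0.3 * bx, [0.01] * 5)
    results = run_all_estimators(inst, EstimatorConfig(seed=1, n_boot=50))
    for r in results:
        assert r.estimate == pytest.approx(0.3, abs=1e-6), r.method


def test_or_scale_is_exact_exponential_of_estimate():
    inst = make_instruments([0.1, 0.2, 0.3], [0.01] * 3,
                            [0.05, 0.1, 0.15], [0.01] * 3)
    r = ivw(inst)
    assert r.or_scale == math.exp(r.estimate)
    assert r.or_ci_low == math.exp(r.ci_low)
    assert r.or_ci_high == math.exp(r.ci_high)
    assert r.ci_low < r.estimate < r.ci_high
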