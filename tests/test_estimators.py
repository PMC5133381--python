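"""Unit tests for the causal-effect estimators."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from mrsense import (
    EstimationError,
    InsufficientVariantsError,
    NotIdentifiedError,
    SimulationConfig,
    egger,
    ivw,
    multivariable_ivw,
    orient_to_exposure,
    ratio_estimates,
    simple_median,
    simulate_dataset,
    to_odds_ratio,
    weighted_median,
)
from mrsense.estimators import _weighted_median
from conftest import build_dataset, random_dataset


# ---------------------------------------------------------------- ratios

@pytest.mark.parametrize(
    "bx,by,sy,theta,se,weight",
    [
        (0.1, 0.05, 0.02, 0.5, 0.2, 25.0),
        # doubling the exposure association halves theta and se, x4 weight
        (0.2, 0.05, 0.02, 0.25, 0.1, 100.0),
        (0.1, 0.0, 0.02, 0.0, 0.2, 25.0),  # null numerator
    ],
)
def test_ratio_arithmetic(bx, by, sy, theta, se, weight):
    data = build_dataset(bx=[bx], by=[by], sy=[sy])
    (r,) = ratio_estimates(data)
    assert r.theta == pytest.approx(theta)
    assert r.se == pytest.approx(se)
    assert r.weight == pytest.approx(weight, rel=1e-12)


def test_ratio_second_order_se_adds_exposure_uncertainty():
    data = build_dataset(bx=[0.2], by=[0.1], sx=[0.05], sy=[0.02])
    (first,) = ratio_estimates(data)
    (second,) = ratio_estimates(data, second_order=True)
    expected = math.sqrt(0.02**2 / 0.2**2 + 0.1**2 * 0.05**2 / 0.2**4)
    assert second.se == pytest.approx(expected)
    assert second.se > first.se


def test_ratio_requires_orientation():
    data = build_dataset(bx=[0.1], by=[0.05], oriented=False)
    with pytest.raises(EstimationError, match="orient"):
        ratio_estimates(data)


# ---------------------------------------------------------------- IVW

def test_ivw_two_variants_hand_value(two_variant):
    est = ivw(two_variant, "fixed")
    assert est.beta == pytest.approx(1.5)
    assert est.se == pytest.approx(1 / math.sqrt(2))


def test_ivw_single_variant_reduces_to_ratio():
    data = build_dataset(bx=[0.25], by=[0.1], sy=[0.04])
    (r,) = ratio_estimates(data)
    est = ivw(data, "fixed")
    assert est.beta == pytest.approx(r.theta)
    assert est.se == pytest.approx(r.se)


def test_ivw_equals_through_origin_weighted_regression(rng):
    """The IVW weighted mean of ratios is exactly WLS of beta_outcome on
    beta_exposure through the origin with weights se_outcome^-2."""
    for _ in range(20):
        data = random_dataset(rng, j=rng.integers(2, 15))
        bx = np.array([v.beta_exposure for v in data.variants])
        by = np.array([v.beta_outcome for v in data.variants])
        sy = np.array([v.se_outcome for v in data.variants])
        fit = sm.WLS(by, bx, weights=sy**-2.0).fit()
        est = ivw(data, "fixed")
        assert est.beta == pytest.approx(fit.params[0], rel=1e-10)
        # fixed-effect SE is the unscaled WLS SE
        unscaled = fit.bse[0] / math.sqrt(fit.mse_resid)
        assert est.se == pytest.approx(unscaled, rel=1e-10)


def test_ivw_homogeneous_dispersion_is_one(homogeneous):
    fixed = ivw(homogeneous, "fixed")
    random = ivw(homogeneous, "multiplicative_random")
    assert fixed.beta == pytest.approx(0.5)
    assert random.beta == fixed.beta
    assert random.dispersion == 1.0
    assert random.se == fixed.se


def test_ivw_random_inflates_se_under_heterogeneity(rng):
    data = random_dataset(rng, j=12, heterogeneity=0.5)
    fixed = ivw(data, "fixed")
    random = ivw(data, "multiplicative_random")
    assert random.beta == fixed.beta
    assert random.dispersion > 1
    assert random.se == pytest.approx(fixed.se * math.sqrt(random.dispersion))


def test_ivw_random_single_variant_errors():
    data = build_dataset(bx=[0.25], by=[0.1])
    with pytest.raises(EstimationError):
        ivw(data, "multiplicative_random")


# ---------------------------------------------------------------- Egger

def test_egger_recovers_exact_linear_relation():
    bx = [0.1, 0.2, 0.3, 0.5]
    data = build_dataset(bx=bx, by=[0.1 + 0.5 * b for b in bx],
                         sy=[0.1, 0.2, 0.05, 0.3])
    est = egger(data, "fixed")
    assert est.intercept == pytest.approx(0.1, abs=1e-12)
    assert est.beta == pytest.approx(0.5, abs=1e-12)
    random = egger(data, "multiplicative_random")
    assert random.dispersion == 1.0  # zero residual Q, phi truncated at 1


def test_egger_matches_statsmodels_wls(rng):
    data = random_dataset(rng, j=20, heterogeneity=0.3)
    bx = np.array([v.beta_exposure for v in data.variants])
    by = np.array([v.beta_outcome for v in data.variants])
    sy = np.array([v.se_outcome for v in data.variants])
    fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2.0).fit()
    est = egger(data, "multiplicative_random")
    assert est.intercept == pytest.approx(fit.params[0], rel=1e-10)
    assert est.beta == pytest.approx(fit.params[1], rel=1e-10)
    # with phi > 1 the random-effects SEs equal statsmodels' scaled SEs
    assert est.dispersion > 1
    assert est.se == pytest.approx(fit.bse[1], rel=1e-10)
    assert est.intercept_se == pytest.approx(fit.bse[0], rel=1e-10)


def test_egger_not_identified_with_equal_instrument_strengths():
    data = build_dataset(bx=[0.2, 0.2, 0.2], by=[0.1, 0.2, 0.3])
    with pytest.raises(NotIdentifiedError, match="not be identified"):
        egger(data, "fixed")


def test_egger_needs_three_variants(two_variant):
    with pytest.raises(InsufficientVariantsError):
        egger(two_variant, "fixed")


def test_egger_unbiased_under_directional_pleiotropy_inside_holding():
    """Simulation oracle: with directional pleiotropy alpha ~ U(0, 0.1) on
    every variant, independent of instrument strength, and true theta = 0,
    the mean Egger intercept is ~0.05 and the mean slope ~0."""
    config = SimulationConfig(J=100, theta=0.0, pleiotropy="directional",
                              invalid_fraction=1.0, pleiotropy_scale=0.1)
    slopes, intercepts = [], []
    for i in range(500):
        data, _ = simulate_dataset(config, seed=1000 + i)
        est = egger(orient_to_exposure(data), "multiplicative_random")
        slopes.append(est.beta)
        intercepts.append(est.intercept)
    mc = 3 * np.std(intercepts) / math.sqrt(500)
    assert np.mean(intercepts) == pytest.approx(0.05, abs=mc)
    mc = 3 * np.std(slopes) / math.sqrt(500)
    assert np.mean(slopes) == pytest.approx(0.0, abs=mc)


# ---------------------------------------------------------------- medians

def test_simple_median_odd_and_even_counts():
    odd = build_dataset(bx=[1, 1, 1], by=[1, 2, 3])
    assert simple_median(odd, n_boot=10).beta == pytest.approx(2.0)
    even = build_dataset(bx=[1, 1, 1, 1], by=[1, 2, 3, 10])
    assert simple_median(even, n_boot=10).beta == pytest.approx(2.5)


def test_weighted_median_interpolation_hand_value():
    # ratio estimates (1, 2, 3) with weights (1, 1, 4):
    # S = (1/12, 3/12, 8/12); crossing between S_2 = 0.25 and S_3 = 2/3
    # beta = 2 + (0.5 - 0.25) / (5/12) = 2.6
    data = build_dataset(bx=[1, 1, 1], by=[1, 2, 3], sy=[1, 1, 0.5])
    est = weighted_median(data, n_boot=10)
    assert est.beta == pytest.approx(2.6)


def test_weighted_median_matches_numpy_interp_oracle(rng):
    """Independent oracle: interpolate the inverse CDF of the weighted
    empirical distribution with numpy.interp at probability 0.5."""
    for _ in range(25):
        j = int(rng.integers(3, 30))
        theta = rng.normal(size=j)
        weight = rng.uniform(0.1, 5.0, size=j)
        order = np.argsort(theta)
        t, w = theta[order], weight[order] / weight.sum()
        s = np.cumsum(w) - 0.5 * w
        expected = float(np.interp(0.5, s, t))
        assert _weighted_median(theta, weight) == pytest.approx(expected, rel=1e-12)


def test_dominant_variant_brackets_the_crossing():
    # weights (0.8, 0.1, 0.1): the 0.5 crossing falls inside the dominant
    # variant's weight mass; interpolation gives 1 + 0.1/0.45 = 1.2222...
    data = build_dataset(bx=[1, 1, 1], by=[1, 2, 3],
                         sy=[1 / math.sqrt(8), 1, 1])
    est = weighted_median(data, n_boot=10)
    assert est.beta == pytest.approx(1 + 0.1 / 0.45)
    assert 1.0 <= est.beta < 2.0


def test_weighted_median_equal_weights_equals_simple(rng):
    for _ in range(10):
        j = int(rng.integers(3, 12))
        by = rng.normal(size=j)
        data = build_dataset(bx=[1] * j, by=by, sy=[0.7] * j)
        wm = weighted_median(data, n_boot=10, seed=3)
        sm_ = simple_median(data, n_boot=10, seed=3)
        assert wm.beta == pytest.approx(sm_.beta, rel=1e-12)


def test_median_bootstrap_deterministic_under_seed(homogeneous):
    a = weighted_median(homogeneous, n_boot=200, seed=42)
    b = weighted_median(homogeneous, n_boot=200, seed=42)
    c = weighted_median(homogeneous, n_boot=200, seed=43)
    assert a.se == b.se
    assert a.se != c.se


def test_median_needs_three_variants(two_variant):
    with pytest.raises(InsufficientVariantsError):
        simple_median(two_variant, n_boot=10)


def test_estimators_invariant_under_permutation(rng):
    data = random_dataset(rng, j=9, heterogeneity=0.2)
    order = rng.permutation(9)
    shuffled = build_dataset(
        bx=[data.variants[i].beta_exposure for i in order],
        by=[data.variants[i].beta_outcome for i in order],
        sx=[data.variants[i].se_exposure for i in order],
        sy=[data.variants[i].se_outcome for i in order],
        ids=[data.variants[i].variant_id for i in order],
    )
    assert ivw(data).beta == pytest.approx(ivw(shuffled).beta, rel=1e-12)
    assert egger(data).beta == pytest.approx(egger(shuffled).beta, rel=1e-12)
    assert weighted_median(data, n_boot=5).beta == pytest.approx(
        weighted_median(shuffled, n_boot=5).beta, rel=1e-12
    )


# ------------------------------------------------------- multivariable

def test_multivariable_single_exposure_equals_ivw(rng):
    data = random_dataset(rng, j=8)
    (mv,) = multivariable_ivw(data, "fixed")
    uni = ivw(data, "fixed")
    assert mv.beta == pytest.approx(uni.beta, rel=1e-12)
    assert mv.se == pytest.approx(uni.se, rel=1e-12)


def test_multivariable_exact_fit_two_exposures(rng):
    j = 8
    bx = rng.uniform(0.1, 0.5, size=j)
    cov = rng.uniform(-0.4, 0.4, size=j)
    by = 0.3 * bx - 0.2 * cov
    data = build_dataset(bx=bx, by=by, sy=rng.uniform(0.05, 0.2, size=j),
                         covariates=[(c,) for c in cov])
    est1, est2 = multivariable_ivw(data, "fixed")
    assert est1.beta == pytest.approx(0.3, abs=1e-10)
    assert est2.beta == pytest.approx(-0.2, abs=1e-10)
    assert est1.exposure != est2.exposure


def test_multivariable_noise_covariate_coefficient_near_zero():
    """Simulation oracle: a covariate whose associations are pure noise,
    uncorrelated with the outcome, gets a coefficient averaging ~0."""
    master = np.random.default_rng(7)
    coefs = []
    for _ in range(500):
        j = 20
        bx = master.uniform(0.1, 0.5, size=j)
        cov = master.normal(0.0, 0.2, size=j)
        sy = np.full(j, 0.05)
        by = 0.25 * bx + master.normal(0.0, sy)
        data = build_dataset(bx=bx, by=by, sy=sy, covariates=[(c,) for c in cov])
        coefs.append(multivariable_ivw(data)[1].beta)
    mc = 3 * np.std(coefs) / math.sqrt(len(coefs))
    assert np.mean(coefs) == pytest.approx(0.0, abs=mc)


def test_multivariable_rank_deficient_errors():
    bx = [0.1, 0.2, 0.3, 0.4]
    data = build_dataset(bx=bx, by=[0.1] * 4, covariates=[(2 * b,) for b in bx])
    with pytest.raises(NotIdentifiedError):
        multivariable_ivw(data)


def test_multivariable_needs_more_variants_than_exposures():
    data = build_dataset(bx=[0.1, 0.2], by=[0.1, 0.2],
                         covariates=[(0.3,), (0.1,)])
    with pytest.raises(InsufficientVariantsError):
        multivariable_ivw(data)


# ---------------------------------------------------------- odds ratios

def test_to_odds_ratio_values():
    data = build_dataset(bx=[0.2, 0.3, 0.4], by=[0.0, 0.0, 0.0],
                         outcome_scale="log_odds")
    null = ivw(data)
    assert to_odds_ratio(null, 1.0).odds_ratio == pytest.approx(1.0)

    # beta = 1 per unit, SD = 1.05 units -> 2.86-fold per SD
    one = build_dataset(bx=[0.2, 0.4], by=[0.2, 0.4], sy=[0.1, 0.1],
                        outcome_scale="log_odds")
    est = ivw(one)
    assert est.beta == pytest.approx(1.0)
    assert to_odds_ratio(est, 1.05).odds_ratio == pytest.approx(math.exp(1.05))


def test_to_odds_ratio_negative_beta_monotone():
    data = build_dataset(bx=[0.2, 0.4, 0.3], by=[-0.1, -0.2, -0.15],
                         sy=[0.1, 0.1, 0.1], outcome_scale="log_odds")
    orr = to_odds_ratio(ivw(data), 1.05)
    assert orr.odds_ratio < 1
    assert orr.ci_low < orr.odds_ratio < orr.ci_high


def test_to_odds_ratio_linear_scale_errors(homogeneous):
    with pytest.raises(EstimationError, match="log-odds"):
        to_odds_ratio(ivw(homogeneous), 1.0)
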