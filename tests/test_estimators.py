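"""Estimator correctness: Wald ratios, IVW identities, Egger, MVMR, odds scale."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from conftest import build_dataset, build_mv_dataset
from mrkit.exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    RankDeficiencyError,
    ScaleMisuseError,
)
from mrkit.mr_estimators import Z95, egger, ivw, mvmr_ivw, to_odds_scale, wald_ratio


def test_wald_ratio_arithmetic():
    est = wald_ratio({"beta_exposure": 0.1, "beta_outcome": 0.05, "se_outcome": 0.02,
                      "snp_id": "rs1"})
    assert est.beta == pytest.approx(0.5)
    assert est.se == pytest.approx(0.2)
    assert est.ci_low == pytest.approx(0.5 - Z95 * 0.2)
    null = wald_ratio({"beta_exposure": -0.07, "beta_outcome": 0.0, "se_outcome": 0.01})
    assert null.beta == 0.0
    with pytest.raises(DegenerateDesignError):
        wald_ratio({"beta_exposure": 0.0, "beta_outcome": 0.1, "se_outcome": 0.01})


def test_wald_se_matches_numerical_delta_method(rng):
    """First-order SE equals the numerically differentiated delta-method SE
    (gradient wrt the outcome beta only) to 1e-6 relative."""
    for _ in range(20):
        bx = rng.uniform(0.01, 0.4) * rng.choice([-1, 1])
        by = rng.normal(0, 0.1)
        sey = rng.uniform(1e-3, 0.05)
        est = wald_ratio({"beta_exposure": bx, "beta_outcome": by, "se_outcome": sey})
        h = 1e-7
        grad = ((by + h) / bx - (by - h) / bx) / (2 * h)
        assert est.se == pytest.approx(abs(grad) * sey, rel=1e-6)


def test_ivw_single_snp_equals_wald():
    ds = build_dataset([0.12], [0.05], [0.02])
    est = ivw(ds, "fixed")
    w = wald_ratio(ds.df.iloc[0])
    assert est.beta == pytest.approx(w.beta, abs=1e-15)
    assert est.se == pytest.approx(w.se, abs=1e-15)


def test_ivw_exact_collinear_floors_random_effects_to_fixed():
    """Exactly proportional betas: beta = 0.5 exactly; zero residual SD is
    floored so the multiplicative-random SE equals the fixed SE."""
    ds = build_dataset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.02] * 3)
    fe = ivw(ds, "fixed")
    mre = ivw(ds, "multiplicative_random")
    assert fe.beta == pytest.approx(0.5, abs=1e-14)
    assert mre.beta == pytest.approx(fe.beta, abs=1e-14)
    assert mre.se == pytest.approx(fe.se, rel=1e-12)


def test_ivw_equals_meta_analysis_of_wald_ratios(rng):
    """Fixed-effect IVW is algebraically the inverse-variance meta-analysis
    of per-SNP Wald ratios with first-order SEs (1e-10, random instances);
    the multiplicative-random point estimate is identical."""
    for _ in range(100):
        k = int(rng.integers(2, 40))
        bx = rng.uniform(0.01, 0.3, k) * rng.choice([-1, 1], k)
        by = rng.normal(0, 0.05, k)
        sey = rng.uniform(1e-3, 0.05, k)
        ds = build_dataset(bx, by, sey)
        est = ivw(ds, "fixed")
        b = by / bx
        w = bx**2 / sey**2
        meta = np.sum(w * b) / np.sum(w)
        meta_se = np.sum(w) ** -0.5
        assert est.beta == pytest.approx(meta, abs=1e-10, rel=1e-10)
        assert est.se == pytest.approx(meta_se, abs=1e-10, rel=1e-10)
        assert ivw(ds, "multiplicative_random").beta == pytest.approx(est.beta, abs=1e-12)


def test_ivw_degenerate_design():
    with pytest.raises(DegenerateDesignError):
        ivw(build_dataset([0.0, 0.0], [0.1, 0.2], [0.01, 0.01]))


def test_egger_exact_fit_and_intercept_shift():
    """Noiseless proportional betas give slope 0.5, intercept 0; adding a
    constant c to every outcome beta moves only the intercept, to c."""
    bx = [0.1, 0.2, 0.3, 0.4]
    by = [0.05, 0.10, 0.15, 0.20]
    res = egger(build_dataset(bx, by, [0.02] * 4))
    assert res.slope.beta == pytest.approx(0.5, abs=1e-12)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)
    shifted = egger(build_dataset(bx, [b + 0.02 for b in by], [0.02] * 4))
    assert shifted.slope.beta == pytest.approx(0.5, abs=1e-12)
    assert shifted.intercept == pytest.approx(0.02, abs=1e-12)


def test_egger_matches_weighted_normal_equations_oracle(rng):
    """Egger slope/intercept and (fixed, unfloored) SEs match an independent
    WLS fit (statsmodels) on oriented data."""
    k = 30
    bx = rng.uniform(0.02, 0.3, k) * rng.choice([-1, 1], k)
    by = 0.4 * bx + 0.01 + rng.normal(0, 0.03, k)
    sey = rng.uniform(0.01, 0.05, k)
    res = egger(build_dataset(bx, by, sey))
    flip = np.sign(bx)
    bx_o, by_o = bx * flip, by * flip
    fit = sm.WLS(by_o, sm.add_constant(bx_o), weights=1.0 / sey**2).fit()
    assert res.slope.beta == pytest.approx(fit.params[1], rel=1e-10)
    assert res.intercept == pytest.approx(fit.params[0], rel=1e-10)
    # statsmodels scales by the residual variance without the floor at 1;
    # reproduce its scaling from the fixed-SE decomposition
    sigma = np.sqrt(fit.scale) if fit.scale > 1 else 1.0
    assert res.slope.se == pytest.approx(fit.bse[1] / np.sqrt(fit.scale) * max(1.0, np.sqrt(fit.scale)), rel=1e-8)


def test_egger_orientation_invariance(rng):
    """Flipping the sign of any subset of (beta_x, beta_y) pairs leaves the
    Egger fit unchanged (the non-negative orientation convention)."""
    k = 12
    bx = rng.uniform(0.02, 0.3, k)
    by = 0.3 * bx + 0.015 + rng.normal(0, 0.02, k)
    sey = rng.uniform(0.01, 0.04, k)
    base = egger(build_dataset(bx, by, sey))
    flip = rng.choice([-1, 1], k)
    flipped = egger(build_dataset(bx * flip, by * flip, sey))
    assert flipped.slope.beta == pytest.approx(base.slope.beta, rel=1e-12)
    assert flipped.intercept == pytest.approx(base.intercept, rel=1e-12)
    assert flipped.slope.se == pytest.approx(base.slope.se, rel=1e-12)


def test_egger_needs_three_snps():
    with pytest.raises(InsufficientDataError):
        egger(build_dataset([0.1, 0.2], [0.05, 0.1], [0.02, 0.02]))


def test_mvmr_zero_second_exposure_reduces_to_univariable(rng):
    k = 20
    bx = rng.uniform(0.02, 0.3, k)
    by = -0.4 * bx + rng.normal(0, 0.02, k)
    sey = rng.uniform(0.01, 0.04, k)
    mv = build_mv_dataset(bx, np.zeros(k), by, sey)
    uni = ivw(build_dataset(bx, by, sey), "fixed")
    est1, est2 = mvmr_ivw(mv, "fixed")
    assert est1.beta == pytest.approx(uni.beta, rel=1e-10)
    assert est2.beta == pytest.approx(0.0, abs=1e-9)


def test_mvmr_matches_statsmodels_wls(rng):
    k = 40
    bx1 = rng.uniform(0.02, 0.3, k) * rng.choice([-1, 1], k)
    bx2 = rng.uniform(0.02, 0.3, k) * rng.choice([-1, 1], k)
    by = 0.2 * bx1 - 0.5 * bx2 + rng.normal(0, 0.02, k)
    sey = rng.uniform(0.01, 0.05, k)
    est1, est2 = mvmr_ivw(build_mv_dataset(bx1, bx2, by, sey), "fixed")
    fit = sm.WLS(by, np.column_stack([bx1, bx2]), weights=1.0 / sey**2).fit()
    assert est1.beta == pytest.approx(fit.params[0], rel=1e-10)
    assert est2.beta == pytest.approx(fit.params[1], rel=1e-10)


def test_mvmr_identical_exposures_raise_rank_deficiency():
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    with pytest.raises(RankDeficiencyError) as err:
        mvmr_ivw(build_mv_dataset(bx, bx, 0.5 * bx, [0.02] * 4))
    assert err.value.condition_number is None or err.value.condition_number > 1e8


@given(st.floats(0.2, 5.0))
def test_outcome_rescaling_rescales_all_estimators(k_scale):
    """Rescaling all outcome betas and SEs by k rescales IVW, Egger and MVMR
    estimates by exactly k."""
    rng = np.random.default_rng(11)
    n = 15
    bx = rng.uniform(0.02, 0.3, n)
    bx2 = rng.uniform(0.02, 0.3, n)
    by = 0.3 * bx - 0.2 * bx2 + 0.01 + rng.normal(0, 0.02, n)
    sey = rng.uniform(0.01, 0.04, n)
    base_i = ivw(build_dataset(bx, by, sey))
    base_e = egger(build_dataset(bx, by, sey))
    base_m = mvmr_ivw(build_mv_dataset(bx, bx2, by, sey))
    scl_i = ivw(build_dataset(bx, k_scale * by, k_scale * sey))
    scl_e = egger(build_dataset(bx, k_scale * by, k_scale * sey))
    scl_m = mvmr_ivw(build_mv_dataset(bx, bx2, k_scale * by, k_scale * sey))
    assert scl_i.beta == pytest.approx(k_scale * base_i.beta, rel=1e-9)
    assert scl_i.se == pytest.approx(k_scale * base_i.se, rel=1e-9)
    assert scl_e.slope.beta == pytest.approx(k_scale * base_e.slope.beta, rel=1e-9)
    assert scl_e.intercept == pytest.approx(k_scale * base_e.intercept, rel=1e-9)
    for got, want in zip(scl_m, base_m):
        assert got.beta == pytest.approx(k_scale * want.beta, rel=1e-9)


def test_to_odds_scale():
    ds = build_dataset([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.02] * 3,
                       outcome_type="binary")
    est = ivw(ds)
    null = est.__class__(**{**est.__dict__, "beta": 0.0, "ci_low": -0.1, "ci_high": 0.1})
    res = to_odds_scale(null)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.percent_change == pytest.approx(0.0)

    low = est.__class__(**{**est.__dict__, "beta": -0.462, "ci_low": -0.673,
                           "ci_high": -0.255})
    res = to_odds_scale(low)
    assert res.odds_ratio == pytest.approx(np.exp(-0.462), rel=1e-12)
    assert res.ci_low == pytest.approx(np.exp(-0.673), rel=1e-12)
    assert round(res.percent_change) == 37
    assert "37%" in res.text and "lower" in res.text

    cont = ivw(build_dataset([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.02] * 3))
    with pytest.raises(ScaleMisuseError):
        to_odds_scale(cont)
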