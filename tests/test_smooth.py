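"""Annual smooth models: OLS nesting, recovery, AR1 handling, CI coverage,
binomial variant."""

import numpy as np
import pandas as pd
import pytest

from gulotherm import (SimConfig, difference_curve, fit_annual_model,
                       fit_binomial_curve, predict_curve, simulate_cohort)
from gulotherm.smooth import _ar1_whiten, _build_design, _gcv_select
from gulotherm.splines import build_basis

from conftest import cohort_daily


def _daily(animals=4, days=365, seed=0, fn=None, pregnant=None, noise=0.05,
           ar1=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(animals):
        doys = np.arange(1, days + 1, dtype=float)
        mu = fn(doys) if fn else np.full(days, 38.5)
        preg = pregnant(a) if pregnant else 0
        e = rng.normal(0, noise, days)
        if ar1:
            for i in range(1, days):
                e[i] = ar1 * e[i - 1] + np.sqrt(1 - ar1 ** 2) * e[i]
        rows.append(pd.DataFrame({
            "animal_id": f"W{a:02d}", "doy": doys, "mean_tb": mu + e,
            "pregnant": preg}))
    return pd.concat(rows, ignore_index=True)


def test_noiseless_constant_gives_flat_curve_and_zero_difference():
    daily = _daily(noise=1e-8, pregnant=lambda a: int(a < 2))
    fit = fit_annual_model(daily, "mean_tb", k=10, use_ar1=False)
    grid = np.arange(1.0, 367.0)
    ref = predict_curve(fit, grid)
    assert np.allclose(ref["estimate"], 38.5, atol=1e-4)
    dc = difference_curve(fit, grid)
    assert np.allclose(dc.estimate, 0.0, atol=1e-4)
    assert not dc.significant.any()


def test_seasonal_curve_recovery_on_synthetic_cohort():
    """Non-pregnant cohort: fitted annual curve peaks near the configured
    DOY 196 and tracks the true sinusoid closely."""
    cfg = SimConfig(n_animals=4, years=1, seed=13, pregnancy_fraction=0.0,
                    fever_rate=0.0, artifact_rate=0.0)
    daily = cohort_daily(simulate_cohort(cfg))
    daily = daily[~daily["excluded"]]
    fit = fit_annual_model(daily, "mean_tb", state_col="pregnant")
    grid = np.arange(1.0, 367.0)
    est = predict_curve(fit, grid)["estimate"].to_numpy()
    assert abs(grid[np.argmax(est)] - 196) <= 15
    truth = 38.5 + 0.15 * np.cos(2 * np.pi * (grid - 196) / 366)
    rmse = np.sqrt(np.mean((est - truth) ** 2))
    assert rmse < 0.05


def test_prewhitening_removes_lag1_autocorrelation():
    daily = _daily(animals=4, seed=3, noise=0.1, ar1=0.6)
    fit = fit_annual_model(daily, "mean_tb", k=10)
    assert fit.ar1_rho == pytest.approx(0.6, abs=0.15)
    # residuals of the whitened problem are serially uncorrelated
    doy = daily["doy"].to_numpy()
    y = daily["mean_tb"].to_numpy()
    animal = daily["animal_id"].to_numpy()
    basis = build_basis(10, 1.0, 366.0, True)
    X, _, _, _, _ = _build_design(doy, None, animal, basis)
    Xw, yw = _ar1_whiten(X, y, animal, doy, fit.ar1_rho)
    # refit on the whitened data with the selected penalties is what the
    # model stores; use its beta directly
    rw = yw - Xw @ fit.beta[:Xw.shape[1]] if Xw.shape[1] == len(fit.beta) \
        else yw - Xw @ np.linalg.lstsq(Xw, yw, rcond=None)[0]
    acs = []
    for a in np.unique(animal):
        r = rw[animal == a]
        acs.append(np.corrcoef(r[1:], r[:-1])[0, 1])
    assert abs(np.mean(acs)) < 0.1


def test_unpenalized_fit_matches_ols_oracle():
    """With all penalties at ~0 the penalized solve reduces to OLS."""
    rng = np.random.default_rng(4)
    daily = _daily(animals=3, days=120, seed=4, noise=0.1)
    doy = daily["doy"].to_numpy()
    y = daily["mean_tb"].to_numpy()
    animal = daily["animal_id"].to_numpy()
    basis = build_basis(8, 1.0, 366.0, False)
    X, penalties, _, _, _ = _build_design(doy, None, animal, basis)
    # the random-effect blocks are collinear with the intercept; compare on
    # the identifiable fitted values rather than coefficients
    lam = np.full(len(penalties), 1e-10)
    A = X.T @ X + sum(l * S for l, S in zip(lam, penalties))
    beta = np.linalg.solve(A, X.T @ y)
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(X @ beta, X @ beta_ols, atol=1e-6)


def test_difference_curve_recovery_shared_window():
    """All pregnancies over DOY 15-60 at 0.5 deg C: the fitted difference
    bottoms out near -0.5 and flags the gestation window."""
    def fn(doys):
        return 38.5 + 0.15 * np.cos(2 * np.pi * (doys - 196) / 366)

    def dip(doys):
        out = np.zeros_like(doys)
        ges = (doys >= 15) & (doys < 60)
        out[ges] = -0.5 * (doys[ges] - 15) / 45
        rec = (doys >= 60) & (doys < 63)
        out[rec] = -0.5 * (1 - (doys[rec] - 60 + 1) / 3)
        return out

    rng = np.random.default_rng(8)
    rows = []
    for a in range(8):
        doys = np.arange(1.0, 366.0)
        preg = int(a < 4)
        mu = fn(doys) + preg * dip(doys)
        rows.append(pd.DataFrame({"animal_id": f"W{a}", "doy": doys,
                                  "mean_tb": mu + rng.normal(0, 0.08, len(doys)),
                                  "pregnant": preg}))
    daily = pd.concat(rows, ignore_index=True)
    fit = fit_annual_model(daily, "mean_tb", k=40)
    dc = difference_curve(fit)
    i = int(np.argmin(dc.estimate))
    assert dc.estimate[i] == pytest.approx(-0.5, abs=0.15)
    sig = set(dc.significant_days.astype(int).tolist())
    true = set(range(15, 61))
    assert len(sig & true) / len(sig | true) >= 0.6


def test_null_difference_ci_covers_zero():
    """Identical groups: pointwise 95% CI contains zero on nearly all days,
    across replicates."""
    rng = np.random.default_rng(11)
    frac_covered = []
    for rep in range(30):
        rows = []
        for a in range(4):
            doys = np.arange(1.0, 366.0, 2.0)
            mu = 38.5 + 0.1 * np.sin(2 * np.pi * doys / 366)
            rows.append(pd.DataFrame({
                "animal_id": f"W{a}", "doy": doys,
                "mean_tb": mu + rng.normal(0, 0.1, len(doys)),
                "pregnant": int(a < 2)}))
        daily = pd.concat(rows, ignore_index=True)
        fit = fit_annual_model(daily, "mean_tb", k=12, use_ar1=False)
        dc = difference_curve(fit)
        frac_covered.append(1.0 - dc.significant.mean())
    assert np.mean(frac_covered) >= 0.90


def test_smoothing_limit_tends_to_linear():
    """Penalty -> infinity forces the smooth into its null space."""
    rng = np.random.default_rng(2)
    doys = np.arange(1.0, 366.0)
    y = 38.5 + np.sin(2 * np.pi * doys / 366) + rng.normal(0, 0.05, len(doys))
    basis = build_basis(10, 1.0, 366.0, False)
    B = basis.design(doys)
    Bc = B - B.mean(axis=0)
    X = np.hstack([np.ones((len(doys), 1)), Bc])
    S = np.zeros((X.shape[1], X.shape[1]))
    S[1:, 1:] = basis.penalty
    fitted_big = X @ np.linalg.solve(X.T @ X + 1e12 * S, X.T @ y)
    # a huge penalty leaves at most a straight line in DOY
    coef = np.polyfit(doys, fitted_big, 1)
    assert np.allclose(fitted_big, np.polyval(coef, doys), atol=1e-2)
    fitted_small = X @ np.linalg.solve(X.T @ X + 1e-8 * S, X.T @ y)
    # deviance is monotone in the smoothing parameter
    assert np.sum((y - fitted_small) ** 2) < np.sum((y - fitted_big) ** 2)


def test_single_class_warns_and_drops_state_terms():
    daily = _daily(pregnant=lambda a: 1)
    with pytest.warns(UserWarning, match="one reproductive class"):
        fit = fit_annual_model(daily, "mean_tb", k=10, use_ar1=False)
    assert not fit.has_state_terms


# --- binomial --------------------------------------------------------------

def test_binomial_all_ones_is_near_one():
    df = pd.DataFrame({"animal_id": "W0",
                       "doy": np.arange(1.0, 366.0),
                       "present": 1})
    with pytest.warns(UserWarning, match="single class"):
        fit = fit_binomial_curve(df, "present", k=8)
    pc = predict_curve(fit, np.arange(1.0, 367.0))
    assert (pc["estimate"] > 0.95).all()


def test_binomial_sinusoidal_probability_recovery():
    rng = np.random.default_rng(0)
    doys = np.tile(np.arange(1.0, 366.0), 10)
    animals = np.repeat([f"W{i:02d}" for i in range(10)], 365)
    p = 0.4 + 0.25 * np.sin(2 * np.pi * doys / 366)
    df = pd.DataFrame({"animal_id": animals, "doy": doys,
                       "present": rng.binomial(1, p)})
    fit = fit_binomial_curve(df, "present", k=20)
    grid = np.arange(1.0, 367.0)
    pc = predict_curve(fit, grid)
    i = int(pc["estimate"].idxmax())
    assert abs(grid[i] - 366 / 4) <= 30
    assert pc["estimate"].max() == pytest.approx(0.65, abs=0.1)


def test_binomial_constant_half():
    rng = np.random.default_rng(1)
    doys = np.tile(np.arange(1.0, 366.0), 6)
    animals = np.repeat([f"W{i}" for i in range(6)], 365)
    df = pd.DataFrame({"animal_id": animals, "doy": doys,
                       "present": rng.binomial(1, 0.5, len(doys))})
    fit = fit_binomial_curve(df, "present", k=15)
    pc = predict_curve(fit, np.arange(1.0, 367.0))
    assert pc["estimate"].between(0.4, 0.6).all()
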