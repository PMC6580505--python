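"""Penalized-spline annual models with reproductive-state difference curves.

The model for a daily response y (daily mean T_b, or daily max - min):

    y_it = alpha + f(DOY_t) + pregnant_i * [delta + d(DOY_t)]
           + b0_i + b1_i * DOY_t + e_it,    e_it ~ AR1(rho)

with f a cyclic penalized cubic spline (the reference annual curve), the
ordered-factor offset delta plus difference smooth d giving the pregnant
deviation, and per-animal random intercepts/slopes as ridge-penalized
terms. Smoothing parameters are chosen by GCV; the AR1 error structure is
handled by iterated Cochrane-Orcutt pre-whitening within animal. This is a
deliberate, documented approximation of a full mixed-model GAMM: it keeps
the inferential structure (smooth + factor-smooth difference + pointwise
CI exclusion) at tractable complexity.

The binomial variant (rhythm-probability curves) uses the same design
without the state terms, fitted by penalized IRLS with a logit link and no
AR1 term.

Confidence bands use the penalty-informed (Bayesian) posterior covariance
sigma^2 (X'X + S_lambda)^-1 and normal quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .splines import SplineBasis, build_basis

DOY_DOMAIN = (1.0, 366.0)  # cyclic with period 365: DOY 366 wraps onto DOY 1
_LAMBDA_GRID = 10.0 ** np.arange(-4.0, 6.5, 0.5)


@dataclass
class SmoothFit:
    """Fitted penalized-spline model (gaussian or binomial)."""

    response: str  # "gaussian" | "binomial"
    basis: SplineBasis
    beta: np.ndarray
    cov: np.ndarray  # Bayesian posterior covariance of beta
    slices: dict[str, slice]
    centers: dict[str, np.ndarray]
    lambdas: dict[str, float]
    sigma2: float
    ar1_rho: float
    n_obs: int
    deviance: float
    edf: float
    animal_ids: tuple[str, ...] = ()
    has_state_terms: bool = True


@dataclass
class DifferenceCurve:
    """Pregnant-minus-reference curve with pointwise 95% band."""

    doy: np.ndarray
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # bool: CI excludes zero

    @property
    def significant_days(self) -> np.ndarray:
        return self.doy[self.significant]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _doy_scaled(doy: np.ndarray) -> np.ndarray:
    return (np.asarray(doy, dtype=float) - 183.0) / 183.0


def _build_design(doy: np.ndarray, pregnant: np.ndarray | None,
                  animal: np.ndarray, basis: SplineBasis
                  ) -> tuple[np.ndarray, list[np.ndarray], dict[str, slice],
                             dict[str, np.ndarray], tuple[str, ...]]:
    n = len(doy)
    B = basis.design(doy)
    cm = B.mean(axis=0)
    Xm = B - cm

    blocks = [np.ones((n, 1))]
    slices = {"intercept": slice(0, 1)}
    pos = 1
    centers = {"main": cm}

    has_state = pregnant is not None and pregnant.any() and not pregnant.all()
    if pregnant is not None and not has_state and pregnant.any():
        warnings.warn("only one reproductive class present; "
                      "state terms dropped")
    if has_state:
        blocks.append(pregnant[:, None].astype(float))
        slices["state"] = slice(pos, pos + 1)
        pos += 1

    blocks.append(Xm)
    slices["main"] = slice(pos, pos + basis.k)
    pos += basis.k

    if has_state:
        cd = B[pregnant.astype(bool)].mean(axis=0)
        Xd = (B - cd) * pregnant[:, None]
        blocks.append(Xd)
        slices["diff"] = slice(pos, pos + basis.k)
        pos += basis.k
        centers["diff"] = cd

    ids = tuple(sorted(set(animal)))
    Zi = np.zeros((n, len(ids)))
    Zs = np.zeros((n, len(ids)))
    ds = _doy_scaled(doy)
    for j, a in enumerate(ids):
        m = animal == a
        Zi[m, j] = 1.0
        Zs[m, j] = ds[m]
    blocks.extend([Zi, Zs])
    slices["rand_int"] = slice(pos, pos + len(ids))
    pos += len(ids)
    slices["rand_slope"] = slice(pos, pos + len(ids))
    pos += len(ids)

    X = np.hstack(blocks)
    penalties = []
    S_main = np.zeros((pos, pos))
    S_main[slices["main"], slices["main"]] = basis.penalty
    penalties.append(S_main)
    if has_state:
        S_diff = np.zeros((pos, pos))
        S_diff[slices["diff"], slices["diff"]] = basis.penalty
        penalties.append(S_diff)
    S_re = np.zeros((pos, pos))
    S_re[slices["rand_int"], slices["rand_int"]] = np.eye(len(ids))
    S_re[slices["rand_slope"], slices["rand_slope"]] = np.eye(len(ids))
    penalties.append(S_re)
    return X, penalties, slices, centers, ids


# ---------------------------------------------------------------------------
# gaussian fit with GCV and AR1 pre-whitening
# ---------------------------------------------------------------------------

def _gcv_select(XtX: np.ndarray, Xty: np.ndarray, yty: float, n: int,
                penalties: list[np.ndarray],
                lam0: np.ndarray | None = None,
                gamma: float = 1.4
                ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Coordinate-descent GCV over a log-spaced lambda grid.

    ``gamma`` inflates each effective degree of freedom in the GCV score
    (the standard guard against GCV undersmoothing). Returns
    (lambdas, beta, edf, rss)."""
    m = len(penalties)
    lam = np.ones(m) if lam0 is None else lam0.copy()

    def solve(lams: np.ndarray) -> tuple[np.ndarray, float, float]:
        A = XtX + sum(l * S for l, S in zip(lams, penalties))
        beta = np.linalg.solve(A, Xty)
        rss = yty - 2 * beta @ Xty + beta @ XtX @ beta
        edf = float(np.trace(np.linalg.solve(A, XtX)))
        return beta, edf, max(rss, 1e-12)

    best = None
    for _ in range(3):  # coordinate passes
        improved = False
        for j in range(m):
            for cand in _LAMBDA_GRID:
                trial = lam.copy()
                trial[j] = cand
                beta, edf, rss = solve(trial)
                denom = max(n - gamma * edf, 1.0)
                gcv = n * rss / denom ** 2
                if best is None or gcv < best[0] - 1e-12:
                    best = (gcv, trial.copy(), beta, edf, rss)
                    improved = True
            lam = best[1].copy()
        if not improved:
            break
    _, lam, beta, edf, rss = best
    return lam, beta, edf, rss


def _ar1_whiten(X: np.ndarray, y: np.ndarray, animal: np.ndarray,
                doy: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Cochrane-Orcutt transform within contiguous day runs per animal."""
    Xw = X.copy()
    yw = y.copy()
    c = np.sqrt(1.0 - rho * rho)
    order = np.lexsort((doy, animal))
    Xs, ys = X[order], y[order]
    an, dy = animal[order], doy[order]
    new_run = np.ones(len(ys), dtype=bool)
    new_run[1:] = (an[1:] != an[:-1]) | (dy[1:] != dy[:-1] + 1)
    Xt = np.where(new_run[:, None], c * Xs, Xs - rho * np.vstack([Xs[:1], Xs[:-1]]))
    yt = np.where(new_run, c * ys, ys - rho * np.concatenate([ys[:1], ys[:-1]]))
    Xw[order] = Xt
    yw[order] = yt
    return Xw, yw


def _lag1_autocorr(resid: np.ndarray, animal: np.ndarray,
                   doy: np.ndarray, detrend_days: int = 31) -> float:
    """Lag-1 autocorrelation of within-animal residuals.

    Residuals are detrended per animal with a centred running mean first:
    slow smooth misfit (e.g. individual gestation timing the population
    curve cannot absorb) would otherwise masquerade as a large AR1
    coefficient and over-whiten the fit.
    """
    order = np.lexsort((doy, animal))
    r, an, dy = resid[order].copy(), animal[order], doy[order]
    for a in np.unique(an):
        m = an == a
        x = r[m]
        if len(x) > detrend_days:
            kernel = np.ones(detrend_days) / detrend_days
            trend = np.convolve(x, kernel, mode="same")
            # renormalize the edges of the moving average
            norm = np.convolve(np.ones_like(x), kernel, mode="same")
            r[m] = x - trend / norm
    adj = (an[1:] == an[:-1]) & (dy[1:] == dy[:-1] + 1)
    num = float(np.sum(r[1:][adj] * r[:-1][adj]))
    den = float(np.sum(r[:-1][adj] ** 2))
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, -0.98, 0.98))


def fit_annual_model(daily: pd.DataFrame, response: str,
                     state_col: str = "pregnant", k: int = 40,
                     cyclic: bool = True, use_ar1: bool = True,
                     max_ar1_iter: int = 20) -> SmoothFit:
    """Fit the annual smooth model to a daily-summary table.

    ``daily`` needs columns animal_id, doy, the response column, and a 0/1
    ``state_col`` marking pregnant animal-days. Excluded days must already
    be dropped (for daily_variation, also imputed days).
    """
    df = daily.dropna(subset=[response]).copy()
    if df["animal_id"].nunique() < 2:
        warnings.warn("fewer than 2 animals; random-effect terms are weakly "
                      "identified")
    doy = df["doy"].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    animal = df["animal_id"].to_numpy()
    pregnant = (df[state_col].to_numpy(dtype=float)
                if state_col in df.columns else None)

    basis = build_basis(k, *DOY_DOMAIN, cyclic=cyclic)
    X, penalties, slices, centers, ids = _build_design(doy, pregnant,
                                                       animal, basis)
    n = len(y)

    rho = 0.0
    lam = None
    for _ in range(max_ar1_iter if use_ar1 else 1):
        Xw, yw = (_ar1_whiten(X, y, animal, doy, rho) if rho != 0.0
                  else (X, y))
        XtX = Xw.T @ Xw
        Xty = Xw.T @ yw
        yty = float(yw @ yw)
        lam, beta, edf, rss = _gcv_select(XtX, Xty, yty, n, penalties,
                                          lam0=lam)
        if not use_ar1:
            break
        resid = y - X @ beta
        rho_new = _lag1_autocorr(resid, animal, doy)
        if abs(rho_new - rho) < 1e-4:
            rho = rho_new
            break
        rho = rho_new

    Xw, yw = (_ar1_whiten(X, y, animal, doy, rho) if rho != 0.0 else (X, y))
    A = Xw.T @ Xw + sum(l * S for l, S in zip(lam, penalties))
    beta = np.linalg.solve(A, Xw.T @ yw)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    edf = float(np.trace(np.linalg.solve(A, Xw.T @ Xw)))
    sigma2 = rss / max(n - edf, 1.0)
    cov = sigma2 * np.linalg.inv(A)

    lam_names = (["main", "diff", "re"] if "diff" in slices
                 else ["main", "re"])
    return SmoothFit(
        response="gaussian", basis=basis, beta=beta, cov=cov, slices=slices,
        centers=centers, lambdas=dict(zip(lam_names, lam)), sigma2=sigma2,
        ar1_rho=rho, n_obs=n, deviance=rss, edf=edf, animal_ids=ids,
        has_state_terms="diff" in slices)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _rows_reference(fit: SmoothFit, doy: np.ndarray) -> np.ndarray:
    L = np.zeros((len(doy), len(fit.beta)))
    L[:, fit.slices["intercept"]] = 1.0
    L[:, fit.slices["main"]] = fit.basis.design(doy) - fit.centers["main"]
    return L


def _rows_difference(fit: SmoothFit, doy: np.ndarray) -> np.ndarray:
    if "diff" not in fit.slices:
        raise ValueError("fit has no state difference terms")
    L = np.zeros((len(doy), len(fit.beta)))
    L[:, fit.slices["state"]] = 1.0
    L[:, fit.slices["diff"]] = fit.basis.design(doy) - fit.centers["diff"]
    return L


def predict_curve(fit: SmoothFit, doy: np.ndarray, group: str = "reference",
                  alpha: float = 0.05) -> pd.DataFrame:
    """Population-level annual curve (random effects at zero) with CI.

    group="reference" gives the non-pregnant curve; group="pregnant" adds
    the state offset and difference smooth.
    """
    doy = np.asarray(doy, dtype=float)
    L = _rows_reference(fit, doy)
    if group == "pregnant":
        L = L + _rows_difference(fit, doy)
    est = L @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", L, fit.cov, L), 0.0))
    z = norm.ppf(1.0 - alpha / 2.0)
    out = pd.DataFrame({"doy": doy, "estimate": est,
                        "ci_low": est - z * se, "ci_high": est + z * se})
    if fit.response == "binomial":
        for c in ("estimate", "ci_low", "ci_high"):
            out[c] = expit(out[c])
    return out


def difference_curve(fit: SmoothFit, doy: np.ndarray | None = None,
                     alpha: float = 0.05) -> DifferenceCurve:
    """Pregnant-minus-reference curve; significant where the CI excludes 0."""
    if doy is None:
        doy = np.arange(1, 367, dtype=float)
    doy = np.asarray(doy, dtype=float)
    L = _rows_difference(fit, doy)
    est = L @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", L, fit.cov, L), 0.0))
    z = norm.ppf(1.0 - alpha / 2.0)
    lo, hi = est - z * se, est + z * se
    return DifferenceCurve(doy, est, lo, hi, (lo > 0.0) | (hi < 0.0))


# ---------------------------------------------------------------------------
# binomial variant (rhythm probability curves)
# ---------------------------------------------------------------------------

_BINOM_LAM_MAIN = 10.0 ** np.arange(-2.0, 5.0)
_BINOM_LAM_RE = np.array([1.0, 10.0, 100.0])


def fit_binomial_curve(daily_binary: pd.DataFrame, outcome: str = "present",
                       k: int = 20, cyclic: bool = True) -> SmoothFit:
    """Penalized logistic fit of a 0/1 daily outcome on a cyclic DOY smooth
    with per-animal random intercept and slope; no AR1 term.

    ``daily_binary`` needs columns animal_id, doy and the outcome column.
    """
    df = daily_binary.dropna(subset=[outcome]).copy()
    doy = df["doy"].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    animal = df["animal_id"].to_numpy()
    if y.min() == y.max():
        warnings.warn("outcome has a single class; curve will be flat at "
                      "the observed rate")
    basis = build_basis(k, *DOY_DOMAIN, cyclic=cyclic)
    X, penalties, slices, centers, ids = _build_design(doy, None, animal,
                                                       basis)
    n = len(y)

    best = None
    for lm in _BINOM_LAM_MAIN:
        for lre in _BINOM_LAM_RE:
            lam = np.array([lm, lre])
            beta, dev, edf, A, ok = _pirls(X, y, penalties, lam)
            if not ok:
                continue
            gcv = n * dev / max(n - 1.4 * edf, 1.0) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lam, beta, dev, edf, A)
    if best is None:
        raise RuntimeError("binomial fit failed for all smoothing values")
    _, lam, beta, dev, edf, A = best
    cov = np.linalg.inv(A)  # phi = 1 for binomial

    return SmoothFit(
        response="binomial", basis=basis, beta=beta, cov=cov, slices=slices,
        centers=centers, lambdas={"main": lam[0], "re": lam[1]}, sigma2=1.0,
        ar1_rho=0.0, n_obs=n, deviance=dev, edf=edf, animal_ids=ids,
        has_state_terms=False)


def _pirls(X: np.ndarray, y: np.ndarray, penalties: list[np.ndarray],
           lam: np.ndarray, max_iter: int = 60, tol: float = 1e-7
           ) -> tuple[np.ndarray, float, float, np.ndarray, bool]:
    """Penalized IRLS for the logit link. Returns (beta, deviance, edf,
    penalized information matrix, converged)."""
    S = sum(l * P for l, P in zip(lam, penalties))
    beta = np.zeros(X.shape[1])
    beta[0] = np.log((y.mean() + 1e-3) / (1 - y.mean() + 1e-3))
    dev_old = np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -15.0, 15.0)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-8)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        A = X.T @ Xw + S
        try:
            beta = np.linalg.solve(A, Xw.T @ z)
        except np.linalg.LinAlgError:
            return beta, np.inf, 0.0, A, False
        mu_new = expit(np.clip(X @ beta, -15.0, 15.0))
        mu_new = np.clip(mu_new, 1e-10, 1 - 1e-10)
        dev = -2.0 * float(np.sum(y * np.log(mu_new)
                                  + (1 - y) * np.log(1 - mu_new)))
        if abs(dev - dev_old) < tol * (abs(dev) + 1e-3):
            dev_old = dev
            break
        dev_old = dev
    eta = np.clip(X @ beta, -15.0, 15.0)
    w = np.maximum(expit(eta) * (1 - expit(eta)), 1e-8)
    Xw = X * w[:, None]
    A = X.T @ Xw + S
    edf = float(np.trace(np.linalg.solve(A, X.T @ Xw)))
    return beta, dev_old, edf, A, True


def curves_frame(fits: dict[str, SmoothFit],
                 doy: np.ndarray | None = None) -> pd.DataFrame:
    """Stack reference/pregnant/difference curves of several fits into the
    curves.csv layout: model, group, doy, estimate, ci_low, ci_high,
    significant."""
    if doy is None:
        doy = np.arange(1, 367, dtype=float)
    rows = []
    for name, fit in fits.items():
        ref = predict_curve(fit, doy)
        ref.insert(0, "group", "reference")
        ref.insert(0, "model", name)
        ref["significant"] = 0
        rows.append(ref)
        if fit.has_state_terms:
            prg = predict_curve(fit, doy, group="pregnant")
            prg.insert(0, "group", "pregnant")
            prg.insert(0, "model", name)
            prg["significant"] = 0
            rows.append(prg)
            dc = difference_curve(fit, doy)
            dd = pd.DataFrame({"model": name, "group": "difference",
                               "doy": dc.doy, "estimate": dc.estimate,
                               "ci_low": dc.ci_low, "ci_high": dc.ci_high,
                               "significant": dc.significant.astype(int)})
            rows.append(dd)
    return pd.concat(rows, ignore_index=True)
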