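"""Comparison regression algorithms behind a single predictor contract.

The benchmark pits the fractional-polynomial model against the algorithms a
normative-modelling practitioner would otherwise reach for: ordinary least
squares, Bayesian linear regression (conjugate Gaussian prior, optionally
evidence-maximised), Gaussian-process regression with an RBF kernel and a
median-heuristic width, and a simplified LMS model in which the outcome
follows the Box-Cox Cole-Green (BCCG) distribution with median mu(age),
relative dispersion sigma(age) and Box-Cox power nu.

All predictors expose ``fit``/``predict`` with identical shapes so the
cross-validation harness never special-cases an algorithm; an ``external``
adapter registers any pre-fitted model (e.g. toolkit-based warped or
hierarchical Bayesian regressions) into the same benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import linalg as sla
from scipy import optimize
from sklearn.linear_model import BayesianRidge

__all__ = [
    "PredictorModel",
    "fit_olsr",
    "fit_blr",
    "fit_gpr",
    "fit_lms",
    "ExternalPredictor",
    "BCCGParams",
    "bccg_zscores",
]


@dataclass
class PredictorModel:
    """A fitted predictor: deterministic point predictions for new rows."""

    kind: str
    predict: Callable[[np.ndarray], np.ndarray]
    state: dict


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def fit_olsr(y, X) -> PredictorModel:
    """Ordinary least squares with intercept; errors on rank deficiency."""
    y = np.asarray(y, dtype=float)
    X = _as_2d(X)
    design = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design in OLSR")

    def predict(Xnew):
        Xnew = _as_2d(Xnew)
        return np.column_stack([np.ones(len(Xnew)), Xnew]) @ coef

    return PredictorModel("OLSR", predict, {"coef": coef})


def fit_blr(
    y,
    X,
    prior_precision: float | None = None,
    noise_precision: float | None = None,
) -> PredictorModel:
    """Bayesian linear regression with a zero-mean Gaussian coefficient prior.

    With both precisions given, the posterior mean is the ridge solution
    with penalty ratio ``lambda = prior_precision / noise_precision``
    (intercept unpenalised, handled by centring).  With precisions unset,
    they are evidence-maximised (empirical Bayes) via
    :class:`sklearn.linear_model.BayesianRidge`.
    """
    y = np.asarray(y, dtype=float)
    X = _as_2d(X)
    if (prior_precision is None) != (noise_precision is None):
        raise ValueError("set both precisions or neither")
    if prior_precision is not None:
        if prior_precision < 0 or noise_precision <= 0:
            raise ValueError("precisions must be positive (prior may be 0)")
        lam = prior_precision / noise_precision
        x_mean = X.mean(axis=0)
        y_mean = float(y.mean())
        Xc = X - x_mean
        yc = y - y_mean
        A = Xc.T @ Xc + lam * np.eye(X.shape[1])
        coef = np.linalg.solve(A, Xc.T @ yc)
        intercept = y_mean - x_mean @ coef

        def predict(Xnew):
            return _as_2d(Xnew) @ coef + intercept

        return PredictorModel(
            "BLR", predict, {"coef": coef, "intercept": intercept, "lambda": lam}
        )

    est = BayesianRidge(fit_intercept=True)
    est.fit(X, y)

    def predict(Xnew):
        return est.predict(_as_2d(Xnew))

    return PredictorModel(
        "BLR",
        predict,
        {"coef": est.coef_, "intercept": est.intercept_,
         "alpha": est.alpha_, "lambda": est.lambda_},
    )


def _median_sq_dist(X: np.ndarray, rng: np.random.Generator, max_pairs: int = 5000):
    n = len(X)
    if n * (n - 1) // 2 <= max_pairs:  # small n: all distinct pairs exactly
        iu, ju = np.triu_indices(n, k=1)
        d2 = np.sum((X[iu] - X[ju]) ** 2, axis=1)
    else:
        i = rng.integers(0, n, size=2 * max_pairs)
        j = rng.integers(0, n, size=2 * max_pairs)
        keep = i != j
        d2 = np.sum((X[i[keep]][:max_pairs] - X[j[keep]][:max_pairs]) ** 2, axis=1)
    return float(np.median(d2))


def fit_gpr(
    y,
    X,
    kernel_width: float | str = "auto",
    noise: float = 1e-6,
    max_n: int = 10_000,
    seed: int = 0,
) -> PredictorModel:
    """Gaussian-process regression, exact dense solve with an RBF kernel.

    The inverse width ``gamma = 1 / (2 * q_med)`` comes from the median of
    squared pairwise distances over at most 5000 sampled pairs (the midpoint
    of the usual 0.1-0.9 quantile heuristic).  ``noise`` is the diagonal
    jitter; a singular kernel matrix raises with instructions to increase
    it.  Inputs are standardised internally.
    """
    y = np.asarray(y, dtype=float)
    X = _as_2d(X)
    n = len(y)
    if n > max_n:
        raise ValueError(f"GPR exact solve capped at n={max_n}, got {n}")
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Xs = (X - x_mean) / x_sd
    y_mean = float(y.mean())
    yc = y - y_mean

    if kernel_width == "auto":
        rng = np.random.default_rng(seed)
        q_med = _median_sq_dist(Xs, rng)
        gamma = 1.0 / (2.0 * q_med) if q_med > 0 else 1.0
    else:
        gamma = 1.0 / (2.0 * float(kernel_width) ** 2)

    d2 = (
        np.sum(Xs**2, axis=1)[:, None]
        + np.sum(Xs**2, axis=1)[None, :]
        - 2.0 * Xs @ Xs.T
    )
    K = np.exp(-gamma * np.maximum(d2, 0.0))
    try:
        cho = sla.cho_factor(K + noise * np.eye(n), lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"kernel matrix singular at jitter {noise}; increase the `noise` "
            "argument"
        ) from exc
    alpha = sla.cho_solve(cho, yc)

    def predict(Xnew):
        Xn = (_as_2d(Xnew) - x_mean) / x_sd
        d2n = (
            np.sum(Xn**2, axis=1)[:, None]
            + np.sum(Xs**2, axis=1)[None, :]
            - 2.0 * Xn @ Xs.T
        )
        Kn = np.exp(-gamma * np.maximum(d2n, 0.0))
        return Kn @ alpha + y_mean

    return PredictorModel("GPR", predict, {"gamma": gamma, "noise": noise})


# ---------------------------------------------------------------------------
# simplified LMS (BCCG) model


@dataclass
class BCCGParams:
    """BCCG parameter curves over age: median mu, dispersion sigma, power nu.

    mu and log-sigma are polynomial functions of standardised age
    (``basis_df`` coefficients each); nu is a constant.  mu(age) and
    sigma(age) must stay positive over the training range.
    """

    mu_coef: np.ndarray
    log_sigma_coef: np.ndarray
    nu: float
    age_center: float
    age_scale: float
    mu_df: int
    sigma_df: int

    def _basis(self, age: np.ndarray, df: int) -> np.ndarray:
        z = (np.asarray(age, dtype=float) - self.age_center) / self.age_scale
        return np.column_stack([z**k for k in range(df)])

    def mu(self, age) -> np.ndarray:
        return self._basis(age, self.mu_df) @ self.mu_coef

    def sigma(self, age) -> np.ndarray:
        return np.exp(self._basis(age, self.sigma_df) @ self.log_sigma_coef)


def bccg_zscores(y, age, params: BCCGParams) -> np.ndarray:
    """Box-Cox z-transform of observations under fitted BCCG parameters."""
    y = np.asarray(y, dtype=float)
    mu = params.mu(age)
    sigma = params.sigma(age)
    nu = params.nu
    if abs(nu) < 1e-10:
        return np.log(y / mu) / sigma
    return ((y / mu) ** nu - 1.0) / (nu * sigma)


def _bccg_negloglik(theta, y, lny, Bmu, Bsig, mu_df, sigma_df):
    mu = Bmu @ theta[:mu_df]
    if np.any(mu <= 0):
        return 1e12
    log_sigma = Bsig @ theta[mu_df : mu_df + sigma_df]
    if np.any(np.abs(log_sigma) > 20):
        return 1e12
    sigma = np.exp(log_sigma)
    nu = theta[-1]
    lnr = lny - np.log(mu)
    if abs(nu) < 1e-10:
        z = lnr / sigma
    else:
        z = (np.exp(nu * lnr) - 1.0) / (nu * sigma)
    # BCCG log-density without the positivity-truncation correction
    ll = (nu - 1.0) * lnr - log_sigma - 0.5 * z**2 - np.log(mu)
    out = -float(np.sum(ll))
    return out if np.isfinite(out) else 1e12


def fit_lms(
    y,
    age,
    mu_df: int = 5,
    sigma_df: int = 3,
    fix_nu: float | None = None,
) -> PredictorModel:
    """Fit the simplified LMS (BCCG) model by maximum likelihood.

    mu(age) uses a polynomial basis with ``mu_df`` coefficients, log
    sigma(age) with ``sigma_df``, nu is a constant (optionally fixed).
    Optimisation is Nelder-Mead-free: BFGS from a moment-based start
    (mu from a least-squares fit of y on the age basis, sigma from the
    relative residual SD, nu from 1).  Point prediction is the fitted
    median mu(age).  Only age is accommodated as a covariate.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(y <= 0):
        raise ValueError("BCCG requires strictly positive outcomes")
    center = float(age.mean())
    scale = float(age.std()) or 1.0
    z = (age - center) / scale
    # collapse the basis when age is (nearly) constant
    if float(age.std()) < 1e-12:
        mu_df_eff, sigma_df_eff = 1, 1
    else:
        mu_df_eff, sigma_df_eff = mu_df, sigma_df
    Bmu = np.column_stack([z**k for k in range(mu_df_eff)])
    Bsig = np.column_stack([z**k for k in range(sigma_df_eff)])

    # moment start
    mu0, *_ = np.linalg.lstsq(Bmu, y, rcond=None)
    resid = y - Bmu @ mu0
    rel_sd = float(np.std(resid) / np.mean(y))
    rel_sd = min(max(rel_sd, 1e-4), 2.0)
    sig0 = np.zeros(sigma_df_eff)
    sig0[0] = np.log(rel_sd)
    nu0 = 1.0 if fix_nu is None else fix_nu
    theta0 = np.concatenate([mu0, sig0, [nu0]])

    lny = np.log(y)

    if fix_nu is None:
        def objective(theta):
            return _bccg_negloglik(theta, y, lny, Bmu, Bsig, mu_df_eff, sigma_df_eff)
        free0 = theta0
    else:
        def objective(theta_free):
            theta = np.concatenate([theta_free, [fix_nu]])
            return _bccg_negloglik(theta, y, lny, Bmu, Bsig, mu_df_eff, sigma_df_eff)
        free0 = theta0[:-1]

    start_nll = objective(free0)
    res = optimize.minimize(objective, free0, method="BFGS",
                            options={"maxiter": 2000})
    if not np.isfinite(res.fun) or res.fun > start_nll + 1e-6:
        raise RuntimeError(
            f"BCCG optimiser failed: start NLL {start_nll:.6g}, "
            f"end NLL {res.fun:.6g} ({res.message})"
        )
    theta = res.x if fix_nu is None else np.concatenate([res.x, [fix_nu]])
    params = BCCGParams(
        mu_coef=theta[:mu_df_eff],
        log_sigma_coef=theta[mu_df_eff : mu_df_eff + sigma_df_eff],
        nu=float(theta[-1]),
        age_center=center,
        age_scale=scale,
        mu_df=mu_df_eff,
        sigma_df=sigma_df_eff,
    )

    def predict(age_new):
        age_new = np.asarray(age_new, dtype=float)
        if age_new.ndim == 2:  # harness passes a design matrix; age is col 0
            age_new = age_new[:, 0]
        return params.mu(age_new)

    return PredictorModel("LMS", predict, {"params": params, "nll": float(res.fun)})


def ExternalPredictor(name: str, predict_fn) -> PredictorModel:
    """Adapter registering an externally fitted model into the benchmark."""
    return PredictorModel("external", predict_fn, {"name": name})
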