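"""Elastic-net penalized logistic regression with a nonzero-coefficient cap.

Minimizes the penalized negative Bernoulli log-likelihood

    L(beta) = (1/N) sum_i [-y_i log p_i - (1-y_i) log(1-p_i)]
              + lambda * (alpha * ||beta||_1 + (1-alpha)/2 * ||beta||_2^2)

by cyclic coordinate descent on the local quadratic (IRLS) approximation,
glmnet-style: alpha=1 is the lasso, alpha=0 ridge.  The intercept is
unpenalized.  Features are standardized to zero mean / unit variance
inside ``fit`` and coefficients are reported on the standardized scale.

The regularization path is walked from the largest lambda (all
coefficients zero) downward and stops before the number of nonzero
coefficients would exceed ``max_nonzero``; among admissible path points
the one with the best (lowest) training deviance is returned.  Each IRLS
step is safeguarded by halving toward the previous iterate whenever the
true objective would increase, so the recorded objective trajectory is
non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import expit

from .config import FitConfig
from .io import FeatureMatrix

__all__ = [
    "ElasticNetModel",
    "ConvergenceError",
    "fit",
    "fit_single",
    "predict_proba",
    "selected_features",
    "lambda_grid",
    "objective_value",
]


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to reach tolerance; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class ElasticNetModel:
    """Fitted model: intercept + sparse coefficients on the standardized scale."""

    intercept: float
    coef: np.ndarray
    lambda_: float
    alpha: float
    feature_ids: list[str]
    means: np.ndarray
    scales: np.ndarray
    path: dict = field(default_factory=dict)

    @property
    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.coef))


@njit(cache=True)
def _objective_nb(X, y, b0, beta, lam, alpha):
    n = X.shape[0]
    nll = 0.0
    for i in range(n):
        eta = b0
        for j in range(X.shape[1]):
            eta += X[i, j] * beta[j]
        # log(1 + exp(eta)) - y*eta, computed stably
        if eta > 0:
            nll += eta + np.log1p(np.exp(-eta)) - y[i] * eta
        else:
            nll += np.log1p(np.exp(eta)) - y[i] * eta
    nll /= n
    l1 = 0.0
    l2 = 0.0
    for j in range(beta.shape[0]):
        l1 += abs(beta[j])
        l2 += beta[j] * beta[j]
    return nll + lam * (alpha * l1 + 0.5 * (1.0 - alpha) * l2)


@njit(cache=True)
def _cd_quadratic_nb(X, w, z, b0, beta, l1, l2, tol, max_sweeps):
    """Cyclic coordinate descent on the weighted penalized least squares
    (1/(2N)) sum_i w_i (z_i - b0 - x_i beta)^2 + l1 ||beta||_1 + (l2/2)||beta||_2^2."""
    n, d = X.shape
    r = np.empty(n)
    for i in range(n):
        eta = b0
        for j in range(d):
            eta += X[i, j] * beta[j]
        r[i] = z[i] - eta
    wsum = 0.0
    for i in range(n):
        wsum += w[i]
    xwx = np.empty(d)
    for j in range(d):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        xwx[j] = s / n
    for _ in range(max_sweeps):
        maxdelta = 0.0
        num = 0.0
        for i in range(n):
            num += w[i] * r[i]
        d0 = num / wsum
        b0 += d0
        for i in range(n):
            r[i] -= d0
        if abs(d0) > maxdelta:
            maxdelta = abs(d0)
        for j in range(d):
            bj = beta[j]
            g = 0.0
            for i in range(n):
                g += w[i] * X[i, j] * r[i]
            g = g / n + xwx[j] * bj
            denom = xwx[j] + l2
            if g > l1:
                bnew = (g - l1) / denom
            elif g < -l1:
                bnew = (g + l1) / denom
            else:
                bnew = 0.0
            diff = bnew - bj
            if diff != 0.0:
                beta[j] = bnew
                for i in range(n):
                    r[i] -= diff * X[i, j]
                if abs(diff) > maxdelta:
                    maxdelta = abs(diff)
        if maxdelta < tol:
            break
    return b0


@njit(cache=True)
def _irls_nb(X, y, lam, alpha, b0, beta, tol, max_iter, max_sweeps):
    """IRLS with monotone-objective safeguard; mutates beta, returns (b0, converged)."""
    n, d = X.shape
    obj = _objective_nb(X, y, b0, beta, lam, alpha)
    eta = np.empty(n)
    w = np.empty(n)
    z = np.empty(n)
    beta_old = np.empty(d)
    beta_cd = np.empty(d)
    for _ in range(max_iter):
        for i in range(n):
            e = b0
            for j in range(d):
                e += X[i, j] * beta[j]
            eta[i] = e
            p = 1.0 / (1.0 + np.exp(-e))
            wi = p * (1.0 - p)
            if wi < 1e-5:
                wi = 1e-5
            w[i] = wi
            z[i] = e + (y[i] - p) / wi
        for j in range(d):
            beta_old[j] = beta[j]
        b0_old = b0
        b0 = _cd_quadratic_nb(X, w, z, b0, beta, lam * alpha, lam * (1.0 - alpha), tol, max_sweeps)
        for j in range(d):
            beta_cd[j] = beta[j]
        b0_cd = b0
        new_obj = _objective_nb(X, y, b0, beta, lam, alpha)
        t = 1.0
        while new_obj > obj + 1e-12 and t > 1e-10:
            t *= 0.5
            for j in range(d):
                beta[j] = beta_old[j] + t * (beta_cd[j] - beta_old[j])
            b0 = b0_old + t * (b0_cd - b0_old)
            new_obj = _objective_nb(X, y, b0, beta, lam, alpha)
        obj = new_obj
        maxdelta = abs(b0 - b0_old)
        for j in range(d):
            if abs(beta[j] - beta_old[j]) > maxdelta:
                maxdelta = abs(beta[j] - beta_old[j])
        if maxdelta < tol:
            return b0, True
    return b0, False


@njit(cache=True)
def _path_nb(X, y, lambdas, alpha, tol, max_iter, max_nonzero, max_sweeps):
    n, d = X.shape
    L = lambdas.shape[0]
    betas = np.zeros((L, d))
    b0s = np.zeros(L)
    devs = np.full(L, np.inf)
    nnzs = np.zeros(L, dtype=np.int64)
    oks = np.zeros(L, dtype=np.bool_)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(d)
    n_adm = 0
    for li in range(L):
        b0, ok = _irls_nb(X, y, lambdas[li], alpha, b0, beta, tol, max_iter, max_sweeps)
        nnz = 0
        for j in range(d):
            if beta[j] != 0.0:
                nnz += 1
        if nnz > max_nonzero:
            break
        betas[n_adm] = beta
        b0s[n_adm] = b0
        nnzs[n_adm] = nnz
        oks[n_adm] = ok
        devs[n_adm] = _objective_nb(X, y, b0, beta, 0.0, alpha)  # unpenalized deviance/2N scale
        n_adm += 1
    return betas, b0s, devs, nnzs, oks, n_adm


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    if np.any(scales == 0):
        bad = np.flatnonzero(scales == 0)
        raise ValueError(f"zero-variance feature column(s) {bad.tolist()}; drop before fitting")
    return np.ascontiguousarray((X - means) / scales), means, scales


def lambda_grid(Xs: np.ndarray, y: np.ndarray, config: FitConfig) -> np.ndarray:
    """Decreasing log-spaced grid from the smallest all-zero lambda."""
    n = len(y)
    alpha_eff = max(config.alpha, 1e-3)
    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / (n * alpha_eff))
    lam_max = max(lam_max, 1e-12) * (1.0 + 1e-9)  # nudge past float ties at the top
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * config.lambda_min_ratio), config.n_lambda
    )


def objective_value(
    X: np.ndarray, y: np.ndarray, intercept: float, coef: np.ndarray, lam: float, alpha: float
) -> float:
    """Penalized negative log-likelihood L(beta) on given (already scaled) data."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    return float(_objective_nb(X, y, float(intercept), np.ascontiguousarray(coef, dtype=float), lam, alpha))


def fit(
    X: np.ndarray | FeatureMatrix,
    y: np.ndarray | None = None,
    config: FitConfig | None = None,
    feature_ids: list[str] | None = None,
    lambdas: np.ndarray | None = None,
) -> ElasticNetModel:
    """Fit the elastic net along the capped regularization path."""
    if isinstance(X, FeatureMatrix):
        feature_ids = list(X.feature_ids)
        if y is None:
            y = X.labels()
        X = X.values
    config = config or FitConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be n_samples x n_features matching y")
    classes = set(np.unique(y))
    if classes != {0.0, 1.0}:
        raise ValueError("y must contain both classes coded 0/1")
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least 2 samples per class")
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(X.shape[1])]
    Xs, means, scales = _standardize(X)
    if lambdas is None:
        lambdas = lambda_grid(Xs, y, config)
    lambdas = np.ascontiguousarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be decreasing")
    y = np.ascontiguousarray(y)
    betas, b0s, devs, nnzs, oks, n_adm = _path_nb(
        Xs, y, lambdas, config.alpha, config.tol, config.max_iter,
        config.max_nonzero, 10 * config.max_iter,
    )
    if n_adm == 0:
        raise ConvergenceError(
            "no admissible path point: the largest lambda already exceeds the coefficient cap",
            {"lambda_max": float(lambdas[0]), "max_nonzero": config.max_nonzero},
        )
    if not np.all(oks[:n_adm]):
        raise ConvergenceError(
            "coordinate descent did not converge at tolerance",
            {
                "tol": config.tol,
                "max_iter": config.max_iter,
                "failed_lambdas": lambdas[:n_adm][~oks[:n_adm]].tolist(),
            },
        )
    best = int(np.argmin(devs[:n_adm]))
    return ElasticNetModel(
        intercept=float(b0s[best]),
        coef=betas[best].copy(),
        lambda_=float(lambdas[best]),
        alpha=config.alpha,
        feature_ids=feature_ids,
        means=means,
        scales=scales,
        path={
            "lambdas": lambdas[:n_adm].tolist(),
            "nonzero": nnzs[:n_adm].tolist(),
            "deviance": devs[:n_adm].tolist(),
            "chosen": best,
        },
    )


def fit_single(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float = 0.5,
    tol: float = 1e-7,
    max_iter: int = 200,
    standardize: bool = True,
) -> tuple[float, np.ndarray, list[float]]:
    """Single-lambda fit returning (intercept, coef, objective trace).

    The trace holds the penalized objective after every IRLS step; the
    safeguarded updates make it non-increasing.  Used for objective-level
    diagnostics and oracle comparisons.
    """
    X = np.asarray(X, dtype=float)
    y = np.ascontiguousarray(np.asarray(y, dtype=float))
    if standardize:
        Xs, _, _ = _standardize(X)
    else:
        Xs = np.ascontiguousarray(X)
    n, d = Xs.shape
    ybar = y.mean()
    b0 = float(np.log(ybar / (1 - ybar)))
    beta = np.zeros(d)
    trace = [float(_objective_nb(Xs, y, b0, beta, lam, alpha))]
    for _ in range(max_iter):
        b0_prev, beta_prev = b0, beta.copy()
        b0, _ = _irls_nb(Xs, y, lam, alpha, b0, beta, tol, 1, 10 * max_iter)
        trace.append(float(_objective_nb(Xs, y, b0, beta, lam, alpha)))
        maxdelta = max(abs(b0 - b0_prev), float(np.max(np.abs(beta - beta_prev))) if d else 0.0)
        if maxdelta < tol:
            return b0, beta, trace
    raise ConvergenceError(
        "single-lambda fit did not converge", {"lam": lam, "trace_tail": trace[-5:]}
    )


def predict_proba(model: ElasticNetModel, X: np.ndarray | FeatureMatrix) -> np.ndarray:
    """Predicted probability of the positive (FRI) class."""
    if isinstance(X, FeatureMatrix):
        if list(X.feature_ids) != list(model.feature_ids):
            missing = set(model.feature_ids) - set(X.feature_ids)
            if missing:
                raise ValueError(f"feature matrix missing model features: {sorted(missing)[:5]}")
            idx = [X.feature_ids.index(f) for f in model.feature_ids]
            X = X.values[:, idx]
        else:
            X = X.values
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.feature_ids):
        raise ValueError("feature count does not match the fitted model")
    Xs = (X - model.means) / model.scales
    return expit(model.intercept + Xs @ model.coef)


def selected_features(model: ElasticNetModel) -> list[str]:
    """Ids of features with nonzero coefficients (embedded selection)."""
    return [f for f, b in zip(model.feature_ids, model.coef) if b != 0.0]
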