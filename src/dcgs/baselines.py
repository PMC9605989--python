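"""Reference genomic-prediction models.

Two statistical baselines — a ridge marker-effect model (the
posterior-mean equivalent of Bayesian ridge regression) and a
single-environment Gaussian-kernel genomic model — plus the usual
off-the-shelf machine-learning regressors.  The ridge/kernel penalty is
the REML-estimated variance ratio, so both are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .reml import reml_fit


@dataclass
class MarkerEffectModel:
    """y = mu + Z gamma with ridge-shrunk marker effects."""

    mu: float
    gamma: np.ndarray
    lam: float
    sigma2_g: float = float("nan")
    sigma2_e: float = float("nan")

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return self.mu + np.asarray(Z, float) @ self.gamma

    def to_dict(self) -> dict:
        return {"mu": self.mu, "lambda": self.lam, "gamma": self.gamma.tolist()}


@dataclass
class KernelModel:
    """Genomic model with a precomputed genetic covariance kernel."""

    mu: float
    alpha: np.ndarray        # (K + lam I)^{-1} (y - mu)
    u: np.ndarray            # fitted genetic effects K alpha
    lam: float
    train_Z: np.ndarray | None
    bandwidth: float | None

    def predict(self, Z_new: np.ndarray | None = None, k_new: np.ndarray | None = None) -> np.ndarray:
        """Predict from new genotype rows or a precomputed kernel block.

        ``k_new`` is the (n_new x n_train) kernel between new and training
        genotypes; if absent it is computed from ``Z_new`` with the stored
        bandwidth.
        """
        if k_new is None:
            if Z_new is None or self.train_Z is None or self.bandwidth is None:
                raise ValueError("need Z_new with stored training genotypes, or k_new")
            k_new = _cross_kernel(np.asarray(Z_new, float), self.train_Z, self.bandwidth)
        return self.mu + k_new @ self.alpha


def fit_ridge(
    Z: np.ndarray, y: np.ndarray, lam: float | None = None, fit_intercept: bool = True
) -> MarkerEffectModel:
    """Empirical-Bayes ridge: gamma = (Z'Z + lam I)^{-1} Z'(y - mu).

    ``lam = se2/sgamma2`` is estimated by REML on the equivalent
    random-effect model Var(y) = sgamma2 * ZZ' + se2 * I unless given.
    The intercept is the GLS mean (or pinned to 0 with
    ``fit_intercept=False``, mainly for closed-form checks).
    """
    Z = np.asarray(Z, float)
    y = np.asarray(y, float).ravel()
    n, p = Z.shape
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 and p >= 1")
    if fit_intercept:
        X = np.ones((n, 1))
        res = reml_fit(y, X, Z @ Z.T, lam=lam)
        mu = float(res.beta[0])
    else:
        if lam is None:
            raise ValueError("fit_intercept=False requires a fixed lam")
        gamma = np.linalg.solve(Z.T @ Z + lam * np.eye(p), Z.T @ y)
        return MarkerEffectModel(mu=0.0, gamma=gamma, lam=float(lam))
    r = y - mu
    gamma = np.linalg.solve(Z.T @ Z + res.lam * np.eye(p), Z.T @ r)
    return MarkerEffectModel(
        mu=mu, gamma=gamma, lam=res.lam, sigma2_g=res.sigma2_g, sigma2_e=res.sigma2_e
    )


def _cross_kernel(Za: np.ndarray, Zb: np.ndarray, q: float) -> np.ndarray:
    d2 = (
        (Za**2).sum(axis=1)[:, None]
        + (Zb**2).sum(axis=1)[None, :]
        - 2.0 * Za @ Zb.T
    )
    return np.exp(-np.maximum(d2, 0.0) / q)


def gaussian_kernel(Z: np.ndarray, bandwidth: float | None = None) -> tuple[np.ndarray, float]:
    """K_ij = exp(-d2_ij / q) with q the median off-diagonal squared distance.

    Returns (K, q).  The diagonal is exactly 1; identical rows give 1.
    """
    Z = np.asarray(Z, float)
    n = Z.shape[0]
    if n < 2:
        raise ValueError("need n >= 2")
    sq = (Z**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T, 0.0)
    if bandwidth is None:
        off = d2[~np.eye(n, dtype=bool)]
        bandwidth = float(np.median(off))
        if bandwidth <= 0:
            raise ValueError("all genotypes identical: zero kernel bandwidth")
    K = np.exp(-d2 / bandwidth)
    np.fill_diagonal(K, 1.0)
    return K, float(bandwidth)


def fit_kernel_model(
    K: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    train_Z: np.ndarray | None = None,
    bandwidth: float | None = None,
) -> KernelModel:
    """Kernel genomic model: u = K (K + lam I)^{-1} (y - mu), lam by REML."""
    K = np.asarray(K, float)
    y = np.asarray(y, float).ravel()
    n = y.size
    if K.shape != (n, n):
        raise ValueError("kernel shape must match y")
    X = np.ones((n, 1))
    res = reml_fit(y, X, K, lam=lam)
    mu = float(res.beta[0])
    r = y - mu
    try:
        alpha = np.linalg.solve(K + res.lam * np.eye(n), r)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"singular (K + lam I): {exc}") from exc
    return KernelModel(
        mu=mu, alpha=alpha, u=K @ alpha, lam=res.lam, train_Z=train_Z, bandwidth=bandwidth
    )


def fit_gk(Z: np.ndarray, y: np.ndarray, lam: float | None = None) -> KernelModel:
    """Convenience wrapper: Gaussian kernel from genotypes, then kernel fit."""
    Z = np.asarray(Z, float)
    K, q = gaussian_kernel(Z)
    return fit_kernel_model(K, y, lam=lam, train_Z=Z, bandwidth=q)


class _ConstantPredictor:
    def __init__(self, c: float):
        self.c = float(c)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.c)


_ML_ALGORITHMS = ("adaboost", "random_forest", "svm", "mlp_default")


def fit_standard_ml(X: np.ndarray, y: np.ndarray, algorithm: str, seed: int = 0):
    """Fit one of the standard scikit-learn regressors, seeded.

    A constant target is fitted as a constant predictor (the degenerate
    case where iterative learners are wasteful and inexact).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] < 10:
        raise ValueError("need n >= 10")
    if algorithm not in _ML_ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {_ML_ALGORITHMS}")
    if np.ptp(y) == 0:
        return _ConstantPredictor(y[0])
    if algorithm == "adaboost":
        model = AdaBoostRegressor(n_estimators=100, random_state=seed)
    elif algorithm == "random_forest":
        model = RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1)
    elif algorithm == "svm":
        model = SVR(kernel="rbf", C=1.0)
    else:  # mlp_default: library-default feedforward net, seeded
        model = MLPRegressor(random_state=seed, max_iter=1000)
    model.fit(X, y)
    return model
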