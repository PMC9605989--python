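"""REML for a single-random-effect linear mixed model.

Model: y = X b + u + e with u ~ N(0, sg2 * K), e ~ N(0, se2 * I), where K
is any PSD covariance (Z Z' for a grouping design, a marker kernel, ...).
The variance ratio lam = se2 / sg2 is profiled: for fixed lam the REML
criterion has a closed form after rotating into the eigenbasis of K, so a
one-dimensional search (golden section on log lam) finds the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOG_LAM_LO, _LOG_LAM_HI = np.log(1e-8), np.log(1e8)
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, lo: float, hi: float, tol: float, maxiter: int = 500) -> float:
    """Minimize unimodal f on [lo, hi] by golden-section search."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(maxiter):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return (a + b) / 2.0


class RemlError(RuntimeError):
    pass


@dataclass
class RemlResult:
    lam: float            # se2 / sg2
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray      # fixed-effect estimates
    u: np.ndarray         # BLUP of the random effect, one per observation row of K
    loglik: float         # REML log-likelihood (up to an additive constant)
    converged: bool


def _profile(log_lam: float, d: np.ndarray, Xt: np.ndarray, yt: np.ndarray) -> tuple:
    """Negative REML criterion at lam = exp(log_lam), plus GLS pieces."""
    lam = np.exp(log_lam)
    w = 1.0 / (d + lam)
    n, p = Xt.shape
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    b = XtW.T @ yt
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        raise RemlError("singular fixed-effect design (aliased terms)") from None
    r = yt - Xt @ beta
    q = float(np.dot(r * w, r))
    dof = n - p
    if q <= 0:
        q = np.finfo(float).tiny
    sg2 = q / dof
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        raise RemlError("singular fixed-effect design (aliased terms)")
    ll = -0.5 * (dof * np.log(sg2) + np.sum(np.log(d + lam)) + logdetA + dof)
    return -ll, beta, sg2, w, r


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-8,
) -> RemlResult:
    """Fit the mixed model; if ``lam`` is given, skip the search.

    Returns BLUPs ``u = K (K + lam I)^{-1} (y - X beta)`` evaluated at the
    REML optimum.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n or K.shape != (n, n):
        raise ValueError("incompatible shapes for y, X, K")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RemlError("fixed-effect design is rank deficient (aliased terms)")

    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    if lam is None:
        log_lam = _golden_section(
            lambda ll: _profile(ll, d, Xt, yt)[0], _LOG_LAM_LO, _LOG_LAM_HI, tol
        )
        if not np.isfinite(_profile(log_lam, d, Xt, yt)[0]):
            raise RemlError("REML profile search diverged")
        converged = True
    else:
        log_lam = float(np.log(lam))
        converged = True

    negll, beta, sg2, w, r = _profile(log_lam, d, Xt, yt)
    lam_hat = float(np.exp(log_lam))
    # u = K V^{-1} (y - Xb) with V = K + lam I, in the eigenbasis
    u = U @ (d * w * r)
    return RemlResult(
        lam=lam_hat,
        sigma2_g=float(sg2),
        sigma2_e=float(sg2 * lam_hat),
        beta=beta,
        u=u,
        loglik=float(-negll),
        converged=converged,
    )
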