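"""Consensus marker selection: L1, univariate tests, tree boosting.

Three complementary selectors vote on markers; the consensus sets are
Inter2 (selected by at least two methods) and Inter3 (selected by all
three).  Inter2 is the looser set suited to classification of
subpopulation membership; Inter3 is the strict set suited to
within-family trait regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.linear_model import Lasso
from sklearn.svm import LinearSVC


@dataclass
class SelectionResult:
    """Per-method masks and the Inter2/Inter3 consensus index sets."""

    l1_mask: np.ndarray
    univariate_mask: np.ndarray
    boosting_mask: np.ndarray
    inter2: np.ndarray  # sorted marker indices with >= 2 votes
    inter3: np.ndarray  # sorted marker indices with 3 votes

    def to_dict(self) -> dict:
        return {
            "l1": np.flatnonzero(self.l1_mask).tolist(),
            "univariate": np.flatnonzero(self.univariate_mask).tolist(),
            "boosting": np.flatnonzero(self.boosting_mask).tolist(),
            "inter2": self.inter2.tolist(),
            "inter3": self.inter3.tolist(),
        }


def _is_classification(y: np.ndarray) -> bool:
    return y.dtype.kind in "USOb" or (
        y.dtype.kind in "iu" and np.unique(y).size <= max(2, int(np.sqrt(y.size)))
    )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; constant columns are zeroed and flagged."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    nonconst = sd > 0
    Xs = np.zeros_like(X, dtype=float)
    Xs[:, nonconst] = (X[:, nonconst] - mu[nonconst]) / sd[nonconst]
    return Xs, nonconst


def select_l1(X: np.ndarray, y: np.ndarray, C: float = 1.0, seed: int = 0) -> np.ndarray:
    """Mask of markers with nonzero coefficients in an L1 linear model.

    Classification targets use a linear SVM with L1 penalty (hinge-type
    squared loss, strength C).  Continuous targets use an L1 linear
    regression with penalty alpha = 1 / (C * sqrt(n)) on standardized
    X and y, so C -> 0 shrinks every coefficient to zero.  Constant
    columns are skipped (never selected).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, p = X.shape
    if n < 3:
        raise ValueError("need n >= 3")
    Xs, nonconst = _standardize(X)
    mask = np.zeros(p, dtype=bool)
    if _is_classification(y):
        model = LinearSVC(
            penalty="l1", dual=False, C=C, max_iter=20000, random_state=seed, tol=1e-5
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs, y)
        if getattr(model, "n_iter_", 0) is not None and np.max(model.n_iter_) >= 20000:
            raise RuntimeError(f"L1 SVM failed to converge within {np.max(model.n_iter_)} iterations")
        coef = np.abs(model.coef_).max(axis=0)
    else:
        ys = (y.astype(float) - y.mean()) / (y.std() or 1.0)
        alpha = 1.0 / (C * np.sqrt(n))
        model = Lasso(alpha=alpha, max_iter=50000, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs, ys)
        coef = np.abs(model.coef_)
    mask[nonconst] = coef[nonconst] > 1e-8
    return mask


def select_univariate(X: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Per-marker significance filter, p < alpha strictly.

    Continuous targets: two-sided t-test of the Pearson correlation,
    t = r sqrt((n-2)/(1-r^2)) on n-2 df.  Discrete targets: one-way
    ANOVA F-test of the dosage across classes.  Zero-variance markers
    get p = 1 and are never selected.
    """
    return univariate_pvalues(X, y) < alpha


def univariate_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-marker p-values behind :func:`select_univariate`."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, p = X.shape
    if n < 4:
        raise ValueError("need n >= 4")
    sd = X.std(axis=0)
    pvals = np.ones(p)
    nz = sd > 0
    if nz.sum() < p:
        warnings.warn("zero-variance markers assigned p = 1", stacklevel=2)
    if _is_classification(y):
        groups = [X[y == c] for c in np.unique(y)]
        # vectorized one-way ANOVA over markers
        ns = np.array([g.shape[0] for g in groups], float)
        means = np.stack([g.mean(axis=0) for g in groups])
        grand = X.mean(axis=0)
        ssb = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
        ssw = sum(((g - m) ** 2).sum(axis=0) for g, m in zip(groups, means))
        dfb, dfw = len(groups) - 1, n - len(groups)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = (ssb / dfb) / (ssw / dfw)
        ok = nz & np.isfinite(F)
        pvals[ok] = stats.f.sf(F[ok], dfb, dfw)
        pvals[nz & ~np.isfinite(F)] = 0.0  # zero within-group variance, perfect separation
    else:
        yc = y.astype(float) - y.mean()
        sy = yc.std()
        if sy == 0:
            raise ValueError("constant target")
        Xc = X - X.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc * yc[:, None]).sum(axis=0) / (n * sd * sy)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
        pv = 2.0 * stats.t.sf(np.abs(t), n - 2)
        pv[np.abs(r) >= 1.0] = 0.0
        pvals[nz] = pv[nz]
    return pvals


def select_boosting(X: np.ndarray, y: np.ndarray, seed: int = 0) -> np.ndarray:
    """Markers whose boosting importance exceeds the mean importance.

    Gradient-boosted trees (100 rounds, depth 3, learning rate 0.1,
    seeded); the mean is taken over nonzero-variance markers.  If every
    importance equals the mean (e.g. all importances zero), nothing is
    selected.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, p = X.shape
    if n < 10:
        raise ValueError("need n >= 10")
    params = dict(n_estimators=100, max_depth=3, learning_rate=0.1, random_state=seed)
    if _is_classification(y):
        model = GradientBoostingClassifier(**params)
    else:
        if np.ptp(y.astype(float)) == 0:
            raise ValueError("constant target")
        model = GradientBoostingRegressor(**params)
    model.fit(X, y)
    imp = model.feature_importances_
    nz = X.std(axis=0) > 0
    thresh = imp[nz].mean() if nz.any() else np.inf
    mask = np.zeros(p, dtype=bool)
    mask[nz] = imp[nz] > thresh
    return mask


def consensus(
    l1_mask: np.ndarray, univariate_mask: np.ndarray, boosting_mask: np.ndarray
) -> SelectionResult:
    """Vote-count consensus of the three method masks."""
    masks = [np.asarray(m, bool) for m in (l1_mask, univariate_mask, boosting_mask)]
    if len({m.shape for m in masks}) != 1 or masks[0].ndim != 1:
        raise ValueError("masks must be 1-D and of equal length")
    votes = sum(m.astype(int) for m in masks)
    return SelectionResult(
        l1_mask=masks[0],
        univariate_mask=masks[1],
        boosting_mask=masks[2],
        inter2=np.flatnonzero(votes >= 2),
        inter3=np.flatnonzero(votes == 3),
    )


def select_consensus(
    X: np.ndarray, y: np.ndarray, alpha: float = 0.05, C: float = 1.0, seed: int = 0
) -> SelectionResult:
    """Run all three selectors and combine them."""
    return consensus(
        select_l1(X, y, C=C, seed=seed),
        select_univariate(X, y, alpha=alpha),
        select_boosting(X, y, seed=seed),
    )


def selection_percentage(n_selected: int, n_markers: int) -> float:
    """Share of the marker panel selected, as a percentage to 2 decimals."""
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    return round(100.0 * n_selected / n_markers, 2)
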