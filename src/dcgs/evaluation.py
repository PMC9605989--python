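"""Validation protocol: stratified splits, metrics, model comparison.

Splitting is stratified on subpopulation (family) labels with
largest-remainder rounding, so fold family proportions stay within one
individual of the global proportions.  Predictive skill is summarized by
the Pearson correlation R between predicted and observed BLUPs and by
the mean absolute percentage error (MAPE); classification by plain
accuracy.  Models are compared on identical splits with one-way ANOVA
followed by Tukey's HSD and compact letter groupings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- metrics

def pearson_r(a, b) -> float:
    """Pearson correlation coefficient."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input to Pearson R")
    return float(np.corrcoef(a, b)[0, 1])


def mape(pred, truth, zero_tol: float = 1e-6) -> float:
    """Mean absolute percentage error, in percent.

    Truth values with |truth| < ``zero_tol`` are excluded (BLUPs are
    centered, so exact zeros can occur); the excluded count is logged.
    An all-near-zero truth vector is an error.
    """
    pred = np.asarray(pred, float).ravel()
    truth = np.asarray(truth, float).ravel()
    if pred.size != truth.size or pred.size < 1:
        raise ValueError("need two equal-length vectors of size >= 1")
    ok = np.abs(truth) >= zero_tol
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("MAPE: excluded %d near-zero truth values", n_excluded)
    if not ok.any():
        raise ValueError("all truth values are (near) zero; MAPE undefined")
    return float(np.mean(np.abs(pred[ok] - truth[ok]) / np.abs(truth[ok])) * 100.0)


def accuracy(pred, truth) -> float:
    """Fraction of correct predictions."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.size != truth.size or pred.size < 1:
        raise ValueError("need two equal-length vectors of size >= 1")
    return float(np.mean(pred == truth))


# ----------------------------------------------------------------- splits

@dataclass
class CVScheme:
    """Cross-validation layout.

    kind: ``stratified_holdout`` (single test split of ``test_fraction``),
    ``stratified_kfold`` (k folds, ``repetitions`` reshuffles) or ``loo``.
    Stratification follows family labels when provided.
    """

    kind: str = "stratified_kfold"
    test_fraction: float = 0.10
    k: int = 4
    repetitions: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("stratified_holdout", "stratified_kfold", "loo"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")


@dataclass
class Split:
    repetition: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray


def _stratified_counts(group_sizes: np.ndarray, total_test: int) -> np.ndarray:
    """Largest-remainder allocation of `total_test` across groups."""
    quota = group_sizes * total_test / group_sizes.sum()
    base = np.floor(quota).astype(int)
    rem = total_test - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment: within each family, shuffle and deal round-robin."""
    n = len(labels)
    folds = np.empty(n, dtype=int)
    start = int(rng.integers(k))
    for fam in np.unique(labels):
        members = np.flatnonzero(labels == fam)
        members = members[rng.permutation(len(members))]
        folds[members] = (np.arange(len(members)) + start) % k
    return folds


def make_splits(ids: list[str], fams=None, scheme: CVScheme | None = None) -> list[Split]:
    """Deterministic, stratified fold assignments for a list of individuals.

    ``fams`` may be a FamilyAssignment-like object (with
    ``for_individuals``), a label array, or None (no stratification).
    """
    scheme = scheme or CVScheme()
    n = len(ids)
    if fams is None:
        labels = np.zeros(n, dtype=int)
    elif hasattr(fams, "for_individuals"):
        labels = fams.for_individuals(list(ids))
    else:
        labels = np.asarray(fams)
    rng = np.random.default_rng(scheme.seed)
    all_idx = np.arange(n)

    if scheme.kind == "loo":
        return [
            Split(0, i, np.delete(all_idx, i), np.array([i])) for i in range(n)
        ]

    if scheme.kind == "stratified_holdout":
        fams_u, sizes = np.unique(labels, return_counts=True)
        total_test = int(round(scheme.test_fraction * n))
        counts = _stratified_counts(sizes.astype(float), total_test)
        test = []
        for fam, c in zip(fams_u, counts):
            members = np.flatnonzero(labels == fam)
            members = members[rng.permutation(len(members))]
            test.extend(members[:c])
        test = np.sort(np.array(test, dtype=int))
        train = np.setdiff1d(all_idx, test)
        return [Split(0, 0, train, test)]

    if n < scheme.k:
        raise ValueError(f"n={n} smaller than k={scheme.k}")
    small = [
        str(f) for f, c in zip(*np.unique(labels, return_counts=True)) if c < scheme.k
    ]
    if small and fams is not None:
        logger.warning("families smaller than k=%d: %s (best-effort allocation)", scheme.k, small)
    splits = []
    for rep in range(scheme.repetitions):
        folds = _stratified_folds(labels, scheme.k, rng)
        for f in range(scheme.k):
            test = np.flatnonzero(folds == f)
            splits.append(Split(rep, f, np.flatnonzero(folds != f), test))
    return splits


# ------------------------------------------------------- model comparison

@dataclass
class CVResult:
    """Tidy per-split metric records plus the comparison tables."""

    records: pd.DataFrame
    anova_f: float = float("nan")
    anova_p: float = float("nan")
    tukey: pd.DataFrame | None = None
    letters: dict[str, str] = field(default_factory=dict)
    per_family: pd.DataFrame | None = None


def _compact_letters(names: list[str], means: dict[str, float], reject: dict) -> dict[str, str]:
    """Compact letter display from pairwise significance (insert & absorb)."""
    ordered = sorted(names, key=lambda m: -means[m])
    letter_sets: list[set[str]] = []
    for m in ordered:
        placed = False
        for grp in letter_sets:
            if all(not reject.get(frozenset((m, o)), False) for o in grp):
                grp.add(m)
                placed = True
        if not placed:
            letter_sets.append({m})
    # absorb duplicate subsets
    letter_sets = [
        g for i, g in enumerate(letter_sets)
        if not any(g < h for j, h in enumerate(letter_sets) if i != j)
    ]
    out = {m: "" for m in names}
    for i, grp in enumerate(letter_sets):
        for m in grp:
            out[m] += chr(ord("a") + i)
    return {m: "".join(sorted(v)) for m, v in out.items()}


def compare_models(records: pd.DataFrame, metric: str = "r", alpha: float = 0.05) -> CVResult:
    """One-way ANOVA + Tukey HSD on per-split scores across models.

    ``records`` must be tidy with columns (model, repetition, fold, r, ...).
    """
    models = sorted(records["model"].unique())
    if len(models) < 2:
        raise ValueError("need >= 2 models to compare")
    groups = [records.loc[records["model"] == m, metric].to_numpy() for m in models]
    if min(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 splits per model")
    F, p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(
        records[metric].to_numpy(), records["model"].to_numpy(), alpha=alpha
    )
    tukey_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    reject = {
        frozenset((row["group1"], row["group2"])): bool(row["reject"])
        for _, row in tukey_df.iterrows()
    }
    means = {m: float(np.mean(g)) for m, g in zip(models, groups)}
    letters = _compact_letters(models, means, reject)
    return CVResult(
        records=records, anova_f=float(F), anova_p=float(p), tukey=tukey_df, letters=letters
    )


def evaluate_models(
    models: dict,
    G,
    blups,
    fams=None,
    scheme: CVScheme | None = None,
    zero_tol: float = 1e-6,
) -> CVResult:
    """Cross-validate prediction pipelines on identical splits.

    ``models`` maps name -> callable(train_idx, test_idx) -> predictions
    for the test individuals; the callable owns its whole pipeline
    (feature selection, fitting), so nothing leaks across the split.
    ``G`` is a GenotypeMatrix (or anything with ``individual_ids``);
    ``blups`` a BlupSet (or array aligned with individuals).
    """
    scheme = scheme or CVScheme()
    if len(models) < 2:
        raise ValueError("need >= 2 models for comparison")
    ids = list(G.individual_ids)
    y = blups.vector(ids) if hasattr(blups, "vector") else np.asarray(blups, float)
    labels = None
    if fams is not None:
        labels = fams.for_individuals(ids) if hasattr(fams, "for_individuals") else np.asarray(fams)
    splits = make_splits(ids, fams, scheme)

    rows = []
    fam_rows = []
    for split in splits:
        truth = y[split.test_idx]
        for name, fit_predict in models.items():
            pred = np.asarray(fit_predict(split.train_idx, split.test_idx), float)
            row = {
                "model": name,
                "repetition": split.repetition,
                "fold": split.fold,
                "r": pearson_r(pred, truth) if truth.size >= 2 and np.std(truth) > 0 and np.std(pred) > 0 else np.nan,
                "mape": mape(pred, truth, zero_tol=zero_tol),
            }
            rows.append(row)
            if labels is not None:
                for fam in np.unique(labels[split.test_idx]):
                    m = labels[split.test_idx] == fam
                    if m.sum() >= 2 and np.std(truth[m]) > 0 and np.std(pred[m]) > 0:
                        fam_rows.append(
                            {
                                "model": name,
                                "repetition": split.repetition,
                                "fold": split.fold,
                                "family": fam,
                                "r": pearson_r(pred[m], truth[m]),
                            }
                        )
    records = pd.DataFrame(rows)
    result = compare_models(records.dropna(subset=["r"]), metric="r")
    result.records = records
    if fam_rows:
        result.per_family = pd.DataFrame(fam_rows)
    return result


# ------------------------------------------------------------ diagnostics

def pca_diagnostic(G, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of the dosage matrix.

    Returns (scores, variance_fractions).  Used to visualize family
    separability; missing calls must be imputed first.
    """
    X = G.dosages() if hasattr(G, "dosages") else np.asarray(G, float)
    if np.isnan(X).any():
        raise ValueError("impute missing calls before PCA")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need n >= 3")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    frac = var / max(Xc.var(axis=0, ddof=1).sum(), np.finfo(float).tiny)
    m = min(n_components, s.size)
    return U[:, :m] * s[:m], frac[:m]
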