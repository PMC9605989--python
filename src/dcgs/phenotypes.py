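"""Phenotype normalization, mixed-model BLUPs, heritability, clustering.

The trait pipeline is the standard one for replicated field trials:

1. normalize raw measurements with a rank-based (ordered-quantile)
   transform so that model residuals are close to Gaussian;
2. fit a linear mixed model with design factors (location, block,
   watering regime / block, line, rank) as fixed effects and genotype as
   the single random effect, estimating (sg2, se2) by REML;
3. extract genotype BLUPs as the prediction target for genomic models;
4. report broad-sense heritability H2 = sg2 / sp2 with sp2 = sg2 + se2;
5. group genotypes phenotypically by complete-linkage hierarchical
   clustering of the BLUPs, choosing the cluster count by internal
   validity indexes (silhouette, Calinski-Harabasz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .reml import RemlError, reml_fit


@dataclass
class PhenotypeModelSpec:
    """Fixed design factors for the trial model; genotype is always random.

    ``fixed_terms`` name columns of the phenotype table.  Each is treated
    as categorical; an intercept is always included and one level of each
    factor is dropped.  Multi-location trials with watering regimes use
    (location, block, watering); single-site row-column trials use
    (block, line, rank).
    """

    fixed_terms: tuple[str, ...] = ("location", "block", "watering")
    genotype_col: str = "individual_id"
    value_col: str = "value"


MULTI_LOCATION_SPEC = PhenotypeModelSpec(("location", "block", "watering"))
ROW_COLUMN_SPEC = PhenotypeModelSpec(("block", "line", "rank"))


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_e

    @property
    def H2(self) -> float:
        return heritability(self)


@dataclass
class BlupSet:
    """Per-genotype BLUPs with the variance components behind them."""

    values: dict[str, float]
    varcomp: VarianceComponents
    residual_normality: float = float("nan")  # corr of sorted residuals vs normal quantiles
    notes: list[str] = field(default_factory=list)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.values)

    def vector(self, ids: list[str] | None = None) -> np.ndarray:
        ids = ids if ids is not None else self.genotype_ids
        return np.array([self.values[i] for i in ids], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual_id": list(self.values), "blup": list(self.values.values())}
        )


@dataclass
class NormalizeRecord:
    """Frozen ordered-quantile map, applicable to new values by interpolation."""

    sorted_input: np.ndarray
    sorted_output: np.ndarray

    def apply(self, new_values) -> np.ndarray:
        return np.interp(np.asarray(new_values, float), self.sorted_input, self.sorted_output)


def normalize(values) -> tuple[np.ndarray, NormalizeRecord]:
    """Ordered-quantile transform to an approximate standard normal.

    The value at rank r of n maps to Phi^{-1}((r - 0.5) / n); ties share
    the average of their rank quantiles.  The output is then centered and
    scaled to unit variance.  Rank-preserving by construction.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 3 finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance input cannot be normalized")
    ranks = stats.rankdata(x, method="average")
    z = stats.norm.ppf((ranks - 0.5) / x.size)
    z = (z - z.mean()) / z.std()
    order = np.argsort(x, kind="stable")
    rec = NormalizeRecord(sorted_input=x[order], sorted_output=z[order])
    return z, rec


def mean_by_plot(ph: pd.DataFrame, plot_cols: list[str], value_col: str = "value") -> pd.DataFrame:
    """Average repeated measurements within a plot (helper for raw field data)."""
    return ph.groupby(plot_cols, as_index=False, observed=True)[value_col].mean()


def _design_matrix(ph: pd.DataFrame, spec: PhenotypeModelSpec) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(ph))]
    names = ["intercept"]
    for term in spec.fixed_terms:
        if term not in ph.columns:
            continue
        dummies = pd.get_dummies(ph[term].astype(str), prefix=term, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(float))
            names.append(c)
    X = np.column_stack(cols)
    # drop aliased columns (e.g. nested factors), keep full rank
    keep, rank = [], 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, keep + [j]])
        if r > rank:
            keep.append(j)
            rank = r
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    return X[:, keep], dropped


def fit_mixed_model(
    ph: pd.DataFrame,
    spec: PhenotypeModelSpec | None = None,
    lam: float | None = None,
) -> BlupSet:
    """REML fit of the trial model; returns genotype BLUPs.

    ``ph`` is a tidy table with one row per measurement.  Fixed terms in
    ``spec`` that are absent from the table are skipped (so the same spec
    covers reduced designs).  ``lam`` fixes se2/sg2 instead of estimating
    it, which is mainly useful for closed-form checks.
    """
    spec = spec or PhenotypeModelSpec()
    y = ph[spec.value_col].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype measurements")
    geno = ph[spec.genotype_col].astype(str).to_numpy()
    geno_levels = sorted(set(geno))
    if len(geno_levels) < 2:
        raise ValueError("genotype factor needs >= 2 levels")
    X, dropped = _design_matrix(ph, spec)
    gidx = {g: i for i, g in enumerate(geno_levels)}
    Zg = np.zeros((len(y), len(geno_levels)))
    Zg[np.arange(len(y)), [gidx[g] for g in geno]] = 1.0

    res = reml_fit(y, X, Zg @ Zg.T, lam=lam)
    vc = VarianceComponents(sigma2_g=res.sigma2_g, sigma2_e=res.sigma2_e)

    # per-genotype BLUP: u is on observation rows; identical within genotype.
    # Centered so the set has exactly zero mean (the random-effect prior is
    # mean zero; unbalanced designs can leave a negligible offset).
    raw = np.array([res.u[geno == g][0] for g in geno_levels])
    raw = raw - raw.mean()
    blups = {g: float(v) for g, v in zip(geno_levels, raw)}

    resid = y - X @ res.beta - res.u
    qq = _normal_quantile_correlation(resid)
    notes = []
    if dropped:
        notes.append(f"aliased fixed-effect columns dropped: {', '.join(dropped)}")
    if qq < 0.95:
        notes.append(f"residual normal-quantile correlation {qq:.3f} < 0.95")
    return BlupSet(values=blups, varcomp=vc, residual_normality=qq, notes=notes)


def _normal_quantile_correlation(resid: np.ndarray) -> float:
    n = resid.size
    if n < 3 or np.ptp(resid) == 0:
        return float("nan")
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return float(np.corrcoef(np.sort(resid), q)[0, 1])


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability H2 = sg2 / sp2."""
    if vc.sigma2_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    return vc.sigma2_g / vc.sigma2_p


def cluster_blups(
    b: BlupSet | np.ndarray, k_range: range = range(2, 6)
) -> tuple[np.ndarray, int]:
    """Complete-linkage clustering of BLUPs; k picked by index vote.

    Silhouette and Calinski-Harabasz each vote for their best k in
    ``k_range``; disagreements are settled in favour of the silhouette
    choice.  Returns (labels, k).
    """
    x = b.vector() if isinstance(b, BlupSet) else np.asarray(b, float).ravel()
    ks = list(k_range)
    if not ks or min(ks) < 2 or max(ks) > x.size - 1:
        raise ValueError(f"k_range must lie within [2, {x.size - 1}]")
    Z = linkage(x[:, None], method="complete", metric="euclidean")
    labels_by_k, sil, ch = {}, {}, {}
    for k in ks:
        lab = fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        if len(set(lab)) < 2:
            sil[k], ch[k] = -1.0, 0.0
            continue
        sil[k] = silhouette_score(x[:, None], lab)
        ch[k] = calinski_harabasz_score(x[:, None], lab)
    best_sil = max(ks, key=lambda k: sil[k])
    best_ch = max(ks, key=lambda k: ch[k])
    k_star = best_sil if best_sil == best_ch else best_sil
    return labels_by_k[k_star], k_star
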