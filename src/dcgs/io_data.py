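"""Genotype I/O, quality control and kNN imputation.

Genotypes are biallelic dosages coded 0/1/2 (count of the alternate
allele), with ``-1`` as the internal missing sentinel.  Input accepts
``NA``, ``.`` , ``./.`` and empty cells as missing.  QC follows the
conventional order for SNP matrices: individuals are filtered on
missingness first, then markers on missingness, then markers on minor
allele frequency computed over the individuals that survived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_MISSING_TOKENS = {"", "NA", "NaN", "nan", ".", "./.", ".|."}


class GenotypeError(ValueError):
    """Raised for malformed genotype input or degenerate QC results."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix.

    Attributes
    ----------
    individual_ids : list of str
        Row labels, unique.
    marker_ids : list of str
        Column labels, unique.
    calls : ndarray of int8/int16, shape (n, p)
        Dosages in {0, 1, 2} or ``MISSING`` (-1).
    """

    individual_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        n, p = self.calls.shape
        if len(self.individual_ids) != n or len(self.marker_ids) != p:
            raise GenotypeError(
                f"dimension mismatch: calls {self.calls.shape} vs "
                f"{len(self.individual_ids)} individuals, {len(self.marker_ids)} markers"
            )
        if len(set(self.individual_ids)) != n:
            raise GenotypeError("duplicate individual IDs")
        if len(set(self.marker_ids)) != p:
            raise GenotypeError("duplicate marker IDs")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid call {self.calls[i, j]} at individual "
                f"{self.individual_ids[i]}, marker {self.marker_ids[j]}"
            )

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def dosages(self) -> np.ndarray:
        """Calls as float with missing mapped to NaN."""
        out = self.calls.astype(float)
        out[out == MISSING] = np.nan
        return out

    def subset(self, individuals=None, markers=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index array."""
        rows = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        cols = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in rows],
            [self.marker_ids[j] for j in cols],
            self.calls[np.ix_(rows, cols)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.individual_ids, columns=self.marker_ids)


@dataclass
class FamilyAssignment:
    """Mapping individual id -> family label."""

    labels: dict[str, str]

    def families(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def for_individuals(self, ids: list[str]) -> np.ndarray:
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise GenotypeError(f"individuals without family assignment: {missing[:5]}")
        return np.array([self.labels[i] for i in ids])


@dataclass
class QCConfig:
    """Marker/individual QC thresholds.

    Defaults follow common SNP-array practice for multi-family panels:
    markers with more than 20% missing calls and individuals with more
    than 50% missing calls are removed, then markers with minor allele
    frequency below 5% are removed.
    """

    max_marker_missing: float = 0.20
    max_individual_missing: float = 0.50
    min_maf: float = 0.05
    knn_k: int = 5

    def __post_init__(self) -> None:
        for name in ("max_marker_missing", "max_individual_missing", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class QCReport:
    dropped_individuals: list[tuple[str, str]] = field(default_factory=list)
    dropped_markers: list[tuple[str, str]] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["id\tkind\treason"]
        for ind, reason in self.dropped_individuals:
            lines.append(f"{ind}\tindividual\t{reason}")
        for mk, reason in self.dropped_markers:
            lines.append(f"{mk}\tmarker\t{reason}")
        return "\n".join(lines) + "\n"


def _parse_call(token: str, where: str) -> int:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return MISSING
    try:
        v = int(float(token))
    except ValueError:
        raise GenotypeError(f"unparseable genotype call {token!r} at {where}") from None
    if v not in (0, 1, 2):
        raise GenotypeError(f"genotype call {v} outside {{0,1,2}} at {where}")
    return v


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from CSV or VCF.

    CSV dialect: header ``individual_id,<marker ids...>``, one row per
    individual.  VCF: biallelic SNP records only; GT fields are mapped
    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, missing -> -1.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "csv"
    if format == "csv":
        return _read_genotypes_csv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_csv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise GenotypeError(f"{path}: empty file")
        cols = header.split(",")
        marker_ids = [c.strip() for c in cols[1:]]
        individual_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != len(cols):
                raise GenotypeError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {len(cols)}"
                )
            individual_ids.append(fields[0].strip())
            rows.append(
                [_parse_call(tok, f"{path}:{lineno}") for tok in fields[1:]]
            )
    if not rows:
        raise GenotypeError(f"{path}: no individuals")
    return GenotypeMatrix(individual_ids, marker_ids, np.array(rows, dtype=np.int16))


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise GenotypeError(f"{path}: cannot parse VCF ({exc})") from exc
    individual_ids = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
            raise GenotypeError(f"non-biallelic-SNP record {rid} rejected")
        marker_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(np.int16)
        col = np.where(gt == 3, 2, gt)
        col[gt == 2] = MISSING
        columns.append(col)
    if not columns:
        raise GenotypeError(f"{path}: VCF contains no usable records")
    return GenotypeMatrix(individual_ids, marker_ids, np.column_stack(columns))


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the CSV dialect of :func:`read_genotypes` (missing as NA)."""
    with open(path, "w") as fh:
        fh.write("individual_id," + ",".join(g.marker_ids) + "\n")
        for i, ind in enumerate(g.individual_ids):
            row = ["NA" if v == MISSING else str(int(v)) for v in g.calls[i]]
            fh.write(ind + "," + ",".join(row) + "\n")


def read_families(path: str | Path) -> FamilyAssignment:
    """Read ``individual_id,family`` CSV."""
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "individual_id" or "family" not in df.columns:
        raise GenotypeError(f"{path}: expected columns individual_id,family")
    if df["individual_id"].duplicated().any():
        dup = df["individual_id"][df["individual_id"].duplicated()].iloc[0]
        raise GenotypeError(f"{path}: duplicate individual {dup}")
    return FamilyAssignment(dict(zip(df["individual_id"], df["family"])))


def write_families(fams: FamilyAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"individual_id": list(fams.labels), "family": list(fams.labels.values())}
    ).to_csv(path, index=False)


def allele_frequency(calls: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per marker; NaN where fully missing."""
    obs = calls != MISSING
    counts = obs.sum(axis=0)
    dos = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, dos / (2.0 * counts), np.nan)


def minor_allele_frequency(calls: np.ndarray) -> np.ndarray:
    f = allele_frequency(calls)
    return np.minimum(f, 1.0 - f)


def apply_marker_qc(
    g: GenotypeMatrix, cfg: QCConfig | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter individuals then markers.

    Order is fixed: (1) individuals with missingness > ``max_individual_missing``;
    (2) markers with missingness > ``max_marker_missing`` over the remaining
    individuals; (3) markers with MAF < ``min_maf``, where MAF = min(f, 1-f)
    and f = allele-dosage sum / (2 x non-missing count).  Re-running QC on
    its own output is a no-op.
    """
    cfg = cfg or QCConfig()
    if g.n_individuals == 0 or g.n_markers == 0:
        raise GenotypeError("empty genotype matrix")
    report = QCReport()

    miss = g.missing_mask()
    ind_rate = miss.mean(axis=1)
    keep_ind = ind_rate <= cfg.max_individual_missing
    for i in np.flatnonzero(~keep_ind):
        report.dropped_individuals.append(
            (g.individual_ids[i], f"missingness {ind_rate[i]:.3f} > {cfg.max_individual_missing}")
        )
    g = g.subset(individuals=keep_ind)
    if g.n_individuals == 0:
        raise GenotypeError("no individuals left after QC")

    miss = g.missing_mask()
    mk_rate = miss.mean(axis=0)
    keep_miss = mk_rate <= cfg.max_marker_missing
    for j in np.flatnonzero(~keep_miss):
        report.dropped_markers.append(
            (g.marker_ids[j], f"missingness {mk_rate[j]:.3f} > {cfg.max_marker_missing}")
        )

    maf = minor_allele_frequency(g.calls)
    low_maf = np.where(np.isnan(maf), True, maf < cfg.min_maf)
    for j in np.flatnonzero(keep_miss & low_maf):
        report.dropped_markers.append(
            (g.marker_ids[j], f"MAF {maf[j]:.4f} < {cfg.min_maf}")
        )
    keep_mk = keep_miss & ~low_maf
    if not keep_mk.any():
        raise GenotypeError("empty after QC: all markers dropped")
    return g.subset(markers=keep_mk), report


def intersection_qc(
    g: GenotypeMatrix, fams: FamilyAssignment, cfg: QCConfig | None = None
) -> tuple[GenotypeMatrix, dict[str, QCReport]]:
    """Per-family QC combined by marker intersection.

    QC is run separately within each family; only markers surviving QC in
    every family are retained.  Individuals dropped within their family's
    QC are dropped globally.
    """
    cfg = cfg or QCConfig()
    labels = fams.for_individuals(g.individual_ids)
    reports: dict[str, QCReport] = {}
    kept_markers: set[str] | None = None
    kept_individuals: list[str] = []
    for fam in sorted(set(labels)):
        sub = g.subset(individuals=labels == fam)
        sub_qc, rep = apply_marker_qc(sub, cfg)
        reports[fam] = rep
        kept_individuals.extend(sub_qc.individual_ids)
        fam_markers = set(sub_qc.marker_ids)
        kept_markers = fam_markers if kept_markers is None else kept_markers & fam_markers
    if not kept_markers:
        raise GenotypeError("empty after QC: no marker survived in every family")
    mk_idx = [j for j, m in enumerate(g.marker_ids) if m in kept_markers]
    ind_set = set(kept_individuals)
    ind_idx = [i for i, ind in enumerate(g.individual_ids) if ind in ind_set]
    return g.subset(individuals=np.array(ind_idx), markers=np.array(mk_idx)), reports


def knn_impute(g: GenotypeMatrix, k: int = 5) -> GenotypeMatrix:
    """Fill missing calls from the k nearest individuals.

    Distance is Euclidean over mutually non-missing markers (scaled to the
    full marker count so individuals with few shared markers are not
    artificially close).  Each missing call becomes the 1/(d+eps)-weighted
    mean of the k nearest individuals with an observed call at that marker,
    rounded half-away-from-zero to the nearest code in {0,1,2}.  Distance
    ties are broken by individual-ID sort order, which makes the result
    reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    miss = g.missing_mask()
    if not miss.any():
        return g
    X = g.dosages()
    n, p = X.shape
    obs = ~np.isnan(X)
    X0 = np.where(obs, X, 0.0)

    # pairwise mean squared difference over shared markers
    shared = obs.astype(float) @ obs.T.astype(float)
    sq = X0**2
    cross = X0 @ X0.T
    # sum over shared markers of (x - y)^2 = sum x^2*obs_y + sum y^2*obs_x - 2 x.y
    ssq = sq @ obs.T.astype(float) + obs.astype(float) @ sq.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(shared > 0, ssq / shared, np.inf)
    d = np.sqrt(np.maximum(d2, 0.0))
    np.fill_diagonal(d, np.inf)

    # deterministic tie-break: sort by (distance, individual id)
    id_rank = np.argsort(np.argsort(g.individual_ids))
    calls = g.calls.copy()
    eps = 1e-9
    for i in np.flatnonzero(miss.any(axis=1)):
        order = np.lexsort((id_rank, d[i]))
        for j in np.flatnonzero(miss[i]):
            donors = [t for t in order if obs[t, j] and np.isfinite(d[i, t])]
            if not donors:
                raise GenotypeError(
                    f"individual {g.individual_ids[i]} has no comparable neighbor "
                    f"for marker {g.marker_ids[j]}"
                )
            sel = donors[:k]
            w = 1.0 / (d[i, sel] + eps)
            val = float(np.dot(w, X[sel, j]) / w.sum())
            calls[i, j] = int(min(2, max(0, np.floor(val + 0.5))))
    return GenotypeMatrix(g.individual_ids, g.marker_ids, calls)
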