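"""Seeded multi-family genotype/phenotype simulator.

Emulates a panel of interconnected biparental F1 families, the data
regime that motivates subpopulation-aware genomic prediction: each family
descends from its own parent pair, allele frequencies drift between
families, within-family linkage comes in blocks, and each family carries
its own set of QTLs (with a configurable shared fraction).  Phenotypes
are genetic value plus Gaussian noise calibrated so the realized
heritability matches the requested one.

Two structural choices mirror how such panels behave in practice:

* QTLs are hidden causal loci, not columns of the emitted marker panel.
  Each QTL co-segregates with one LD block, so panel markers in that
  block tag it — but the marker-QTL phase is set by the family's
  parental haplotypes and therefore flips arbitrarily between families.
  A pooled linear model that learns a tag's effect in one family is
  misled in the others, which is the classic reason cross-population
  genomic prediction degrades and the setting the divide-and-conquer
  system is built for.
* Genetic values are centered within family, so family membership itself
  carries no trait signal: families are distinguishable from markers
  (once ``family_divergence`` > 0) but share the same trait
  distribution, as in panels where marker PCA separates families cleanly
  while the normalized trait does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_data import MISSING, FamilyAssignment, GenotypeMatrix


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the simulator.

    Defaults mirror a three-family panel with the size imbalance typical
    of perennial breeding trials (family sizes 30/127/251) and a
    moderately heritable growth trait (h2 = 0.55).
    """

    n_families: int = 3
    family_sizes: tuple[int, ...] = (30, 127, 251)
    n_markers: int = 7414
    n_qtl_per_family: int = 20
    qtl_overlap: float = 0.0
    h2: float = 0.55
    family_divergence: float = 2.0
    ld_block_size: int = 20
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.family_sizes) != self.n_families:
            raise ValueError("family_sizes length must equal n_families")
        if any(s < 1 for s in self.family_sizes) or self.n_markers < 1:
            raise ValueError("sizes must be positive")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must be in (0, 1]")
        if not 0.0 <= self.qtl_overlap <= 1.0:
            raise ValueError("qtl_overlap must be in [0, 1]")
        if self.n_qtl_per_family > self.n_markers:
            raise ValueError("n_qtl_per_family exceeds n_markers")
        if self.family_divergence < 0:
            raise ValueError("family_divergence must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth behind a simulated dataset.

    ``qtl_indices`` identify hidden causal loci (ids into the simulator's
    QTL pool, not panel columns); ``qtl_blocks`` give the LD block each
    QTL co-segregates with, i.e. which panel markers tag it.
    """

    qtl_indices: dict[str, list[int]]
    qtl_blocks: dict[str, list[int]]
    qtl_effects: dict[str, list[float]]
    genetic_values: dict[str, float]
    realized_h2: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "qtl_indices": self.qtl_indices,
                    "qtl_blocks": self.qtl_blocks,
                    "qtl_effects": self.qtl_effects,
                    "genetic_values": self.genetic_values,
                    "realized_h2": self.realized_h2,
                },
                fh,
                indent=1,
            )


def _family_frequencies(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Base frequencies ~U(0.1, 0.9), drifted per family on the logit scale."""
    base = rng.uniform(0.1, 0.9, size=cfg.n_markers)
    logit = np.log(base / (1 - base))
    freqs = np.empty((cfg.n_families, cfg.n_markers))
    for f in range(cfg.n_families):
        shift = rng.normal(0.0, cfg.family_divergence, size=cfg.n_markers)
        freqs[f] = 1.0 / (1.0 + np.exp(-(logit + shift)))
    return np.clip(freqs, 0.02, 0.98)


def _f1_family(
    rng: np.random.Generator,
    freqs: np.ndarray,
    qtl_freqs: np.ndarray,
    qtl_block: np.ndarray,
    size: int,
    block_size: int,
    parents: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Marker and hidden-QTL dosages for `size` F1 offspring of one cross.

    Parent haplotypes are drawn locus-wise from the family allele
    frequencies (or supplied).  Offspring inherit one haplotype per
    parent per LD block with no within-block recombination, and each
    hidden QTL travels with its assigned block, so panel markers tag it
    with a phase fixed by this family's parental haplotypes.
    """
    p = freqs.size
    n_q = qtl_freqs.size
    if parents is None:
        marker_par = rng.random((2, 2, p)) < freqs  # (parent, haplotype, locus)
        qtl_par = rng.random((2, 2, n_q)) < qtl_freqs
    else:
        marker_par, qtl_par = parents
    n_blocks = int(np.ceil(p / block_size))
    block_of = np.repeat(np.arange(n_blocks), block_size)[:p]
    # per offspring, per parent, per block: which haplotype is transmitted
    choice = rng.integers(0, 2, size=(size, 2, n_blocks))
    dos = np.empty((size, p), dtype=np.int16)
    qtl_dos = np.empty((size, n_q), dtype=np.int16)
    for i in range(size):
        h1 = marker_par[0, choice[i, 0, block_of], np.arange(p)]
        h2 = marker_par[1, choice[i, 1, block_of], np.arange(p)]
        dos[i] = h1.astype(np.int16) + h2.astype(np.int16)
        q1 = qtl_par[0, choice[i, 0, qtl_block], np.arange(n_q)]
        q2 = qtl_par[1, choice[i, 1, qtl_block], np.arange(n_q)]
        qtl_dos[i] = q1.astype(np.int16) + q2.astype(np.int16)
    return dos, qtl_dos


def simulate_families(
    cfg: SyntheticConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, FamilyAssignment, TruthRecord]:
    """Generate a seeded multi-family dataset.

    Returns (genotypes, phenotype table, family assignment, truth).  The
    phenotype table has columns ``individual_id, family, value``.  With
    ``h2 == 1`` the phenotype equals the genetic value exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = _family_frequencies(rng, cfg)
    n_blocks = int(np.ceil(cfg.n_markers / cfg.ld_block_size))

    # hidden QTL pool: shared QTLs first, then one private slice per family
    n_shared = int(round(cfg.qtl_overlap * cfg.n_qtl_per_family))
    per_family_private = cfg.n_qtl_per_family - n_shared
    n_qtl_total = n_shared + cfg.n_families * per_family_private
    qtl_block = rng.integers(0, n_blocks, size=n_qtl_total)
    qtl_base_freq = rng.uniform(0.1, 0.9, size=n_qtl_total)
    shared_effects = rng.normal(0.0, 1.0, size=n_shared)

    fam_labels = [f"F{f + 1}" for f in range(cfg.n_families)]
    qtl_indices: dict[str, list[int]] = {}
    qtl_effects: dict[str, list[float]] = {}
    for f, fam in enumerate(fam_labels):
        private = np.arange(
            n_shared + f * per_family_private, n_shared + (f + 1) * per_family_private
        )
        idx = np.concatenate([np.arange(n_shared), private]).astype(int)
        eff = np.concatenate([shared_effects, rng.normal(0.0, 1.0, size=per_family_private)])
        qtl_indices[fam] = idx.tolist()
        qtl_effects[fam] = eff.tolist()
    qtl_blocks = {fam: [int(qtl_block[q]) for q in qtl_indices[fam]] for fam in fam_labels}

    ind_ids: list[str] = []
    fam_map: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    g_vals: list[np.ndarray] = []
    # With zero divergence, families are meant to be statistically
    # exchangeable; distinct parent pairs would still stratify them, so
    # all families then descend from one shared cross.
    shared_parents = None
    if cfg.family_divergence == 0:
        shared_parents = (
            rng.random((2, 2, cfg.n_markers)) < freqs[0],
            rng.random((2, 2, n_qtl_total)) < qtl_base_freq,
        )
    for f, (fam, size) in enumerate(zip(fam_labels, cfg.family_sizes)):
        dos, qtl_dos = _f1_family(
            rng, freqs[f], qtl_base_freq, qtl_block, size, cfg.ld_block_size,
            parents=shared_parents,
        )
        blocks.append(dos)
        ids = [f"{fam}_{i + 1:03d}" for i in range(size)]
        ind_ids.extend(ids)
        fam_map.update({i: fam for i in ids})
        idx = np.array(qtl_indices[fam])
        eff = np.array(qtl_effects[fam])
        g = qtl_dos[:, idx].astype(float) @ eff
        g_vals.append(g - g.mean())  # family means carry no signal

    calls = np.vstack(blocks)
    g_all = np.concatenate(g_vals)

    var_g = float(np.var(g_all))
    if cfg.h2 >= 1.0 or var_g == 0.0:
        noise = np.zeros_like(g_all)
        se2 = 0.0
    else:
        se2 = var_g * (1.0 - cfg.h2) / cfg.h2
        noise = rng.normal(0.0, np.sqrt(se2), size=g_all.size)
    y = g_all + noise
    denom = var_g + se2
    realized = var_g / denom if denom > 0 else 1.0

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = calls.copy()
        calls[mask] = MISSING

    geno = GenotypeMatrix(ind_ids, [f"m{j + 1}" for j in range(cfg.n_markers)], calls)
    pheno = pd.DataFrame(
        {"individual_id": ind_ids, "family": [fam_map[i] for i in ind_ids], "value": y}
    )
    truth = TruthRecord(
        qtl_indices=qtl_indices,
        qtl_blocks=qtl_blocks,
        qtl_effects={k: list(map(float, v)) for k, v in qtl_effects.items()},
        genetic_values={i: float(v) for i, v in zip(ind_ids, g_all)},
        realized_h2=float(realized),
    )
    return geno, pheno, FamilyAssignment(fam_map), truth


def simulate_trial(
    n_genotypes: int = 100,
    h2: float = 0.55,
    n_locations: int = 2,
    n_blocks: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated field-trial phenotypes for mixed-model checks.

    One observation per genotype x location x block, with fixed location
    and block(location) effects, a genotype effect ~N(0, sg2) and residual
    ~N(0, se2) chosen so sg2/(sg2+se2) = h2 (sg2 fixed at 1).
    """
    rng = np.random.default_rng(seed)
    sg2 = 1.0
    se2 = sg2 * (1.0 - h2) / h2
    g = rng.normal(0.0, np.sqrt(sg2), size=n_genotypes)
    loc_eff = rng.normal(0.0, 0.5, size=n_locations)
    blk_eff = rng.normal(0.0, 0.3, size=(n_locations, n_blocks))
    rows = []
    for k in range(n_locations):
        for j in range(n_blocks):
            e = rng.normal(0.0, np.sqrt(se2), size=n_genotypes)
            for i in range(n_genotypes):
                rows.append(
                    {
                        "individual_id": f"G{i + 1:03d}",
                        "location": f"L{k + 1}",
                        "block": f"L{k + 1}B{j + 1}",
                        "value": 10.0 + loc_eff[k] + blk_eff[k, j] + g[i] + e[i],
                    }
                )
    return pd.DataFrame(rows)
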