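"""Two-stage divide-and-conquer genomic prediction.

The system holds one classification network (the *router*) that assigns
an unlabeled genotype to a subpopulation, and one regression network per
subpopulation that predicts the trait BLUP from that subpopulation's own
marker subset.  Marker subsets come from consensus feature selection:
the looser Inter2 set for the router (family membership is an easy,
linearly separable signal) and the strict Inter3 set for each family's
regression (trait signal is family specific).  Every component gets its
own hyperparameter grid, bounded by its own training-set size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .feature_selection import select_consensus
from .io_data import FamilyAssignment, GenotypeMatrix
from .mlp import GridSpec, MLPConfig, MLPNetwork, train_mlp, grid_search
from .phenotypes import BlupSet


@dataclass
class DCOptions:
    """Training options; defaults are the full recipe.

    ``grid_points_per_layer`` bounds the hyperparameter grid per hidden
    layer; ``activations``/``learning_rates`` default to the full grid.
    ``fs_alpha``/``fs_C`` parametrize feature selection.  ``min_family``
    is the smallest trainable family.
    """

    grid_points_per_layer: int = 8
    activations: tuple[str, ...] = ("relu", "sigmoid", "tanh")
    learning_rates: tuple[float, ...] = (0.005, 0.001, 0.0001)
    epochs: int = 200
    batch_size: int = 16
    grid_cv: int = 1  # >1 scores each regression config by k-fold CV instead of one split
    fs_alpha: float = 0.05
    fs_C: float = 1.0
    min_family: int = 8
    seed: int = 0


@dataclass
class FamilyComponent:
    markers: np.ndarray          # Inter3 indices into the marker universe
    network: MLPNetwork
    config: MLPConfig


@dataclass
class DCModel:
    """Router + per-family regression networks over a fixed marker universe."""

    marker_ids: list[str]
    router_markers: np.ndarray   # Inter2 indices
    router: MLPNetwork
    router_config: MLPConfig
    families: dict[str, FamilyComponent]
    training_log: dict = field(default_factory=dict)

    @property
    def family_labels(self) -> list[str]:
        return sorted(self.families)

    def save(self, directory: str | Path) -> None:
        """Serialize as a directory of JSON files."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "router.json").write_text(json.dumps(self.router.to_dict()))
        manifest = {
            "marker_ids": self.marker_ids,
            "router_markers": self.router_markers.tolist(),
            "families": {},
            "training_log": self.training_log,
        }
        for fam, comp in self.families.items():
            (d / f"family_{fam}.json").write_text(json.dumps(comp.network.to_dict()))
            manifest["families"][fam] = {"markers": comp.markers.tolist()}
        (d / "manifest.json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, directory: str | Path) -> "DCModel":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        router = MLPNetwork.from_dict(json.loads((d / "router.json").read_text()))
        families = {}
        for fam, meta in manifest["families"].items():
            net = MLPNetwork.from_dict(json.loads((d / f"family_{fam}.json").read_text()))
            families[fam] = FamilyComponent(
                markers=np.array(meta["markers"], int), network=net, config=net.cfg
            )
        return cls(
            marker_ids=manifest["marker_ids"],
            router_markers=np.array(manifest["router_markers"], int),
            router=router,
            router_config=router.cfg,
            families=families,
            training_log=manifest.get("training_log", {}),
        )


def induce_families(G: GenotypeMatrix, k_range: range = range(2, 6), seed: int = 0) -> FamilyAssignment:
    """Unsupervised family labels: k-means on leading genotype PCs.

    Used when no pedigree-based assignment exists; k is chosen by
    silhouette over ``k_range``.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    from .evaluation import pca_diagnostic

    scores, _ = pca_diagnostic(G, n_components=10)
    best = None
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)
        sil = silhouette_score(scores, km.labels_)
        if best is None or sil > best[0]:
            best = (sil, km.labels_)
    labels = best[1]
    return FamilyAssignment(
        {ind: f"C{lab + 1}" for ind, lab in zip(G.individual_ids, labels)}
    )


def _fit_component(
    X: np.ndarray,
    y: np.ndarray,
    task: str,
    opts: DCOptions,
    seed: int,
    config: MLPConfig | None,
) -> tuple[MLPNetwork, MLPConfig, dict]:
    """Grid-search (unless a config is pinned) then train on all rows."""
    base = MLPConfig(epochs=opts.epochs, batch_size=opts.batch_size, seed=seed)
    log: dict = {}
    if config is None:
        q = len(np.unique(y)) if task == "classification" else 1
        m = len(X)
        grid = GridSpec.from_data(
            m,
            q,
            points_per_layer=opts.grid_points_per_layer,
            activations=opts.activations,
            learning_rates=opts.learning_rates,
        )
        cv = opts.grid_cv if task == "regression" else 1
        gr = grid_search(X, y, grid, task=task, cv=cv, seed=seed, base=base)
        config = gr.best
        log["grid_size"] = len(gr.records)
        if task == "classification":
            log["best_dev_accuracy"] = max(r["accuracy"] for r in gr.records)
        else:
            log["best_dev_r"] = max(r["r"] for r in gr.records)
    net = train_mlp(X, y, config, task=task)
    if task == "regression":
        # MAE training targets the conditional median and can leave a small
        # output offset; recalibrate the output intercept on the training
        # rows so per-family predictions are unbiased before they are pooled
        shift = float(np.mean(np.asarray(y, float)) - np.mean(net.predict(X)))
        net.biases[-1] = net.biases[-1] + shift
    log["final_loss"] = net.loss_trace[-1]
    return net, config, log


def dc_fit(
    G: GenotypeMatrix,
    blups: BlupSet | np.ndarray,
    fams: FamilyAssignment | None,
    options: DCOptions | None = None,
    router_config: MLPConfig | None = None,
    family_configs: dict[str, MLPConfig] | None = None,
    marker_sets: dict[str, np.ndarray] | None = None,
) -> DCModel:
    """Train the full two-stage system on one training population.

    ``router_config``/``family_configs`` pin hyperparameters (skipping the
    grid search), and ``marker_sets`` pins feature subsets (keys:
    ``"router"`` and family labels) — both are used when refitting inside
    cross-validation folds after a one-off selection on the development
    set.  When ``fams`` is None, families are induced by clustering.
    """
    opts = options or DCOptions()
    if fams is None:
        fams = induce_families(G, seed=opts.seed)
    ids = list(G.individual_ids)
    labels = fams.for_individuals(ids)
    fam_levels = sorted(set(labels))
    if len(fam_levels) < 2:
        raise ValueError("divide-and-conquer needs >= 2 families")
    for fam in fam_levels:
        n_f = int((labels == fam).sum())
        if n_f < opts.min_family:
            raise ValueError(f"family {fam} has {n_f} training individuals (< {opts.min_family})")

    y = blups.vector(ids) if isinstance(blups, BlupSet) else np.asarray(blups, float)
    X = G.calls.astype(float)
    log: dict = {"families": {}}
    family_configs = family_configs or {}
    marker_sets = marker_sets or {}

    # stage 1: router on Inter2 markers for the family-label target
    if "router" in marker_sets:
        router_idx = np.asarray(marker_sets["router"], int)
    else:
        sel = select_consensus(X, labels, alpha=opts.fs_alpha, C=opts.fs_C, seed=opts.seed)
        router_idx = sel.inter2
        log["router_fs"] = {k: len(v) for k, v in sel.to_dict().items()}
    if router_idx.size == 0:
        raise ValueError("router feature selection returned no markers")
    router, r_cfg, r_log = _fit_component(
        X[:, router_idx], labels, "classification", opts, opts.seed, router_config
    )
    log["router"] = r_log

    # stage 2: per-family regressor on that family's Inter3 markers
    families: dict[str, FamilyComponent] = {}
    for i, fam in enumerate(fam_levels):
        rows = labels == fam
        Xf, yf = X[rows], y[rows]
        if fam in marker_sets:
            idx = np.asarray(marker_sets[fam], int)
        else:
            sel = select_consensus(Xf, yf, alpha=opts.fs_alpha, C=opts.fs_C, seed=opts.seed + 1 + i)
            idx = sel.inter3
            log["families"][fam] = {"fs": {k: len(v) for k, v in sel.to_dict().items()}}
            if idx.size == 0:
                # strict consensus can be empty on small families; fall back
                # to the looser two-vote set so the component stays trainable
                idx = sel.inter2
        if idx.size == 0:
            raise ValueError(f"feature selection returned no markers for family {fam}")
        net, cfg, f_log = _fit_component(
            Xf[:, idx], yf, "regression", opts, opts.seed + 1 + i, family_configs.get(fam)
        )
        log["families"].setdefault(fam, {}).update(f_log)
        families[fam] = FamilyComponent(markers=idx, network=net, config=cfg)

    return DCModel(
        marker_ids=list(G.marker_ids),
        router_markers=router_idx,
        router=router,
        router_config=r_cfg,
        families=families,
        training_log=log,
    )


def dc_predict(model: DCModel, G_new: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Route each individual, then score it with its family's regressor.

    Returns (predicted family labels, predicted BLUPs).  ``G_new`` must
    carry every marker of the training universe (by ID); columns are
    realigned if ordered differently.
    """
    missing = [m for m in model.marker_ids if m not in set(G_new.marker_ids)]
    if missing:
        raise ValueError(f"missing marker columns: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    if list(G_new.marker_ids) == list(model.marker_ids):
        X = G_new.calls.astype(float)
    else:
        pos = {m: j for j, m in enumerate(G_new.marker_ids)}
        X = G_new.calls[:, [pos[m] for m in model.marker_ids]].astype(float)

    routed = model.router.predict(X[:, model.router_markers])
    preds = np.empty(len(X), dtype=float)
    for fam in np.unique(routed):
        comp = model.families[str(fam)]
        rows = routed == fam
        preds[rows] = comp.network.predict(X[np.ix_(rows, comp.markers)])
    return routed.astype(str), preds
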