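import numpy as np
import pytest

from dcgs import (
    DCModel,
    DCOptions,
    FamilyAssignment,
    GenotypeMatrix,
    MLPConfig,
    dc_fit,
    dc_predict,
    fit_ridge,
    pearson_r,
)

FAST = dict(
    grid_points_per_layer=2,
    activations=("relu",),
    learning_rates=(0.005,),
    epochs=60,
)


def _two_family_cancellation(seed=0, n_per_family=60, p_trait=20, p_struct=10):
    """Noise-free construction where one marker's effect is +1 in family A
    and -1 in family B, so pooled models see the effects cancel."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_family
    X_trait = rng.integers(0, 3, size=(n, p_trait)).astype(float)
    # structure markers: near-fixed opposite alleles per family
    X_struct = np.zeros((n, p_struct))
    X_struct[:n_per_family] = rng.choice([0, 0, 0, 1], size=(n_per_family, p_struct))
    X_struct[n_per_family:] = rng.choice([1, 2, 2, 2], size=(n_per_family, p_struct))
    X = np.hstack([X_trait, X_struct])
    fam = np.array(["A"] * n_per_family + ["B"] * n_per_family)
    causal = 3
    y = np.where(fam == "A", 1.0, -1.0) * X[:, causal]
    for f in ("A", "B"):
        y[fam == f] -= y[fam == f].mean()
    ids = [f"i{k}" for k in range(n)]
    G = GenotypeMatrix(ids, [f"m{j}" for j in range(X.shape[1])], X.astype(int))
    fams = FamilyAssignment(dict(zip(ids, fam)))
    return G, y, fams, causal


class TestDcFit:
    def test_model_structure_and_composition_identity(self):
        G, y, fams, _ = _two_family_cancellation()
        model = dc_fit(G, y, fams, DCOptions(**FAST, seed=0))
        assert sorted(model.families) == ["A", "B"]
        routed, preds = dc_predict(model, G)
        X = G.calls.astype(float)
        # each prediction equals the routed family's regressor applied alone
        for fam in ("A", "B"):
            comp = model.families[fam]
            rows = routed == fam
            alone = comp.network.predict(X[np.ix_(np.flatnonzero(rows), comp.markers)])
            assert np.allclose(preds[rows], alone)

    def test_deterministic_end_to_end(self):
        G, y, fams, _ = _two_family_cancellation(seed=3)
        m1 = dc_fit(G, y, fams, DCOptions(**FAST, seed=1))
        m2 = dc_fit(G, y, fams, DCOptions(**FAST, seed=1))
        assert np.allclose(dc_predict(m1, G)[1], dc_predict(m2, G)[1])

    def test_small_family_rejected(self):
        G, y, fams, _ = _two_family_cancellation(n_per_family=10)
        opts = DCOptions(**FAST, min_family=20)
        with pytest.raises(ValueError, match="family"):
            dc_fit(G, y, fams, opts)

    def test_single_family_rejected(self):
        G, y, fams, _ = _two_family_cancellation()
        one = FamilyAssignment({i: "A" for i in G.individual_ids})
        with pytest.raises(ValueError, match=">= 2 families"):
            dc_fit(G, y, one, DCOptions(**FAST))

    def test_family_specific_selections_nearly_disjoint(self, tiny_panel):
        g, ph, fams, truth = tiny_panel
        y = ph["value"].to_numpy()
        y = y - y.mean()
        model = dc_fit(g, y, fams, DCOptions(**FAST, seed=2))
        sets = [set(comp.markers.tolist()) for comp in model.families.values()]
        # QTL sets are disjoint (overlap 0); allow a few coincidental shares
        n_qtl = len(truth.qtl_indices["F1"])
        overlap = len(sets[0] & sets[1])
        assert overlap <= 0.0 * n_qtl + 3


class TestDcPredict:
    def test_beats_pooled_ridge_under_effect_cancellation(self):
        G, y, fams, _ = _two_family_cancellation(seed=1, n_per_family=60)
        rng = np.random.default_rng(9)
        test = rng.permutation(len(y))[:24]
        train = np.setdiff1d(np.arange(len(y)), test)
        X = G.calls.astype(float)

        ridge = fit_ridge(X[train], y[train])
        r_pooled = abs(pearson_r(ridge.predict(X[test]), y[test]))
        assert r_pooled <= 0.2

        sub = G.subset(individuals=train)
        fam_sub = FamilyAssignment({i: fams.labels[i] for i in sub.individual_ids})
        model = dc_fit(sub, y[train], fam_sub, DCOptions(**{**FAST, "epochs": 200}, seed=0))
        _, preds = dc_predict(model, G.subset(individuals=test))
        assert pearson_r(preds, y[test]) >= 0.9

    def test_misrouting_degrades_accuracy_monotonically(self):
        G, y, fams, _ = _two_family_cancellation(seed=2)
        model = dc_fit(G, y, fams, DCOptions(**{**FAST, "epochs": 200}, seed=0))
        X = G.calls.astype(float)
        routed, _ = dc_predict(model, G)
        rs = []
        for rate in (0.0, 0.5, 1.0):
            rng = np.random.default_rng(4)
            flip = rng.random(len(y)) < rate
            wrong = np.where(routed == "A", "B", "A")
            use = np.where(flip, wrong, routed)
            preds = np.empty(len(y))
            for fam in ("A", "B"):
                comp = model.families[fam]
                rows = use == fam
                preds[rows] = comp.network.predict(X[np.ix_(np.flatnonzero(rows), comp.markers)])
            rs.append(pearson_r(preds, y))
        assert rs[0] > rs[1] > rs[2]

    def test_missing_markers_rejected(self):
        G, y, fams, _ = _two_family_cancellation()
        model = dc_fit(G, y, fams, DCOptions(**FAST))
        truncated = G.subset(markers=np.arange(G.n_markers - 2))
        with pytest.raises(ValueError, match="missing marker"):
            dc_predict(model, truncated)

    def test_serialization_roundtrip(self, tmp_path):
        G, y, fams, _ = _two_family_cancellation(seed=5)
        model = dc_fit(G, y, fams, DCOptions(**FAST))
        model.save(tmp_path / "model")
        loaded = DCModel.load(tmp_path / "model")
        r1, p1 = dc_predict(model, G)
        r2, p2 = dc_predict(loaded, G)
        assert np.array_equal(r1, r2)
        assert np.allclose(p1, p2)


class TestUnsupervisedMode:
    def test_induced_families_recover_structure(self, tiny_panel):
        from dcgs import induce_families

        g, ph, fams, _ = tiny_panel
        induced = induce_families(g, seed=0)
        true_labels = fams.for_individuals(g.individual_ids)
        ind_labels = induced.for_individuals(g.individual_ids)
        # cluster labels must align with true families up to renaming
        from collections import Counter

        agree = 0
        for c in set(ind_labels):
            agree += Counter(true_labels[ind_labels == c]).most_common(1)[0][1]
        assert agree / len(true_labels) > 0.95
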