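import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcgs import (
    CVScheme,
    FamilyAssignment,
    GenotypeMatrix,
    accuracy,
    compare_models,
    make_splits,
    mape,
    pca_diagnostic,
    pearson_r,
)


def _fams(counts):
    labels = {}
    i = 0
    for fam, c in counts.items():
        for _ in range(c):
            labels[f"i{i}"] = fam
            i += 1
    return list(labels), FamilyAssignment(labels)


class TestMetrics:
    def test_identity_gives_perfect_scores(self):
        a = np.array([1.0, 2.0, 3.0])
        assert pearson_r(a, a) == pytest.approx(1.0)
        assert mape(a, a) == pytest.approx(0.0)

    def test_mape_hand_example(self):
        assert mape([1.0, 2.0], [2.0, 4.0]) == pytest.approx(50.0)

    def test_accuracy_fraction(self):
        assert accuracy(["a", "b", "b", "a"], ["a", "b", "b", "b"]) == pytest.approx(0.75)

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=200), rng.normal(size=200)
        ref_r = stats.pearsonr(a, b).statistic
        assert pearson_r(a, b) == pytest.approx(ref_r, abs=1e-10)
        ref_mape = float(np.mean(np.abs(a - b) / np.abs(b)) * 100)
        assert mape(a, b) == pytest.approx(ref_mape, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_mape_excludes_near_zero_truth(self):
        val = mape([1.0, 5.0], [0.0, 4.0])
        assert val == pytest.approx(25.0)
        with pytest.raises(ValueError):
            mape([1.0], [0.0])


class TestSplits:
    def test_stratified_holdout_proportions(self):
        ids, fams = _fams({"A": 50, "B": 30, "C": 20})
        split = make_splits(ids, fams, CVScheme(kind="stratified_holdout", test_fraction=0.10, seed=0))[0]
        labels = fams.for_individuals([ids[i] for i in split.test_idx])
        counts = dict(zip(*np.unique(labels, return_counts=True)))
        assert counts == {"A": 5, "B": 3, "C": 2}
        assert len(split.train_idx) == 90

    def test_kfold_family_proportions_within_one(self):
        ids, fams = _fams({"A": 50, "B": 30, "C": 21})
        labels = fams.for_individuals(ids)
        splits = make_splits(ids, fams, CVScheme(kind="stratified_kfold", k=4, repetitions=3, seed=1))
        assert len(splits) == 12
        for split in splits:
            test_labels = labels[split.test_idx]
            for fam, total in zip(*np.unique(labels, return_counts=True)):
                expected = total / 4
                got = (test_labels == fam).sum()
                assert abs(got - expected) <= 1.0

    def test_folds_partition_individuals(self):
        ids, fams = _fams({"A": 17, "B": 9})
        splits = make_splits(ids, fams, CVScheme(kind="stratified_kfold", k=4, repetitions=1, seed=2))
        covered = np.concatenate([s.test_idx for s in splits])
        assert sorted(covered.tolist()) == list(range(26))

    def test_loo(self):
        splits = make_splits([f"i{k}" for k in range(7)], None, CVScheme(kind="loo"))
        assert len(splits) == 7
        assert all(s.test_idx.size == 1 for s in splits)

    def test_seed_reproducibility(self):
        ids, fams = _fams({"A": 40, "B": 25})
        s1 = make_splits(ids, fams, CVScheme(kind="stratified_kfold", k=4, repetitions=2, seed=9))
        s2 = make_splits(ids, fams, CVScheme(kind="stratified_kfold", k=4, repetitions=2, seed=9))
        for a, b in zip(s1, s2):
            assert np.array_equal(a.test_idx, b.test_idx)


class TestCompareModels:
    def _records(self, scores_by_model):
        rows = []
        for model, scores in scores_by_model.items():
            for i, s in enumerate(scores):
                rows.append({"model": model, "repetition": 0, "fold": i, "r": s})
        return pd.DataFrame(rows)

    def test_identical_models_share_letter(self):
        v = list(np.linspace(0.1, 0.9, 10))
        res = compare_models(self._records({"m1": v, "m2": v}))
        assert res.letters["m1"] == res.letters["m2"]

    def test_clear_winner_gets_own_letter(self):
        rng = np.random.default_rng(0)
        res = compare_models(
            self._records(
                {
                    "a": rng.normal(0.2, 0.05, 50),
                    "b": rng.normal(0.2, 0.05, 50),
                    "c": rng.normal(0.8, 0.05, 50),
                }
            )
        )
        assert res.letters["c"] not in (res.letters["a"], res.letters["b"])
        assert set(res.letters["a"]) & set(res.letters["b"])
        assert res.anova_p < 1e-6

    def test_hand_computed_anova_f(self):
        res = compare_models(
            self._records({"g1": [1, 2, 3], "g2": [2, 3, 4], "g3": [3, 4, 5]})
        )
        assert res.anova_f == pytest.approx(3.0)

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            compare_models(self._records({"only": [0.1, 0.2]}))


class TestPcaDiagnostic:
    def test_separated_clouds_split_on_pc1(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.2, size=(30, 10))
        b = rng.normal(3, 0.2, size=(30, 10))
        X = np.vstack([a, b])
        scores, frac = pca_diagnostic(X, n_components=2)
        labels = np.array([0] * 30 + [1] * 30)
        assert silhouette_score(scores[:, :1], labels) > 0.9

    def test_variance_fractions_bounded(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 8))
        _, frac = pca_diagnostic(X, n_components=8)
        assert frac.sum() <= 1.0 + 1e-9

    def test_column_permutation_leaves_scores_unchanged_up_to_sign(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 6))
        s1, _ = pca_diagnostic(X, n_components=3)
        s2, _ = pca_diagnostic(X[:, ::-1], n_components=3)
        for j in range(3):
            assert np.allclose(s1[:, j], s2[:, j], atol=1e-8) or np.allclose(
                s1[:, j], -s2[:, j], atol=1e-8
            )

    def test_genotype_matrix_input(self, small_genotypes):
        scores, frac = pca_diagnostic(small_genotypes)
        assert scores.shape[0] == 5
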