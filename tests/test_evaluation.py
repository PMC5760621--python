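"""Cross-validation protocol and ranking metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sigtarget import (
    ConfigurationError,
    FeatureMatrix,
    SyntheticConfig,
    auc,
    aupr,
    build_label_matrix,
    build_protein_similarity,
    cell_average,
    compound_kfold_split,
    cross_validate,
    generate,
    stratify_by_degree,
)


def auc_by_enumeration(scores, labels):
    """Exhaustive positive-negative pair counting, ties worth 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def aupr_by_enumeration(scores, labels):
    """Average precision from the sorted list (average ties' precision)."""
    order = np.argsort(np.asarray(scores, float))[::-1]
    y = np.asarray(labels)[order]
    s = np.asarray(scores, float)[order]
    # group ties: sklearn's AP steps through distinct thresholds
    precisions = []
    tp = fp = 0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            j += 1
        new_tp = int((y[i:j] == 1).sum())
        tp += new_tp
        fp += (j - i) - new_tp
        if new_tp:
            precisions.append((new_tp, tp / (tp + fp)))
        i = j
    n_pos = int((np.asarray(labels) == 1).sum())
    return sum(k * p for k, p in precisions) / n_pos


class TestCompoundKfoldSplit:
    def test_even_fold_sizes(self):
        folds = compound_kfold_split([f"c{i}" for i in range(10)], 5, seed=0)
        sizes = np.bincount(list(folds.values()))
        assert list(sizes) == [2, 2, 2, 2, 2]

    def test_disjoint_exhaustive_nearly_balanced(self):
        compounds = [f"c{i}" for i in range(23)]
        folds = compound_kfold_split(compounds, 5, seed=3)
        assert set(folds) == set(compounds)
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert sizes.sum() == 23 and sizes.max() - sizes.min() <= 1

    def test_deterministic_under_seed(self):
        compounds = [f"c{i}" for i in range(17)]
        assert compound_kfold_split(compounds, 4, 9) == compound_kfold_split(
            compounds, 4, 9
        )

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ConfigurationError):
            compound_kfold_split(["a", "b"], 3, 0)


class TestAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([4, 3, 2, 1], [1, 1, -1, -1], 1.0),
            ([1, 2, 3, 4], [1, 1, -1, -1], 0.0),
            ([4, 3, 2, 1], [1, -1, 1, -1], 0.75),
            ([1, 1, 1, 1], [1, -1, 1, -1], 0.5),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            auc([1, 2], [1, 1])

    @given(
        n=hst.integers(4, 60),
        seed=hst.integers(0, 10_000),
        tie_prob=hst.floats(0.0, 0.8),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_equals_exhaustive_pair_enumeration(self, n, seed, tie_prob):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n)
        ties = rng.random(n) < tie_prob
        scores[ties] = np.round(scores[ties])  # force ties
        labels = rng.choice([-1, 1], size=n)
        labels[0], labels[1] = 1, -1
        assert auc(scores, labels) == pytest.approx(
            auc_by_enumeration(scores, labels), abs=1e-12
        )


class TestAupr:
    def test_perfect_ranking(self):
        assert aupr([5, 4, 3, 2, 1], [1, 1, -1, -1, -1]) == pytest.approx(1.0)

    def test_alternating_example(self):
        # positives at ranks 1 and 3: (1 + 2/3) / 2
        assert aupr([4, 3, 2, 1], [1, -1, 1, -1]) == pytest.approx((1 + 2 / 3) / 2)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(5)
        n, n_pos = 4000, 400
        labels = np.array([1] * n_pos + [-1] * (n - n_pos))
        vals = [aupr(rng.normal(size=n), labels) for _ in range(5)]
        assert np.mean(vals) == pytest.approx(0.1, abs=0.03)

    @given(n=hst.integers(5, 40), seed=hst.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_stepwise_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=n), 1)  # some ties
        labels = rng.choice([-1, 1], size=n)
        labels[0], labels[1] = 1, -1
        assert aupr(scores, labels) == pytest.approx(
            aupr_by_enumeration(scores, labels), abs=1e-12
        )


@pytest.fixture(scope="module")
def cv_world():
    cfg = SyntheticConfig(
        n_genes=120, n_proteins=6, n_compounds=60, signal_strength=3.0,
        fraction_activators=0.0, seed=21,
    )
    ds = generate(cfg)
    chem = FeatureMatrix.from_profiles(cell_average(ds.chemical))
    kd = FeatureMatrix.from_profiles(cell_average(ds.knockdown))
    labels = build_label_matrix(ds.interactions, "inhibition")
    return chem, kd, labels


class TestCrossValidate:
    def test_dc_high_snr_recovers_targets(self, cv_world):
        chem, kd, labels = cv_world
        res = cross_validate(
            chem, labels, method="dc", protein_profiles=kd, k=5, seed=0
        )
        assert res.summary["mean_auc"] > 0.9

    def test_pooled_counts_match_label_totals(self, cv_world):
        chem, kd, labels = cv_world
        res = cross_validate(
            chem, labels, method="dc", protein_profiles=kd, k=5, seed=0
        )
        for row in res.table.itertuples():
            j = labels.proteins.index(row.protein_id)
            assert row.n_test_pos == int((labels.labels[:, j] == 1).sum())
            assert row.n_test_neg == int((labels.labels[:, j] == -1).sum())

    def test_permuted_labels_are_null(self):
        rng = np.random.default_rng(8)
        cfg = SyntheticConfig(
            n_genes=100, n_proteins=5, n_compounds=250, signal_strength=3.0,
            fraction_activators=0.0, seed=13,
        )
        ds = generate(cfg)
        chem = FeatureMatrix.from_profiles(cell_average(ds.chemical))
        kd = FeatureMatrix.from_profiles(cell_average(ds.knockdown))
        labels = build_label_matrix(ds.interactions, "inhibition")
        perm = rng.permutation(len(labels.compounds))
        shuffled = type(labels)(
            labels.mode,
            labels.compounds,
            labels.proteins,
            labels.labels[perm],
        )
        res = cross_validate(
            chem, shuffled, method="dc", protein_profiles=kd, k=5, seed=1
        )
        assert 0.4 <= res.summary["mean_auc"] <= 0.6

    def test_jl_beats_chance_at_high_snr(self, cv_world):
        chem, kd, labels = cv_world
        res = cross_validate(
            chem, labels, method="jl", similarity=build_protein_similarity(kd),
            k=5, seed=0,
        )
        assert res.summary["mean_auc"] > 0.8

    def test_balanced_and_full_training_share_test_sets(self, cv_world):
        chem, kd, labels = cv_world
        sim = build_protein_similarity(kd)
        full = cross_validate(chem, labels, method="jl", similarity=sim, k=5, seed=0)
        balanced = cross_validate(
            chem, labels, method="jl", similarity=sim, k=5, seed=0,
            sampling="balanced:3",
        )
        assert full.fold_assignment == balanced.fold_assignment
        cols = ["protein_id", "n_test_pos", "n_test_neg"]
        assert full.table[cols].equals(balanced.table[cols])

    def test_missing_inputs_rejected(self, cv_world):
        chem, kd, labels = cv_world
        with pytest.raises(ConfigurationError):
            cross_validate(chem, labels, method="dc")
        with pytest.raises(ConfigurationError):
            cross_validate(chem, labels, method="jl")


class TestStratifyByDegree:
    def test_single_bin_equals_overall_mean(self, cv_world):
        chem, kd, labels = cv_world
        res = cross_validate(chem, labels, method="dc", protein_profiles=kd, k=5, seed=0)
        table = stratify_by_degree(res, [(1, np.inf)])
        assert table.loc[0, "mean_auc"] == pytest.approx(res.summary["mean_auc"])
        assert table.loc[0, "count"] == len(res.table)

    def test_bins_partition_and_empty_bin_reported(self, cv_world):
        chem, kd, labels = cv_world
        res = cross_validate(chem, labels, method="dc", protein_profiles=kd, k=5, seed=0)
        maxdeg = res.table["degree"].max()
        table = stratify_by_degree(res, [(1, 1), (2, maxdeg), (maxdeg + 1, np.inf)])
        assert table["count"].sum() == len(res.table)
        assert table.loc[2, "count"] == 0 and np.isnan(table.loc[2, "mean_auc"])

    def test_uncovered_degrees_rejected(self, cv_world):
        chem, kd, labels = cv_world
        res = cross_validate(chem, labels, method="dc", protein_profiles=kd, k=5, seed=0)
        with pytest.raises(ConfigurationError):
            stratify_by_degree(res, [(1, 1)])

    def test_degree_dependent_signal_gives_monotone_auc(self):
        """Stronger per-protein programs at higher degree -> higher AUC bins."""
        degrees = [1, 1, 1, 1, 4, 4, 4, 4]
        scale = [0.4] * 4 + [1.6] * 4
        cfg = SyntheticConfig(
            n_genes=150, n_proteins=8, n_compounds=40, signal_strength=1.0,
            protein_degrees=degrees, protein_signal_scale=scale,
            fraction_activators=0.0, seed=4,
        )
        ds = generate(cfg)
        chem = FeatureMatrix.from_profiles(cell_average(ds.chemical))
        kd = FeatureMatrix.from_profiles(cell_average(ds.knockdown))
        labels = build_label_matrix(ds.interactions, "inhibition")
        res = cross_validate(chem, labels, method="dc", protein_profiles=kd, k=4, seed=0)
        table = stratify_by_degree(res, [(1, 1), (2, np.inf)])
        assert table.loc[1, "mean_auc"] >= table.loc[0, "mean_auc"]
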