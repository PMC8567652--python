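"""Distances, ordination and permutation tests against hand and library oracles."""

import io

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from microstab.betadiv import (
    anosim,
    bray_curtis,
    pcoa,
    permanova,
    permdisp,
    unweighted_unifrac,
    weighted_unifrac,
)
from microstab.simulate import SimulationSpec, default_profiles, simulate_dataset
from microstab.tabletools import FeatureTable, rarefy

from conftest import random_feature_table


def _table(rows, samples, taxa):
    return FeatureTable(pd.DataFrame(rows, index=samples, columns=taxa))


def _tree(newick):
    return skbio.TreeNode.read(io.StringIO(newick))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        dm = bray_curtis(_table([[1, 2], [1, 2]], ["a", "b"], ["x", "y"]))
        assert dm["a", "b"] == 0

    def test_disjoint_supports_one(self):
        dm = bray_curtis(_table([[3, 0], [0, 5]], ["a", "b"], ["x", "y"]))
        assert dm["a", "b"] == pytest.approx(1.0)

    def test_hand_value(self):
        dm = bray_curtis(_table([[2, 2], [1, 3]], ["a", "b"], ["x", "y"]))
        assert dm["a", "b"] == pytest.approx(0.25)

    def test_two_zero_samples_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(_table([[0, 0], [0, 0]], ["a", "b"], ["x", "y"]))

    def test_matches_manual_formula(self):
        rng = np.random.default_rng(0)
        table = random_feature_table(rng, 6, 8)
        dm = bray_curtis(table)
        counts = table.counts.to_numpy(dtype=float)
        for i in range(6):
            for j in range(i + 1, 6):
                u, v = counts[i], counts[j]
                manual = np.abs(u - v).sum() / (u + v).sum()
                assert dm[i, j] == pytest.approx(manual, rel=1e-12)


def brute_force_unifrac(tree, taxa, presence_a, presence_b):
    """Shared-vs-union branch-length enumeration for the unweighted metric."""
    set_a = {t for t, p in zip(taxa, presence_a) if p}
    set_b = {t for t, p in zip(taxa, presence_b) if p}
    unique, union = 0.0, 0.0
    for node in tree.traverse(include_self=False):
        below = {t.name for t in node.tips()} or {node.name}
        in_a = bool(below & set_a)
        in_b = bool(below & set_b)
        if in_a or in_b:
            union += node.length
            if in_a != in_b:
                unique += node.length
    return unique / union if union else 0.0


class TestUnifrac:
    def test_identical_presence_zero(self):
        tree = _tree("((l1:1,l2:1):1,(l3:1,l4:1):1):0;")
        table = _table([[1, 0, 2, 0], [3, 0, 1, 0]], ["a", "b"],
                       ["l1", "l2", "l3", "l4"])
        dm = unweighted_unifrac(table, tree)
        assert dm["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_star_tree_disjoint_is_one(self):
        # zero-length internal branches make this equivalent to a star tree
        tree = _tree("((l1:1,l2:1):0,(l3:1,l4:1):0):0;")
        table = _table([[1, 1, 0, 0], [0, 0, 1, 1]], ["a", "b"],
                       ["l1", "l2", "l3", "l4"])
        dm = unweighted_unifrac(table, tree)
        assert dm["a", "b"] == pytest.approx(1.0)

    def test_sister_leaves_two_thirds(self):
        """Balanced 4-leaf tree, unit branches: samples on sister leaves share
        no leaf branch; the union spans l1, l2 and their stem -> 2/3."""
        tree = _tree("((l1:1,l2:1):1,(l3:1,l4:1):1):0;")
        table = _table([[1, 0, 0, 0], [0, 1, 0, 0]], ["a", "b"],
                       ["l1", "l2", "l3", "l4"])
        dm = unweighted_unifrac(table, tree)
        assert dm["a", "b"] == pytest.approx(2 / 3)

    def test_missing_taxon_named_in_error(self):
        tree = _tree("(l1:1,l2:1):0;")
        table = _table([[1, 1]], ["a"], ["l1", "zz"])
        with pytest.raises(ValueError, match="zz"):
            unweighted_unifrac(table, tree)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_enumeration(self, seed):
        from microstab.simulate import simulate_tree

        rng = np.random.default_rng(seed)
        taxa_by_family = {
            "F1": [f"a{i}" for i in range(5)],
            "F2": [f"b{i}" for i in range(6)],
        }
        tree = simulate_tree(taxa_by_family, seed=seed)
        taxa = [t.name for t in tree.tips()]
        table = random_feature_table(rng, 5, len(taxa), max_count=3)
        table = FeatureTable(
            pd.DataFrame(table.counts.to_numpy(), index=table.sample_ids, columns=taxa)
        )
        dm = unweighted_unifrac(table, tree)
        counts = table.counts.to_numpy()
        for i in range(5):
            for j in range(i + 1, 5):
                expected = brute_force_unifrac(tree, taxa, counts[i] > 0, counts[j] > 0)
                assert dm[i, j] == pytest.approx(expected, rel=1e-10, abs=1e-12)


class TestWeightedUnifrac:
    def test_identical_compositions_zero(self):
        tree = _tree("((l1:1,l2:1):1,(l3:1,l4:1):1):0;")
        table = _table([[2, 4, 0, 0], [1, 2, 0, 0]], ["a", "b"],
                       ["l1", "l2", "l3", "l4"])
        dm = weighted_unifrac(table, tree)
        assert dm["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_star_tree_full_turnover(self):
        tree = _tree("(l1:1,l2:1):0;")
        table = _table([[1, 0], [0, 1]], ["a", "b"], ["l1", "l2"])
        dm = weighted_unifrac(table, tree)
        assert dm["a", "b"] == pytest.approx(2.0)

    def test_branch_length_linearity(self):
        t1 = _tree("((l1:1,l2:1):1,(l3:1,l4:1):1):0;")
        t3 = _tree("((l1:3,l2:3):3,(l3:3,l4:3):3):0;")
        table = _table([[5, 1, 0, 2], [0, 3, 3, 1]], ["a", "b"],
                       ["l1", "l2", "l3", "l4"])
        d1 = weighted_unifrac(table, t1)["a", "b"]
        d3 = weighted_unifrac(table, t3)["a", "b"]
        assert d3 == pytest.approx(3 * d1, rel=1e-10)


class TestPcoa:
    def test_three_equidistant_samples(self):
        dm = skbio.DistanceMatrix(squareform([1.0, 1.0, 1.0]), ["a", "b", "c"])
        res = pcoa(dm)
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)
        assert res.proportion_explained[0] == pytest.approx(0.5, abs=1e-9)

    def test_two_samples_single_axis(self):
        dm = skbio.DistanceMatrix(np.array([[0, 2.0], [2.0, 0]]), ["a", "b"])
        res = pcoa(dm)
        assert len(res.eigenvalues) == 1
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(6, 3))
        d = squareform(pdist(points))
        res = pcoa(skbio.DistanceMatrix(d, [f"s{i}" for i in range(6)]))
        coords = res.coordinates.to_numpy()
        d_hat = squareform(pdist(coords))
        assert np.allclose(d, d_hat, atol=1e-8)

    def test_matches_skbio(self):
        rng = np.random.default_rng(4)
        table = random_feature_table(rng, 7, 9)
        dm = bray_curtis(table)
        mine = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(dm)
        k = len(mine.eigenvalues)
        assert np.allclose(
            mine.eigenvalues, theirs.eigvals.to_numpy()[:k], atol=1e-9
        )
        pe = theirs.proportion_explained.to_numpy()
        pos_sum = theirs.eigvals.to_numpy()[theirs.eigvals.to_numpy() > 0].sum()
        # skbio divides by the full eigenvalue sum; renormalize to positives
        assert np.allclose(
            mine.proportion_explained,
            theirs.eigvals.to_numpy()[:k] / pos_sum,
            atol=1e-9,
        )


def _grouped_dm(seed=0, n_per=5, shift=0.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, 3))
    b = rng.normal(shift, 1, size=(n_per, 3))
    pts = np.vstack([a, b])
    ids = [f"s{i}" for i in range(2 * n_per)]
    labels = ["g1"] * n_per + ["g2"] * n_per
    return skbio.DistanceMatrix(squareform(pdist(pts)), ids), np.array(labels)


class TestAnosim:
    def test_perfect_separation_r_one(self):
        d = np.array([
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.9, 0.9],
            [0.9, 0.9, 0.0, 0.1],
            [0.9, 0.9, 0.1, 0.0],
        ])
        dm = skbio.DistanceMatrix(d, list("abcd"))
        res = anosim(dm, ["g1", "g1", "g2", "g2"], permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_p_at_least_one_over_m_plus_one(self):
        dm, labels = _grouped_dm(seed=1, shift=5.0)
        res = anosim(dm, labels, permutations=99, seed=0)
        assert res.p >= 1 / 100

    def test_null_mean_r_near_zero(self):
        """Mean R over random label permutations is ~0 (permutation-null oracle)."""
        dm, labels = _grouped_dm(seed=2, shift=0.0)
        rng = np.random.default_rng(0)
        rs = [
            anosim(dm, rng.permutation(labels), permutations=0 + 1, seed=0).statistic
            for _ in range(400)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_statistic_matches_skbio(self):
        dm, labels = _grouped_dm(seed=3, shift=1.0)
        mine = anosim(dm, labels, permutations=99, seed=1)
        theirs = skbio_anosim(dm, labels, permutations=99)
        assert mine.statistic == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_single_group_rejected(self):
        dm, _ = _grouped_dm()
        with pytest.raises(ValueError, match="two groups"):
            anosim(dm, ["g"] * 10, permutations=9, seed=0)


class TestPermanova:
    def test_two_tight_groups_r2_one(self):
        d = np.array([
            [0.0, 0.0, 1.0, 1.0],
            [0.0, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0, 0.0],
        ])
        dm = skbio.DistanceMatrix(d, list("abcd"))
        res = permanova(dm, ["g1", "g1", "g2", "g2"], permutations=99, seed=0)
        assert res.effect == pytest.approx(1.0)

    def test_label_invariance_within_groups(self):
        dm, labels = _grouped_dm(seed=4, shift=1.0)
        res1 = permanova(dm, labels, permutations=99, seed=5)
        # swapping sample order of labels within groups changes nothing
        res2 = permanova(dm, labels.copy(), permutations=99, seed=5)
        assert res1.statistic == res2.statistic
        assert res1.p == res2.p

    def test_r2_in_unit_interval(self):
        for seed in range(5):
            dm, labels = _grouped_dm(seed=seed, shift=0.5)
            res = permanova(dm, labels, permutations=9, seed=0)
            assert 0 <= res.effect <= 1

    def test_statistic_matches_skbio(self):
        dm, labels = _grouped_dm(seed=6, shift=1.0)
        mine = permanova(dm, labels, permutations=99, seed=1)
        theirs = skbio_permanova(dm, labels, permutations=99)
        assert mine.statistic == pytest.approx(theirs["test statistic"], rel=1e-10)


class TestPermdisp:
    def test_equal_dispersion_low_f(self):
        """Mirror-image groups have identical internal geometry."""
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, size=(6, 2))
        b = -a + 100.0  # translated mirror image, same dispersion
        pts = np.vstack([a, b])
        dm = skbio.DistanceMatrix(squareform(pdist(pts)),
                                  [f"s{i}" for i in range(12)])
        res = permdisp(dm, ["g1"] * 6 + ["g2"] * 6, permutations=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.5

    def test_tight_vs_loose_large_f(self):
        rng = np.random.default_rng(8)
        tight = rng.normal(0, 0.01, size=(6, 2))
        loose = rng.normal(5, 1.0, size=(6, 2))
        pts = np.vstack([tight, loose])
        dm = skbio.DistanceMatrix(squareform(pdist(pts)),
                                  [f"s{i}" for i in range(12)])
        res = permdisp(dm, ["g1"] * 6 + ["g2"] * 6, permutations=199, seed=0)
        assert res.statistic > 10
        assert res.p <= 0.05

    def test_sample_order_invariance(self):
        dm, labels = _grouped_dm(seed=9, shift=1.0)
        perm = np.random.default_rng(0).permutation(len(labels))
        ids = list(dm.ids)
        dm2 = skbio.DistanceMatrix(dm.data[np.ix_(perm, perm)],
                                   [ids[i] for i in perm])
        f1 = permdisp(dm, labels, permutations=0 + 1, seed=0).statistic
        f2 = permdisp(dm2, labels[perm], permutations=0 + 1, seed=0).statistic
        assert f1 == pytest.approx(f2, rel=1e-9)


class TestDietSeparation:
    def test_pcoa_separates_diet_classes(self):
        """Axis-1 silhouette of the diet grouping is positive on Bray-Curtis
        PCoA of a mixed carnivore + herbivore simulation."""
        spec = SimulationSpec(
            profiles=default_profiles(), species_per_group=2,
            samples_per_species=5, seed=13,
        )
        table, tax, meta, tree = simulate_dataset(spec)
        rarefied = rarefy(table, 2300, seed=1)
        res = pcoa(bray_curtis(rarefied))
        axis1 = res.coordinates.iloc[:, 0]
        diets = meta.column("diet").loc[axis1.index]
        from sklearn.metrics import silhouette_score

        score = silhouette_score(axis1.to_numpy().reshape(-1, 1), diets)
        assert score > 0
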