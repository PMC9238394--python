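"""Phylogeny-aware algorithms: distances, covariance, matched controls,
phylo-PCA, phylogenetic logistic regression, max contrasting pairs."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import random_binary_tree, star_newick
from _oracles import brute_matched_subsets, brute_max_contrasting_pairs, brute_patristic

from panhab.io import read_newick
from panhab.phylo import (
    label_permutation_test,
    matched_control_selection,
    max_contrasting_pairs,
    patristic_distances,
    phylo_pca,
    phylo_vcv,
    phyloglm_test,
)


class TestPatristic:
    def test_hand_sums(self, small_tree):
        D = patristic_distances(small_tree)
        assert D.loc["A", "B"] == pytest.approx(1.0)
        assert D.loc["A", "C"] == pytest.approx(1.4)
        assert np.allclose(np.diag(D.to_numpy()), 0.0)

    def test_star_tree(self):
        D = patristic_distances(read_newick(star_newick(6, 0.8)))
        off = D.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.allclose(off, 1.6)

    def test_matches_edge_set_oracle(self):
        t = random_binary_tree(20, seed=3)
        D = patristic_distances(t)
        labels = list(D.index)
        for a, b in [(labels[i], labels[j]) for i in range(0, 20, 3)
                     for j in range(i + 1, 20, 5)]:
            assert D.loc[a, b] == pytest.approx(brute_patristic(t, a, b), abs=1e-9)


class TestPhyloVCV:
    def test_hand_values(self, small_tree):
        C = phylo_vcv(small_tree)
        assert C.loc["A", "B"] == pytest.approx(0.2)
        assert C.loc["A", "A"] == pytest.approx(0.7)
        assert C.loc["A", "C"] == pytest.approx(0.0)

    def test_star_tree_diagonal(self):
        C = phylo_vcv(read_newick(star_newick(5)))
        assert np.allclose(C.to_numpy(), np.eye(5))

    def test_patristic_identity_on_random_trees(self):
        """C[i,i] + C[j,j] - 2 C[i,j] equals the patristic distance."""
        for seed in range(30):
            t = random_binary_tree(10, seed)
            C = phylo_vcv(t).to_numpy()
            D = patristic_distances(t).to_numpy()
            ident = np.add.outer(np.diag(C), np.diag(C)) - 2 * C
            assert np.allclose(ident, D, atol=1e-9)

    def test_positive_semidefinite(self):
        for seed in range(5):
            C = phylo_vcv(random_binary_tree(15, seed)).to_numpy()
            assert np.linalg.eigvalsh(C).min() > -1e-8


class TestMatchedControls:
    def test_full_pool_zero_deviation(self, rng):
        t = random_binary_tree(10, seed=7)
        D = patristic_distances(t)
        tips = list(D.index)
        res = matched_control_selection(D, tips[:3], tips[3:], size=7, repeats=20, seed=0)
        assert sorted(res["selected_ids"]) == sorted(tips[3:])
        assert res["subset_mean"] == pytest.approx(res["target_mean"])

    def test_matches_exhaustive_argmin(self):
        t = random_binary_tree(8, seed=11)
        D = patristic_distances(t)
        tips = list(D.index)
        pma, pool = tips[:4], tips[4:]
        res = matched_control_selection(D, pma, pool, size=2, repeats=400, seed=5)
        subsets = brute_matched_subsets(D, pma, pool, 2)
        # with 400 uniform draws over C(4,2)=6 subsets, all were seen; the
        # selected subset must attain the minimal |mean - target| (ties allowed)
        target = res["target_mean"]
        best_dev = min(abs(m - target) for m in subsets.values())
        sel_dev = abs(subsets[frozenset(res["selected_ids"])] - target)
        assert sel_dev == pytest.approx(best_dev, abs=1e-12)

    def test_deterministic_for_seed(self):
        t = random_binary_tree(12, seed=2)
        D = patristic_distances(t)
        tips = list(D.index)
        r1 = matched_control_selection(D, tips[:4], tips[4:], 4, 50, seed=9)
        r2 = matched_control_selection(D, tips[:4], tips[4:], 4, 50, seed=9)
        assert r1 == r2

    def test_size_exceeding_pool_rejected(self, small_tree):
        D = patristic_distances(small_tree)
        with pytest.raises(ValueError):
            matched_control_selection(D, ["A"], ["B", "C"], size=3)


class TestPhyloPCA:
    def test_star_tree_equals_standard_pca(self):
        rng = np.random.default_rng(0)
        t = read_newick(star_newick(12))
        X = pd.DataFrame(rng.normal(size=(12, 4)), index=[f"T{i}" for i in range(12)])
        res = phylo_pca(X, t)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        eigval, eigvec = np.linalg.eigh(np.cov(Xc.T, ddof=1))
        order = np.argsort(eigval)[::-1]
        ref_scores = Xc @ eigvec[:, order]
        for k in range(4):
            ours = res["scores"].to_numpy()[:, k]
            ref = ref_scores[:, k]
            assert np.allclose(ours, ref, atol=1e-8) or np.allclose(ours, -ref, atol=1e-8)

    def test_rank_one_data(self):
        t = read_newick(star_newick(8))
        base = np.arange(8, dtype=float)
        X = pd.DataFrame({"a": base, "b": 2 * base}, index=[f"T{i}" for i in range(8)])
        res = phylo_pca(X, t)
        assert res["eigenvalues"][0] > 1e-8
        assert abs(res["eigenvalues"][1]) < 1e-8

    def test_three_tip_manual_gls(self, small_tree):
        """Scores agree with a from-scratch GLS computation."""
        X = pd.DataFrame({"x": [1.0, 2.0, 4.0], "y": [0.5, 0.1, 0.9]},
                         index=["A", "B", "C"])
        res = phylo_pca(X, small_tree)
        C = np.array([[0.7, 0.2, 0.0], [0.2, 0.7, 0.0], [0.0, 0.0, 0.7]])
        Ci = np.linalg.inv(C)
        ones = np.ones((3, 1))
        a = (ones.T @ Ci @ X.to_numpy()) / (ones.T @ Ci @ ones)
        Xc = X.to_numpy() - a
        S = Xc.T @ Ci @ Xc / 2
        eigval, eigvec = np.linalg.eigh((S + S.T) / 2)
        order = np.argsort(eigval)[::-1]
        ref = Xc @ eigvec[:, order]
        for k in range(2):
            ours = res["scores"].to_numpy()[:, k]
            assert (np.allclose(ours, ref[:, k], atol=1e-8)
                    or np.allclose(ours, -ref[:, k], atol=1e-8))

    def test_too_few_tips_rejected(self, small_tree):
        X = pd.DataFrame({"x": [1.0, 2.0], "y": [3.0, 4.0]}, index=["A", "B"])
        with pytest.raises(ValueError):
            phylo_pca(X, small_tree)


class TestPhyloGLM:
    def test_star_tree_reduces_to_logistic(self):
        rng = np.random.default_rng(4)
        n = 50
        t = read_newick(star_newick(n))
        x = rng.normal(size=n)
        xs = (x - x.mean()) / x.std()
        y = (rng.random(n) < 1 / (1 + np.exp(-xs))).astype(float)
        res = phyloglm_test(y, x, tree=t)
        ref = sm.GLM(y, sm.add_constant(xs), family=sm.families.Binomial()).fit()
        assert res["estimate"] == pytest.approx(ref.params[1], rel=0.01)
        assert res["p"] == pytest.approx(ref.pvalues[1], rel=0.01)
        assert res["alpha"] == 0.0

    def test_sign_convention(self):
        # covariate strongly higher in the focal class -> positive estimate
        rng = np.random.default_rng(5)
        t = random_binary_tree(40, seed=1)
        from panhab.phylo import phylo_vcv as vcv
        C = vcv(t)
        y = np.array([1.0] * 12 + [0.0] * 28)
        x = np.where(y == 1, 2.5, 0.0) + rng.normal(0, 1, 40)
        res = phyloglm_test(y, x, C=C)
        assert res["estimate"] > 0
        assert res["p"] < 0.05

    def test_single_class_rejected(self, small_tree):
        with pytest.raises(ValueError):
            phyloglm_test([1, 1, 1], [0.1, 0.2, 0.3], tree=small_tree)

    def test_constant_covariate_rejected(self, small_tree):
        with pytest.raises(ValueError):
            phyloglm_test([1, 0, 1], [2.0, 2.0, 2.0], tree=small_tree)


class TestMaxContrastingPairs:
    def test_perfect_quartet(self, quartet_tree):
        geno = {"A": 1, "B": 0, "C": 1, "D": 0}
        res = max_contrasting_pairs(quartet_tree, geno, geno)
        assert (res.max_pairs, res.best_supporting, res.worst_supporting) == (2, 2, 2)

    def test_constant_genotype(self, quartet_tree):
        res = max_contrasting_pairs(quartet_tree, {t: 1 for t in "ABCD"},
                                    {"A": 1, "B": 0, "C": 1, "D": 0})
        assert res.max_pairs == 0
        assert res.p_worst == 1.0

    def test_missing_trait_rejected(self, quartet_tree):
        with pytest.raises(Exception, match="missing"):
            max_contrasting_pairs(quartet_tree, {"A": 1, "B": 0, "C": 1},
                                  {t: 0 for t in "ABCD"})

    def test_matches_exhaustive_search(self):
        """DP equals brute force over edge-disjoint pairings on small trees."""
        rng = np.random.default_rng(99)
        checked = 0
        for rep in range(200):
            n = int(rng.integers(4, 9))
            t = random_binary_tree(n, seed=1000 + rep)
            tips = [l.taxon.label for l in t.leaf_node_iter()]
            geno = {tip: int(rng.integers(0, 2)) for tip in tips}
            pheno = {tip: int(rng.integers(0, 2)) for tip in tips}
            res = max_contrasting_pairs(t, geno, pheno)
            mp, worst, best = brute_max_contrasting_pairs(t, geno, pheno)
            assert res.max_pairs == mp
            assert res.worst_supporting == worst
            assert res.best_supporting == best
            checked += 1
        assert checked == 200

    def test_p_best_not_larger_than_p_worst(self):
        rng = np.random.default_rng(3)
        for rep in range(20):
            t = random_binary_tree(12, seed=rep)
            tips = [l.taxon.label for l in t.leaf_node_iter()]
            geno = {tip: int(rng.integers(0, 2)) for tip in tips}
            pheno = {tip: int(rng.integers(0, 2)) for tip in tips}
            res = max_contrasting_pairs(t, geno, pheno)
            assert res.p_best <= res.p_worst + 1e-12


class TestLabelPermutation:
    def test_single_permutation_bounds(self, quartet_tree):
        geno = {"A": 1, "B": 0, "C": 1, "D": 0}
        p = label_permutation_test(quartet_tree, geno, geno, n_perm=1, seed=0)
        assert p in (0.5, 1.0)

    def test_perfect_association_significant(self):
        t = random_binary_tree(16, seed=8)
        tips = [l.taxon.label for l in t.leaf_node_iter()]
        rng = np.random.default_rng(2)
        geno = {tip: int(rng.integers(0, 2)) for tip in tips}
        p = label_permutation_test(t, geno, geno, n_perm=999, seed=1)
        assert p <= 0.05

    def test_deterministic_for_seed(self, quartet_tree):
        geno = {"A": 1, "B": 0, "C": 1, "D": 0}
        pheno = {"A": 1, "B": 1, "C": 0, "D": 0}
        p1 = label_permutation_test(quartet_tree, geno, pheno, n_perm=99, seed=4)
        p2 = label_permutation_test(quartet_tree, geno, pheno, n_perm=99, seed=4)
        assert p1 == p2
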