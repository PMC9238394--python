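"""Genome-wide enrichment analyses: per-term comparisons, phyloglm scan,
phylo-PCA projection, stringent pan-GWAS, stratified and targeted tests."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_binary_tree

from panhab.datatypes import (
    AnnotationMap,
    CazyLabel,
    FamilyAnnotation,
    GeneFamilyMatrix,
    GenomeMeta,
)
from panhab.enrichment import (
    PanGwasConfig,
    category_count_comparison,
    cazy_aggregate,
    clade_stratified_comparison,
    enriched_term_phylopca,
    ko_presence_matrix,
    metadata_comparison,
    pan_gwas,
    pathway_phyloglm_scan,
    targeted_ko_presence_tests,
    term_count_matrix,
    term_families,
)
from panhab.io import read_newick


def simple_annotations():
    return AnnotationMap({
        "F1": FamilyAnnotation(frozenset("C"), "K00001", frozenset({"P1"}),
                               CazyLabel("GH", 13, 1)),
        "F2": FamilyAnnotation(frozenset("C"), "K00002", frozenset({"P1"}),
                               CazyLabel("GH", 13, 31)),
        "F3": FamilyAnnotation(frozenset("G"), "K00003", frozenset({"P2"}),
                               CazyLabel("GT", 2, None)),
        "F4": FamilyAnnotation(frozenset(), None, frozenset(), CazyLabel("GH", 4, None)),
    })


class TestCategoryComparison:
    def test_identical_genomes_nothing_significant(self):
        counts = pd.DataFrame(np.ones((4, 10), dtype=int),
                              index=["F1", "F2", "F3", "F4"],
                              columns=[f"G{i}" for i in range(10)])
        metas = [GenomeMeta(f"G{i}", "PMA" if i < 3 else "NPMA") for i in range(10)]
        table = category_count_comparison(GeneFamilyMatrix(counts), simple_annotations(),
                                          metas, "COG", "copy")
        assert (table.p > 0.9).all()

    def test_implanted_copy_inflation_recovered(self, rng):
        """A 3x copy inflation of one COG letter in the focal group is flagged."""
        n_a, n_b = 15, 40
        genomes = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
        base = rng.poisson(3.0, (6, n_a + n_b))
        base[0, :n_a] = rng.poisson(9.0, n_a)  # F0 inflated in group A
        counts = pd.DataFrame(base, index=[f"F{i}" for i in range(6)], columns=genomes)
        ann = AnnotationMap({
            "F0": FamilyAnnotation(cog_category=frozenset("C")),
            **{f"F{i}": FamilyAnnotation(cog_category=frozenset("G")) for i in range(1, 6)},
        })
        metas = [GenomeMeta(g, "PMA" if g.startswith("A") else "NPMA") for g in genomes]
        table = category_count_comparison(GeneFamilyMatrix(counts), ann, metas, "COG")
        row = table[table.term == "C"].iloc[0]
        assert row.p_adj < 0.05
        assert row.direction == "A"

    def test_presence_mode_counts_distinct_families(self):
        counts = pd.DataFrame([[5, 0], [2, 1]], index=["F1", "F2"], columns=["G1", "G2"])
        ann = AnnotationMap({
            "F1": FamilyAnnotation(cog_category=frozenset("C")),
            "F2": FamilyAnnotation(cog_category=frozenset("C")),
        })
        tc = term_count_matrix(GeneFamilyMatrix(counts),
                               term_families(ann, "COG"), "presence")
        assert tc.loc["C", "G1"] == 2
        assert tc.loc["C", "G2"] == 1

    def test_cazy_class_totals_conserve_gene_counts(self, default_dataset):
        matrix, ann = default_dataset["matrix"], default_dataset["annotations"]
        by_class = term_count_matrix(matrix, term_families(ann, "CAZY_CLASS"))
        cazy_fams = [f for f, r in ann.items() if r.cazy is not None]
        totals = matrix.counts.loc[cazy_fams].sum(axis=0)
        assert np.array_equal(by_class.sum(axis=0).to_numpy(),
                              totals[by_class.columns].to_numpy())


class TestCazyAggregate:
    def test_subfamily_rollup(self):
        ann = simple_annotations()
        fam = cazy_aggregate(ann, "family")
        assert sorted(fam["GH13"]) == ["F1", "F2"]
        assert fam["GH4"] == ["F4"]
        cls = cazy_aggregate(ann, "class")
        assert sorted(cls["GH"]) == ["F1", "F2", "F4"]
        sub = cazy_aggregate(ann, "subfamily")
        assert sub["GH13_31"] == ["F2"]

    def test_class_totals_equal_family_totals(self, default_dataset):
        ann = default_dataset["annotations"]
        n_by_class = sum(len(v) for v in cazy_aggregate(ann, "class").values())
        n_by_family = sum(len(v) for v in cazy_aggregate(ann, "family").values())
        assert n_by_class == n_by_family


class TestPhyloglmScan:
    def test_enriched_pathways_recovered(self, default_dataset):
        scan = pathway_phyloglm_scan(default_dataset["matrix"],
                                     default_dataset["annotations"],
                                     default_dataset["metadata"],
                                     default_dataset["tree"])
        truth = set(default_dataset["truth"]["enriched_pathways"]["PMA"])
        flagged = set(scan[(scan.p < 0.05) & (scan.estimate > 0)].term)
        assert len(truth & flagged) >= 8  # >= 8 of the 10 implanted

    def test_constant_terms_skipped(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        counts = pd.DataFrame([[2, 2, 2, 2], [1, 0, 2, 1]],
                              index=["F1", "F2"], columns=list("ABCD"))
        ann = AnnotationMap({
            "F1": FamilyAnnotation(pathways=frozenset({"P1"})),
            "F2": FamilyAnnotation(pathways=frozenset({"P2"})),
        })
        metas = [GenomeMeta(g, "PMA" if g in "AB" else "NPMA") for g in "ABCD"]
        scan = pathway_phyloglm_scan(GeneFamilyMatrix(counts), ann, metas, t)
        assert list(scan.term) == ["P2"]


class TestPhyloPCAProjection:
    def test_disjoint_profiles_separate(self, rng):
        n_a, n_b = 10, 20
        tree = random_binary_tree(n_a + n_b, seed=5)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        metas = [GenomeMeta(t, "PMA" if i < n_a else "NPMA")
                 for i, t in enumerate(tips)]
        counts = np.zeros((4, n_a + n_b), dtype=int)
        counts[0:2, :n_a] = rng.poisson(6, (2, n_a))   # terms P1,P2 in group A
        counts[2:4, n_a:] = rng.poisson(6, (2, n_b))   # terms P3,P4 in group B
        matrix = GeneFamilyMatrix(pd.DataFrame(counts, index=list("WXYZ"), columns=tips))
        ann = AnnotationMap({f: FamilyAnnotation(pathways=frozenset({p}))
                             for f, p in zip("WXYZ", ["P1", "P2", "P3", "P4"])})
        res = enriched_term_phylopca(matrix, ann, metas, tree, ["P1", "P2", "P3", "P4"])
        assert res["pc_habitat_p"]["PC1"] < 0.01

    def test_identical_profiles_not_separated(self):
        tree = random_binary_tree(12, seed=9)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        metas = [GenomeMeta(t, "PMA" if i < 4 else "NPMA") for i, t in enumerate(tips)]
        rng = np.random.default_rng(0)
        counts = np.tile(rng.poisson(4, (3, 1)), (1, 12)) + rng.integers(0, 2, (3, 12))
        matrix = GeneFamilyMatrix(pd.DataFrame(counts, index=list("XYZ"), columns=tips))
        ann = AnnotationMap({f: FamilyAnnotation(pathways=frozenset({p}))
                             for f, p in zip("XYZ", ["P1", "P2", "P3"])})
        res = enriched_term_phylopca(matrix, ann, metas, tree, ["P1", "P2", "P3"])
        assert res["pc_habitat_p"]["PC1"] > 0.05

    def test_needs_two_terms(self, default_dataset):
        with pytest.raises(ValueError):
            enriched_term_phylopca(default_dataset["matrix"],
                                   default_dataset["annotations"],
                                   default_dataset["metadata"],
                                   default_dataset["tree"], ["P001"])


class TestPanGwas:
    def balanced_fixture(self):
        tree = read_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1,"
            "((I:1,J:1):1,(K:1,L:1):1):1,((M:1,N:1):1,(O:1,P:1):1):1);")
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        # habitat split across clades: one tip of each cherry is focal
        habitat = {t: ("PMA" if i % 2 == 0 else "NPMA") for i, t in enumerate(tips)}
        metas = [GenomeMeta(t, habitat[t]) for t in tips]
        presence = pd.DataFrame(
            {t: [habitat[t] == "PMA", True, t in "ABCD"] for t in tips},
            index=["KO_perfect", "KO_everywhere", "KO_clade"],
        )
        return presence, metas, tree

    def test_perfect_ko_enriched_and_universal_skipped(self):
        presence, metas, tree = self.balanced_fixture()
        res = pan_gwas(presence, metas, tree,
                       PanGwasConfig(n_perm=499, seed=11, fisher_alpha=0.1))
        assert "KO_perfect" in res["enriched_pma"]
        assert "KO_everywhere" not in res["table"].index  # constant -> skipped

    def test_null_calibration_permuted_labels(self, default_dataset, rng):
        """With habitat labels shuffled, (almost) nothing is called enriched."""
        matrix, ann = default_dataset["matrix"], default_dataset["annotations"]
        kop = ko_presence_matrix(matrix, ann)
        metas = default_dataset["metadata"]
        labels = rng.permutation([m.habitat for m in metas])
        shuffled = [GenomeMeta(m.genome_id, h, m.taxonomy, m.cluster,
                               m.genome_size_mb, m.gc_percent)
                    for m, h in zip(metas, labels)]
        res = pan_gwas(kop, shuffled, default_dataset["tree"],
                       PanGwasConfig(n_perm=99, seed=0))
        n_called = len(res["enriched_pma"]) + len(res["enriched_npma"])
        assert n_called <= max(2, 0.05 * len(res["table"]))


class TestStratified:
    def build(self, rng):
        genomes = [f"G{i}" for i in range(24)]
        cluster = ["I"] * 8 + ["II"] * 8 + [None] * 8
        habitat = (["PMA"] * 4 + ["NPMA"] * 4) * 3
        counts = rng.poisson(2.0, (3, 24))
        # signal only in cluster II focal genomes
        counts[0, 8:12] += 8
        matrix = GeneFamilyMatrix(pd.DataFrame(
            counts, index=["F1", "F2", "F3"], columns=genomes))
        ann = AnnotationMap({
            "F1": FamilyAnnotation(cog_category=frozenset("C")),
            "F2": FamilyAnnotation(cog_category=frozenset("G")),
            "F3": FamilyAnnotation(cog_category=frozenset("E")),
        })
        metas = [GenomeMeta(g, h, cluster=c)
                 for g, h, c in zip(genomes, habitat, cluster)]
        return matrix, ann, metas

    def test_signal_localized_to_cluster(self, rng):
        matrix, ann, metas = self.build(rng)
        res = clade_stratified_comparison(matrix, ann, metas, "COG")
        assert set(res) == {"I", "II"}
        sig_II = res["II"][(res["II"].term == "C")].p.iloc[0]
        sig_I = res["I"][(res["I"].term == "C")].p.iloc[0]
        assert sig_II < 0.05 < sig_I

    def test_undersized_cluster_is_na(self, rng):
        matrix, ann, metas = self.build(rng)
        for m in metas:
            if m.cluster == "I" and m.habitat == "PMA" and m.genome_id != "G0":
                m.cluster = None
        res = clade_stratified_comparison(matrix, ann, metas, "COG")
        assert res["I"] is None


class TestMetadataComparison:
    def test_bundle_genome_size_significant(self, default_dataset):
        table = metadata_comparison(default_dataset["metadata"])
        size_row = table[table.term == "genome_size_mb"].iloc[0]
        assert size_row.p < 0.05
        assert size_row.direction == "A"  # focal genomes are larger

    def test_sd_fields_match_sample_sd(self, default_dataset):
        table = metadata_comparison(default_dataset["metadata"])
        sizes_a = [m.genome_size_mb for m in default_dataset["metadata"]
                   if m.habitat == "PMA"]
        row = table[table.term == "genome_size_mb"].iloc[0]
        assert row.sd_a == pytest.approx(np.std(sizes_a, ddof=1))
        assert row.mean_a == pytest.approx(np.mean(sizes_a))


class TestTargetedKO:
    def build(self, k_a, n_a, k_b, n_b):
        genomes = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
        present = ([1] * k_a + [0] * (n_a - k_a)) + ([1] * k_b + [0] * (n_b - k_b))
        counts = pd.DataFrame([present], index=["F1"], columns=genomes)
        ann = AnnotationMap({"F1": FamilyAnnotation(ko="K13954")})
        metas = [GenomeMeta(g, "PMA" if g.startswith("A") else "NPMA") for g in genomes]
        return GeneFamilyMatrix(counts), ann, metas

    def test_adh_proportions_significant(self):
        matrix, ann, metas = self.build(27, 30, 66, 100)
        table = targeted_ko_presence_tests(matrix, ann, metas, ["K13954"])
        assert table.p.iloc[0] < 0.05
        assert table.direction.iloc[0] == "A"
        assert table.presence_a.iloc[0] == 27

    def test_ldh_proportions_significant(self):
        matrix, ann, metas = self.build(30, 30, 80, 100)
        table = targeted_ko_presence_tests(matrix, ann, metas, ["K13954"])
        assert table.p.iloc[0] < 0.01

    def test_equal_proportions_p_one(self):
        matrix, ann, metas = self.build(15, 30, 50, 100)
        table = targeted_ko_presence_tests(matrix, ann, metas, ["K13954"])
        assert table.p.iloc[0] == pytest.approx(1.0)

    def test_unmapped_ko_na_row(self):
        matrix, ann, metas = self.build(5, 10, 5, 10)
        table = targeted_ko_presence_tests(matrix, ann, metas, ["K13954", "K99999"])
        assert table[table.term == "K99999"].method.iloc[0] == "unmapped"
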