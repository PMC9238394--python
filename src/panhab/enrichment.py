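"""Genome-wide habitat-enrichment analyses.

Per-term copy/presence comparisons (COG categories, CAZy classes and
families), the phylogenetic logistic-regression pathway scan, phylo-PCA of
significant terms, the stringent pan-GWAS (Fisher + max-contrasting-pairs
+ label permutation, all three must pass), clade-stratified comparisons,
metadata comparisons, and targeted KO presence tests. Group A is always
the focal (PMA) habitat; BH adjustment is applied within each analysis
family, never pooled across analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationMap,
    GeneFamilyMatrix,
    GenomeMeta,
    empty_result_table,
    make_result_table,
    metadata_frame,
)
from .phylo import (
    TreeIndex,
    label_permutation_test,
    max_contrasting_pairs,
    phylo_pca,
    phylo_vcv,
    phyloglm_test,
)
from .stats import bh_adjust, fisher_exact_2x2, mann_whitney

NAMESPACES = ("COG", "KEGG_PATHWAY", "KO", "CAZY_CLASS", "CAZY_FAMILY")


def _habitat_groups(metadata: list[GenomeMeta], genomes: list[str]) -> tuple[list[str], list[str]]:
    habitat = {m.genome_id: m.habitat for m in metadata}
    a = [g for g in genomes if habitat.get(g) == "PMA"]
    b = [g for g in genomes if habitat.get(g) == "NPMA"]
    if not a or not b:
        raise ValueError("both habitat groups must be present")
    return a, b


def term_families(annotations: AnnotationMap, namespace: str) -> dict[str, list[str]]:
    """Map each term in a namespace to the families annotated with it."""
    if namespace not in NAMESPACES:
        raise ValueError(f"namespace must be one of {NAMESPACES}")
    out: dict[str, list[str]] = {}
    for fam, rec in annotations.items():
        if namespace == "COG":
            terms = sorted(rec.cog_category)
        elif namespace == "KEGG_PATHWAY":
            terms = sorted(rec.pathways)
        elif namespace == "KO":
            terms = [rec.ko] if rec.ko else []
        elif namespace == "CAZY_CLASS":
            terms = [rec.cazy.class_label] if rec.cazy else []
        else:  # CAZY_FAMILY
            terms = [rec.cazy.family_label] if rec.cazy and rec.cazy.family_label else []
        for term in terms:
            out.setdefault(term, []).append(fam)
    return out


def cazy_aggregate(annotations: AnnotationMap, level: str = "family") -> dict[str, list[str]]:
    """Roll CAZy labels up to class / family / subfamily term->families maps.

    Subfamily labels (GH13_31) aggregate into their family (GH13) and class
    (GH); counts are conserved across levels because every labelled family
    appears exactly once per level it resolves at.
    """
    if level not in ("class", "family", "subfamily"):
        raise ValueError("level must be class, family or subfamily")
    out: dict[str, list[str]] = {}
    for fam, rec in annotations.items():
        if rec.cazy is None:
            continue
        if level == "class":
            term = rec.cazy.class_label
        elif level == "family":
            term = rec.cazy.family_label
        else:
            term = str(rec.cazy) if rec.cazy.subfamily is not None else None
        if term:
            out.setdefault(term, []).append(fam)
    return out


def term_count_matrix(
    matrix: GeneFamilyMatrix,
    families_by_term: dict[str, list[str]],
    mode: str = "copy",
) -> pd.DataFrame:
    """Terms x genomes count table: total copies or distinct present families."""
    if mode not in ("copy", "presence"):
        raise ValueError("mode must be copy or presence")
    source = matrix.counts if mode == "copy" else matrix.presence().astype(int)
    known = set(matrix.family_ids)
    rows = {}
    for term, fams in sorted(families_by_term.items()):
        fams = [f for f in fams if f in known]
        if fams:
            rows[term] = source.loc[fams].sum(axis=0)
    return pd.DataFrame(rows).T


def category_count_comparison(
    matrix: GeneFamilyMatrix,
    annotations: AnnotationMap,
    metadata: list[GenomeMeta],
    namespace: str = "COG",
    mode: str = "copy",
) -> pd.DataFrame:
    """Per-term Mann-Whitney comparison of per-genome counts between habitats."""
    group_a, group_b = _habitat_groups(metadata, matrix.genome_ids)
    counts = term_count_matrix(matrix, term_families(annotations, namespace), mode)
    rows = []
    for term in counts.index:
        xa = counts.loc[term, group_a].to_numpy(dtype=float)
        xb = counts.loc[term, group_b].to_numpy(dtype=float)
        if xa.sum() == 0 and xb.sum() == 0:
            continue
        res = mann_whitney(xa, xb, "two_sided")
        ma, mb = float(xa.mean()), float(xb.mean())
        rows.append({
            "term": term, "namespace": namespace,
            "mean_a": ma, "sd_a": float(xa.std(ddof=1)),
            "mean_b": mb, "sd_b": float(xb.std(ddof=1)),
            "statistic": res.statistic, "p": res.p,
            "estimate": ma - mb,
            "direction": "A" if ma > mb else ("B" if mb > ma else "none"),
            "method": f"mann_whitney[{mode}]",
        })
    if not rows:
        return empty_result_table()
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"])
    return make_result_table(table.to_dict("records")).sort_values("p", ignore_index=True)


def pathway_phyloglm_scan(
    matrix: GeneFamilyMatrix,
    annotations: AnnotationMap,
    metadata: list[GenomeMeta],
    tree: dendropy.Tree,
    namespace: str = "KEGG_PATHWAY",
    mode: str = "copy",
) -> pd.DataFrame:
    """Per-term phylogenetic logistic regression of habitat on gene counts.

    Covariate = per-genome gene count of the term; estimate > 0 means
    enrichment in the focal (PMA) group. Constant covariates are skipped;
    raw p < 0.05 is the flagging threshold, BH-adjusted p is also reported.
    """
    genomes = matrix.genome_ids
    habitat = {m.genome_id: m.habitat for m in metadata}
    y = np.array([1.0 if habitat.get(g) == "PMA" else 0.0 for g in genomes])
    if len(set(y)) < 2:
        raise ValueError("both habitat groups must be present")
    C_full = phylo_vcv(tree)
    C = C_full.loc[genomes, genomes]
    counts = term_count_matrix(matrix, term_families(annotations, namespace), mode)
    rows = []
    for term in counts.index:
        x = counts.loc[term, genomes].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        res = phyloglm_test(y, x, C=C)
        ma = float(x[y == 1].mean())
        mb = float(x[y == 0].mean())
        rows.append({
            "term": term, "namespace": namespace,
            "mean_a": ma, "sd_a": float(x[y == 1].std(ddof=1)),
            "mean_b": mb, "sd_b": float(x[y == 0].std(ddof=1)),
            "statistic": res["estimate"] / res["se"] if res["se"] else float("nan"),
            "p": res["p"], "estimate": res["estimate"],
            "direction": "A" if res["estimate"] > 0 else ("B" if res["estimate"] < 0 else "none"),
            "method": "phyloglm" + ("" if res["converged"] else "[fallback_logistic]"),
        })
    if not rows:
        return empty_result_table()
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"])
    return make_result_table(table.to_dict("records")).sort_values("p", ignore_index=True)


def enriched_term_phylopca(
    matrix: GeneFamilyMatrix,
    annotations: AnnotationMap,
    metadata: list[GenomeMeta],
    tree: dendropy.Tree,
    significant_terms: list[str],
    namespace: str = "KEGG_PATHWAY",
    mode: str = "copy",
) -> dict:
    """Phylo-PCA of genomes on significant-term gene counts.

    Returns per-genome PC scores plus a Mann-Whitney habitat comparison on
    PC1 and PC2.
    """
    if len(significant_terms) < 2:
        raise ValueError("need >= 2 significant terms")
    if len(matrix.genome_ids) < 3:
        raise ValueError("need >= 3 genomes")
    counts = term_count_matrix(matrix, term_families(annotations, namespace), mode)
    missing = [t for t in significant_terms if t not in counts.index]
    if missing:
        raise ValueError(f"terms without annotated families: {missing}")
    X = counts.loc[significant_terms].T.astype(float)
    result = phylo_pca(X, tree)
    scores = result["scores"]
    group_a, group_b = _habitat_groups(metadata, list(scores.index))
    pc_tests = {}
    for pc in ("PC1", "PC2"):
        if pc in scores.columns:
            res = mann_whitney(scores.loc[group_a, pc], scores.loc[group_b, pc], "two_sided")
            pc_tests[pc] = res.p
    result["pc_habitat_p"] = pc_tests
    return result


# ------------------------------------------------------------- pan-GWAS

@dataclass
class PanGwasConfig:
    fisher_alpha: float = 0.05      # on BH-adjusted Fisher p
    pairwise_alpha: float = 0.05    # on worst-case pairwise binomial p
    perm_alpha: float = 0.05        # on empirical permutation p
    n_perm: int = 1000
    seed: int | None = None

    def __post_init__(self):
        for a in (self.fisher_alpha, self.pairwise_alpha, self.perm_alpha):
            if not 0.0 < a < 1.0:
                raise ValueError("alphas must lie in (0, 1)")


def ko_presence_matrix(matrix: GeneFamilyMatrix, annotations: AnnotationMap) -> pd.DataFrame:
    """KO x genome boolean presence table (union over families sharing a KO)."""
    return term_count_matrix(matrix, term_families(annotations, "KO"), "presence") >= 1


def pan_gwas(
    ko_presence: pd.DataFrame,
    metadata: list[GenomeMeta],
    tree: dendropy.Tree,
    config: PanGwasConfig | None = None,
) -> dict:
    """Stringent presence/absence pan-GWAS.

    Per KO: Fisher's exact test on the presence x habitat table (BH across
    KOs), the max-contrasting-pairs worst-case binomial p, and the label
    permutation test. A KO is called enriched only when all three pass
    their thresholds; the permutation test (the expensive step) is only run
    for KOs that already passed the first two. Direction from the odds
    ratio. KOs present or absent everywhere are skipped.
    """
    if config is None:
        config = PanGwasConfig()
    genomes = list(ko_presence.columns)
    habitat = {m.genome_id: m.habitat for m in metadata}
    y = pd.Series([1 if habitat.get(g) == "PMA" else 0 for g in genomes], index=genomes)
    if y.nunique() < 2:
        raise ValueError("both habitat groups must be present")
    n_a = int(y.sum())
    n_b = len(y) - n_a
    tix = TreeIndex(tree)
    extra = set(genomes) - set(tix.labels)
    if extra:
        raise ValueError(f"genomes absent from tree: {sorted(extra)}")
    y_tree = {lab: int(y.get(lab, 0)) for lab in tix.labels}

    kept = []
    for ko in ko_presence.index:
        pres = ko_presence.loc[ko]
        total = int(pres.sum())
        if total == 0 or total == len(genomes):
            continue
        a = int(pres[y == 1].sum())
        c = int(pres[y == 0].sum())
        fisher = fisher_exact_2x2(a, n_a - a, c, n_b - c)
        kept.append({"ko": ko, "a": a, "c": c, "fisher_p": fisher.p,
                     "odds": fisher.statistic})
    if not kept:
        return {"enriched_pma": [], "enriched_npma": [], "table": pd.DataFrame()}
    table = pd.DataFrame(kept).set_index("ko")
    table["fisher_p_adj"] = bh_adjust(table["fisher_p"])

    rng = np.random.default_rng(config.seed)
    pairwise_p = []
    perm_p = []
    for ko, row in table.iterrows():
        geno = {g: int(v) for g, v in ko_presence.loc[ko].items()}
        geno_tree = {lab: geno.get(lab, 0) for lab in tix.labels}
        pw = max_contrasting_pairs(tix, geno_tree, y_tree)
        pairwise_p.append(pw.p_worst)
        if row["fisher_p_adj"] < config.fisher_alpha and pw.p_worst < config.pairwise_alpha:
            perm_p.append(label_permutation_test(
                tix, geno_tree, y_tree, n_perm=config.n_perm,
                seed=int(rng.integers(2**31 - 1)),
                early_stop=config.perm_alpha,
            ))
        else:
            perm_p.append(float("nan"))
    table["pairwise_p_worst"] = pairwise_p
    table["perm_p"] = perm_p
    table["enriched"] = (
        (table["fisher_p_adj"] < config.fisher_alpha)
        & (table["pairwise_p_worst"] < config.pairwise_alpha)
        & (table["perm_p"] < config.perm_alpha)
    )
    rate_a = table["a"] / n_a
    rate_b = table["c"] / n_b
    table["direction"] = np.where(rate_a > rate_b, "A", np.where(rate_b > rate_a, "B", "none"))
    enriched_pma = sorted(table.index[table["enriched"] & (table["direction"] == "A")])
    enriched_npma = sorted(table.index[table["enriched"] & (table["direction"] == "B")])
    return {"enriched_pma": enriched_pma, "enriched_npma": enriched_npma, "table": table}


# ---------------------------------------------------- stratified & misc

def clade_stratified_comparison(
    matrix: GeneFamilyMatrix,
    annotations: AnnotationMap,
    metadata: list[GenomeMeta],
    namespace: str = "COG",
    mode: str = "copy",
    min_per_habitat: int = 2,
) -> dict[str, pd.DataFrame | None]:
    """category_count_comparison restricted to each phylogenetic cluster.

    Clusters with fewer than ``min_per_habitat`` genomes in either habitat
    are reported as None (NA); unlabeled genomes are skipped.
    """
    by_cluster: dict[str, list[GenomeMeta]] = {}
    for m in metadata:
        if m.cluster is not None:
            by_cluster.setdefault(m.cluster, []).append(m)
    out: dict[str, pd.DataFrame | None] = {}
    for cluster, members in sorted(by_cluster.items()):
        n_a = sum(1 for m in members if m.habitat == "PMA")
        n_b = sum(1 for m in members if m.habitat == "NPMA")
        if n_a < min_per_habitat or n_b < min_per_habitat:
            out[cluster] = None
            continue
        ids = [m.genome_id for m in members if m.genome_id in set(matrix.genome_ids)]
        out[cluster] = category_count_comparison(
            matrix.subset_genomes(ids), annotations, members, namespace, mode,
        )
    return out


def metadata_comparison(metadata: list[GenomeMeta]) -> pd.DataFrame:
    """Mann-Whitney comparison of genome size and GC% between habitats."""
    frame = metadata_frame(metadata)
    a = frame[frame.habitat == "PMA"]
    b = frame[frame.habitat == "NPMA"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both habitat groups must be present")
    rows = []
    for term in ("genome_size_mb", "gc_percent"):
        xa = a[term].dropna().to_numpy(dtype=float)
        xb = b[term].dropna().to_numpy(dtype=float)
        res = mann_whitney(xa, xb, "two_sided")
        ma, mb = float(xa.mean()), float(xb.mean())
        rows.append({
            "term": term, "namespace": "METADATA",
            "mean_a": ma, "sd_a": float(xa.std(ddof=1)),
            "mean_b": mb, "sd_b": float(xb.std(ddof=1)),
            "statistic": res.statistic, "p": res.p, "p_adj": float("nan"),
            "estimate": ma - mb,
            "direction": "A" if ma > mb else ("B" if mb > ma else "none"),
            "method": "mann_whitney",
        })
    return make_result_table(rows)


def targeted_ko_presence_tests(
    matrix: GeneFamilyMatrix,
    annotations: AnnotationMap,
    metadata: list[GenomeMeta],
    ko_list: list[str],
) -> pd.DataFrame:
    """Fisher presence tests (BH across the list) plus Mann-Whitney copy tests.

    KOs mapped to no family yield an NA row.
    """
    group_a, group_b = _habitat_groups(metadata, matrix.genome_ids)
    presence = matrix.presence()
    counts = matrix.counts
    rows = []
    for ko in ko_list:
        fams = [f for f in annotations.families_with_ko(ko) if f in presence.index]
        if not fams:
            rows.append({"term": ko, "namespace": "KO", "method": "unmapped",
                         "p": float("nan"), "p_adj": float("nan"),
                         "direction": "none"})
            continue
        pres = presence.loc[fams].any(axis=0)
        a = int(pres[group_a].sum())
        c = int(pres[group_b].sum())
        fisher = fisher_exact_2x2(a, len(group_a) - a, c, len(group_b) - c)
        copies_a = counts.loc[fams, group_a].sum(axis=0).to_numpy(dtype=float)
        copies_b = counts.loc[fams, group_b].sum(axis=0).to_numpy(dtype=float)
        mw = mann_whitney(copies_a, copies_b, "two_sided")
        rate_a, rate_b = a / len(group_a), c / len(group_b)
        rows.append({
            "term": ko, "namespace": "KO",
            "mean_a": float(copies_a.mean()), "sd_a": float(copies_a.std(ddof=1)),
            "mean_b": float(copies_b.mean()), "sd_b": float(copies_b.std(ddof=1)),
            "statistic": fisher.statistic, "p": fisher.p,
            "estimate": rate_a - rate_b,
            "direction": "A" if rate_a > rate_b else ("B" if rate_b > rate_a else "none"),
            "method": "fisher_exact+mann_whitney",
            "presence_a": a, "presence_b": c, "copy_mw_p": mw.p,
        })
    table = pd.DataFrame(rows)
    mapped = table["method"] != "unmapped"
    table["p_adj"] = float("nan")
    if mapped.any():
        table.loc[mapped, "p_adj"] = bh_adjust(table.loc[mapped, "p"])
    extra = table[["presence_a", "presence_b", "copy_mw_p"]] if "presence_a" in table else None
    base = make_result_table(table.drop(columns=["presence_a", "presence_b", "copy_mw_p"],
                                        errors="ignore").to_dict("records"))
    if extra is not None:
        base = pd.concat([base, extra.reset_index(drop=True)], axis=1)
    return base
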