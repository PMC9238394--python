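"""Pan/core gene-family classification, equal-size rarefaction and
core-genome functional profiling.

Rarefaction compares the two habitat groups at the same sampled genome
count so pan/core size differences are not artefacts of unequal group
sizes. Core = families present in every sampled genome (strict 100%
presence). The core-pathway enrichment rule flags a pathway when the
two-sided Mann-Whitney p on per-genome core gene counts is < 0.05 AND the
larger group mean exceeds twice the smaller one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AnnotationMap, GeneFamilyMatrix, make_result_table
from .stats import bh_adjust, mann_whitney


def classify_families(matrix: GeneFamilyMatrix, genome_subset: list[str]) -> dict:
    """Partition families over a genome subset into pan/core/accessory/unique."""
    if not genome_subset:
        raise ValueError("genome_subset must be non-empty")
    sub = matrix.subset_genomes(genome_subset)
    presence = sub.presence().to_numpy()
    fams = np.asarray(sub.family_ids, dtype=object)
    n_present = presence.sum(axis=1)
    pan = set(fams[n_present >= 1])
    core = set(fams[n_present == len(genome_subset)])
    unique = set(fams[n_present == 1])
    if len(genome_subset) == 1:
        unique = set()  # with one genome every present family is core
    accessory = pan - core - unique
    return {"pan": pan, "core": core, "accessory": accessory, "unique": unique}


def rarefaction(
    matrix: GeneFamilyMatrix,
    groups: dict[str, list[str]],
    g_max: int | None = None,
    repeats: int = 100,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Equal-size pan/core rarefaction with a per-g group comparison.

    For each sampled genome count g in 1..g_max and each group, draws
    ``repeats`` uniform without-replacement genome samples and records pan
    and core sizes. Returns (per-replicate table, per-g Mann-Whitney
    comparison of the two groups on pan and core size distributions,
    raw and BH-adjusted).
    """
    names = list(groups)
    if g_max is None:
        g_max = min(len(v) for v in groups.values())
    if g_max > min(len(v) for v in groups.values()):
        raise ValueError("g_max exceeds the smallest group size")
    rng = np.random.default_rng(seed)
    presence = matrix.presence()
    rows = []
    for name in names:
        members = list(groups[name])
        block = presence.loc[:, members].to_numpy()
        for g in range(1, g_max + 1):
            for rep in range(repeats):
                idx = rng.choice(len(members), size=g, replace=False)
                sample = block[:, idx]
                rows.append({
                    "g": g, "group": name, "replicate": rep,
                    "pan_size": int(sample.any(axis=1).sum()),
                    "core_size": int(sample.all(axis=1).sum()),
                })
    table = pd.DataFrame(rows)
    tests = []
    if repeats >= 2 and len(names) == 2:
        a, b = names
        for g in range(1, g_max + 1):
            at = table[(table.g == g) & (table.group == a)]
            bt = table[(table.g == g) & (table.group == b)]
            row = {"g": g}
            for what in ("pan_size", "core_size"):
                res = mann_whitney(at[what], bt[what], "two_sided")
                row[f"{what}_p"] = res.p
                row[f"{what}_mean_{a}"] = float(at[what].mean())
                row[f"{what}_mean_{b}"] = float(bt[what].mean())
            tests.append(row)
    tests = pd.DataFrame(tests)
    if not tests.empty:
        for what in ("pan_size", "core_size"):
            tests[f"{what}_p_adj"] = bh_adjust(tests[f"{what}_p"])
    return table, tests


def core_category_profile(
    matrix: GeneFamilyMatrix,
    annotations: AnnotationMap,
    genome_subset: list[str],
    namespace: str = "COG",
) -> pd.DataFrame:
    """Per-genome relative abundance of functional categories in the core genome.

    Restricted to core families of the subset; a category's abundance in a
    genome is its copy count among annotated core families divided by the
    genome's total copies in annotated core families. Families with several
    COG letters contribute their copies to each letter.
    """
    if namespace not in ("COG", "KEGG_PATHWAY"):
        raise ValueError("namespace must be COG or KEGG_PATHWAY")
    core = classify_families(matrix, genome_subset)["core"]
    if not core:
        raise ValueError("empty core genome for the given subset")
    counts = matrix.subset_genomes(genome_subset).counts
    term_families: dict[str, list[str]] = {}
    annotated: set[str] = set()
    for fam in core:
        rec = annotations.get(fam)
        if rec is None:
            continue
        terms = sorted(rec.cog_category) if namespace == "COG" else sorted(rec.pathways)
        if terms:
            annotated.add(fam)
        for term in terms:
            term_families.setdefault(term, []).append(fam)
    if not annotated:
        raise ValueError("no annotated core families")
    totals = counts.loc[sorted(annotated)].sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"genome(s) with zero annotated core copies: {bad}")
    profile = pd.DataFrame(
        {term: counts.loc[fams].sum(axis=0) / totals for term, fams in sorted(term_families.items())}
    )
    profile.index.name = "genome_id"
    return profile


def core_pathway_enrichment(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    p_threshold: float = 0.05,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Fold + rank core-genome enrichment rule applied per term.

    Inputs are per-genome term count (or abundance) tables for the two
    groups (group A = focal). A term is enriched when the two-sided
    Mann-Whitney p < 0.05 and the larger group mean is more than twice the
    smaller. Terms with zero mean in both groups are skipped.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("both groups need >= 2 genomes")
    terms = sorted(set(profiles_a.columns) | set(profiles_b.columns))
    rows = []
    for term in terms:
        xa = profiles_a[term].to_numpy(dtype=float) if term in profiles_a else np.zeros(len(profiles_a))
        xb = profiles_b[term].to_numpy(dtype=float) if term in profiles_b else np.zeros(len(profiles_b))
        ma, mb = float(xa.mean()), float(xb.mean())
        if ma == 0.0 and mb == 0.0:
            continue
        res = mann_whitney(xa, xb, "two_sided")
        hi, lo = max(ma, mb), min(ma, mb)
        fold = np.inf if lo == 0 else hi / lo
        enriched = res.p < p_threshold and fold > fold_threshold
        rows.append({
            "term": term, "namespace": "KEGG_PATHWAY",
            "mean_a": ma, "sd_a": float(xa.std(ddof=1)),
            "mean_b": mb, "sd_b": float(xb.std(ddof=1)),
            "statistic": res.statistic, "p": res.p,
            "estimate": ma - mb,
            "direction": "A" if ma > mb else ("B" if mb > ma else "none"),
            "method": "mann_whitney+fold>2",
            "enriched": bool(enriched),
            "fold": float(fold),
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = bh_adjust(table["p"])
        base = make_result_table(table.drop(columns=["enriched", "fold"]).to_dict("records"))
        base["enriched"] = table["enriched"].to_numpy()
        base["fold"] = table["fold"].to_numpy()
        return base
    return make_result_table([])
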