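"""Seeded generator of complete synthetic datasets with known ground truth.

The generated world emulates the study design the pipeline targets: a
130-genome collection (30 focal pit-mud-associated genomes vs 100
background genomes) related by a birth-death phylogeny, gene families
gained and lost by a two-state Markov process along branches, habitat
effects applied on the terminal branches of focal tips, KO-bearing
families implanted with group-specific penetrance, metabolic-route step
genes drawn to group-specific completeness targets, metadata drawn from
the published group means, and a best-hit table with implanted cross-genus
transfers on a low-identity background. Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

import random
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .datatypes import (
    AnnotationMap,
    CazyLabel,
    FamilyAnnotation,
    GeneFamilyMatrix,
    GenomeMeta,
)
from .hgt import BestHitRecord, write_besthits
from .io import (
    validate_dataset,
    write_annotations,
    write_json,
    write_matrix,
    write_metadata,
    write_newick,
)
from .pathways import default_routes, routes_to_yaml

# COG letter pool with weights loosely shaped like a clostridial genome
_COG_WEIGHTS = {
    "J": 6, "K": 7, "L": 6, "M": 5, "T": 5, "E": 6, "G": 5, "C": 4, "P": 5,
    "F": 3, "H": 3, "I": 2, "O": 3, "N": 2, "U": 2, "V": 2, "D": 1, "Q": 2,
    "S": 8, "R": 6,
}
_CAZY_CLASS_WEIGHTS = {"GH": 0.435, "GT": 0.29, "CBM": 0.11, "CE": 0.08, "PL": 0.05, "AA": 0.035}
_CAZY_FAMILY_POOL = {
    "GH": [4, 13, 23, 5, 19, 39, 1, 3, 43], "GT": [28, 35, 26, 2, 4],
    "CBM": [50, 48, 13], "CE": [1, 14, 4], "PL": [9, 1], "AA": [3, 6],
}
# GH13 gets subfamilies with some probability
_SUBFAMILY_PROB = 0.4

_TAXA = [
    # (probability, class, order, family, genus)
    (0.70, "Clostridia", "Eubacteriales", "Clostridiaceae", "Clostridium"),
    (0.10, "Clostridia", "Eubacteriales", "Clostridiaceae", "Paraclostridium"),
    (0.20, "Bacilli", "Bacillales", "Bacillaceae", "Bacillus"),
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic world; defaults state the emulated study design."""

    n_pma: int = 30
    n_npma: int = 100
    n_families: int = 1500
    birth_rate: float = 1.0
    death_rate: float = 0.2
    clustering_fraction: float = 0.633
    # gene gain/loss
    core_fraction: float = 0.35
    core_presence: float = 0.97
    accessory_presence: float = 0.30
    switch_rate: float = 2.0            # gain+loss rate per unit tree height
    n_enriched_presence: int = 30
    presence_effect: float = 8.0        # gain-rate multiplier on focal tip branches
    n_depleted_presence: int = 10
    n_enriched_copy: int = 20
    copy_effect: float = 3.0            # copy-mean multiplier in focal genomes
    copy_mean: float = 0.3              # copies = 1 + Poisson(copy_mean) when present
    # habitat-associated KO families (implanted penetrance)
    n_habitat_kos: int = 20
    ko_penetrance: tuple[float, float] = (0.9, 0.1)
    npma_direction_fraction: float = 0.25
    # metadata (group means from the emulated collection)
    size_mb: tuple[tuple[float, float], tuple[float, float]] = ((4.53, 1.22), (3.92, 1.08))
    gc: tuple[tuple[float, float], tuple[float, float]] = ((32.0, 7.0), (33.0, 5.0))
    # route completeness targets per group (PMA, NPMA)
    route_penetrance: dict = field(default_factory=lambda: {
        "starch_to_glucose": (0.933, 0.77),
        "glycolysis": (0.97, 0.95),
        "lactate_to_pyruvate": (1.0, 0.80),
        "pyruvate_to_acetylCoA": (1.0, 1.0),
        "ethanol_to_acetylCoA": (0.667, 0.55),
        "acetylCoA_to_butyrate": (0.567, 0.34),
    })
    # published presence proportions for alcohol dehydrogenase drive its step
    adh_step_presence: tuple[float, float] = (0.9, 0.66)
    # annotations
    cog_fraction: float = 0.75
    ko_fraction: float = 0.25
    pathway_pool: int = 30
    n_enriched_pathways: int = 10
    cazy_fraction: float = 0.15
    # best-hit table / HGT scenario
    bg_genes_per_genome: int = 20
    bg_cross_genus_fraction: float = 0.3
    bg_identity: tuple[float, float] = (60.0, 5.0)
    bg_identity_clip: tuple[float, float] = (30.0, 95.0)
    transfer_identity: tuple[float, float] = (98.0, 1.0)
    transfer_identity_clip: tuple[float, float] = (90.0, 100.0)
    bg_coverage: tuple[float, float] = (80.0, 10.0)
    transfer_coverage: tuple[float, float] = (95.0, 3.0)
    coverage_clip: tuple[float, float] = (50.0, 100.0)
    n_transfers: int = 40
    seed: int = 0

    @property
    def n_genomes(self) -> int:
        return self.n_pma + self.n_npma


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


# ------------------------------------------------------------------ tree

def simulate_tree(n_tips: int, birth: float, death: float, seed: int,
                  max_attempts: int = 50) -> dendropy.Tree:
    """Birth-death tree with ``n_tips`` extant tips, height scaled to 1.

    Tips are relabelled G001..GNNN in leaf order. Total-extinction draws
    are retried with derived seeds, up to ``max_attempts``.
    """
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    last_error: Exception | None = None
    for attempt in range(max_attempts):
        rng = random.Random((seed + 7919 * attempt) % (2**31 - 1))
        try:
            tree = treesim.birth_death_tree(
                birth_rate=birth, death_rate=death,
                num_extant_tips=n_tips, rng=rng,
            )
            break
        except Exception as exc:  # total extinction
            last_error = exc
    else:
        raise RuntimeError(f"tree simulation failed after {max_attempts} attempts: {last_error}")
    tree.is_rooted = True
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length = edge.length / height
    taxon_namespace = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxon_namespace.new_taxon(f"G{i + 1:03d}")
    tree.taxon_namespace = taxon_namespace
    return tree


def assign_habitats(tree: dendropy.Tree, n_pma: int, clustering_fraction: float,
                    seed: int) -> dict[str, str]:
    """Assign habitat labels, placing a fraction of focal tips in few clades."""
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if n_pma >= len(tips):
        raise ValueError("n_pma must be smaller than the number of tips")
    rng = np.random.default_rng(seed)
    quota = int(round(clustering_fraction * n_pma))
    pma: set[str] = set()
    clades = []
    for node in tree.preorder_internal_node_iter():
        leaves = [l.taxon.label for l in node.leaf_iter()]
        if 2 <= len(leaves) <= quota:
            clades.append(leaves)
    order = rng.permutation(len(clades))
    for k in order:
        leaves = clades[k]
        if len(pma) + len(leaves) <= quota and not (pma & set(leaves)):
            pma.update(leaves)
        if len(pma) >= quota:
            break
    if len(pma) < quota and clustering_fraction > 0 and not clades:
        warnings.warn("no feasible clades for clustered habitat assignment; using uniform")
    remaining = [t for t in tips if t not in pma]
    extra = rng.choice(len(remaining), size=n_pma - len(pma), replace=False)
    pma.update(remaining[i] for i in extra)
    return {t: ("PMA" if t in pma else "NPMA") for t in tips}


# ---------------------------------------------------------- gene content

def simulate_gene_content(
    tree: dendropy.Tree,
    habitats: dict[str, str],
    config: GeneratorConfig,
    seed: int,
) -> tuple[GeneFamilyMatrix, dict]:
    """Two-state Markov gene gain/loss along branches plus implanted effects.

    Ordinary families evolve presence/absence with gain rate g = pi * s and
    loss rate d = (1 - pi) * s from a stationary root state. Presence-
    enriched (depleted) families have their gain (loss) rate multiplied by
    the effect size on terminal branches of focal tips. Copy numbers for
    present families are 1 + Poisson(mu), with mu multiplied in focal
    genomes for copy-enriched families. Route-step and habitat-KO families
    are drawn directly from their penetrance targets.
    """
    rng = np.random.default_rng(seed)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    is_pma = np.array([habitats[t] == "PMA" for t in tips])

    routes = default_routes()
    atomic = [r for r in routes.values() if not r.composite_of]
    route_specs = []  # (family_id, route_id, step_idx, ko, p_pma, p_npma)
    fam_counter = 0

    def next_fid() -> str:
        nonlocal fam_counter
        fam_counter += 1
        return f"F{fam_counter:05d}"

    for route in atomic:
        q_pma, q_npma = config.route_penetrance.get(route.route_id, (0.9, 0.9))
        k = len(route.steps)
        for step_idx, step in enumerate(route.steps):
            ko = sorted(step)[0]
            if ko == "K13954":
                p_pair = config.adh_step_presence
            else:
                p_pair = (q_pma ** (1.0 / k), q_npma ** (1.0 / k))
            route_specs.append((next_fid(), route.route_id, step_idx, ko, *p_pair))

    n_hab = config.n_habitat_kos
    n_npma_dir = int(round(config.npma_direction_fraction * n_hab))
    habitat_ko_specs = []  # (family_id, ko, p_pma, p_npma, direction)
    hi, lo = config.ko_penetrance
    for i in range(n_hab):
        ko = f"K9{i + 1:04d}"
        if i < n_npma_dir:
            habitat_ko_specs.append((next_fid(), ko, lo, hi, "NPMA"))
        else:
            habitat_ko_specs.append((next_fid(), ko, hi, lo, "PMA"))

    n_special = len(route_specs) + len(habitat_ko_specs)
    n_ordinary = config.n_families - n_special
    if n_ordinary < config.n_enriched_presence + config.n_depleted_presence + 10:
        raise ValueError("n_families too small for the configured special families")
    ordinary_ids = [next_fid() for _ in range(n_ordinary)]

    n_core = int(round(config.core_fraction * n_ordinary))
    pis = np.full(n_ordinary, config.accessory_presence)
    pis[:n_core] = config.core_presence
    # enriched / depleted presence families come from the accessory block
    acc_idx = np.arange(n_core, n_ordinary)
    chosen = rng.choice(acc_idx, size=config.n_enriched_presence + config.n_depleted_presence,
                        replace=False)
    enr_idx = chosen[:config.n_enriched_presence]
    dep_idx = chosen[config.n_enriched_presence:]
    effect = np.ones(n_ordinary)
    effect[enr_idx] = config.presence_effect       # gain boosted on focal tips
    effect[dep_idx] = 1.0 / config.presence_effect  # gain suppressed on focal tips

    s = config.switch_rate
    gain = pis * s
    loss = (1.0 - pis) * s

    # evolve presence along the tree (vectorized across families per edge)
    tip_index = {t: i for i, t in enumerate(tips)}
    presence = np.zeros((n_ordinary, len(tips)), dtype=bool)
    root_state = rng.random(n_ordinary) < pis
    state_of: dict[int, np.ndarray] = {id(tree.seed_node): root_state}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = state_of[id(node.parent_node)]
        t_len = node.edge.length or 0.0
        if node.is_leaf() and habitats[node.taxon.label] == "PMA":
            g_eff = gain * effect
            s_eff = g_eff + loss
        else:
            g_eff = gain
            s_eff = g_eff + loss
        pi_eff = g_eff / s_eff
        decay = np.exp(-s_eff * t_len)
        p_one = np.where(parent_state, pi_eff + (1 - pi_eff) * decay, pi_eff * (1 - decay))
        state = rng.random(n_ordinary) < p_one
        if node.is_leaf():
            presence[:, tip_index[node.taxon.label]] = state
        else:
            state_of[id(node)] = state

    # copy numbers
    copy_idx = rng.choice(np.arange(n_core), size=min(config.n_enriched_copy, n_core),
                          replace=False)
    mu = np.full((n_ordinary, len(tips)), config.copy_mean)
    mu[np.ix_(copy_idx, np.where(is_pma)[0])] = config.copy_mean * config.copy_effect
    counts = np.where(presence, 1 + rng.poisson(mu), 0)

    # special families drawn from penetrance targets
    special_rows = []
    special_ids = []
    for fid, _route, _step, _ko, p_pma, p_npma in route_specs:
        p = np.where(is_pma, p_pma, p_npma)
        pres = rng.random(len(tips)) < p
        special_rows.append(np.where(pres, 1 + rng.poisson(config.copy_mean, len(tips)), 0))
        special_ids.append(fid)
    for fid, _ko, p_pma, p_npma, _direction in habitat_ko_specs:
        p = np.where(is_pma, p_pma, p_npma)
        pres = rng.random(len(tips)) < p
        special_rows.append(np.where(pres, 1 + rng.poisson(config.copy_mean, len(tips)), 0))
        special_ids.append(fid)

    all_ids = special_ids + ordinary_ids
    all_counts = np.vstack([np.array(special_rows), counts]) if special_rows else counts
    frame = pd.DataFrame(all_counts.astype(np.int64), index=all_ids, columns=tips)
    frame.index.name = "family_id"
    matrix = GeneFamilyMatrix(frame)

    truth = {
        "enriched_presence_families": {
            "PMA": sorted(ordinary_ids[i] for i in enr_idx),
            "NPMA": sorted(ordinary_ids[i] for i in dep_idx),
        },
        "copy_enriched_families": sorted(ordinary_ids[i] for i in copy_idx),
        "habitat_kos": {
            ko: {"family": fid, "direction": direction,
                 "penetrance": {"PMA": p_pma, "NPMA": p_npma}}
            for fid, ko, p_pma, p_npma, direction in habitat_ko_specs
        },
        "route_families": {
            fid: {"route": route_id, "step": step, "ko": ko,
                  "presence": {"PMA": p_pma, "NPMA": p_npma}}
            for fid, route_id, step, ko, p_pma, p_npma in route_specs
        },
        "route_penetrance": {
            rid: {"PMA": q[0], "NPMA": q[1]} for rid, q in config.route_penetrance.items()
        },
    }
    return matrix, truth


# ----------------------------------------------------------- annotations

def simulate_annotations(
    matrix: GeneFamilyMatrix,
    truth: dict,
    config: GeneratorConfig,
    seed: int,
) -> AnnotationMap:
    """Assign COG letters, KOs, pathway ids and CAZy labels to families.

    Route and habitat-KO families keep their designated KOs. A block of
    pathway ids is reserved for the presence/copy-enriched families so
    pathway-level scans have recoverable signal; CAZy classes are weighted
    toward GH and GT.
    """
    rng = np.random.default_rng(seed)
    letters = list(_COG_WEIGHTS)
    weights = np.array([_COG_WEIGHTS[l] for l in letters], dtype=float)
    weights /= weights.sum()
    cazy_classes = list(_CAZY_CLASS_WEIGHTS)
    cazy_w = np.array([_CAZY_CLASS_WEIGHTS[c] for c in cazy_classes])
    cazy_w /= cazy_w.sum()

    designated_ko = {info["family"]: ko for ko, info in truth["habitat_kos"].items()}
    designated_ko.update({fid: info["ko"] for fid, info in truth["route_families"].items()})
    enriched_fams = set(truth["enriched_presence_families"]["PMA"]) | set(
        truth["copy_enriched_families"]
    )
    depleted_fams = set(truth["enriched_presence_families"]["NPMA"])

    n_enr_pw = config.n_enriched_pathways
    enriched_pathways = [f"P{i + 1:03d}" for i in range(n_enr_pw)]
    depleted_pathways = [f"P{i + 1:03d}" for i in range(n_enr_pw, n_enr_pw + 2)]
    background_pathways = [
        f"P{i + 1:03d}" for i in range(n_enr_pw + 2, config.pathway_pool)
    ]

    records: dict[str, FamilyAnnotation] = {}
    generic_ko = 0
    for fid in matrix.family_ids:
        cog: frozenset[str] = frozenset()
        if rng.random() < config.cog_fraction:
            n_letters = 2 if rng.random() < 0.05 else 1
            cog = frozenset(rng.choice(letters, size=n_letters, replace=False, p=weights))
        ko = designated_ko.get(fid)
        if ko is None and rng.random() < config.ko_fraction:
            generic_ko += 1
            ko = f"K8{generic_ko:04d}"
        if fid in enriched_fams:
            pathways = frozenset(rng.choice(enriched_pathways, size=1))
        elif fid in depleted_fams:
            pathways = frozenset(rng.choice(depleted_pathways, size=1))
        elif rng.random() < 0.5:
            pathways = frozenset(rng.choice(background_pathways, size=1))
        else:
            pathways = frozenset()
        cazy = None
        if fid in enriched_fams and rng.random() < 0.3:
            fam_num = int(rng.choice([13, 4]))
            sub = int(rng.integers(1, 40)) if rng.random() < _SUBFAMILY_PROB else None
            cazy = CazyLabel("GH", fam_num, sub)
        elif rng.random() < config.cazy_fraction:
            cls = str(rng.choice(cazy_classes, p=cazy_w))
            fam_num = int(rng.choice(_CAZY_FAMILY_POOL[cls]))
            sub = None
            if cls == "GH" and fam_num == 13 and rng.random() < _SUBFAMILY_PROB:
                sub = int(rng.integers(1, 40))
            cazy = CazyLabel(cls, fam_num, sub)
        records[fid] = FamilyAnnotation(cog, ko, pathways, cazy)
    truth["enriched_pathways"] = {"PMA": enriched_pathways, "NPMA": depleted_pathways}
    return AnnotationMap(records)


# ------------------------------------------------------------- metadata

def _cluster_labels(tree: dendropy.Tree, n_clusters: int = 3) -> dict[str, str]:
    """Split the tree into ``n_clusters`` monophyletic groups (largest-first)."""
    groups = [list(tree.seed_node.child_nodes())]
    parts = list(tree.seed_node.child_nodes())
    while len(parts) < n_clusters:
        parts.sort(key=lambda nd: sum(1 for _ in nd.leaf_iter()), reverse=True)
        big = parts.pop(0)
        children = big.child_nodes()
        if not children:
            parts.append(big)
            break
        parts.extend(children)
    names = ["I", "II", "III", "IV", "V", "VI"]
    labels: dict[str, str] = {}
    for k, node in enumerate(parts[:len(names)]):
        for leaf in node.leaf_iter():
            labels[leaf.taxon.label] = names[min(k, n_clusters - 1)]
    return labels


def simulate_metadata(
    tree: dendropy.Tree,
    habitats: dict[str, str],
    config: GeneratorConfig,
    seed: int,
) -> list[GenomeMeta]:
    """Genome sizes and GC from truncated group normals; taxonomy and clusters."""
    rng = np.random.default_rng(seed)
    clusters = _cluster_labels(tree)
    probs = np.array([t[0] for t in _TAXA])
    out = []
    for tip in (leaf.taxon.label for leaf in tree.leaf_node_iter()):
        group = 0 if habitats[tip] == "PMA" else 1
        mean, sd = config.size_mb[group]
        size = float(rng.normal(mean, sd))
        while size <= 0.5:
            size = float(rng.normal(mean, sd))
        mean, sd = config.gc[group]
        gc = float(np.clip(rng.normal(mean, sd), 20.0, 80.0))
        _, cls, order, fam, genus = _TAXA[rng.choice(len(_TAXA), p=probs)]
        species = f"{genus} sp{int(rng.integers(1, 6))}"
        out.append(GenomeMeta(
            genome_id=tip, habitat=habitats[tip],
            taxonomy={"phylum": "Bacillota", "class": cls, "order": order,
                      "family": fam, "genus": genus, "species": species},
            cluster=clusters.get(tip),
            genome_size_mb=size, gc_percent=gc,
        ))
    return out


# ------------------------------------------------------------- best hits

def simulate_besthits(
    habitats: dict[str, str],
    metadata: list[GenomeMeta],
    config: GeneratorConfig,
    seed: int,
    family_ids: list[str] | None = None,
) -> tuple[list[BestHitRecord], dict]:
    """Background best-hit records plus implanted cross-genus transfers."""
    rng = np.random.default_rng(seed)
    genomes = [m.genome_id for m in metadata]
    genus = {m.genome_id: m.taxonomy.get("genus", "?") for m in metadata}
    by_genus: dict[str, list[str]] = {}
    for g in genomes:
        by_genus.setdefault(genus[g], []).append(g)

    def pick_partner(g: str, cross: bool) -> str:
        same = [x for x in by_genus[genus[g]] if x != g]
        other = [x for x in genomes if genus[x] != genus[g]]
        pool = other if (cross or not same) else same
        if not pool:
            pool = [x for x in genomes if x != g]
        return str(pool[rng.integers(len(pool))])

    lo_i, hi_i = config.bg_identity_clip
    lo_c, hi_c = config.coverage_clip
    records: list[BestHitRecord] = []
    gene_families: dict[str, str] = {}
    for g in genomes:
        for i in range(config.bg_genes_per_genome):
            gid = f"{g}_g{i + 1:03d}"
            cross = bool(rng.random() < config.bg_cross_genus_fraction)
            partner = pick_partner(g, cross)
            ident = float(np.clip(rng.normal(*config.bg_identity), lo_i, hi_i))
            cov = float(np.clip(rng.normal(*config.bg_coverage), lo_c, hi_c))
            records.append(BestHitRecord(gid, g, f"{partner}_h{i + 1:03d}", partner, ident, cov))
            if family_ids is not None:
                gene_families[gid] = str(family_ids[rng.integers(len(family_ids))])

    implanted = []
    t_lo, t_hi = config.transfer_identity_clip
    for k in range(config.n_transfers):
        g = str(genomes[rng.integers(len(genomes))])
        donor = pick_partner(g, cross=True)
        gid = f"{g}_hgt{k + 1:03d}"
        ident = float(np.clip(rng.normal(*config.transfer_identity), t_lo, t_hi))
        cov = float(np.clip(rng.normal(*config.transfer_coverage), lo_c, hi_c))
        records.append(BestHitRecord(gid, g, f"{donor}_d{k + 1:03d}", donor, ident, cov))
        if family_ids is not None:
            gene_families[gid] = str(family_ids[rng.integers(len(family_ids))])
        implanted.append({"gene": gid, "recipient": g, "donor": donor,
                          "identity": ident, "coverage": cov})
    truth = {"implanted_transfers": implanted, "gene_families": gene_families}
    return records, truth


# ------------------------------------------------------------- bundle

def generate_dataset(config: GeneratorConfig, outdir: str | Path) -> dict:
    """Write a complete, validated dataset bundle; returns the truth dict.

    Files: tree.nwk, matrix.tsv, metadata.tsv, annotations.tsv,
    besthits.tsv, routes.yaml, truth.json. Partial output is removed on
    failure. Byte-identical for a fixed seed.
    """
    outdir = Path(outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        rng = np.random.default_rng(config.seed)
        tree = simulate_tree(config.n_genomes, config.birth_rate, config.death_rate,
                             _child_seed(rng))
        habitats = assign_habitats(tree, config.n_pma, config.clustering_fraction,
                                   _child_seed(rng))
        matrix, truth = simulate_gene_content(tree, habitats, config, _child_seed(rng))
        annotations = simulate_annotations(matrix, truth, config, _child_seed(rng))
        metadata = simulate_metadata(tree, habitats, config, _child_seed(rng))
        besthits, hgt_truth = simulate_besthits(
            habitats, metadata, config, _child_seed(rng), matrix.family_ids,
        )
        truth.update(hgt_truth)
        truth["n_pma"] = config.n_pma
        truth["n_npma"] = config.n_npma
        truth["seed"] = config.seed

        report = validate_dataset(matrix, metadata, tree, annotations)

        write_newick(tree, outdir / "tree.nwk")
        write_matrix(matrix, outdir / "matrix.tsv")
        write_metadata(metadata, outdir / "metadata.tsv")
        write_annotations(annotations, outdir / "annotations.tsv")
        write_besthits(besthits, outdir / "besthits.tsv")
        routes_to_yaml(default_routes(), outdir / "routes.yaml")
        write_json(truth, outdir / "truth.json")
        write_json(report, outdir / "validation.json")
    except Exception:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for name in ("tree.nwk", "matrix.tsv", "metadata.tsv", "annotations.tsv",
                         "besthits.tsv", "routes.yaml", "truth.json", "validation.json"):
                (outdir / name).unlink(missing_ok=True)
        raise
    return truth
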