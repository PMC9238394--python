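"""Best-hit horizontal-gene-transfer candidate screening.

A gene is an HGT candidate at a taxonomic rank when its single best
non-self-genome hit lies in a genome assigned to a different group at that
rank and passes identity/coverage cutoffs. Candidates found at several
ranks are merged, keeping the most specific rank at which donor and
recipient groups differ. Gene-tree/species-tree reconciliation is out of
scope, so every event carries validated=False.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .datatypes import DataValidationError, AnnotationMap

RANK_ORDER = ("class", "order", "family", "genus", "species")

DEFAULT_MIN_IDENTITY = 75.0
DEFAULT_MIN_COVERAGE = 75.0


@dataclass(frozen=True)
class BestHitRecord:
    gene_id: str
    genome_id: str
    hit_gene_id: str
    hit_genome_id: str
    identity: float
    coverage: float

    def __post_init__(self):
        if not 0.0 <= self.identity <= 100.0:
            raise DataValidationError(f"gene {self.gene_id}: identity outside [0, 100]")
        if not 0.0 <= self.coverage <= 100.0:
            raise DataValidationError(f"gene {self.gene_id}: coverage outside [0, 100]")


@dataclass
class HGTEvent:
    recipient_gene: str
    recipient_genome: str
    hit_gene: str
    donor_genome: str
    donor_group: str
    recipient_group: str
    rank: str
    identity: float
    coverage: float
    family_id: str | None = None
    validated: bool = False


def read_besthits(path: str | Path) -> list[BestHitRecord]:
    """Read a per-gene best-hit TSV (one row per gene: its best non-self hit)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["gene_id", "genome_id", "hit_gene_id", "hit_genome_id", "identity", "coverage"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise DataValidationError(f"best-hit table missing column(s): {missing}")
    out = []
    for i, row in frame.iterrows():
        try:
            out.append(BestHitRecord(
                row.gene_id, row.genome_id, row.hit_gene_id, row.hit_genome_id,
                float(row.identity), float(row.coverage),
            ))
        except (DataValidationError, ValueError) as exc:
            raise DataValidationError(f"best-hit row {i + 2}: {exc}") from None
    genes = [r.gene_id for r in out]
    dup = sorted(g for g, k in Counter(genes).items() if k > 1)
    if dup:
        raise DataValidationError(f"multiple best hits for gene(s): {dup[:5]}")
    return out


def write_besthits(records: list[BestHitRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


def detect_candidates(
    besthits: list[BestHitRecord],
    taxonomy: dict[str, dict[str, str]],
    rank: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[HGTEvent]:
    """HGT candidates at one taxonomic rank.

    ``taxonomy`` maps genome_id -> {rank: group}. An event is emitted when
    the best hit's group at the rank differs from the gene's own, and both
    identity and coverage pass their cutoffs.
    """
    if rank not in RANK_ORDER:
        raise ValueError(f"rank must be one of {RANK_ORDER}")
    genomes = {r.genome_id for r in besthits} | {r.hit_genome_id for r in besthits}
    unranked = sorted(g for g in genomes if rank not in taxonomy.get(g, {}))
    if unranked:
        raise DataValidationError(f"genomes missing rank {rank!r}: {unranked}")
    events = []
    for rec in besthits:
        if rec.genome_id == rec.hit_genome_id:
            continue
        own = taxonomy[rec.genome_id][rank]
        other = taxonomy[rec.hit_genome_id][rank]
        if own == other:
            continue
        if rec.identity < min_identity or rec.coverage < min_coverage:
            continue
        events.append(HGTEvent(
            recipient_gene=rec.gene_id, recipient_genome=rec.genome_id,
            hit_gene=rec.hit_gene_id, donor_genome=rec.hit_genome_id,
            donor_group=other, recipient_group=own, rank=rank,
            identity=rec.identity, coverage=rec.coverage,
        ))
    return events


def merge_ranks(events: list[HGTEvent]) -> list[HGTEvent]:
    """Merge events detected at several ranks, keeping the most specific.

    Events sharing (recipient_gene, hit_gene) collapse into one record at
    the most specific rank at which donor and recipient groups differ.
    Idempotent; output has unique (recipient_gene, hit_gene) keys.
    """
    specificity = {rank: i for i, rank in enumerate(RANK_ORDER)}
    kept: dict[tuple[str, str], HGTEvent] = {}
    for ev in events:
        key = (ev.recipient_gene, ev.hit_gene)
        old = kept.get(key)
        if old is None or specificity[ev.rank] > specificity[old.rank]:
            kept[key] = ev
    return list(kept.values())


def annotate_events(
    events: list[HGTEvent],
    gene_families: dict[str, str],
) -> list[HGTEvent]:
    """Attach the gene-family id of each recipient gene (for summaries)."""
    for ev in events:
        ev.family_id = gene_families.get(ev.recipient_gene)
    return events


def summarize_transfers(
    events: list[HGTEvent],
    annotations: AnnotationMap | None = None,
) -> dict:
    """Directional donor->recipient counts plus COG and CAZy histograms."""
    pair_counts = Counter((ev.donor_group, ev.recipient_group) for ev in events)
    cog = Counter()
    cazy = Counter()
    if annotations is not None:
        for ev in events:
            if ev.family_id is None:
                continue
            rec = annotations.get(ev.family_id)
            if rec is None:
                continue
            for letter in rec.cog_category:
                cog[letter] += 1
            if rec.cazy is not None:
                cazy[str(rec.cazy)] += 1
    return {
        "n_events": len(events),
        "pair_counts": {f"{d}->{r}": n for (d, r), n in sorted(pair_counts.items())},
        "cog_histogram": dict(sorted(cog.items())),
        "cazy_histogram": dict(sorted(cazy.items())),
    }


def events_frame(events: list[HGTEvent]) -> pd.DataFrame:
    return pd.DataFrame([ev.__dict__ for ev in events])


def edge_list(events: list[HGTEvent]) -> pd.DataFrame:
    """Donor/recipient/weight edge list for external graph viewers."""
    counts = Counter((ev.donor_group, ev.recipient_group) for ev in events)
    return pd.DataFrame(
        [{"donor": d, "recipient": r, "weight": n} for (d, r), n in sorted(counts.items())]
    )
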