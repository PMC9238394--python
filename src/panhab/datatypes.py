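"""Core domain types for two-habitat comparative pangenomics.

The analysis compares a focal habitat group (PMA, pit-mud-associated) against
a background group (NPMA). Group "A" in every result table is always PMA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HABITATS = ("PMA", "NPMA")
TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus", "species")
COG_LETTERS = tuple("JAKLBDYVTMNZWUOCGEFHIPQRS")
CAZY_CLASSES = ("GH", "GT", "CE", "PL", "CBM", "AA")

RESULT_COLUMNS = [
    "term", "namespace", "mean_a", "sd_a", "mean_b", "sd_b",
    "statistic", "p", "p_adj", "estimate", "direction", "method",
]

_CAZY_RE = re.compile(r"^(GH|GT|CE|PL|CBM|AA)(?:(\d+)(?:_(\d+))?)?$")


class DataValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


@dataclass(frozen=True)
class CazyLabel:
    """Parsed CAZy label: class, optional family number, optional subfamily.

    ``GH`` -> (GH, None, None); ``GH13`` -> (GH, 13, None);
    ``GH13_31`` -> (GH, 13, 31).
    """

    cls: str
    family: int | None = None
    subfamily: int | None = None

    @classmethod
    def parse(cls, label: str) -> "CazyLabel":
        m = _CAZY_RE.match(label.strip())
        if m is None:
            raise DataValidationError(f"unparsable CAZy label: {label!r}")
        fam = int(m.group(2)) if m.group(2) else None
        sub = int(m.group(3)) if m.group(3) else None
        if sub is not None and fam is None:
            raise DataValidationError(f"unparsable CAZy label: {label!r}")
        return cls(m.group(1), fam, sub)

    @property
    def class_label(self) -> str:
        return self.cls

    @property
    def family_label(self) -> str | None:
        return None if self.family is None else f"{self.cls}{self.family}"

    def __str__(self) -> str:
        s = self.cls
        if self.family is not None:
            s += str(self.family)
            if self.subfamily is not None:
                s += f"_{self.subfamily}"
        return s


@dataclass
class GenomeMeta:
    """Per-genome metadata: habitat label, taxonomy, cluster, size, GC."""

    genome_id: str
    habitat: str
    taxonomy: dict[str, str] = field(default_factory=dict)
    cluster: str | None = None
    genome_size_mb: float = float("nan")
    gc_percent: float = float("nan")

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise DataValidationError(
                f"genome {self.genome_id}: unknown habitat {self.habitat!r}; "
                f"expected one of {HABITATS}"
            )
        if np.isfinite(self.gc_percent) and not 0.0 <= self.gc_percent <= 100.0:
            raise DataValidationError(
                f"genome {self.genome_id}: gc_percent {self.gc_percent} outside [0, 100]"
            )
        if np.isfinite(self.genome_size_mb) and self.genome_size_mb <= 0:
            raise DataValidationError(
                f"genome {self.genome_id}: genome_size_mb must be > 0"
            )


def metadata_frame(metadata: list[GenomeMeta]) -> pd.DataFrame:
    """Tabulate a metadata list (one row per genome, taxonomy as columns)."""
    ids = [m.genome_id for m in metadata]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise DataValidationError(f"duplicate genome_id(s) in metadata: {dup}")
    rows = []
    for m in metadata:
        row = {
            "genome_id": m.genome_id,
            "habitat": m.habitat,
            "cluster": m.cluster,
            "genome_size_mb": m.genome_size_mb,
            "gc_percent": m.gc_percent,
        }
        for rank in TAXONOMY_RANKS:
            row[rank] = m.taxonomy.get(rank)
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome_id")


class GeneFamilyMatrix:
    """Gene-family copy-number matrix: families as rows, genomes as columns.

    Counts are non-negative integers; presence means copy number >= 1.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            raise DataValidationError("duplicate family_ids in matrix")
        if counts.columns.has_duplicates:
            raise DataValidationError("duplicate genome_ids in matrix")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise DataValidationError("matrix counts must be integers")
            counts = counts.astype(np.int64)
            values = counts.to_numpy()
        if (values < 0).any():
            raise DataValidationError("matrix counts must be >= 0")
        self.counts = counts.astype(np.int64)

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def presence(self) -> pd.DataFrame:
        """Boolean presence view (copy number >= 1)."""
        return self.counts >= 1

    def subset_genomes(self, genome_ids) -> "GeneFamilyMatrix":
        missing = [g for g in genome_ids if g not in self.counts.columns]
        if missing:
            raise DataValidationError(f"unknown genome id(s): {missing}")
        return GeneFamilyMatrix(self.counts.loc[:, list(genome_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneFamilyMatrix) and self.counts.equals(other.counts)


@dataclass
class FamilyAnnotation:
    """Functional annotation record for one gene family."""

    cog_category: frozenset[str] = frozenset()
    ko: str | None = None
    pathways: frozenset[str] = frozenset()
    cazy: CazyLabel | None = None


class AnnotationMap:
    """family_id -> functional terms across namespaces (COG/KO/pathway/CAZy)."""

    def __init__(self, records: dict[str, FamilyAnnotation]):
        for fam, rec in records.items():
            bad = set(rec.cog_category) - set(COG_LETTERS)
            if bad:
                raise DataValidationError(
                    f"family {fam}: unknown COG letter(s) {sorted(bad)}"
                )
        self.records = dict(records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, family_id: str) -> bool:
        return family_id in self.records

    def get(self, family_id: str) -> FamilyAnnotation | None:
        return self.records.get(family_id)

    def items(self):
        return self.records.items()

    def families_with_ko(self, ko: str) -> list[str]:
        return [f for f, r in self.records.items() if r.ko == ko]

    def orphans(self, matrix: GeneFamilyMatrix) -> list[str]:
        """Annotated families absent from the matrix."""
        known = set(matrix.family_ids)
        return sorted(f for f in self.records if f not in known)


def empty_result_table() -> pd.DataFrame:
    return pd.DataFrame(columns=RESULT_COLUMNS)


def make_result_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble and validate a per-term result table.

    Enforces p, p_adj in [0, 1] and p_adj >= p (within float rounding).
    """
    if not rows:
        return empty_result_table()
    table = pd.DataFrame(rows)
    for col in RESULT_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    table = table[RESULT_COLUMNS]
    finite_p = table["p"].dropna()
    if ((finite_p < 0) | (finite_p > 1)).any():
        raise DataValidationError("p outside [0, 1] in result table")
    both = table.dropna(subset=["p", "p_adj"])
    if (both["p_adj"] < both["p"] - 1e-12).any():
        raise DataValidationError("p_adj < p in result table")
    return table
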