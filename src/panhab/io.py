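"""Readers and writers for the on-disk formats.

Trees are Newick (via dendropy); matrices, metadata, annotations and result
tables are UTF-8 tab-delimited TSV with a header row; the validation report
and ground truth are JSON.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .datatypes import (
    TAXONOMY_RANKS,
    AnnotationMap,
    CazyLabel,
    DataValidationError,
    FamilyAnnotation,
    GeneFamilyMatrix,
    GenomeMeta,
    metadata_frame,
)


# ---------------------------------------------------------------- trees

def read_newick(source: str | Path, missing_length_zero: bool = False) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Duplicate tip labels are a hard error. Missing branch lengths are an
    error unless ``missing_length_zero`` substitutes 0.
    """
    s = str(source)
    looks_like_newick = s.lstrip().startswith("(") or ";" in s
    text = s if looks_like_newick else Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        if "duplicate" in str(exc).lower() or "multiple" in str(exc).lower():
            raise DataValidationError(f"duplicate tip label(s) in tree: {exc}") from None
        raise
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dup = sorted(label for label, k in Counter(labels).items() if k > 1)
    if dup:
        raise DataValidationError(f"duplicate tip label(s) in tree: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if missing_length_zero:
                edge.length = 0.0
            else:
                raise DataValidationError(
                    "tree has edges without branch lengths "
                    "(pass missing_length_zero=True to substitute 0)"
                )
        elif edge.length < 0:
            raise DataValidationError("tree has negative branch length(s)")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(s)
    return s


def tree_tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------- matrix

def read_matrix(path: str | Path) -> GeneFamilyMatrix:
    """Read a family x genome copy-number TSV (rows: families; header: genome IDs)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    counts = np.empty(raw.shape, dtype=np.int64)
    for i, (fam, row) in enumerate(raw.iterrows()):
        for j, value in enumerate(row):
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise DataValidationError(f"row {i + 2}: ragged or missing count")
            try:
                number = float(value)
            except ValueError:
                raise DataValidationError(
                    f"row {i + 2}: non-numeric count {value!r} for family {fam}"
                ) from None
            if number != int(number):
                raise DataValidationError(
                    f"row {i + 2}: non-integer count {value!r} for family {fam}"
                )
            if number < 0:
                raise DataValidationError(
                    f"row {i + 2}: negative count {value!r} for family {fam}"
                )
            counts[i, j] = int(number)
    frame = pd.DataFrame(counts, index=raw.index.astype(str), columns=raw.columns.astype(str))
    frame.index.name = "family_id"
    return GeneFamilyMatrix(frame)


def write_matrix(matrix: GeneFamilyMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "family_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------- metadata

_META_COLUMNS = ["genome_id", "habitat", "cluster", "genome_size_mb", "gc_percent"]


def read_metadata(path: str | Path) -> list[GenomeMeta]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("genome_id", "habitat") if c not in frame.columns]
    if missing:
        raise DataValidationError(f"metadata missing required column(s): {missing}")
    out: list[GenomeMeta] = []
    for i, row in frame.iterrows():
        taxonomy = {
            rank: row[rank]
            for rank in TAXONOMY_RANKS
            if rank in frame.columns and isinstance(row[rank], str) and row[rank]
        }
        cluster = row.get("cluster")
        if not isinstance(cluster, str) or not cluster:
            cluster = None
        try:
            meta = GenomeMeta(
                genome_id=str(row["genome_id"]),
                habitat=str(row["habitat"]),
                taxonomy=taxonomy,
                cluster=cluster,
                genome_size_mb=float(row["genome_size_mb"]) if "genome_size_mb" in frame.columns else float("nan"),
                gc_percent=float(row["gc_percent"]) if "gc_percent" in frame.columns else float("nan"),
            )
        except (DataValidationError, ValueError) as exc:
            raise DataValidationError(f"metadata row {i + 2}: {exc}") from None
        out.append(meta)
    metadata_frame(out)  # checks genome_id uniqueness
    return out


def write_metadata(metadata: list[GenomeMeta], path: str | Path) -> None:
    frame = metadata_frame(metadata).reset_index()
    cols = _META_COLUMNS + [r for r in TAXONOMY_RANKS if r in frame.columns]
    frame[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


# ------------------------------------------------------------- annotations

def read_annotations(path: str | Path) -> AnnotationMap:
    """Read a family -> {COG letters, KO, pathways, CAZy} TSV.

    Columns: family_id, cog_category (concatenated letters), ko,
    pathways (comma-separated), cazy. Empty cells mean "unannotated".
    """
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "family_id" not in frame.columns:
        raise DataValidationError("annotations missing 'family_id' column")
    records: dict[str, FamilyAnnotation] = {}
    for i, row in frame.iterrows():
        fam = str(row["family_id"])
        try:
            cazy = CazyLabel.parse(row["cazy"]) if row.get("cazy", "") else None
            rec = FamilyAnnotation(
                cog_category=frozenset(row.get("cog_category", "")),
                ko=row["ko"] if row.get("ko", "") else None,
                pathways=frozenset(
                    p for p in row.get("pathways", "").split(",") if p
                ),
                cazy=cazy,
            )
        except DataValidationError as exc:
            raise DataValidationError(f"annotations row {i + 2}: {exc}") from None
        records[fam] = rec
    try:
        return AnnotationMap(records)
    except DataValidationError as exc:
        raise DataValidationError(f"annotations: {exc}") from None


def write_annotations(annotations: AnnotationMap, path: str | Path) -> None:
    rows = []
    for fam, rec in annotations.items():
        rows.append({
            "family_id": fam,
            "cog_category": "".join(sorted(rec.cog_category)),
            "ko": rec.ko or "",
            "pathways": ",".join(sorted(rec.pathways)),
            "cazy": str(rec.cazy) if rec.cazy else "",
        })
    pd.DataFrame(rows, columns=["family_id", "cog_category", "ko", "pathways", "cazy"]).to_csv(
        path, sep="\t", index=False
    )


# ------------------------------------------------------------- results

def write_result_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------- validation

def validate_dataset(
    matrix: GeneFamilyMatrix,
    metadata: list[GenomeMeta],
    tree: dendropy.Tree,
    annotations: AnnotationMap | None = None,
) -> dict:
    """Cross-check genome sets and summarize a dataset bundle.

    Raises if any matrix genome is absent from metadata or from the tree;
    returns a JSON-ready report with per-habitat genome counts and the
    fraction of matrix families carrying any annotation.
    """
    matrix_genomes = set(matrix.genome_ids)
    meta_genomes = {m.genome_id for m in metadata}
    tip_genomes = set(tree_tip_labels(tree))

    missing_meta = sorted(matrix_genomes - meta_genomes)
    if missing_meta:
        raise DataValidationError(f"genomes absent from metadata: {missing_meta}")
    missing_tips = sorted(matrix_genomes - tip_genomes)
    if missing_tips:
        raise DataValidationError(f"genomes absent from tree: {missing_tips}")

    habitat_counts = Counter(m.habitat for m in metadata if m.genome_id in matrix_genomes)
    report = {
        "n_genomes": len(matrix_genomes),
        "n_families": len(matrix.family_ids),
        "habitat_counts": dict(habitat_counts),
        "extra_metadata_genomes": sorted(meta_genomes - matrix_genomes),
        "extra_tree_tips": sorted(tip_genomes - matrix_genomes),
    }
    if annotations is not None:
        orphans = annotations.orphans(matrix)

        def has_terms(rec) -> bool:
            return bool(rec.cog_category or rec.ko or rec.pathways or rec.cazy)

        annotated = sum(
            1 for f in matrix.family_ids
            if f in annotations and has_terms(annotations.get(f))
        )
        report["orphan_annotations"] = len(orphans)
        report["annotated_family_fraction"] = (
            annotated / len(matrix.family_ids) if matrix.family_ids else 0.0
        )
    return report


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
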