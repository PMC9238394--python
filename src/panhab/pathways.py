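"""Metabolic-route completeness scoring and the Poisson group comparison.

A route is an ordered list of steps, each step a set of alternative KO
identifiers (KEGG-module-style OR-within-step, AND-across-steps); composite
routes are conjunctions of other routes. The default registry models
butyrate synthesis from starch, lactic acid and ethanol. Only the
l-lactate dehydrogenase (K00016) and alcohol dehydrogenase (K13954) KOs
are anchored in published gene lists; every other step's KO set is an
editable, non-authoritative default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import AnnotationMap, GeneFamilyMatrix, GenomeMeta, make_result_table
from .stats import poisson_group_test


@dataclass
class PathwayRoute:
    route_id: str
    steps: list[frozenset[str]] = field(default_factory=list)
    composite_of: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.composite_of:
            if self.steps:
                raise ValueError(f"route {self.route_id}: composite routes have no steps")
            if len(self.composite_of) < 2:
                raise ValueError(f"route {self.route_id}: composite needs >= 2 components")
        elif not self.steps or any(not s for s in self.steps):
            raise ValueError(f"route {self.route_id}: atomic routes need non-empty steps")


def default_routes() -> dict[str, PathwayRoute]:
    """Butyrate-synthesis route registry (starch / lactate / ethanol feeds)."""
    def atomic(rid, *steps):
        return PathwayRoute(rid, [frozenset(s) for s in steps])

    routes = [
        # starch -> glucose: alpha-amylase, then alpha-/oligo-glucosidase
        atomic("starch_to_glucose", {"K01176", "K05343"}, {"K01187", "K01182"}),
        # glucose -> pyruvate (glycolysis payoff-and-preparatory backbone)
        atomic(
            "glycolysis",
            {"K00845"}, {"K01810"}, {"K00850"}, {"K01623", "K01624"},
            {"K01803"}, {"K00134"}, {"K00927"}, {"K01834", "K15633"},
            {"K01689"}, {"K00873"},
        ),
        # lactate -> pyruvate: l-lactate dehydrogenase
        atomic("lactate_to_pyruvate", {"K00016"}),
        # pyruvate -> acetyl-CoA: PFOR or PDH E1
        atomic("pyruvate_to_acetylCoA", {"K03737", "K00163", "K00162"}),
        # ethanol -> acetyl-CoA: alcohol dehydrogenase, acetaldehyde dehydrogenase
        atomic("ethanol_to_acetylCoA", {"K13954", "K00001"}, {"K00132", "K04072"}),
        # acetyl-CoA -> butyrate: thiolase, 3-hydroxybutyryl-CoA dehydrogenase,
        # crotonase, butyryl-CoA dehydrogenase, butyrate kinase/transferase
        atomic(
            "acetylCoA_to_butyrate",
            {"K00626"}, {"K00074"}, {"K01715"}, {"K00248"}, {"K00929", "K01034"},
        ),
        PathwayRoute("starch_to_butyrate", composite_of=[
            "starch_to_glucose", "glycolysis", "pyruvate_to_acetylCoA", "acetylCoA_to_butyrate",
        ]),
        PathwayRoute("lactate_to_butyrate", composite_of=[
            "lactate_to_pyruvate", "pyruvate_to_acetylCoA", "acetylCoA_to_butyrate",
        ]),
        PathwayRoute("ethanol_to_butyrate", composite_of=[
            "ethanol_to_acetylCoA", "acetylCoA_to_butyrate",
        ]),
    ]
    return {r.route_id: r for r in routes}


def routes_to_yaml(routes: dict[str, PathwayRoute], path: str | Path) -> None:
    doc = {}
    for rid, route in routes.items():
        if route.composite_of:
            doc[rid] = {"composite_of": list(route.composite_of)}
        else:
            doc[rid] = {"steps": [sorted(s) for s in route.steps]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def routes_from_yaml(path: str | Path) -> dict[str, PathwayRoute]:
    doc = yaml.safe_load(Path(path).read_text())
    out = {}
    for rid, spec in doc.items():
        out[rid] = PathwayRoute(
            rid,
            [frozenset(s) for s in spec.get("steps", [])],
            list(spec.get("composite_of", [])),
        )
    return out


def route_complete(
    genome_ko_set: set[str],
    route: PathwayRoute,
    routes_registry: dict[str, PathwayRoute],
    _stack: frozenset[str] = frozenset(),
) -> bool:
    """True when every step of the route has at least one present KO.

    Composite routes are complete iff all components are complete; cyclic
    composite references are an error.
    """
    if route.route_id in _stack:
        raise ValueError(f"cyclic composite route reference at {route.route_id}")
    if route.composite_of:
        stack = _stack | {route.route_id}
        for rid in route.composite_of:
            if rid not in routes_registry:
                raise ValueError(f"route {route.route_id}: unknown component {rid}")
            if not route_complete(genome_ko_set, routes_registry[rid], routes_registry, stack):
                return False
        return True
    return all(step & genome_ko_set for step in route.steps)


def genome_ko_sets(matrix: GeneFamilyMatrix, annotations: AnnotationMap) -> dict[str, set[str]]:
    """Per-genome KO sets (KOs of families with copy >= 1)."""
    presence = matrix.presence()
    fam_ko = {f: rec.ko for f, rec in annotations.items() if rec.ko}
    out: dict[str, set[str]] = {g: set() for g in matrix.genome_ids}
    for fam, ko in fam_ko.items():
        if fam not in presence.index:
            continue
        for g in presence.columns[presence.loc[fam]]:
            out[g].add(ko)
    return out


def completeness_scan(
    matrix: GeneFamilyMatrix,
    annotations: AnnotationMap,
    metadata: list[GenomeMeta],
    routes: dict[str, PathwayRoute] | None = None,
) -> pd.DataFrame:
    """Per-genome route completeness table (genomes x routes, boolean).

    A genome with zero KO annotations is counted incomplete for every route.
    """
    if routes is None:
        routes = default_routes()
    ko_sets = genome_ko_sets(matrix, annotations)
    habitat = {m.genome_id: m.habitat for m in metadata}
    rows = []
    for g in matrix.genome_ids:
        row = {"genome_id": g, "habitat": habitat.get(g)}
        for rid, route in routes.items():
            row[rid] = route_complete(ko_sets[g], route, routes)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("genome_id")
    return table


def completeness_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-habitat per-route completeness proportion."""
    routes = [c for c in table.columns if c != "habitat"]
    return table.groupby("habitat")[routes].mean()


def route_group_test(table: pd.DataFrame, metadata: list[GenomeMeta] | None = None) -> pd.DataFrame:
    """Poisson observed-vs-expected comparison of route completeness.

    Per route, the completeness counts of the two habitat groups are
    compared with the cross-expectation Poisson test (group A = PMA).
    """
    if "habitat" not in table.columns:
        if metadata is None:
            raise ValueError("need a habitat column or metadata")
        habitat = {m.genome_id: m.habitat for m in metadata}
        table = table.assign(habitat=[habitat[g] for g in table.index])
    a = table[table.habitat == "PMA"]
    b = table[table.habitat == "NPMA"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both habitat groups must be present")
    rows = []
    for rid in (c for c in table.columns if c != "habitat"):
        k_a, k_b = int(a[rid].sum()), int(b[rid].sum())
        res = poisson_group_test(k_a, len(a), k_b, len(b))
        rows.append({
            "term": rid, "namespace": "ROUTE",
            "mean_a": k_a / len(a), "sd_a": float("nan"),
            "mean_b": k_b / len(b), "sd_b": float("nan"),
            "statistic": float(k_a), "p": res["p"], "p_adj": float("nan"),
            "estimate": k_a / len(a) - k_b / len(b),
            "direction": res["direction"],
            "method": "poisson_group_test",
        })
    return make_result_table(rows)
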