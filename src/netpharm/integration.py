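"""Cross-profile synthesis: Venn regions, k-of-m expansion, gene-pathway
networks and key-pathway nomination.

A "key pathway" is an annotation term significantly enriched in the screened
target set of every expression profile (the intersection of per-profile
significant-term sets).  The gene-pathway network is the bipartite graph of
candidate genes vs. significant terms; the gene of maximal degree (number of
distinct significant terms that contain it) is nominated as the core target,
with all tied maxima reported.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx

from .enrichment import EnrichmentRecord


@dataclass
class VennReport:
    """Exact region decomposition of 2-6 named sets.

    ``regions`` maps a region key — the ``"&"``-joined names of the sets the
    region belongs to — to the lexicographically sorted member list.  The
    regions partition the union.
    """

    set_names: list[str]
    regions: dict[str, list[str]]

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def region(self, *names: str) -> list[str]:
        return self.regions.get("&".join(sorted(names)), [])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"set_names": self.set_names, "regions": self.regions,
             "counts": self.counts()},
            indent=2, sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["region", "n", "members"])
            for key in sorted(self.regions):
                w.writerow([key, len(self.regions[key]), ";".join(self.regions[key])])


def venn(sets: dict[str, set[str]]) -> VennReport:
    """Decompose named sets into their 2^m - 1 exclusive regions."""
    if not 2 <= len(sets) <= 6:
        raise ValueError(f"venn needs 2-6 sets, got {len(sets)}")
    names = list(sets)
    union = set().union(*sets.values())
    regions: dict[str, list[str]] = {}
    for el in union:
        members = sorted(n for n in names if el in sets[n])
        regions.setdefault("&".join(members), []).append(el)
    for v in regions.values():
        v.sort()
    return VennReport(set_names=names, regions=regions)


def at_least(sets: dict[str, set[str]], k: int) -> set[str]:
    """Elements present in at least k of the sets (k=1 union, k=m
    intersection)."""
    if not 1 <= k <= len(sets):
        raise ValueError(f"k must be in [1, {len(sets)}], got {k}")
    union = set().union(*sets.values())
    return {el for el in union if sum(el in s for s in sets.values()) >= k}


@dataclass
class GenePathwayNetwork:
    """Bipartite gene <-> significant-term network with degree ranking."""

    edges: list[tuple[str, str]] = field(default_factory=list)  # (gene, term_id)
    degrees: dict[str, int] = field(default_factory=dict)
    ranked_genes: list[str] = field(default_factory=list)
    core_genes: set[str] = field(default_factory=set)

    @property
    def n_genes(self) -> int:
        return len(self.degrees)

    @property
    def n_terms(self) -> int:
        return len({t for _, t in self.edges})

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for gene, term in self.edges:
            g.add_node(gene, kind="gene")
            g.add_node(term, kind="term")
            g.add_edge(gene, term)
        return g

    def degree_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["gene", "degree", "is_core"])
            for g in self.ranked_genes:
                w.writerow([g, self.degrees[g], int(g in self.core_genes)])


def gene_pathway_network(
    records: list[EnrichmentRecord], candidates: set[str]
) -> GenePathwayNetwork:
    """Connect candidate genes to the significant terms whose hit sets
    contain them; rank genes by degree (descending, ties lexicographic) and
    report every tied maximum as a core gene."""
    if not candidates:
        raise ValueError("candidate gene set is empty")
    edges = sorted(
        (gene, rec.term_id)
        for rec in records
        for gene in rec.hit_genes & candidates
    )
    net = GenePathwayNetwork(edges=edges)
    if not edges:
        return net
    for gene, _ in edges:
        net.degrees[gene] = net.degrees.get(gene, 0) + 1
    net.ranked_genes = sorted(net.degrees, key=lambda g: (-net.degrees[g], g))
    dmax = net.degrees[net.ranked_genes[0]]
    net.core_genes = {g for g, d in net.degrees.items() if d == dmax}
    return net


def key_pathways(per_profile_terms: list[set[str]]) -> set[str]:
    """Term ids significant in every profile."""
    if len(per_profile_terms) < 2:
        raise ValueError("need >= 2 profiles")
    out = set(per_profile_terms[0])
    for s in per_profile_terms[1:]:
        out &= s
    return out


def key_pathway_table(
    per_profile_records: dict[str, list[EnrichmentRecord]], fdr_max: float = 0.05
) -> list[dict]:
    """Key pathways with per-profile p/fdr side by side."""
    sig_sets = [
        {r.term_id for r in recs if r.fdr < fdr_max}
        for recs in per_profile_records.values()
    ]
    shared = key_pathways(sig_sets)
    rows = []
    for term in sorted(shared):
        row: dict = {"term_id": term}
        for prof, recs in per_profile_records.items():
            rec = next(r for r in recs if r.term_id == term)
            row[prof] = {"p": rec.p, "fdr": rec.fdr, "k": rec.k}
            row.setdefault("name", rec.term_name)
            row.setdefault("category", rec.category)
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# run report


class ReportSchemaError(ValueError):
    """Report does not conform to the shipped schema."""


def _check(instance, schema, path="$") -> None:
    """Minimal structural validator for the subset of JSON Schema used by
    the shipped report schema (type, properties, required, items, enum)."""
    typ = schema.get("type")
    type_map = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "integer": int, "boolean": bool,
    }
    if typ is not None:
        expected = type_map[typ]
        if typ == "number" and isinstance(instance, bool):
            raise ReportSchemaError(f"{path}: boolean where number expected")
        if not isinstance(instance, expected) or (
            typ in ("integer",) and isinstance(instance, bool)
        ):
            raise ReportSchemaError(f"{path}: expected {typ}, got {type(instance).__name__}")
    if "enum" in schema and instance not in schema["enum"]:
        raise ReportSchemaError(f"{path}: {instance!r} not in {schema['enum']}")
    if typ == "object":
        for req in schema.get("required", []):
            if req not in instance:
                raise ReportSchemaError(f"{path}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}")
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            for key in instance:
                if key not in schema.get("properties", {}):
                    _check(instance[key], extra, f"{path}.{key}")
    if typ == "array" and "items" in schema:
        for i, el in enumerate(instance):
            _check(el, schema["items"], f"{path}[{i}]")


def validate_report(report: dict) -> None:
    """Validate a run report against the packaged report schema."""
    ref = resources.files("netpharm.data").joinpath("report.schema.json")
    schema = json.loads(ref.read_text())
    _check(report, schema)


def build_report(
    config_hash: str,
    seed: int,
    profiles: dict[str, dict | None],
    compounds: dict | None = None,
    integration: dict | None = None,
    recovery: dict | None = None,
) -> dict:
    """Assemble the end-of-run report.

    A stage that did not run is recorded as ``{"status": "absent"}`` rather
    than failing the report.  The result is deterministic for a fixed seed
    and config (no timestamps, sorted keys on serialization).
    """
    def stage(value):
        return value if value is not None else {"status": "absent"}

    return {
        "schema_version": 1,
        "config_hash": config_hash,
        "seed": seed,
        "compounds": stage(compounds),
        "profiles": {pid: stage(p) for pid, p in profiles.items()},
        "integration": stage(integration),
        "recovery": stage(recovery),
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
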