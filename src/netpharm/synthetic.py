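"""Synthetic herb-compound-target-disease systems with planted ground truth.

Stands in for the external sources of a network-pharmacology study — a
compound database (TCMSP-like table with OB/DL columns and cross-herb
duplicates), two-group expression profiles (GEO-like log2 matrices with a
planted differentially expressed gene set), a merged interactome (scale-free
preferential-attachment graph with a densely wired high-centrality core) and
flat GO/KEGG-like annotations (one planted term per category enriched in the
core).  Every artifact is written in exactly the format the pipeline reads,
and a manifest records the planted truth so recovery can be scored.

One scenario seed governs everything through fixed per-component substreams
(``default_rng([seed, offset])``), so regenerating one artifact never
perturbs the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .compounds import Compound, CompoundTable
from .diffexpr import CASE, CONTROL, ExpressionProfile
from .enrichment import CATEGORIES, GeneSet, write_gmt

# fixed substream offsets (scenario seed -> independent component streams)
_OFF_SCENARIO = 1
_OFF_PPI = 2
_OFF_ANNOT = 3
_OFF_COMPOUNDS = 4
_OFF_EXPR_BASE = 10  # + profile index

HERB_CODES = ("RRP", "RAS", "RD", "RAB", "P", "PCRV", "FC", "CE", "RPA")


@dataclass
class SyntheticManifest:
    """Planted ground truth of one generated scenario."""

    seed: int
    params: dict = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)
    ppi_nodes: list[str] = field(default_factory=list)
    core_nodes: list[str] = field(default_factory=list)
    planted_terms: dict[str, str] = field(default_factory=dict)  # category -> term_id
    profiles: dict[str, dict] = field(default_factory=dict)  # id -> {up: [...], down: [...]}
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticManifest":
        return cls(**json.loads(Path(path).read_text()))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    n_genes: int = 2000,
    n_case: int = 12,
    n_control: int = 12,
    n_de: int = 300,
    delta: float = 1.0,
    sigma: float = 0.5,
    seed: int = 0,
    genes: list[str] | None = None,
    de_genes: list[str] | None = None,
) -> tuple[ExpressionProfile, dict]:
    """Two-group log2 matrix with ``n_de`` genes shifted by +-delta in cases.

    Baseline per-gene means are drawn once (Normal(7, 1.5), a typical log2
    microarray scale); i.i.d. Normal(0, sigma^2) noise is added everywhere;
    the first half of the planted genes shift up, the second half down.
    Returns the profile and a manifest entry with the up/down gene lists.
    """
    if not (n_case >= 3 and n_control >= 3):
        raise ValueError("need n_case, n_control >= 3")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    genes = list(genes) if genes is not None else _gene_names(n_genes)
    if len(genes) != n_genes:
        raise ValueError("len(genes) != n_genes")
    if de_genes is None:
        rng_pick = np.random.default_rng([seed, _OFF_EXPR_BASE, 0])
        de_genes = [genes[i] for i in rng_pick.choice(n_genes, size=n_de, replace=False)]
    if len(de_genes) > n_genes:
        raise ValueError("n_de exceeds n_genes")

    rng = np.random.default_rng([seed, _OFF_EXPR_BASE, 1])
    base = rng.normal(7.0, 1.5, n_genes)
    mat = base[:, None] + rng.normal(0.0, sigma, (n_genes, n_case + n_control))

    idx = {g: i for i, g in enumerate(genes)}
    half = len(de_genes) // 2
    up, down = de_genes[:half], de_genes[half:]
    for g in up:
        mat[idx[g], :n_case] += delta
    for g in down:
        mat[idx[g], :n_case] -= delta

    samples = [f"case_{i+1}" for i in range(n_case)] + [f"ctrl_{i+1}" for i in range(n_control)]
    groups = {s: (CASE if s.startswith("case") else CONTROL) for s in samples}
    profile = ExpressionProfile(
        values=pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples),
        groups=groups,
    )
    entry = {"up": sorted(up), "down": sorted(down), "delta": delta, "sigma": sigma,
             "n_case": n_case, "n_control": n_control}
    return profile, entry


# ---------------------------------------------------------------------------
# interactome


def gen_ppi(
    n_nodes: int = 500,
    m_attach: int = 3,
    core_size: int = 20,
    core_extra_p: float = 0.9,
    seed: int = 0,
    nodes: list[str] | None = None,
) -> tuple[nx.Graph, dict]:
    """Scale-free interactome with a planted high-centrality core.

    A Barabasi-Albert base graph (preferential attachment, ``m_attach`` edges
    per arriving node) is overlaid with a near-clique hosted on the
    ``core_size`` highest-degree nodes: core nodes are pairwise wired with
    probability ``core_extra_p`` and each additionally attached to
    ceil(3 * m_attach) random non-core nodes.  Hosting the module on the
    hubs is what makes the core a genuinely high-centrality structure — it
    dominates degree, betweenness and neighborhood-cohesion scores, the way
    a disease module sitting on interactome hubs would; a module planted on
    random low-degree nodes can never out-rank scale-free hubs on degree.
    The result is guaranteed simple.
    """
    if not core_size < n_nodes:
        raise ValueError("core_size must be < n_nodes")
    if m_attach < 1:
        raise ValueError("m_attach must be >= 1")
    rng = np.random.default_rng([seed, _OFF_PPI])
    base_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(n_nodes, m_attach, seed=base_seed)

    labels = list(nodes) if nodes is not None else [f"P{i:05d}" for i in range(1, n_nodes + 1)]
    if len(labels) != n_nodes:
        raise ValueError("len(nodes) != n_nodes")
    g = nx.relabel_nodes(g, dict(enumerate(labels)))

    core = sorted(
        sorted(g.nodes(), key=lambda v: (-g.degree(v), v))[:core_size]
    )
    core_set = set(core)
    for i, a in enumerate(core):
        for b in core[i + 1:]:
            if rng.random() < core_extra_p:
                g.add_edge(a, b)
    non_core = [v for v in labels if v not in core_set]
    n_extra = math.ceil(3 * m_attach)
    for a in core:
        picks = rng.choice(len(non_core), size=n_extra, replace=False)
        for j in picks:
            g.add_edge(a, non_core[j])

    entry = {"n_nodes": n_nodes, "m_attach": m_attach, "core_size": core_size,
             "core_extra_p": core_extra_p, "core_nodes": core}
    return g, entry


# ---------------------------------------------------------------------------
# annotations


def gen_annotations(
    universe: list[str],
    n_terms: int = 200,
    size_range: tuple[int, int] = (10, 60),
    core_nodes: list[str] | None = None,
    planted_frac: float = 1.0,
    seed: int = 0,
) -> tuple[list[GeneSet], dict]:
    """Flat gene-set database with one core-enriched term per category.

    Background terms draw uniformly from the universe; each planted term
    takes ceil(planted_frac * |core|) core genes padded with random non-core
    genes up to an in-range size.
    """
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError("size_range exceeds universe size")
    if core_nodes and not 0 < planted_frac <= 1:
        raise ValueError("planted_frac must be in (0, 1]")
    rng = np.random.default_rng([seed, _OFF_ANNOT])
    universe = list(universe)
    sets: list[GeneSet] = []
    planted: dict[str, str] = {}

    if core_nodes:
        core = sorted(core_nodes)
        n_core_in = math.ceil(planted_frac * len(core))
        non_core = [g for g in universe if g not in set(core)]
        for ci, cat in enumerate(CATEGORIES):
            size = int(rng.integers(max(lo, n_core_in), hi + 1))
            chosen = [core[i] for i in rng.choice(len(core), size=n_core_in, replace=False)]
            pad = [non_core[i] for i in
                   rng.choice(len(non_core), size=size - n_core_in, replace=False)]
            tid = f"PLANT_{cat}"
            sets.append(GeneSet(term_id=tid, term_name=f"planted core module ({cat})",
                                category=cat, genes=frozenset(chosen + pad)))
            planted[cat] = tid

    n_background = n_terms - len(sets)
    for i in range(n_background):
        cat = CATEGORIES[int(rng.integers(len(CATEGORIES)))]
        size = int(rng.integers(lo, hi + 1))
        members = [universe[j] for j in rng.choice(len(universe), size=size, replace=False)]
        sets.append(GeneSet(term_id=f"T{i+1:04d}", term_name=f"background term {i+1}",
                            category=cat, genes=frozenset(members)))

    entry = {"n_terms": len(sets), "size_range": list(size_range),
             "planted_frac": planted_frac, "planted_terms": planted}
    return sets, entry


# ---------------------------------------------------------------------------
# compounds


def gen_compound_table(
    n_compounds: int = 120,
    herbs: tuple[str, ...] = HERB_CODES,
    dup_frac: float = 0.15,
    ob_range: tuple[float, float] = (10.0, 90.0),
    dl_beta: tuple[float, float] = (2.0, 2.0),
    targets_per_compound: tuple[int, int] = (2, 8),
    universe: list[str] | None = None,
    core_nodes: list[str] | None = None,
    core_bias: float = 0.3,
    seed: int = 0,
) -> tuple[CompoundTable, dict[str, set[str]], dict]:
    """TCMSP-shaped compound table plus a compound->target map.

    A ``dup_frac`` fraction of compounds belongs to two or three herbs and is
    emitted as one row per herb (same compound id), so the raw table
    exercises de-duplication.  OB is uniform on ``ob_range`` (percent), DL is
    Beta-distributed on [0, 1].  Targets draw from ``universe``; when
    ``core_nodes`` is given each target is drawn from the core with
    probability ``core_bias`` so downstream screening has signal.
    """
    if not 0 <= dup_frac < 1:
        raise ValueError("dup_frac must be in [0, 1)")
    rng = np.random.default_rng([seed, _OFF_COMPOUNDS])
    universe = list(universe) if universe is not None else _gene_names(2000)
    core = sorted(core_nodes) if core_nodes else []
    non_core = [g for g in universe if g not in set(core)]

    rows: list[Compound] = []
    target_map: dict[str, set[str]] = {}
    n_multi = 0
    for i in range(n_compounds):
        cid = f"SYN{i+1:06d}"
        name = f"synthetic-compound-{i+1}"
        ob = float(rng.uniform(*ob_range))
        dl = float(rng.beta(*dl_beta))
        if rng.random() < dup_frac:
            n_herbs = int(rng.integers(2, 4))
            n_multi += 1
        else:
            n_herbs = 1
        assigned = [herbs[j] for j in rng.choice(len(herbs), size=n_herbs, replace=False)]
        for h in assigned:  # one row per herb: raw duplicates
            rows.append(Compound(compound_id=cid, name=name, ob=ob, dl=dl,
                                 herbs=frozenset([h])))
        n_targets = int(rng.integers(targets_per_compound[0], targets_per_compound[1] + 1))
        tset: set[str] = set()
        while len(tset) < n_targets:
            if core and rng.random() < core_bias:
                tset.add(core[int(rng.integers(len(core)))])
            else:
                tset.add(non_core[int(rng.integers(len(non_core)))])
        target_map[cid] = tset

    table = CompoundTable(rows=rows, provenance=f"synthetic(seed={seed})")
    entry = {"n_compounds": n_compounds, "n_multi_herb": n_multi, "dup_frac": dup_frac,
             "core_bias": core_bias}
    return table, target_map, entry


def write_compound_table(table: CompoundTable, path: str | Path) -> None:
    """Write a raw compound table in the canonical TSV dialect
    (ID/Name/OB/DL/Medical plants)."""
    with open(path, "w") as fh:
        fh.write("ID\tName\tOB\tDL\tMedical plants\n")
        for c in table.rows:
            fh.write(f"{c.compound_id}\t{c.name}\t{c.ob:.4f}\t{c.dl:.4f}\t"
                     f"{', '.join(sorted(c.herbs))}\n")


def write_target_map(target_map: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(target_map):
            for g in sorted(target_map[cid]):
                fh.write(f"{cid}\t{g}\n")


def read_target_map(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split("\t")
            if len(parts) >= 2:
                out.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return out


def write_ppi(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# full scenario


def gen_scenario(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 2000,
    n_profiles: int = 3,
    n_case: int = 12,
    n_control: int = 12,
    n_de: int = 300,
    delta: float = 1.0,
    sigma: float = 0.5,
    ppi_nodes: int = 500,
    m_attach: int = 3,
    core_size: int = 20,
    core_extra_p: float = 0.9,
    n_terms: int = 200,
    term_size_range: tuple[int, int] = (10, 60),
    planted_frac: float = 1.0,
    n_compounds: int = 120,
    dup_frac: float = 0.15,
) -> SyntheticManifest:
    """Generate a complete multi-profile study into ``outdir``.

    The interactome nodes are a random subset of the gene universe; each
    profile's planted DE set contains every core node (the shared disease
    module) plus a per-profile random remainder, so the planted pathway is
    recoverable from all profiles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, _OFF_SCENARIO])
    genes = _gene_names(n_genes)

    ppi_node_names = sorted(
        genes[i] for i in rng.choice(n_genes, size=ppi_nodes, replace=False)
    )
    ppi, ppi_entry = gen_ppi(
        n_nodes=ppi_nodes, m_attach=m_attach, core_size=core_size,
        core_extra_p=core_extra_p, seed=seed, nodes=ppi_node_names,
    )
    core = ppi_entry["core_nodes"]

    annotations, annot_entry = gen_annotations(
        universe=genes, n_terms=n_terms, size_range=term_size_range,
        core_nodes=core, planted_frac=planted_frac, seed=seed,
    )

    compounds, target_map, comp_entry = gen_compound_table(
        n_compounds=n_compounds, dup_frac=dup_frac, universe=ppi_node_names,
        core_nodes=core, seed=seed,
    )

    manifest = SyntheticManifest(
        seed=seed,
        params={
            "n_genes": n_genes, "n_profiles": n_profiles, "n_case": n_case,
            "n_control": n_control, "n_de": n_de, "delta": delta, "sigma": sigma,
            "ppi_nodes": ppi_nodes, "m_attach": m_attach, "core_size": core_size,
            "core_extra_p": core_extra_p, "n_terms": n_terms,
            "term_size_range": list(term_size_range), "planted_frac": planted_frac,
            "n_compounds": n_compounds, "dup_frac": dup_frac,
        },
        genes=genes,
        ppi_nodes=ppi_node_names,
        core_nodes=core,
        planted_terms=annot_entry["planted_terms"],
    )

    non_core_pool = [g for g in genes if g not in set(core)]
    for i in range(n_profiles):
        pid = f"profile_{i+1}"
        n_rest = max(n_de - len(core), 0)
        rest = [non_core_pool[j]
                for j in rng.choice(len(non_core_pool), size=n_rest, replace=False)]
        de = sorted(core) + sorted(rest)
        profile, entry = gen_expression(
            n_genes=n_genes, n_case=n_case, n_control=n_control, n_de=len(de),
            delta=delta, sigma=sigma, seed=seed + i, genes=genes, de_genes=de,
        )
        mpath = outdir / f"{pid}_matrix.tsv"
        gpath = outdir / f"{pid}_groups.tsv"
        profile.to_tsv(mpath, gpath)
        manifest.profiles[pid] = entry
        manifest.files[f"{pid}_matrix"] = mpath.name
        manifest.files[f"{pid}_groups"] = gpath.name

    write_ppi(ppi, outdir / "ppi.tsv")
    write_gmt(annotations, outdir / "annotations.gmt")
    write_compound_table(compounds, outdir / "compounds.tsv")
    write_target_map(target_map, outdir / "targets.tsv")
    manifest.files.update(
        ppi="ppi.tsv", annotations="annotations.gmt",
        compounds="compounds.tsv", targets="targets.tsv",
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
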