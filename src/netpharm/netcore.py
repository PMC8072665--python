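"""PPI graph construction and centrality-based target screening.

The working object is a simple undirected :class:`networkx.Graph`.  Target
screening follows a two-stage cascade over six node-centrality scores:

DC   degree centrality, deg(v).
BC   betweenness (Brandes), unnormalized, each unordered pair counted once.
CCT  closeness, Wasserman-Faust composite
     (r_v/(n-1)) * (r_v / sum of distances to reachable nodes); equals the
     classical (n-1)/sum(dist) on connected graphs.
EC   eigenvector centrality: non-negative principal eigenvector of the
     adjacency matrix, L2-normalized, scored on the largest connected
     component (other nodes score 0).
LAC  local average connectivity: mean degree of v's neighbors within the
     subgraph induced by those neighbors.
NC   network centrality (edge-clustering form): sum over neighbors w of
     ECC(v, w) = |common neighbors| / min(deg v - 1, deg w - 1), with
     ECC = 0 when the denominator is 0.

Stage 1 keeps nodes whose degree strictly exceeds a threshold (an absolute
cutoff, or factor x median degree); stage 2 recomputes the remaining metrics
on the stage-1 induced subgraph and keeps nodes strictly above the median of
every configured metric.  Strict inequalities mean fully tied score vectors
(e.g. a complete graph) eliminate everything, which is the documented
degenerate behaviour.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ALL_METRICS = ("DC", "BC", "CCT", "EC", "LAC", "NC")
STAGE2_DEFAULT = ("BC", "CCT", "EC", "LAC", "NC")


class GraphInputError(ValueError):
    """Non-simple or otherwise invalid graph input."""


# ---------------------------------------------------------------------------
# construction


@dataclass
class BipartiteNetwork:
    """Compound-target bipartite network (isolated vertices excluded)."""

    compounds: list[str]
    targets: list[str]
    edges: list[tuple[str, str]]

    @property
    def n_nodes(self) -> int:
        return len(self.compounds) + len(self.targets)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def compound_degrees(self) -> list[tuple[str, int]]:
        """Per-compound target counts, descending, ties lexicographic."""
        deg: dict[str, int] = {c: 0 for c in self.compounds}
        for c, _ in self.edges:
            deg[c] += 1
        return sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.compounds, kind="compound")
        g.add_nodes_from(self.targets, kind="target")
        g.add_edges_from(self.edges)
        return g


def build_ct_network(
    compound_targets: dict[str, set[str]], disease_genes: set[str]
) -> BipartiteNetwork:
    """Connect each compound to its targets that are also disease genes;
    compounds and targets left without an edge are dropped."""
    edges: list[tuple[str, str]] = []
    for comp in sorted(compound_targets):
        for gene in sorted(set(compound_targets[comp]) & set(disease_genes)):
            edges.append((comp, gene))
    if not edges:
        log.warning("compound-target network is empty (no targets overlap disease genes)")
    compounds = sorted({c for c, _ in edges})
    targets = sorted({t for _, t in edges})
    return BipartiteNetwork(compounds=compounds, targets=targets, edges=edges)


def validate_simple(g: nx.Graph) -> None:
    if g.is_directed() or g.is_multigraph():
        raise GraphInputError("graph must be simple and undirected")
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise GraphInputError(f"graph has {len(loops)} self-loops")


def read_ppi_tsv(path: str | Path) -> nx.Graph:
    """Read a 2- or 3-column (SIF-compatible) interaction list into a simple
    undirected graph; self-loops are dropped with a logged count, duplicate
    edges collapse silently."""
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            parts = [p.strip() for p in parts if p.strip()]
            if not parts:
                continue
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:
                a, _, b = parts
            else:
                raise GraphInputError(f"{path}:{lineno}: expected 2 or 3 columns")
            if a == b:
                n_loops += 1
                continue
            g.add_edge(a, b)
    if n_loops:
        log.info("%s: dropped %d self-loops", path, n_loops)
    return g


def write_sif(g: nx.Graph, path: str | Path, interaction: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{interaction}\t{b}\n")
        for v in sorted(n for n in g.nodes() if g.degree(n) == 0):
            fh.write(f"{v}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def neighborhood_network(seeds: set[str], ppi: nx.Graph) -> nx.Graph:
    """One-hop seed expansion: the subgraph induced by the seeds present in
    the interactome plus their first neighbors."""
    validate_simple(ppi)
    present = set(seeds) & set(ppi.nodes())
    if not present:
        log.warning("no seed occurs in the interactome; returning empty graph")
        return nx.Graph()
    nodes = set(present)
    for s in present:
        nodes.update(ppi.neighbors(s))
    return ppi.subgraph(nodes).copy()


def intersect_networks(g1: nx.Graph, g2: nx.Graph) -> nx.Graph:
    """Node-and-edge intersection of two graphs."""
    nodes = set(g1.nodes()) & set(g2.nodes())
    out = nx.Graph()
    out.add_nodes_from(nodes)
    for a, b in g1.edges():
        if a in nodes and b in nodes and g2.has_edge(a, b):
            out.add_edge(a, b)
    return out


# ---------------------------------------------------------------------------
# centralities


def _eigenvector_power(g: nx.Graph, tol: float = 1e-10, max_iter: int = 100_000) -> dict:
    """Principal-eigenvector scores by power iteration on the largest
    connected component.

    Iterates v <- (A + I) v / ||.||2: the identity shift leaves the Perron
    vector unchanged while making the iteration matrix primitive, so the
    sequence cannot oscillate on bipartite components.  Nodes outside the
    largest component score 0.
    """
    scores = {v: 0.0 for v in g.nodes()}
    if g.number_of_nodes() == 0:
        return scores
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0]))
    nodes = sorted(comp)
    if len(nodes) == 1:
        scores[nodes[0]] = 1.0
        return scores
    sub = g.subgraph(nodes)
    a = nx.to_numpy_array(sub, nodelist=nodes)
    np.fill_diagonal(a, 1.0)  # A + I
    v = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        w = a @ v
        w /= np.linalg.norm(w)
        if np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    v /= np.linalg.norm(v)
    for node, val in zip(nodes, v):
        scores[node] = float(val)
    return scores


def _lac(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes():
        nbrs = list(g.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        nbr_set = set(nbrs)
        # sum of induced degrees = 2 * edges within the neighborhood
        within = sum(1 for a in nbrs for b in g.neighbors(a) if b in nbr_set)
        out[v] = within / len(nbrs)
    return out


def _nc(g: nx.Graph) -> dict:
    adj = {v: set(g.neighbors(v)) for v in g.nodes()}
    out = {}
    for v in g.nodes():
        total = 0.0
        dv = len(adj[v])
        for w in adj[v]:
            denom = min(dv - 1, len(adj[w]) - 1)
            if denom > 0:
                total += len(adj[v] & adj[w]) / denom
        out[v] = total
    return out


def centralities(g: nx.Graph, metrics: tuple[str, ...] = ALL_METRICS) -> pd.DataFrame:
    """Score every node on the requested metrics; one column per metric,
    rows sorted by node label."""
    validate_simple(g)
    unknown = set(metrics) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    nodes = sorted(g.nodes())
    cols: dict[str, dict] = {}
    if "DC" in metrics:
        cols["DC"] = dict(g.degree())
    if "BC" in metrics:
        cols["BC"] = nx.betweenness_centrality(g, normalized=False)
    if "CCT" in metrics:
        cols["CCT"] = nx.closeness_centrality(g, wf_improved=True)
    if "EC" in metrics:
        cols["EC"] = _eigenvector_power(g)
    if "LAC" in metrics:
        cols["LAC"] = _lac(g)
    if "NC" in metrics:
        cols["NC"] = _nc(g)
    return pd.DataFrame({m: [cols[m][v] for v in nodes] for m in metrics}, index=nodes)


# ---------------------------------------------------------------------------
# screening cascade


@dataclass
class CascadeConfig:
    """Two-stage screen configuration.

    Stage 1 cuts on degree: ``dc_abs`` if given, else ``dc_factor`` x median
    degree.  Stage 2 cuts at the median of every metric in
    ``stage2_metrics``, recomputed on the stage-1 subgraph.  All cuts are
    strict (score > threshold).
    """

    dc_abs: float | None = None
    dc_factor: float = 2.0
    stage2_metrics: tuple[str, ...] = STAGE2_DEFAULT

    def __post_init__(self) -> None:
        if not self.stage2_metrics:
            raise ValueError("stage2_metrics must be non-empty")
        if self.dc_abs is None and not self.dc_factor > 0:
            raise ValueError("dc_factor must be > 0")


@dataclass
class CascadeResult:
    stages: list[dict] = field(default_factory=list)
    final_nodes: list[str] = field(default_factory=list)
    final_graph: nx.Graph | None = None
    empty_after_stage1: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "stages": self.stages,
                "final_nodes": self.final_nodes,
                "empty_after_stage1": self.empty_after_stage1,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def screen_stage(
    g: nx.Graph, scores: pd.DataFrame, metrics: tuple[str, ...], thresholds: dict[str, float]
) -> nx.Graph:
    """Induced subgraph on nodes strictly above the threshold of every
    listed metric."""
    for m in metrics:
        if m not in scores.columns:
            raise ValueError(f"metric {m!r} missing from the score table")
        if m not in thresholds:
            raise ValueError(f"no threshold supplied for metric {m!r}")
    keep = [
        v for v in g.nodes()
        if all(scores.at[v, m] > thresholds[m] for m in metrics)
    ]
    return g.subgraph(keep).copy()


def run_cascade(g: nx.Graph, cfg: CascadeConfig | None = None) -> CascadeResult:
    """Degree cut, then joint strict-median cut on the stage-1 subgraph."""
    if g.number_of_nodes() == 0:
        raise GraphInputError("cascade input graph is empty")
    cfg = cfg or CascadeConfig()
    res = CascadeResult()
    res.stages.append(
        {"stage": "input", "n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges()}
    )

    dc = centralities(g, metrics=("DC",))
    dc_median = float(np.median(dc["DC"].to_numpy()))
    tau1 = float(cfg.dc_abs) if cfg.dc_abs is not None else cfg.dc_factor * dc_median
    g1 = screen_stage(g, dc, ("DC",), {"DC": tau1})
    res.stages.append(
        {
            "stage": "degree",
            "n_nodes": g1.number_of_nodes(),
            "n_edges": g1.number_of_edges(),
            "dc_median": dc_median,
            "threshold": tau1,
            "rule": "absolute" if cfg.dc_abs is not None else f"{cfg.dc_factor}x median",
        }
    )
    if g1.number_of_nodes() == 0:
        res.empty_after_stage1 = True
        log.warning("cascade empty after the degree stage (threshold %g)", tau1)
        return res

    scores = centralities(g1, metrics=tuple(cfg.stage2_metrics))
    medians = {m: float(np.median(scores[m].to_numpy())) for m in cfg.stage2_metrics}
    g2 = screen_stage(g1, scores, tuple(cfg.stage2_metrics), medians)
    res.stages.append(
        {
            "stage": "centrality_medians",
            "n_nodes": g2.number_of_nodes(),
            "n_edges": g2.number_of_edges(),
            "metrics": list(cfg.stage2_metrics),
            "thresholds": medians,
        }
    )
    res.final_graph = g2
    res.final_nodes = sorted(g2.nodes())
    return res
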