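"""End-to-end orchestration of the network-pharmacology inference chain.

Per profile: differential expression -> compound-target network -> one-hop
seed networks for formulation targets and disease genes -> network
intersection -> two-stage centrality cascade -> over-representation
analysis.  Across profiles: Venn decompositions, the >=2-of-m expansion,
gene-pathway networks and key-pathway nomination, all folded into a single
deterministic JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import compounds as cmod
from . import integration as imod
from . import netcore
from .diffexpr import ExpressionProfile, differential_expression
from .enrichment import CATEGORIES, enrich, parse_gmt, top_terms, write_enrichment_csv
from .synthetic import SyntheticManifest, read_target_map

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class ProfileSpec:
    profile_id: str
    matrix: str
    groups: str


@dataclass
class PipelineConfig:
    """Every printed threshold of the procedure, in one serializable block:
    ADME cutoffs (OB >= 30, DL >= 0.18), DE screening (p < 0.05,
    |log2FC| > 0.05), the degree rule and stage-2 metric set of the cascade,
    the enrichment FDR cutoff (< 0.05) and top-k (20), and the k-of-m
    integration rule."""

    compounds: str = ""
    targets: str = ""
    ppi: str = ""
    gmt: str = ""
    profiles: list[ProfileSpec] = field(default_factory=list)
    outdir: str = "netpharm_out"
    seed: int = 0
    manifest: str | None = None

    ob_min: float = 30.0
    dl_min: float = 0.18
    p_max: float = 0.05
    lfc_min: float = 0.05
    use_fdr: bool = False
    test: str = "moderated"
    dc_abs: float | None = None
    dc_factor: float = 2.0
    stage2_metrics: tuple[str, ...] = netcore.STAGE2_DEFAULT
    fdr_max: float = 0.05
    top_k: int = 20
    at_least_k: int = 2

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["profiles"] = [asdict(p) for p in self.profiles]
        d["stage2_metrics"] = list(self.stage2_metrics)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["profiles"] = [ProfileSpec(**p) for p in d.get("profiles", [])]
        if "stage2_metrics" in d:
            d["stage2_metrics"] = tuple(d["stage2_metrics"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- validation ---------------------------------------------------------

    def validate(self, require_profiles: int = 1) -> None:
        for name in ("compounds", "targets", "ppi", "gmt"):
            path = getattr(self, name)
            if not path:
                raise ConfigError(f"config field {name!r} is required")
            if not Path(path).exists():
                raise ConfigError(f"{name} file not found: {path}")
        if len(self.profiles) < require_profiles:
            raise ConfigError(
                f"need >= {require_profiles} profiles, got {len(self.profiles)}"
            )
        for p in self.profiles:
            for f in (p.matrix, p.groups):
                if not Path(f).exists():
                    raise ConfigError(f"profile {p.profile_id}: file not found: {f}")
        if not (0 < self.p_max <= 1 and 0 < self.fdr_max <= 1):
            raise ConfigError("p_max and fdr_max must lie in (0, 1]")
        if self.manifest and not Path(self.manifest).exists():
            raise ConfigError(f"manifest file not found: {self.manifest}")

    @classmethod
    def for_scenario(cls, scenario_dir: str | Path, outdir: str | Path | None = None,
                     seed: int = 0, **overrides) -> "PipelineConfig":
        """Point a config at a directory produced by
        :func:`netpharm.synthetic.gen_scenario`."""
        d = Path(scenario_dir)
        manifest = SyntheticManifest.from_json(d / "manifest.json")
        profiles = [
            ProfileSpec(profile_id=pid,
                        matrix=str(d / manifest.files[f"{pid}_matrix"]),
                        groups=str(d / manifest.files[f"{pid}_groups"]))
            for pid in sorted(manifest.profiles)
        ]
        return cls(
            compounds=str(d / manifest.files["compounds"]),
            targets=str(d / manifest.files["targets"]),
            ppi=str(d / manifest.files["ppi"]),
            gmt=str(d / manifest.files["annotations"]),
            profiles=profiles,
            outdir=str(outdir if outdir is not None else d / "out"),
            seed=seed,
            manifest=str(d / "manifest.json"),
            **overrides,
        )


# ---------------------------------------------------------------------------
# shared inputs


@dataclass
class SharedInputs:
    table: cmod.CompoundTable  # ADME-filtered, de-duplicated
    census: cmod.HerbCensus
    n_input: int
    n_pass_adme: int
    target_map: dict[str, set[str]]
    ppi: "netcore.nx.Graph"
    db: list


def load_shared(cfg: PipelineConfig) -> SharedInputs:
    raw = cmod.parse_compound_table(cfg.compounds)
    filtered = cmod.filter_adme(raw, ob_min=cfg.ob_min, dl_min=cfg.dl_min)
    table = cmod.deduplicate(filtered)
    census = cmod.herb_census(table)
    target_map = read_target_map(cfg.targets)
    keep = set(table.ids())
    target_map = {c: t for c, t in target_map.items() if c in keep}
    return SharedInputs(
        table=table,
        census=census,
        n_input=len(raw),
        n_pass_adme=len(filtered),
        target_map=target_map,
        ppi=netcore.read_ppi_tsv(cfg.ppi),
        db=parse_gmt(cfg.gmt),
    )


# ---------------------------------------------------------------------------
# per-profile run


@dataclass
class ProfileResult:
    profile_id: str
    deg_summary: dict
    disease_genes: set[str]
    ct: netcore.BipartiteNetwork
    cascade: netcore.CascadeResult
    records: list
    report: dict


def run_profile(cfg: PipelineConfig, profile_id: str,
                shared: SharedInputs | None = None) -> ProfileResult:
    """Run the full single-profile chain and write its artifacts under
    ``<outdir>/<profile_id>/``."""
    spec = next((p for p in cfg.profiles if p.profile_id == profile_id), None)
    if spec is None:
        raise ConfigError(f"unknown profile id {profile_id!r}")
    shared = shared or load_shared(cfg)
    outdir = Path(cfg.outdir) / profile_id
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("[%s] differential expression", profile_id)
    profile = ExpressionProfile.from_tsv(spec.matrix, spec.groups)
    degs = differential_expression(
        profile, p_max=cfg.p_max, lfc_min=cfg.lfc_min,
        use_fdr=cfg.use_fdr, test=cfg.test,
    )
    degs.to_csv(outdir / "degs.csv")
    degs.summary_json(outdir / "deg_summary.json")
    disease = degs.significant_genes()
    log.info("[%s] %d DE genes (%d up / %d down)",
             profile_id, len(disease), degs.n_up, degs.n_down)

    ct = netcore.build_ct_network(shared.target_map, disease)
    netcore.write_sif(ct.to_graph(), outdir / "ct_network.sif")
    log.info("[%s] compound-target network: %d nodes (%d compounds, %d targets), %d edges",
             profile_id, ct.n_nodes, len(ct.compounds), len(ct.targets), ct.n_edges)

    formulation_targets = set().union(*shared.target_map.values()) \
        if shared.target_map else set()
    net_form = netcore.neighborhood_network(formulation_targets, shared.ppi)
    net_dis = netcore.neighborhood_network(disease, shared.ppi)
    inter = netcore.intersect_networks(net_form, net_dis)
    netcore.write_sif(inter, outdir / "intersection.sif")
    log.info("[%s] intersection network: %d nodes, %d edges",
             profile_id, inter.number_of_nodes(), inter.number_of_edges())

    cascade_cfg = netcore.CascadeConfig(
        dc_abs=cfg.dc_abs, dc_factor=cfg.dc_factor,
        stage2_metrics=tuple(cfg.stage2_metrics),
    )
    cascade = netcore.run_cascade(inter, cascade_cfg)
    cascade.to_json(outdir / "cascade.json")
    for st in cascade.stages:
        log.info("[%s] cascade %s: %d nodes / %d edges",
                 profile_id, st["stage"], st["n_nodes"], st["n_edges"])

    records: list = []
    if cascade.final_nodes:
        records = enrich(set(cascade.final_nodes), shared.db)
        write_enrichment_csv(records, outdir / "enrichment.csv")

    n_sig = sum(1 for r in records if r.fdr < cfg.fdr_max)
    top_by_cat = {
        cat: [r.term_id for r in top_terms(
            [r for r in records if r.category == cat], k=cfg.top_k, fdr_max=cfg.fdr_max)]
        for cat in CATEGORIES
    }
    report = {
        "status": "ok",
        "deg": degs.summary(),
        "ct_network": {
            "n_compounds": len(ct.compounds),
            "n_targets": len(ct.targets),
            "n_nodes": ct.n_nodes,
            "n_edges": ct.n_edges,
            "top_compounds": [list(t) for t in ct.compound_degrees()[:5]],
        },
        "intersection": {
            "n_nodes": inter.number_of_nodes(),
            "n_edges": inter.number_of_edges(),
        },
        "cascade": {
            "stages": cascade.stages,
            "final_nodes": cascade.final_nodes,
            "empty_after_stage1": cascade.empty_after_stage1,
        },
        "enrichment": {
            "n_tested": len(records),
            "n_significant": n_sig,
            "top_terms": top_by_cat,
        },
    }
    return ProfileResult(
        profile_id=profile_id, deg_summary=degs.summary(), disease_genes=disease,
        ct=ct, cascade=cascade, records=records, report=report,
    )


# ---------------------------------------------------------------------------
# full run


def run_all(cfg: PipelineConfig) -> dict:
    """Run every profile then the cross-profile integration; returns the full
    report (also written to ``<outdir>/report.json``)."""
    cfg.validate(require_profiles=2)
    shared = load_shared(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    results: dict[str, ProfileResult] = {}
    failures: dict[str, str] = {}
    for spec in cfg.profiles:
        try:
            results[spec.profile_id] = run_profile(cfg, spec.profile_id, shared)
        except Exception as exc:  # stage failure: record, keep going
            log.error("profile %s failed: %s", spec.profile_id, exc)
            failures[spec.profile_id] = str(exc)

    integration = None
    recovery = None
    if not failures and len(results) >= 2:
        target_sets = {pid: set(r.ct.targets) for pid, r in results.items()}
        screened_sets = {pid: set(r.cascade.final_nodes) for pid, r in results.items()}
        venn_targets = imod.venn(target_sets)
        venn_screened = imod.venn(screened_sets)
        expansion = sorted(imod.at_least(target_sets, cfg.at_least_k))

        gp_nets = {}
        for pid, r in results.items():
            sig = [rec for rec in r.records if rec.fdr < cfg.fdr_max]
            if sig and r.cascade.final_nodes:
                net = imod.gene_pathway_network(sig, set(r.cascade.final_nodes))
                net.degree_csv(outdir / pid / "gene_pathway_degrees.csv")
                gp_nets[pid] = {
                    "n_genes": net.n_genes,
                    "n_terms": net.n_terms,
                    "core_genes": sorted(net.core_genes),
                }

        pathway_records = {
            pid: [rec for rec in r.records if rec.category == "PATHWAY"]
            for pid, r in results.items()
        }
        key_rows = imod.key_pathway_table(pathway_records, fdr_max=cfg.fdr_max)
        integration = {
            "venn_targets": {"counts": venn_targets.counts()},
            "venn_screened": {"counts": venn_screened.counts()},
            "at_least_2": expansion,
            "key_pathways": key_rows,
            "gene_pathway": gp_nets,
        }
        venn_targets.to_json(outdir / "venn_targets.json")
        venn_screened.to_json(outdir / "venn_screened.json")

        if cfg.manifest:
            manifest = SyntheticManifest.from_json(cfg.manifest)
            core = set(manifest.core_nodes)
            prec, rec_ = [], []
            for r in results.values():
                got = set(r.cascade.final_nodes)
                if got:
                    prec.append(len(got & core) / len(got))
                    rec_.append(len(got & core) / len(core))
                else:
                    prec.append(0.0)
                    rec_.append(0.0)
            planted = manifest.planted_terms.get("PATHWAY")
            recovery = {
                "core_precision": sum(prec) / len(prec),
                "core_recall": sum(rec_) / len(rec_),
                "planted_pathway_recovered": bool(
                    planted and any(row["term_id"] == planted for row in key_rows)
                ),
            }

    profile_reports: dict[str, dict | None] = {
        pid: results[pid].report if pid in results else {"status": "failed",
                                                         "error": failures[pid]}
        for pid in [p.profile_id for p in cfg.profiles]
    }
    report = imod.build_report(
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        profiles=profile_reports,
        compounds={
            "n_input": shared.n_input,
            "n_pass_adme": shared.n_pass_adme,
            "unique_compounds": shared.census.unique_compounds,
            "total_assignments": shared.census.total_assignments,
            "per_herb": dict(sorted(shared.census.per_herb.items())),
        },
        integration=integration,
        recovery=recovery,
    )
    if failures:
        report["failures"] = failures
    imod.write_report(report, outdir / "report.json")
    return report


def summarize_report(report: dict) -> str:
    """Human-readable digest of a run report."""
    lines = [f"config {report['config_hash']}  seed {report['seed']}"]
    comp = report.get("compounds", {})
    if "unique_compounds" in comp:
        lines.append(
            f"compounds: {comp['n_input']} raw rows -> {comp['n_pass_adme']} pass ADME "
            f"-> {comp['unique_compounds']} unique ({comp['total_assignments']} "
            "herb assignments)"
        )
    for pid, prof in report.get("profiles", {}).items():
        if prof.get("status") != "ok":
            lines.append(f"{pid}: {prof.get('status')}")
            continue
        deg = prof["deg"]
        casc = prof["cascade"]
        lines.append(
            f"{pid}: {deg['n_up']} up / {deg['n_down']} down DE genes; "
            f"CT net {prof['ct_network']['n_nodes']} nodes / "
            f"{prof['ct_network']['n_edges']} edges; "
            f"cascade -> {len(casc['final_nodes'])} targets; "
            f"{prof['enrichment']['n_significant']} enriched terms"
        )
    integ = report.get("integration", {})
    if "key_pathways" in integ:
        ids = [row["term_id"] for row in integ["key_pathways"]]
        lines.append(f"key pathways (all profiles): {', '.join(ids) if ids else 'none'}")
    rec = report.get("recovery", {})
    if "core_precision" in rec:
        lines.append(
            f"planted-core recovery: precision {rec['core_precision']:.3f}, "
            f"recall {rec['core_recall']:.3f}; planted pathway recovered: "
            f"{rec['planted_pathway_recovered']}"
        )
    return "\n".join(lines)
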