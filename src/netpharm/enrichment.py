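"""Hypergeometric over-representation analysis of flat gene-set annotations.

Annotations are flat GMT gene sets (no ontology-graph propagation) in four
categories: BP, CC, MF (ontology branches) and PATHWAY.  For a query of n
genes drawn from a universe of N, a term covering K universe genes with k
query hits is scored by the hypergeometric upper tail
P(X >= k), and terms are adjusted per category with Benjamini-Hochberg
step-up FDR.  Terms with no query hit are excluded before adjustment, so the
tested family is "terms with at least one hit"; this is logged.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

CATEGORIES = ("BP", "CC", "MF", "PATHWAY")
DEFAULT_CATEGORY = "PATHWAY"


class GmtError(ValueError):
    """Malformed GMT input."""


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"{self.term_id}: empty gene set")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.term_id}: unknown category {self.category!r}")


@dataclass
class EnrichmentRecord:
    """One tested term: hit counts, hypergeometric p, BH FDR, fold."""

    term_id: str
    term_name: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p: float
    fdr: float
    hit_genes: frozenset[str]

    @property
    def fold(self) -> float:
        return (self.k / self.n) / (self.K / self.N)


def parse_gmt(path: str | Path, default_category: str = DEFAULT_CATEGORY) -> list[GeneSet]:
    """Read GMT lines ``term_id <tab> description <tab> gene...``.

    A description of the form ``<CATEGORY>:<name>`` assigns the term to that
    category; anything else falls back to ``default_category``.  Genes are
    de-duplicated per term; lines without genes are skipped with a warning;
    duplicate term ids are an error.
    """
    out: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GmtError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
            term_id, desc = parts[0].strip(), parts[1].strip()
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            if not genes:
                log.warning("%s:%d: term %s has no genes; skipped", path, lineno, term_id)
                continue
            if term_id in seen:
                raise GmtError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            category, _, name = desc.partition(":")
            if category not in CATEGORIES:
                category, name = default_category, desc
            out.append(GeneSet(term_id=term_id, term_name=name or term_id,
                               category=category, genes=genes))
    return out


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.term_id}\t{gs.category}:{gs.term_name}\t{genes}\n")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: set[str],
    db: list[GeneSet],
    universe: set[str] | str = "auto",
) -> list[EnrichmentRecord]:
    """Score every term with >= 1 query hit; BH adjustment per category.

    ``universe="auto"`` uses the union of all database genes; query and
    terms are intersected with the universe first.  Records are sorted by p
    ascending, ties by fold descending then term id.
    """
    if universe == "auto":
        uni: set[str] = set()
        for gs in db:
            uni |= gs.genes
    else:
        uni = set(universe)
    q = set(query) & uni
    if not q:
        raise ValueError("query does not intersect the universe")
    N, n = len(uni), len(q)

    records: list[EnrichmentRecord] = []
    n_skipped = 0
    for gs in db:
        term_genes = gs.genes & uni
        hits = term_genes & q
        if not hits:
            n_skipped += 1
            continue
        k, K = len(hits), len(term_genes)
        records.append(
            EnrichmentRecord(
                term_id=gs.term_id,
                term_name=gs.term_name,
                category=gs.category,
                k=k, K=K, n=n, N=N,
                p=hypergeom_tail(k, K, n, N),
                fdr=np.nan,
                hit_genes=frozenset(hits),
            )
        )
    if n_skipped:
        log.info("%d terms without query hits excluded before BH", n_skipped)

    for cat in CATEGORIES:
        idx = [i for i, r in enumerate(records) if r.category == cat]
        if not idx:
            continue
        fdrs = bh_adjust([records[i].p for i in idx])
        for i, f in zip(idx, fdrs):
            records[i].fdr = float(f)

    records.sort(key=lambda r: (r.p, -r.fold, r.term_id))
    return records


def top_terms(
    records: list[EnrichmentRecord], k: int = 20, fdr_max: float = 0.05
) -> list[EnrichmentRecord]:
    """First k records with fdr strictly below fdr_max (records assumed
    sorted as produced by :func:`enrich`)."""
    sig = [r for r in records if r.fdr < fdr_max]
    return sig[:k]


def write_enrichment_csv(records: list[EnrichmentRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["term_id", "name", "category", "k", "K", "n", "N",
                    "p", "fdr", "fold", "hit_genes"])
        for r in records:
            w.writerow([r.term_id, r.term_name, r.category, r.k, r.K, r.n, r.N,
                        f"{r.p:.6g}", f"{r.fdr:.6g}", f"{r.fold:.6g}",
                        ";".join(sorted(r.hit_genes))])
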