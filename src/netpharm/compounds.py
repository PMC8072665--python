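"""ADME screening of herbal compound tables.

Candidate compounds of a multi-herb decoction are screened on two
pharmacokinetic covariates: oral bioavailability (OB, percent absorbed into
systemic circulation) and drug-likeness (DL, unitless similarity to known
drugs, in [0, 1]).  The conventional traditional-Chinese-medicine screening
rule retains compounds with OB >= 30% and DL >= 0.18.  Because several
compounds occur in more than one herb, the screened table is de-duplicated on
the compound identifier (herb assignments are merged) and a per-herb census is
kept so the assignment accounting (unique compounds vs. compound-herb
assignments) stays auditable.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

log = logging.getLogger(__name__)

#: logical field -> default column header of the shipped compound table
DEFAULT_DIALECT = {
    "id": "ID",
    "name": "Name",
    "ob": "OB",
    "dl": "DL",
    "herbs": "Medical plants",
}

#: default ADME thresholds (inclusive)
OB_MIN_DEFAULT = 30.0
DL_MIN_DEFAULT = 0.18


class CompoundTableError(ValueError):
    """Malformed compound table (missing column or unparseable row)."""


@dataclass(frozen=True)
class Compound:
    """One compound row: identifier, display name, OB (%), DL, herb codes."""

    compound_id: str
    name: str
    ob: float
    dl: float
    herbs: frozenset[str]

    def __post_init__(self) -> None:
        if self.ob < 0:
            raise ValueError(f"{self.compound_id}: OB must be >= 0, got {self.ob}")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"{self.compound_id}: DL must be in [0,1], got {self.dl}")
        if not self.herbs:
            raise ValueError(f"{self.compound_id}: herbs set must be non-empty")


@dataclass
class CompoundTable:
    """Ordered collection of :class:`Compound` rows with a provenance label."""

    rows: list[Compound] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def ids(self) -> list[str]:
        return [c.compound_id for c in self.rows]

    def to_csv(self, path: str | Path, herbs_sep: str = ",") -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["compound_id", "name", "ob", "dl", "herbs"])
            for c in self.rows:
                w.writerow(
                    [c.compound_id, c.name, c.ob, c.dl,
                     herbs_sep.join(sorted(c.herbs))]
                )


@dataclass
class HerbCensus:
    """Per-herb compound counts plus the global assignment accounting.

    ``total_assignments`` counts every (compound, herb) pair, so a compound
    shared by three herbs contributes three assignments but one unique
    compound; equality of the two holds iff every compound is single-herb.
    """

    per_herb: dict[str, int]
    total_assignments: int
    unique_compounds: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "per_herb": dict(sorted(self.per_herb.items())),
                "total_assignments": self.total_assignments,
                "unique_compounds": self.unique_compounds,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["herb", "n_compounds"])
            for herb in sorted(self.per_herb):
                w.writerow([herb, self.per_herb[herb]])


def _sniff_delimiter(path: Path) -> str:
    head = path.open().readline()
    return "\t" if "\t" in head else ","


def parse_compound_table(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    herbs_sep: str = ",",
    delimiter: str | None = None,
    provenance: str | None = None,
) -> CompoundTable:
    """Read a delimited compound table into a :class:`CompoundTable`.

    ``dialect`` maps the logical fields (id, name, ob, dl, herbs) onto the
    file's column headers; the herbs cell is split on ``herbs_sep``, herb
    codes upper-cased and trimmed.  Duplicate compound ids are preserved at
    this stage (see :func:`deduplicate`).
    """
    path = Path(path)
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    delim = delimiter or _sniff_delimiter(path)

    rows: list[Compound] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for logical, col in cols.items():
            if col not in header:
                raise CompoundTableError(
                    f"{path}: required column {col!r} (field {logical!r}) "
                    f"not found; header is {header}"
                )
        for lineno, rec in enumerate(reader, start=2):
            try:
                ob = float(rec[cols["ob"]])
                dl = float(rec[cols["dl"]])
            except (TypeError, ValueError) as exc:
                raise CompoundTableError(
                    f"{path}:{lineno}: non-numeric OB/DL "
                    f"({rec[cols['ob']]!r}, {rec[cols['dl']]!r})"
                ) from exc
            herbs = frozenset(
                h.strip().upper() for h in rec[cols["herbs"]].split(herbs_sep) if h.strip()
            )
            rows.append(
                Compound(
                    compound_id=rec[cols["id"]].strip(),
                    name=rec[cols["name"]].strip(),
                    ob=ob,
                    dl=dl,
                    herbs=herbs,
                )
            )
    return CompoundTable(rows=rows, provenance=provenance or str(path))


def load_packaged_compounds() -> CompoundTable:
    """Load the shipped candidate-compound table of Bushen Zhuangjin decoction
    (TCMSP screening at OB >= 30%, DL >= 0.18; 98 compounds across 9 herbs)."""
    ref = resources.files("netpharm.data").joinpath("bzd_compounds.tsv")
    with resources.as_file(ref) as p:
        return parse_compound_table(p, provenance="packaged:bzd_compounds.tsv")


def filter_adme(
    table: CompoundTable,
    ob_min: float = OB_MIN_DEFAULT,
    dl_min: float = DL_MIN_DEFAULT,
) -> CompoundTable:
    """Retain compounds with ob >= ob_min and dl >= dl_min (both inclusive)."""
    kept = [c for c in table.rows if c.ob >= ob_min and c.dl >= dl_min]
    return CompoundTable(rows=kept, provenance=table.provenance)


def deduplicate(table: CompoundTable) -> CompoundTable:
    """Merge rows sharing a compound_id: herb sets are unioned, OB/DL taken
    from the first occurrence (a conflicting later value is logged, not kept),
    row order follows first occurrence."""
    merged: dict[str, Compound] = {}
    for c in table.rows:
        if c.compound_id not in merged:
            merged[c.compound_id] = c
            continue
        first = merged[c.compound_id]
        if abs(first.ob - c.ob) > 1e-9 or abs(first.dl - c.dl) > 1e-9:
            log.warning(
                "compound %s: conflicting OB/DL on merge (%g/%g vs %g/%g); "
                "keeping first occurrence",
                c.compound_id, first.ob, first.dl, c.ob, c.dl,
            )
        merged[c.compound_id] = replace(first, herbs=first.herbs | c.herbs)
    return CompoundTable(rows=list(merged.values()), provenance=table.provenance)


def herb_census(table: CompoundTable) -> HerbCensus:
    """Count compounds per herb; a multi-herb compound counts once per herb."""
    per_herb: Counter[str] = Counter()
    for c in table.rows:
        per_herb.update(c.herbs)
    total = sum(len(c.herbs) for c in table.rows)
    return HerbCensus(
        per_herb=dict(per_herb),
        total_assignments=total,
        unique_compounds=len(table.rows),
    )
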