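"""Potential-germline-repertoire tables and cross-species comparisons.

A repertoire table tallies, per gene set or subgroup, the number of genes by
functionality with the number of alleles in parentheses — the standard
"potential germline repertoire" presentation.  Cells use the printed
dialect ``"2 F (3), 1 P"``: count, functionality label (single-letter O for
ORF; combined FO/FP/OP/FOP for genes whose alleles differ), optional allele
count defaulting to the gene count.  A small parser for that grammar lives
here so published tables can be loaded as fixtures and recomputed.

Comparison reports are set algebra over the row keys: sets missing from one
species, new sets, per-set count deltas, duplication flags (count at least
twice the reference — a reporting heuristic, configurable) and CDR-length
differences per subgroup.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .locus import LocusSequence

__all__ = [
    "CellEntry",
    "GeneRecord",
    "RepertoireTable",
    "ComparisonReport",
    "parse_cell",
    "render_cell",
    "build_repertoire_table",
    "compare_repertoires",
    "locus_statistics",
    "cdr_length_table",
    "load_table_fixture",
    "load_cdr_fixture",
    "fixture_path",
]

LABELS = ("F", "ORF", "P", "FO", "FP", "OP", "FOP")
_PRINTED = {"O": "ORF"}  # printed tables abbreviate ORF as O
_TO_PRINTED = {"ORF": "O"}

_CELL_RE = re.compile(r"^\s*(\d+)\s+(FOP|FO|FP|OP|O|F|P)\s*(?:\((\d+)\))?\s*$")


@dataclass(frozen=True)
class CellEntry:
    count: int
    label: str  # canonical: F, ORF, P, FO, FP, OP, FOP
    alleles: int


def parse_cell(text: str) -> list[CellEntry]:
    """Parse one printed repertoire cell, e.g. ``"2 F (3), 1 P"``; "-" is empty."""
    text = text.strip()
    if text in ("", "-"):
        return []
    entries = []
    for chunk in text.split(","):
        m = _CELL_RE.match(chunk)
        if not m:
            raise ValueError(f"unparseable repertoire cell {chunk!r}")
        count = int(m.group(1))
        label = _PRINTED.get(m.group(2), m.group(2))
        alleles = int(m.group(3)) if m.group(3) else count
        entries.append(CellEntry(count, label, alleles))
    return entries


def render_cell(entries: list[CellEntry]) -> str:
    if not entries:
        return "-"
    out = []
    for e in entries:
        s = f"{e.count} {_TO_PRINTED.get(e.label, e.label)}"
        if e.alleles != e.count:
            s += f" ({e.alleles})"
        out.append(s)
    return ", ".join(out)


@dataclass
class GeneRecord:
    """One gene as aggregated into repertoire tables."""

    name: str  # e.g. TRAJ29 or TRAV8-3
    prefix: str  # TRAV/TRDV/TRAJ/TRDD/TRDJ/TRAC/TRDC
    set_key: str  # set or subgroup row key, e.g. TRAJ29, TRAV8
    functionality: str  # combined label across alleles
    alleles: int = 1
    localized: bool = True


@dataclass
class RepertoireTable:
    prefix: str
    rows: dict[str, list[CellEntry]] = field(default_factory=dict)
    non_localized: int = 0

    def row_genes(self, key: str) -> int:
        return sum(e.count for e in self.rows.get(key, []))

    def row_alleles(self, key: str) -> int:
        return sum(e.alleles for e in self.rows.get(key, []))

    def totals_per_functionality(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for entries in self.rows.values():
            for e in entries:
                out[e.label] = out.get(e.label, 0) + e.count
        return out

    def grand_total(self) -> tuple[int, int]:
        genes = sum(self.row_genes(k) for k in self.rows)
        alleles = sum(self.row_alleles(k) for k in self.rows)
        return genes, alleles

    def sets(self) -> list[str]:
        return [k for k in self.rows if self.rows[k]]


def _set_sort_key(key: str) -> tuple:
    m = re.search(r"(\d+)$", key)
    return (key[: m.start()] if m else key, int(m.group(1)) if m else 0)


def build_repertoire_table(genes: list[GeneRecord], group_by: str = "set") -> RepertoireTable:
    """Aggregate annotated gene records into a repertoire table.

    Rows are keyed by the record set/subgroup key and sorted numerically;
    within a row, genes sharing a combined functionality label collapse
    into one cell entry with summed allele counts.
    """
    if not genes:
        return RepertoireTable(prefix="")
    prefixes = {g.prefix for g in genes}
    if len(prefixes) > 1:
        raise ValueError(f"records mix locus prefixes {prefixes}")
    acc: dict[str, dict[str, list[int]]] = {}
    non_localized = 0
    for g in genes:
        if g.functionality not in LABELS:
            raise ValueError(f"record {g.name} lacks a combined functionality label")
        slot = acc.setdefault(g.set_key, {}).setdefault(g.functionality, [0, 0])
        slot[0] += 1
        slot[1] += g.alleles
        if not g.localized:
            non_localized += 1
    rows = {}
    for key in sorted(acc, key=_set_sort_key):
        rows[key] = [
            CellEntry(c, label, a) for label, (c, a) in sorted(
                acc[key].items(), key=lambda kv: LABELS.index(kv[0])
            )
        ]
    return RepertoireTable(prefix=prefixes.pop(), rows=rows, non_localized=non_localized)


@dataclass
class ComparisonReport:
    missing_sets: list[str]
    new_sets: list[str]
    count_deltas: dict[str, tuple[int, int]]
    duplications: list[str]


def compare_repertoires(
    table_a: RepertoireTable, table_b: RepertoireTable, duplication_factor: int = 2
) -> ComparisonReport:
    """Set algebra over two repertoire tables of the same locus prefix.

    ``missing_sets`` are present in A and absent in B; ``new_sets`` the
    reverse; ``duplications`` flags shared sets where B holds at least
    ``duplication_factor`` times as many genes as A.
    """
    if table_a.prefix != table_b.prefix:
        raise ValueError(f"prefix mismatch: {table_a.prefix} vs {table_b.prefix}")
    sets_a, sets_b = set(table_a.sets()), set(table_b.sets())
    shared = sets_a & sets_b
    deltas = {k: (table_a.row_genes(k), table_b.row_genes(k)) for k in sorted(shared, key=_set_sort_key)}
    dup = [k for k, (a, b) in deltas.items() if b >= duplication_factor * a]
    return ComparisonReport(
        missing_sets=sorted(sets_a - sets_b, key=_set_sort_key),
        new_sets=sorted(sets_b - sets_a, key=_set_sort_key),
        count_deltas=deltas,
        duplications=dup,
    )


def locus_statistics(genes: list[GeneRecord], locus: LocusSequence | None = None) -> dict[str, str]:
    """Locus-overview record: per-type gene counts with non-localized noted.

    Counts render in the ``"39 (+16 non localized)"`` dialect; the locus
    contributes its chromosome, orientation and span.
    """
    out: dict[str, str] = {}
    if locus is not None:
        out["chromosome"] = f"{locus.chromosome} ({locus.orientation})"
        out["size_kb"] = str(locus.span_kb)
    prefixes = sorted({g.prefix for g in genes})
    for prefix in prefixes:
        loc = sum(1 for g in genes if g.prefix == prefix and g.localized)
        nl = sum(1 for g in genes if g.prefix == prefix and not g.localized)
        out[prefix] = f"{loc} (+{nl} non localized)" if nl else str(loc)
    return out


def parse_count_cell(text: str) -> tuple[int, int]:
    """Parse a locus-overview count like ``"277 (+16 non localized)"``."""
    m = re.match(r"^\s*(\d+)(?:\s*\(\+\s*(\d+)\s*non localized\))?\s*$", text)
    if not m:
        raise ValueError(f"unparseable count cell {text!r}")
    return int(m.group(1)), int(m.group(2) or 0)


# ---------------------------------------------------------------------------
# CDR-length comparison


def cdr_length_table(
    per_species: dict[str, dict[str, frozenset[str]]],
) -> dict[str, dict]:
    """Per-subgroup CDR-length triple sets by species, with difference flags.

    ``per_species`` maps species -> subgroup -> set of "[c1.c2.c3]" strings.
    A subgroup is flagged when the species that carry it disagree on the
    set of lengths.  Subgroups absent from a species are not counted as a
    difference.
    """
    subgroups = sorted({sg for d in per_species.values() for sg in d}, key=_set_sort_key)
    out = {}
    for sg in subgroups:
        present = {sp: d[sg] for sp, d in per_species.items() if sg in d and d[sg]}
        distinct = set(map(frozenset, present.values()))
        out[sg] = {"triples": present, "flagged": len(distinct) > 1}
    return out


# ---------------------------------------------------------------------------
# fixture loading


def fixture_path(name: str) -> Path:
    return Path(str(resources.files("trlocus").joinpath("data", name)))


def load_table_fixture(path: str | Path, species: str, prefix: str) -> RepertoireTable:
    """Load one species column of a published repertoire table (TSV fixture)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    if species not in df.columns:
        raise ValueError(f"species {species!r} not in fixture columns {list(df.columns)}")
    rows = {}
    for _, row in df.iterrows():
        rows[row.iloc[0]] = parse_cell(row[species])
    return RepertoireTable(prefix=prefix, rows=rows)


def load_cdr_fixture(path: str | Path) -> dict[str, dict[str, frozenset[str]]]:
    """Load a CDR-length table fixture: cells hold space-separated triples."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    key_col = df.columns[0]
    out: dict[str, dict[str, frozenset[str]]] = {sp: {} for sp in df.columns[1:]}
    for _, row in df.iterrows():
        for sp in df.columns[1:]:
            cell = row[sp].strip()
            if cell in ("", "-"):
                continue
            triples = frozenset(re.findall(r"\[\d+\.\d+\.\d+\]", cell))
            if triples:
                out[sp][row[key_col]] = triples
    return out
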