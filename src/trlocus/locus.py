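"""Locus-level sequence handling.

A T-cell receptor locus is analysed in its 5'->3' *locus frame*: the
transcription orientation of the majority of its genes.  Loci that sit in
reverse (REV) orientation on the chromosome are reverse-complemented once on
input and every downstream coordinate refers to the oriented sequence.
Chromosome (source) coordinates are kept for provenance only.

Coordinates are 1-based and inclusive throughout, matching the NCBI-style
spans of assembly accessions and the GFF3 convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LocusSequence",
    "LocusBounds",
    "Marker",
    "orient_locus",
    "span_kb",
    "delimit_locus",
    "count_assembly_gaps",
    "read_locus",
    "write_locus",
    "write_gff3",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def orient_locus(raw_sequence: str, complement: bool) -> str:
    """Place a raw chromosome slice in the 5'->3' locus frame.

    Returns the reverse complement when ``complement`` is true (REV locus),
    the identity otherwise.  Only upper-case A, C, G, T and N are accepted;
    the position of the first offending character is reported on rejection.
    """
    for i, base in enumerate(raw_sequence):
        if base not in _VALID:
            raise ValueError(f"non-IUPAC character {base!r} at position {i + 1}")
    if complement:
        return raw_sequence.translate(_COMPLEMENT)[::-1]
    return raw_sequence


def span_kb(start: int, end: int) -> int:
    """Span of a 1-based inclusive interval, rounded to the nearest kilobase."""
    if end < start:
        raise ValueError(f"end ({end}) < start ({start})")
    return int((end - start + 1) / 1000 + 0.5)


def count_assembly_gaps(sequence: str, min_run: int = 10) -> tuple[int, list[tuple[int, int]]]:
    """Maximal runs of N of length >= ``min_run``, as sorted disjoint 1-based intervals.

    The default run length distinguishes scaffold gaps from single ambiguous
    bases.
    """
    runs = [
        (m.start() + 1, m.end())
        for m in re.finditer("N+", sequence)
        if m.end() - m.start() >= min_run
    ]
    return len(runs), runs


@dataclass
class LocusSequence:
    """An oriented locus (or unplaced contig) with provenance coordinates."""

    locus_id: str
    species: str
    sequence: str
    chromosome: str = ""
    orientation: str = "FWD"  # orientation on the chromosome: FWD or REV
    assembly_accession: str = ""
    start: int | None = None  # 1-based inclusive, on the chromosome
    end: int | None = None
    complement: bool = False
    gap_runs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gap_runs:
            _, self.gap_runs = count_assembly_gaps(self.sequence)
        self.validate()

    def validate(self) -> None:
        if self.start is not None and self.end is not None:
            if self.end < self.start:
                raise ValueError("source end < start")
            if len(self.sequence) != self.end - self.start + 1:
                raise ValueError(
                    "sequence length does not match source coordinates: "
                    f"{len(self.sequence)} vs {self.end - self.start + 1}"
                )
        prev_end = 0
        for s, e in self.gap_runs:
            if s <= prev_end:
                raise ValueError("gap runs must be sorted and disjoint")
            if set(self.sequence[s - 1 : e]) != {"N"}:
                raise ValueError(f"gap run ({s},{e}) is not all N")
            prev_end = e

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def span_kb(self) -> int:
        if self.start is None or self.end is None:
            return span_kb(1, len(self.sequence))
        return span_kb(self.start, self.end)


@dataclass(frozen=True)
class Marker:
    """A flanking non-IG/TR coding gene used to delimit the locus."""

    gene_id: str
    interval: tuple[int, int]


@dataclass
class LocusBounds:
    borne5: Marker | None
    borne3: Marker | None
    first_gene: tuple[int, int]
    last_gene: tuple[int, int]
    distance5_kb: int | None
    distance3_kb: int | None


def _gap_kb(a_end: int, b_start: int) -> int:
    """kb between two intervals (end of the first to start of the second)."""
    if b_start - a_end <= 1:
        return 0
    return span_kb(a_end + 1, b_start - 1)


def delimit_locus(
    markers: list[tuple[str, tuple[int, int]]],
    gene_intervals: list[tuple[int, int]],
) -> LocusBounds:
    """Delimit the locus between the conserved flanking marker genes.

    The 5' bound is the marker nearest upstream of the first gene; the 3'
    bound the marker nearest downstream of the last gene.  A missing marker
    yields an explicit absent flag (``None``), as happens when the upstream
    marker falls outside the assembled region.
    """
    if not gene_intervals:
        raise ValueError("no gene intervals")
    genes = sorted(gene_intervals)
    first, last = genes[0], genes[-1]
    for gene_id, (ms, me) in markers:
        for gs, ge in genes:
            if ms <= ge and gs <= me:
                raise ValueError(f"marker {gene_id} overlaps gene interval ({gs},{ge})")
    upstream = [(gid, iv) for gid, iv in markers if iv[1] < first[0]]
    downstream = [(gid, iv) for gid, iv in markers if iv[0] > last[1]]
    borne5 = max(upstream, key=lambda m: m[1][1], default=None)
    borne3 = min(downstream, key=lambda m: m[1][0], default=None)
    return LocusBounds(
        borne5=Marker(*borne5) if borne5 else None,
        borne3=Marker(*borne3) if borne3 else None,
        first_gene=first,
        last_gene=last,
        distance5_kb=_gap_kb(borne5[1][1], first[0]) if borne5 else None,
        distance3_kb=_gap_kb(last[1], borne3[1][0]) if borne3 else None,
    )


# ---------------------------------------------------------------------------
# I/O


def read_locus(fasta_path: str | Path, meta_path: str | Path | None = None) -> LocusSequence:
    """Read a locus FASTA plus its YAML metadata sidecar.

    When the sidecar flags the source as ``complement: true`` the sequence on
    disk is assumed to be the raw chromosome slice and is oriented here.
    """
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    seq = str(record.seq).upper()
    meta: dict = {}
    if meta_path is not None:
        meta = yaml.safe_load(Path(meta_path).read_text()) or {}
    complement = bool(meta.get("complement", False))
    if meta.get("oriented", True) is False and complement:
        seq = orient_locus(seq, True)
    return LocusSequence(
        locus_id=meta.get("locus_id", record.id),
        species=meta.get("species", ""),
        sequence=seq,
        chromosome=str(meta.get("chromosome", "")),
        orientation="REV" if complement else meta.get("orientation", "FWD"),
        assembly_accession=meta.get("assembly_accession", ""),
        start=meta.get("start"),
        end=meta.get("end"),
        complement=complement,
    )


def write_locus(locus: LocusSequence, fasta_path: str | Path, meta_path: str | Path | None = None) -> None:
    record = SeqRecord(Seq(locus.sequence), id=locus.locus_id, description=locus.species)
    with open(fasta_path, "w") as handle:
        SeqIO.write([record], handle, "fasta")  # biopython wraps at 60 columns
    if meta_path is not None:
        meta = {
            "locus_id": locus.locus_id,
            "species": locus.species,
            "chromosome": locus.chromosome,
            "orientation": locus.orientation,
            "assembly_accession": locus.assembly_accession,
            "start": locus.start,
            "end": locus.end,
            "complement": locus.complement,
            "oriented": True,
        }
        Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def write_gff3(features: list[tuple], locus_id: str, path: str | Path) -> None:
    """Write annotation features as GFF3 (locus-frame, 1-based inclusive).

    ``features`` are tuples ``(type, start, end, strand, attributes_dict)``.
    """
    lines = ["##gff-version 3"]
    for ftype, start, end, strand, attrs in features:
        attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
        lines.append(
            "\t".join(
                [locus_id, "trlocus", ftype, str(start), str(end), ".", strand, ".", attr_s]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
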