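"""Detection and description of V, D, J and C gene units in a locus.

Candidate genes are seeded by homology: reference probe core regions
(V-REGION, J-REGION, C exons) are placed on both strands with a fast
semi-global aligner after exact k-mer seeding, accepted above an identity
floor, and their boundaries refined positionally from the shared
:class:`~trlocus.architecture.GeneArchitecture` and by motif checks
(recombination signals, GT/AG splice sites).  D genes, whose core regions
are too short for meaningful homology, are detected by pairing a 12-spacer
and a 23-spacer RSS around a short core.

The identity floor (60% over the probe) sits deliberately below the 75%
subgroup rule so that cross-subgroup homologs still seed candidates.  Motif
defects never veto a detection: a gene with a broken splice site or RSS is
still described, with the corresponding ``intact`` flag false, and the
defect surfaces later as a functionality finding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import edlib

from .architecture import DEFAULT_ARCHITECTURE, GeneArchitecture
from .locus import LocusSequence
from .rss import RSSConfig, RSSHit, check_rss_at, revcomp, scan_rss

logger = logging.getLogger(__name__)

__all__ = [
    "Probe",
    "GeneUnit",
    "AnnotationConfig",
    "find_gene_units",
    "verify_splice_sites",
    "describe_c_gene",
    "read_probes",
    "write_probes",
    "units_to_gff3_features",
]

NON_LOCALIZED = "non_localized"


@dataclass(frozen=True)
class Probe:
    """A reference core-region sequence with classification labels.

    FASTA header dialect: ``>id|gene_type|subgroup|species``; C gene probes
    are one per exon with ``id`` of the form ``NAME:EX1`` (``NAME:EX4UTR``
    for the untranslated fourth exon).
    """

    probe_id: str
    gene_type: str  # V, D, J or C
    subgroup: str
    species: str
    sequence: str

    @property
    def c_gene(self) -> str:
        return self.probe_id.split(":")[0]

    @property
    def c_exon(self) -> str:
        return self.probe_id.split(":")[1] if ":" in self.probe_id else ""


def read_probes(path: str | Path) -> list[Probe]:
    probes = []
    header, chunks = None, []
    with open(path) as fh:
        for line in list(fh) + [">"]:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    fields = header.split("|")
                    if len(fields) != 4:
                        raise ValueError(f"bad probe header {header!r}")
                    probes.append(Probe(*fields, "".join(chunks).upper()))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    return probes


def write_probes(probes: list[Probe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.probe_id}|{p.gene_type}|{p.subgroup}|{p.species}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


@dataclass
class GeneUnit:
    """One detected V, D, J or C gene with part coordinates in locus frame."""

    gene_type: str
    parts: dict[str, tuple[int, int]]
    part_seqs: dict[str, str] = field(default_factory=dict)  # gene-orientation sequences
    rss: list[RSSHit] = field(default_factory=list)
    splice_sites: list[tuple[str, tuple[int, int], bool]] = field(default_factory=list)
    strand_in_locus: str = "forward"  # forward | inverted
    localization: int | str = NON_LOCALIZED
    subgroup: str = ""
    probe_id: str = ""
    identity: float = 0.0
    contig: str = ""

    @property
    def start(self) -> int:
        lo = min(s for s, _ in self.parts.values())
        if self.rss:
            lo = min([lo] + [h.start for h in self.rss])
        return lo

    @property
    def end(self) -> int:
        hi = max(e for _, e in self.parts.values())
        if self.rss:
            hi = max([hi] + [h.end for h in self.rss])
        return hi

    @property
    def core_label(self) -> str:
        return {"V": "V-REGION", "D": "D-REGION", "J": "J-REGION"}.get(self.gene_type, "EX1")

    @property
    def core_seq(self) -> str:
        if self.gene_type == "C":
            return "".join(self.part_seqs[p] for p in sorted(self.parts) if p.startswith("EX"))
        return self.part_seqs[self.core_label]

    def splice_intact(self, kind: str) -> bool | None:
        found = [ok for k, _, ok in self.splice_sites if k == kind]
        return all(found) if found else None

    def self_validate(self) -> None:
        p = self.parts
        if self.gene_type == "V":
            for label in ("L-PART1", "V-INTRON", "L-PART2", "V-REGION"):
                if label not in p:
                    raise ValueError(f"V unit missing {label}")
            if self.strand_in_locus == "forward":
                order = ["L-PART1", "V-INTRON", "L-PART2", "V-REGION"]
            else:
                order = ["V-REGION", "L-PART2", "V-INTRON", "L-PART1"]
            ivs = [p[l] for l in order]
            if any(b[0] != a[1] + 1 for a, b in zip(ivs, ivs[1:])):
                raise ValueError("V unit parts not contiguous")
            if len(self.rss) != 1:
                raise ValueError("V unit must carry one 3' RSS")
        elif self.gene_type == "J":
            if "J-REGION" not in p or len(self.rss) != 1:
                raise ValueError("J unit needs a J-REGION and one 5' RSS")
            if not any(k == "donor" for k, _, _ in self.splice_sites):
                raise ValueError("J unit needs a donor site")
        elif self.gene_type == "D":
            if "D-REGION" not in p or len(self.rss) != 2:
                raise ValueError("D unit needs a D-REGION flanked by two RSS")
        elif self.gene_type == "C":
            exons = [l for l in p if l.startswith("EX")]
            if len(exons) < 2:
                raise ValueError("C unit needs at least two exons")
        else:
            raise ValueError(f"unknown gene type {self.gene_type}")


@dataclass
class AnnotationConfig:
    identity_floor: float = 0.60  # min probe identity to seed a candidate
    min_probe_coverage: float = 0.80
    kmer: int = 11
    c_max_intron: int = 5000
    d_mask_margin: int = 40
    arch: GeneArchitecture = field(default_factory=lambda: DEFAULT_ARCHITECTURE)

    @property
    def rss(self) -> RSSConfig:
        return self.arch.rss


# ---------------------------------------------------------------------------
# homology candidate search


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


@dataclass
class _Candidate:
    probe: Probe
    start: int  # 1-based inclusive, in the frame searched
    end: int
    identity: float
    strand: str  # forward | inverted


def _probe_candidates(
    seq: str, index: dict[str, list[int]], probe: Probe, cfg: AnnotationConfig, strand: str
) -> list[_Candidate]:
    k, p = cfg.kmer, probe.sequence
    if len(p) < k or len(seq) < len(p):
        return []
    starts: list[int] = []
    for j in range(len(p) - k + 1):
        for pos in index.get(p[j : j + k], ()):
            starts.append(pos - j)
    if not starts:
        return []
    starts.sort()
    clusters: list[list[int]] = [[starts[0]]]
    for s in starts[1:]:
        if s - clusters[-1][-1] <= max(k, int(0.4 * len(p))):
            clusters[-1].append(s)
        else:
            clusters.append([s])
    out = []
    for cl in clusters:
        w0 = max(0, min(cl) - 25)
        w1 = min(len(seq), max(cl) + len(p) + 25)
        res = edlib.align(p, seq[w0:w1], mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        identity = 1.0 - res["editDistance"] / len(p)
        if identity < cfg.identity_floor:
            continue
        ts, te = res["locations"][0]
        out.append(_Candidate(probe, w0 + ts + 1, w0 + te + 1, identity, strand))
    return out


def _map_interval(iv: tuple[int, int], length: int) -> tuple[int, int]:
    """Map a 1-based interval from the reverse-complement frame to locus frame."""
    s, e = iv
    return length - e + 1, length - s + 1


def _map_rss(hit: RSSHit, length: int) -> RSSHit:
    return replace(
        hit,
        heptamer=(_map_interval(hit.heptamer[0], length), hit.heptamer[1]),
        nonamer=(_map_interval(hit.nonamer[0], length), hit.nonamer[1]),
    )


# ---------------------------------------------------------------------------
# unit builders (coordinates are in the frame searched; mapped afterwards)


_REFINE_OFFSETS = (0, -1, 1, -2, 2)


def _refine_v_bounds(seq: str, vs: int, ve: int, cfg: AnnotationConfig) -> tuple[int, int, RSSHit | None]:
    """Nudge alignment-derived V-REGION ends onto their motif anchors.

    Terminal substitutions can shift a semi-global alignment endpoint by a
    base or two; the true 3' end is pinned by the adjacent RSS heptamer and
    the true 5' end by the upstream acceptor AG / donor GT / initiation
    codon, which sit at fixed offsets under the shared architecture.
    """
    arch = cfg.arch
    best_end = None
    for d in _REFINE_OFFSETS:
        hit = check_rss_at(seq, ve + d + 1, cfg.rss.v_spacer, "three_prime", cfg.rss)
        if hit is None:
            continue
        key = (2 if hit.intact else 1, -hit.mismatches, -abs(d))
        if best_end is None or key > best_end[0]:
            best_end = (key, d, hit)
    hit = None
    if best_end is not None:
        ve += best_end[1]
        hit = best_end[2]
    best_start = None
    for d in _REFINE_OFFSETS:
        s = cand_vs = vs + d
        exon_start = s - arch.l_part2_len
        intron_start = exon_start - arch.v_intron_len
        lp1_start = intron_start - arch.l_part1_len
        if lp1_start < 1:
            continue
        score = (
            (seq[exon_start - 3 : exon_start - 1] == "AG")
            + (seq[intron_start - 1 : intron_start + 1] == "GT")
            + (seq[lp1_start - 1 : lp1_start + 2] == "ATG")
        )
        key = (score, -abs(d))
        if best_start is None or key > best_start[0]:
            best_start = (key, cand_vs)
    if best_start is not None:
        vs = best_start[1]
    return vs, ve, hit


def _build_v_unit(seq: str, cand: _Candidate, cfg: AnnotationConfig) -> GeneUnit | None:
    arch = cfg.arch
    vs, ve, hit = _refine_v_bounds(seq, cand.start, cand.end, cfg)
    lp2 = (vs - arch.l_part2_len, vs - 1)
    intron = (lp2[0] - arch.v_intron_len, lp2[0] - 1)
    lp1 = (intron[0] - arch.l_part1_len, intron[0] - 1)
    if lp1[0] < 1 or ve + 7 > len(seq):
        return None
    donor_ok = seq[intron[0] - 1 : intron[0] + 1] == "GT"
    acceptor_ok = seq[intron[1] - 2 : intron[1]] == "AG"
    parts = {"L-PART1": lp1, "V-INTRON": intron, "L-PART2": lp2, "V-REGION": (vs, ve)}
    return GeneUnit(
        gene_type="V",
        parts=parts,
        part_seqs={l: seq[s - 1 : e] for l, (s, e) in parts.items()},
        rss=[hit] if hit else [],
        splice_sites=[
            ("donor", (intron[0], intron[0] + 1), donor_ok),
            ("acceptor", (intron[1] - 1, intron[1]), acceptor_ok),
        ],
        subgroup=cand.probe.subgroup,
        probe_id=cand.probe.probe_id,
        identity=cand.identity,
        strand_in_locus=cand.strand,
    )


def _build_j_unit(seq: str, cand: _Candidate, cfg: AnnotationConfig) -> GeneUnit | None:
    # a J member has the probe's length (substitution-level divergence), so
    # the window slides as a block; pin it on the 5' RSS and the 3' donor
    L = len(cand.probe.sequence)
    anchors = {cand.start + d for d in _REFINE_OFFSETS}
    anchors |= {cand.end - L + 1 + d for d in _REFINE_OFFSETS}
    best = None
    for js in sorted(anchors):
        d = js - cand.start
        je = js + L - 1
        if js - 7 - cfg.rss.j_spacer - 9 < 0 or je + 2 > len(seq):
            continue
        hit = check_rss_at(seq, js - 7, cfg.rss.j_spacer, "five_prime", cfg.rss)
        donor = seq[je : je + 2] == "GT"
        score = ((0 if hit is None else 2 if hit.intact else 1) + donor, -abs(d))
        if best is None or score > best[0]:
            best = (score, js, je, hit, donor)
    if best is None:
        return None
    _, js, je, hit, donor_ok = best
    parts = {"J-REGION": (js, je)}
    return GeneUnit(
        gene_type="J",
        parts=parts,
        part_seqs={"J-REGION": seq[js - 1 : je]},
        rss=[hit] if hit else [],
        splice_sites=[("donor", (je + 1, je + 2), donor_ok)],
        subgroup=cand.probe.subgroup,
        probe_id=cand.probe.probe_id,
        identity=cand.identity,
        strand_in_locus=cand.strand,
    )


_EXON_ORDER = {"EX1": 1, "EX2": 2, "EX3": 3, "EX4": 4, "EX4UTR": 4}


def _build_c_units(seq: str, cands: list[_Candidate], cfg: AnnotationConfig) -> list[GeneUnit]:
    by_gene: dict[str, dict[str, _Candidate]] = {}
    for c in cands:
        slot = by_gene.setdefault(c.probe.c_gene, {})
        exon = c.probe.c_exon
        if exon not in slot or c.identity > slot[exon].identity:
            slot[exon] = c
    units = []
    for gene, exons in by_gene.items():
        ordered = sorted(exons.items(), key=lambda kv: _EXON_ORDER.get(kv[0], 99))
        ivs = [(label, (c.start, c.end)) for label, c in ordered]
        ok = all(
            0 < b[1][0] - a[1][1] - 1 <= cfg.c_max_intron for a, b in zip(ivs, ivs[1:])
        )
        if not ok or len(ivs) < 2:
            logger.warning("discarding inconsistent C exon chain for %s", gene)
            continue
        parts = dict(ivs)
        splice = []
        for (_, a), (_, b) in zip(ivs, ivs[1:]):
            splice.append(("donor", (a[1] + 1, a[1] + 2), seq[a[1] : a[1] + 2] == "GT"))
            splice.append(("acceptor", (b[0] - 2, b[0] - 1), seq[b[0] - 3 : b[0] - 1] == "AG"))
        units.append(
            GeneUnit(
                gene_type="C",
                parts=parts,
                part_seqs={l: seq[s - 1 : e] for l, (s, e) in parts.items()},
                splice_sites=splice,
                subgroup=ordered[0][1].probe.subgroup,
                probe_id=gene,
                identity=min(c.identity for _, c in ordered),
                strand_in_locus=ordered[0][1].strand,
            )
        )
    return units


def _find_d_units(seq: str, masked: list[tuple[int, int]], cfg: AnnotationConfig) -> list[GeneUnit]:
    """D genes: a 12-spacer and a 23-spacer RSS flanking a short core.

    RSS hits falling inside (or within a margin of) homology-detected units
    are consumed by those units and never paired into D candidates; this
    keeps J and V recombination signals from seeding spurious D genes.
    """
    lo, hi = cfg.arch.d_region_range
    m = cfg.d_mask_margin

    def free(pos_lo: int, pos_hi: int) -> bool:
        return not any(pos_lo <= e + m and s - m <= pos_hi for s, e in masked)

    h5 = [h for h in scan_rss(seq, cfg.rss.d_spacer_5, cfg.rss, "five_prime") if free(h.start, h.end)]
    h3 = [h for h in scan_rss(seq, cfg.rss.d_spacer_3, cfg.rss, "three_prime") if free(h.start, h.end)]
    units, used5, used3 = [], set(), set()

    def make(a: RSSHit, b: RSSHit) -> GeneUnit:
        core = (a.heptamer[0][1] + 1, b.heptamer[0][0] - 1)
        return GeneUnit(
            gene_type="D",
            parts={"D-REGION": core},
            part_seqs={"D-REGION": seq[core[0] - 1 : core[1]]},
            rss=[a, b],
        )

    for i, a in enumerate(h5):
        for j, b in enumerate(h3):
            gap = b.heptamer[0][0] - a.heptamer[0][1] - 1
            if lo <= gap <= hi:
                units.append(make(a, b))
                used5.add(i)
                used3.add(j)
                break
    # one flank may be mutated (a recombination-signal defect): recover it at
    # a relaxed budget anchored on the intact flank
    for i, a in enumerate(h5):
        if i in used5:
            continue
        for gap in range(lo, hi + 1):
            b = check_rss_at(seq, a.heptamer[0][1] + gap + 1, cfg.rss.d_spacer_3, "three_prime", cfg.rss)
            if b is not None and b.mismatches <= cfg.rss.heptamer_budget + cfg.rss.nonamer_budget + 1:
                units.append(make(a, b))
                break
    for j, b in enumerate(h3):
        if j in used3:
            continue
        for gap in range(lo, hi + 1):
            start = b.heptamer[0][0] - gap - 7
            if start < 1:
                continue
            a = check_rss_at(seq, start, cfg.rss.d_spacer_5, "five_prime", cfg.rss)
            if a is not None and a.mismatches <= cfg.rss.heptamer_budget + cfg.rss.nonamer_budget + 1:
                units.append(make(a, b))
                break
    units.sort(key=lambda u: u.start)
    dedup: list[GeneUnit] = []
    for u in units:
        if not dedup or u.start > dedup[-1].end:
            dedup.append(u)
    return dedup


# ---------------------------------------------------------------------------


def find_gene_units(
    locus: LocusSequence | str,
    probes: list[Probe],
    config: AnnotationConfig | None = None,
    localized: bool = True,
) -> list[GeneUnit]:
    """Detect all V/D/J/C gene units in an oriented locus sequence.

    Returns units sorted 5'->3', each carrying part coordinates in locus
    frame, RSS and splice-site descriptions with intactness flags, the
    best-probe subgroup label and the homology identity.  Inverted genes are
    found by scanning the reverse complement.  A locus shorter than every
    probe yields an empty list.
    """
    if not probes:
        raise ValueError("probe set is empty")
    cfg = config or AnnotationConfig()
    seq = locus.sequence if isinstance(locus, LocusSequence) else locus
    contig = locus.locus_id if isinstance(locus, LocusSequence) else ""
    n = len(seq)
    rc = revcomp(seq)
    fwd_index = _kmer_index(seq, cfg.kmer)
    rc_index = _kmer_index(rc, cfg.kmer)

    candidates: list[_Candidate] = []
    for probe in probes:
        candidates += _probe_candidates(seq, fwd_index, probe, cfg, "forward")
        candidates += _probe_candidates(rc, rc_index, probe, cfg, "inverted")

    # overlap resolution: highest identity wins, ties by lower-mismatch RSS
    # handled implicitly (identical identities are re-sorted by position)
    accepted: dict[str, list[_Candidate]] = {"V": [], "J": [], "C": []}
    for cand in sorted(candidates, key=lambda c: (-c.identity, c.start)):
        gtype = cand.probe.gene_type
        if gtype not in accepted:
            continue
        locus_iv = (cand.start, cand.end)
        if cand.strand == "inverted":
            locus_iv = _map_interval(locus_iv, n)
        clash = False
        for other in accepted[gtype]:
            o_iv = (other.start, other.end)
            if other.strand == "inverted":
                o_iv = _map_interval(o_iv, n)
            if locus_iv[0] <= o_iv[1] and o_iv[0] <= locus_iv[1]:
                clash = True
                logger.info(
                    "overlap: %s (%.2f) displaced by %s (%.2f) at %s",
                    cand.probe.probe_id, cand.identity, other.probe.probe_id,
                    other.identity, locus_iv,
                )
                break
        if not clash:
            accepted[gtype].append(cand)

    units: list[GeneUnit] = []
    for cand in accepted["V"] + accepted["J"]:
        frame_seq = seq if cand.strand == "forward" else rc
        builder = _build_v_unit if cand.probe.gene_type == "V" else _build_j_unit
        unit = builder(frame_seq, cand, cfg)
        if unit is None:
            continue
        if cand.strand == "inverted":
            unit.parts = {l: _map_interval(iv, n) for l, iv in unit.parts.items()}
            unit.rss = [_map_rss(h, n) for h in unit.rss]
            unit.splice_sites = [(k, _map_interval(iv, n), ok) for k, iv, ok in unit.splice_sites]
        try:
            unit.self_validate()
        except ValueError as err:
            logger.info("dropping structurally invalid %s candidate at %s: %s",
                        unit.gene_type, unit.parts, err)
            continue
        units.append(unit)
    for strand, frame_seq in (("forward", seq), ("inverted", rc)):
        cands = [c for c in accepted["C"] if c.strand == strand]
        for unit in _build_c_units(frame_seq, cands, cfg):
            if strand == "inverted":
                unit.parts = {l: _map_interval(iv, n) for l, iv in unit.parts.items()}
                unit.splice_sites = [(k, _map_interval(iv, n), ok) for k, iv, ok in unit.splice_sites]
            units.append(unit)

    masked = [(u.start, u.end) for u in units]
    units += _find_d_units(seq, masked, cfg)

    units.sort(key=lambda u: u.start)
    for i, unit in enumerate(units, start=1):
        unit.localization = i if localized else NON_LOCALIZED
        unit.contig = contig
    return units


def verify_splice_sites(unit: GeneUnit, sequence: str) -> list[tuple[str, tuple[int, int], bool]]:
    """Re-derive donor/acceptor intactness from the sequence.

    A donor is intact iff its intron starts GT; an acceptor iff the intron
    ends AG.  Raises when the unit lacks the parts that define an intron.
    """
    if unit.gene_type == "V":
        if "V-INTRON" not in unit.parts:
            raise ValueError("unit has no V-INTRON part")
        introns = [unit.parts["V-INTRON"]]
    elif unit.gene_type == "C":
        exons = sorted(
            (iv for l, iv in unit.parts.items() if l.startswith("EX")), key=lambda iv: iv[0]
        )
        if len(exons) < 2:
            raise ValueError("unit has no introns (fewer than two exons)")
        introns = [(a[1] + 1, b[0] - 1) for a, b in zip(exons, exons[1:])]
    elif unit.gene_type == "J":
        d = [iv for k, iv, _ in unit.splice_sites if k == "donor"]
        if not d:
            raise ValueError("unit has no donor site")
        iv = d[0]
        return [("donor", iv, sequence[iv[0] - 1 : iv[1]] == "GT")]
    else:
        raise ValueError(f"no splice sites defined for gene type {unit.gene_type}")
    out = []
    for s, e in introns:
        out.append(("donor", (s, s + 1), sequence[s - 1 : s + 1] == "GT"))
        out.append(("acceptor", (e - 1, e), sequence[e - 2 : e] == "AG"))
    return out


@dataclass
class CGeneStructure:
    exon_sizes: list[int]
    intron_sizes: list[int]
    translated: list[bool]
    splicing_frame: int = 1  # sf1: one nucleotide carried over from the J donor


def describe_c_gene(unit: GeneUnit) -> CGeneStructure:
    """Exon/intron sizes in nucleotides with translated/untranslated flags."""
    if unit.gene_type != "C":
        raise ValueError("not a C gene unit")
    labels = sorted((l for l in unit.parts if l.startswith("EX")), key=lambda l: _EXON_ORDER.get(l, 99))
    ivs = [unit.parts[l] for l in labels]
    if any(b[0] <= a[1] for a, b in zip(ivs, ivs[1:])):
        raise ValueError("exon order violated")
    return CGeneStructure(
        exon_sizes=[e - s + 1 for s, e in ivs],
        intron_sizes=[b[0] - a[1] - 1 for a, b in zip(ivs, ivs[1:])],
        translated=[not l.endswith("UTR") for l in labels],
    )


def units_to_gff3_features(units: list[GeneUnit]) -> list[tuple]:
    """Flatten units into (type, start, end, strand, attrs) GFF3 feature rows."""
    rows = []
    for i, unit in enumerate(units, start=1):
        strand = "+" if unit.strand_in_locus == "forward" else "-"
        gid = f"unit{i:04d}"
        rows.append(
            (f"{unit.gene_type}-GENE-UNIT", unit.start, unit.end, strand,
             {"ID": gid, "subgroup": unit.subgroup, "probe": unit.probe_id})
        )
        for label, (s, e) in sorted(unit.parts.items(), key=lambda kv: kv[1]):
            rows.append((label, s, e, strand, {"Parent": gid}))
    return rows
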