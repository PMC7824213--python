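"""Synthetic TRA/TRD-style loci with known ground truth.

The generator emits loci with the structural properties the annotation
pipeline assumes — an ordered V cluster of subgroup families derived from
founders at controlled divergence, a nested D-J-C cluster, a J-C cluster
with optionally duplicated J cassettes, an inverted V gene downstream of
the first C gene, assembly gaps, and non-localized gene contigs — so every
downstream stage is testable with no external data.

Ground truth is exact: every gene carries its intended part coordinates,
functionality, subgroup and CDR lengths.  Genes built without injected
defects satisfy the functional-gene rules by construction: mutations during
family expansion are codon-aware (they never create a stop codon, nor a
cysteine or tryptophan inside a V-REGION, which keeps the numbering anchors
unambiguous) and never touch protected motifs (initiation codon, GT/AG
splice sites, recombination signals, anchor codons, the J F/W-G-X-G motif).

No attempt is made to imitate real nucleotide composition, codon usage or
empirically learned RSS profiles; the point is controlled recovery testing,
not realism of base content.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from Bio.Data.CodonTable import standard_dna_table

from .architecture import DEFAULT_ARCHITECTURE, GeneArchitecture
from .annotate import Probe
from .locus import LocusSequence
from .rss import revcomp

__all__ = [
    "SimConfig",
    "TruthRecord",
    "GeneInstance",
    "SimResult",
    "simulate_locus",
    "make_v_instance",
    "make_v_family",
    "inject_defect",
    "make_cdr2less_v",
    "DEFECT_KINDS",
]

FILLER_AA = "ADEFGHIKLMNPQRSTVY"  # no Cys/Trp: anchors stay unambiguous
_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _BY_AA.setdefault(_aa, []).append(_codon)
_STOPS = set(standard_dna_table.stop_codons)

DEFECT_KINDS = ("stop_codon", "frameshift", "splice_break", "rss_break", "conserved_aa_change")
_P_KINDS = {"stop_codon", "frameshift"}

_APPLICABLE = {
    "V": set(DEFECT_KINDS),
    "J": {"stop_codon", "splice_break", "rss_break"},
    "D": {"rss_break"},
    "C": {"stop_codon", "splice_break"},
}


def _translate_codon(codon: str) -> str:
    return standard_dna_table.forward_table.get(codon, "*" if codon in _STOPS else "X")


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _codon_for(rng: random.Random, aa: str) -> str:
    return rng.choice(_BY_AA[aa])


# ---------------------------------------------------------------------------
# configuration and records


@dataclass
class SimConfig:
    seed: int = 0
    n_subgroups: int = 8
    genes_per_subgroup: tuple[int, int] = (3, 6)
    founder_divergence: float = 0.40
    within_subgroup_divergence: float = 0.05
    defect_rates: dict[str, float] = field(default_factory=dict)
    n_trdv_subgroups: int = 1  # V-cluster subgroups of delta type
    include_inverted_v: bool = True  # inverted V downstream of the delta C gene
    d_genes: int = 6
    trdj_genes: int = 4
    j_block: tuple[int, int] = (10, 1)  # (n_sets, duplication_factor) for the alpha J block
    intergenic_length: tuple[int, int] = (700, 1500)
    gap_runs: int = 2
    gap_length: tuple[int, int] = (60, 200)
    n_nonlocalized: int = 0
    include_bornes: bool = True
    cdr1_range: tuple[int, int] = (4, 10)
    cdr2_range: tuple[int, int] = (2, 8)
    cdr3_range: tuple[int, int] = (2, 6)
    species: str = "synthetic"
    locus_id: str = "SYNLOC"
    arch: GeneArchitecture = field(default_factory=lambda: DEFAULT_ARCHITECTURE)

    def validate(self) -> None:
        for kind, p in self.defect_rates.items():
            if kind not in DEFECT_KINDS:
                raise ValueError(f"unknown defect kind {kind!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"defect rate for {kind} outside [0,1]")
        if not 0.0 <= self.within_subgroup_divergence < 0.25:
            raise ValueError("within-subgroup divergence must be in [0, 0.25)")
        if self.cdr1_range[1] > 12 or self.cdr2_range[1] > 10:
            raise ValueError("infeasible config: CDR length exceeds position capacity")
        if self.n_trdv_subgroups > self.n_subgroups:
            raise ValueError("more delta subgroups than subgroups")


@dataclass
class GeneInstance:
    """One gene unit in its own (gene) orientation, with relative layout."""

    gene_id: str
    gene_type: str
    seq: str
    parts: dict[str, tuple[int, int]]  # 1-based, relative to seq
    rss_layout: list[tuple[str, tuple[int, int], tuple[int, int]]]  # (side, hept, nona)
    protected: frozenset[int]
    subgroup: int | None = None
    cdr_lengths: tuple[int, int, int] | None = None
    functionality: str = "F"
    defect: str | None = None
    locus_tag: str = "TRA"


@dataclass
class TruthRecord:
    gene_id: str
    gene_type: str
    locus_tag: str
    contig: str
    strand: str  # forward | inverted
    parts: dict[str, tuple[int, int]]  # absolute, locus frame
    rss: list[tuple[str, tuple[int, int], tuple[int, int]]]
    intended_functionality: str
    intended_subgroup: int | None
    intended_cdr_lengths: tuple[int, int, int] | None
    defect: str | None
    localized: bool = True


@dataclass
class SimResult:
    locus: LocusSequence
    truth: list[TruthRecord]
    contigs: list[LocusSequence]
    probes: list[Probe]
    markers: list[tuple[str, tuple[int, int]]]
    config: SimConfig

    def __iter__(self):
        return iter((self.locus, self.truth))


# ---------------------------------------------------------------------------
# gene builders


def _make_rss(rng: random.Random, spacer: int, side: str, arch: GeneArchitecture):
    """An RSS segment with 0-1 mutations outside the critical heptamer bases."""
    cfg = arch.rss
    hept, nona = list(cfg.heptamer), list(cfg.nonamer)
    if rng.random() < 0.5:  # one heptamer mutation at positions 4-7
        i = rng.randrange(3, 7)
        hept[i] = rng.choice([b for b in "ACGT" if b != hept[i]])
    if rng.random() < 0.5:
        i = rng.randrange(9)
        nona[i] = rng.choice([b for b in "ACGT" if b != nona[i]])
    hept_s, nona_s, sp = "".join(hept), "".join(nona), _random_dna(rng, spacer)
    if side == "three_prime":
        seq = hept_s + sp + nona_s
        return seq, (1, 7), (8 + spacer, 16 + spacer)
    seq = revcomp(nona_s) + sp + revcomp(hept_s)
    return seq, (10 + spacer, 16 + spacer), (1, 9)


def _shift(iv: tuple[int, int], off: int) -> tuple[int, int]:
    return iv[0] + off, iv[1] + off


def make_v_instance(
    rng: random.Random,
    cdr_lengths: tuple[int, int, int],
    arch: GeneArchitecture | None = None,
    gene_id: str = "V",
    subgroup: int | None = None,
) -> GeneInstance:
    """A defect-free V gene unit: L-PART1, intron, L-PART2+V-REGION, 23-RSS."""
    arch = arch or DEFAULT_ARCHITECTURE
    c1, c2, c3 = cdr_lengths
    if not (0 <= c1 <= 12 and 0 <= c2 <= 10):
        raise ValueError("infeasible CDR lengths")
    leader = "ATG" + "".join(_codon_for(rng, rng.choice(FILLER_AA)) for _ in range(18))
    lp1, lp2 = leader[: arch.l_part1_len], leader[arch.l_part1_len :]
    intron = "GT" + _random_dna(rng, arch.v_intron_len - 4) + "AG"

    def filler(n: int) -> str:
        return "".join(rng.choice(FILLER_AA) for _ in range(n))

    protein = (
        filler(22) + "C" + filler(3)        # FR1, 1st-CYS at position 23
        + filler(c1)                        # CDR1
        + filler(2) + "W" + filler(14)      # FR2, conserved Trp at 41
        + filler(c2)                        # CDR2
        + filler(38) + "C"                  # FR3, 2nd-CYS at 104
        + filler(c3)                        # germline CDR3
    )
    v_nt = "".join(
        "TGT" if aa == "C" else "TGG" if aa == "W" else _codon_for(rng, aa) for aa in protein
    )
    rss_seq, hept, nona = _make_rss(rng, arch.rss.v_spacer, "three_prime", arch)

    il, l1, l2 = arch.v_intron_len, arch.l_part1_len, arch.l_part2_len
    parts = {
        "L-PART1": (1, l1),
        "V-INTRON": (l1 + 1, l1 + il),
        "L-PART2": (l1 + il + 1, l1 + il + l2),
        "V-REGION": (l1 + il + l2 + 1, l1 + il + l2 + len(v_nt)),
    }
    off = parts["V-REGION"][1]
    seq = lp1 + intron + lp2 + v_nt + rss_seq
    anchor_idx = (22, 26 + c1 + 2, 26 + c1 + 17 + c2 + 38)  # 0-based protein indices
    v0 = parts["V-REGION"][0]
    protected = set(range(1, 4))  # ATG
    protected |= {l1 + 1, l1 + 2, l1 + il - 1, l1 + il}  # donor GT, acceptor AG
    for idx in anchor_idx:
        protected |= set(range(v0 + 3 * idx, v0 + 3 * idx + 3))
    for iv in (hept, nona):
        protected |= set(range(off + iv[0], off + iv[1] + 1))
    return GeneInstance(
        gene_id=gene_id,
        gene_type="V",
        seq=seq,
        parts=parts,
        rss_layout=[("three_prime", _shift(hept, off), _shift(nona, off))],
        protected=frozenset(protected),
        subgroup=subgroup,
        cdr_lengths=(c1, c2, c3),
    )


def make_j_instance(
    rng: random.Random, arch: GeneArchitecture | None = None, gene_id: str = "J", subgroup: int | None = None
) -> GeneInstance:
    arch = arch or DEFAULT_ARCHITECTURE
    n_codons = (arch.j_region_len - 1) // 3
    codons = [_codon_for(rng, rng.choice(FILLER_AA)) for _ in range(n_codons)]
    m = arch.j_motif_codon
    codons[m] = rng.choice(_BY_AA[rng.choice("FW")])
    codons[m + 1] = rng.choice(_BY_AA["G"])
    codons[m + 3] = rng.choice(_BY_AA["G"])
    j_nt = "".join(codons) + rng.choice("ACGT")
    rss_seq, hept, nona = _make_rss(rng, arch.rss.j_spacer, "five_prime", arch)
    r = len(rss_seq)
    seq = rss_seq + j_nt + "GT"  # donor splicing the J to the C gene
    protected = set(range(hept[0], hept[1] + 1)) | set(range(nona[0], nona[1] + 1))
    protected |= {r + len(j_nt) + 1, r + len(j_nt) + 2}  # donor
    protected |= set(range(r + 3 * m + 1, r + 3 * (m + 4) + 1))  # F/W-G-X-G motif
    return GeneInstance(
        gene_id=gene_id,
        gene_type="J",
        seq=seq,
        parts={"J-REGION": (r + 1, r + len(j_nt))},
        rss_layout=[("five_prime", hept, nona)],
        protected=frozenset(protected),
        subgroup=subgroup,
    )


def make_d_instance(rng: random.Random, arch: GeneArchitecture | None = None, gene_id: str = "D") -> GeneInstance:
    arch = arch or DEFAULT_ARCHITECTURE
    core = _random_dna(rng, rng.randint(*arch.d_region_range))
    r5, h5, n5 = _make_rss(rng, arch.rss.d_spacer_5, "five_prime", arch)
    r3, h3, n3 = _make_rss(rng, arch.rss.d_spacer_3, "three_prime", arch)
    off3 = len(r5) + len(core)
    seq = r5 + core + r3
    protected = set()
    for iv in (h5, n5):
        protected |= set(range(iv[0], iv[1] + 1))
    for iv in (h3, n3):
        protected |= set(range(off3 + iv[0], off3 + iv[1] + 1))
    return GeneInstance(
        gene_id=gene_id,
        gene_type="D",
        seq=seq,
        parts={"D-REGION": (len(r5) + 1, len(r5) + len(core))},
        rss_layout=[("five_prime", h5, n5), ("three_prime", _shift(h3, off3), _shift(n3, off3))],
        protected=frozenset(protected),
        locus_tag="TRD",
    )


def make_c_instance(rng: random.Random, arch: GeneArchitecture | None = None, gene_id: str = "C") -> GeneInstance:
    """A C gene: GT/AG-bounded exons, last exon untranslated, terminal stop."""
    arch = arch or DEFAULT_ARCHITECTURE
    sizes, introns = arch.c_exon_sizes, arch.c_intron_sizes
    coding_len = sum(sizes[:-1]) - arch.c_carryover
    if coding_len % 3 != 0:
        raise ValueError("C exon sizes not compatible with the sf1 splicing frame")
    n_codons = coding_len // 3
    cds = _random_dna(rng, arch.c_carryover) + "".join(
        _codon_for(rng, rng.choice(FILLER_AA)) for _ in range(n_codons - 1)
    ) + "TAA"
    exons, pos = [], 0
    for size in sizes[:-1]:
        exons.append(cds[pos : pos + size])
        pos += size
    exons.append(_random_dna(rng, sizes[-1]))  # EX4UTR

    labels = [f"EX{i+1}" for i in range(len(sizes) - 1)] + ["EX4UTR"]
    seq_parts, parts, protected, cursor = [], {}, set(), 0
    for i, (label, exon) in enumerate(zip(labels, exons)):
        if i > 0:
            intron = "GT" + _random_dna(rng, introns[i - 1] - 4) + "AG"
            protected |= {cursor + 1, cursor + 2, cursor + len(intron) - 1, cursor + len(intron)}
            seq_parts.append(intron)
            cursor += len(intron)
        parts[label] = (cursor + 1, cursor + len(exon))
        seq_parts.append(exon)
        cursor += len(exon)
    # terminal stop codon of the constant-domain reading frame
    ex3_end = parts[labels[-2]][1]
    protected |= {ex3_end - 2, ex3_end - 1, ex3_end}
    return GeneInstance(
        gene_id=gene_id,
        gene_type="C",
        seq="".join(seq_parts),
        parts=parts,
        rss_layout=[],
        protected=frozenset(protected),
    )


# ---------------------------------------------------------------------------
# mutation machinery


def _coding_codons(inst: GeneInstance) -> dict[int, tuple[tuple[int, ...], str]]:
    """Map genomic position -> (codon positions, region kind) for coding parts."""
    if inst.gene_type == "V":
        order = ["L-PART1", "L-PART2", "V-REGION"]
        positions = [p for label in order for p in range(inst.parts[label][0], inst.parts[label][1] + 1)]
        v_lo, v_hi = inst.parts["V-REGION"]
        kind = lambda ps: "V" if any(v_lo <= q <= v_hi for q in ps) else "coding"
    elif inst.gene_type == "J":
        lo, hi = inst.parts["J-REGION"]
        positions = list(range(lo, hi + 1))
        kind = lambda ps: "coding"
    elif inst.gene_type == "C":
        exons = sorted((l for l in inst.parts if l.startswith("EX") and not l.endswith("UTR")))
        positions = [p for l in exons for p in range(inst.parts[l][0], inst.parts[l][1] + 1)]
        positions = positions[2:]  # sf1 carry-over completes an upstream codon
        kind = lambda ps: "coding"
    else:
        return {}
    out: dict[int, tuple[tuple[int, ...], str]] = {}
    for i in range(0, len(positions) - len(positions) % 3, 3):
        codon = tuple(positions[i : i + 3])
        for p in codon:
            out[p] = (codon, kind(codon))
    return out


def _mutate_seq(inst: GeneInstance, divergence: float, rng: random.Random) -> str:
    """Substitution-only mutation, skipping protected sites and unsafe codons."""
    seq = list(inst.seq)
    coding = _coding_codons(inst)
    for pos in range(1, len(seq) + 1):
        if pos in inst.protected or rng.random() >= divergence:
            continue
        old = seq[pos - 1]
        new = rng.choice([b for b in "ACGT" if b != old])
        entry = coding.get(pos)
        if entry is not None:
            codon_pos, kind = entry
            codon = "".join(new if q == pos else seq[q - 1] for q in codon_pos)
            aa = _translate_codon(codon)
            if aa == "*" or (kind == "V" and aa in "CW"):
                continue  # unsafe substitution: skip, do not retry
        seq[pos - 1] = new
    return "".join(seq)


def make_v_family(
    founder: GeneInstance, n: int, divergence: float, rng: random.Random
) -> list[GeneInstance]:
    """n members derived from a founder by ~divergence substitutions per site.

    Pairwise identity between members is >= 1 - 2*divergence in expectation;
    a divergence of 0.25 or more no longer guarantees subgroup integrity
    under the 75% rule and triggers a warning.
    """
    if divergence >= 0.25:
        import warnings

        warnings.warn("divergence >= 0.25: subgroup integrity no longer guaranteed")
    members = []
    for i in range(1, n + 1):
        members.append(
            replace(founder, gene_id=f"{founder.gene_id}.{i}", seq=_mutate_seq(founder, divergence, rng))
        )
    return members


# ---------------------------------------------------------------------------
# defect injection


def _edit(seq: str, pos: int, new: str) -> str:
    return seq[: pos - 1] + new + seq[pos - 1 + len(new) :]


def inject_defect(inst: GeneInstance, kind: str, rng: random.Random) -> GeneInstance:
    """Minimally mutate a defect-free gene so its functionality changes.

    Stop codons and frameshifts make a pseudogene (P); splice, RSS and
    conserved-amino-acid defects make an ORF.  The edit is 1-2 nt.
    """
    if kind not in DEFECT_KINDS:
        raise ValueError(f"unknown defect kind {kind!r}")
    if inst.defect is not None:
        raise ValueError(f"gene {inst.gene_id} already carries a defect")
    if kind not in _APPLICABLE[inst.gene_type]:
        raise ValueError(f"{kind} not applicable to a {inst.gene_type} gene")
    seq, parts, rss = inst.seq, dict(inst.parts), list(inst.rss_layout)

    if kind == "stop_codon":
        if inst.gene_type == "V":
            c1, c2, _ = inst.cdr_lengths
            idx = 26 + c1 + 17 + c2 + 5 + rng.randrange(20)  # inside FR3, before 2nd-CYS
            pos = parts["V-REGION"][0] + 3 * idx
        elif inst.gene_type == "J":
            pos = parts["J-REGION"][0] + 3 * (2 + rng.randrange(4))
        else:  # C: a mid-EX1 codon of the constant-domain frame
            pos = parts["EX1"][0] + 2 + 3 * (10 + rng.randrange(40))
        seq = _edit(seq, pos, "TAA")
    elif kind == "frameshift":
        c1, c2, _ = inst.cdr_lengths
        idx = 26 + c1 + 17 + c2 + 5 + rng.randrange(20)
        pos = parts["V-REGION"][0] + 3 * idx
        seq = seq[: pos - 1] + seq[pos:]  # single-nucleotide deletion
        lo, hi = parts["V-REGION"]
        parts["V-REGION"] = (lo, hi - 1)
        rss = [(side, (h[0] - 1, h[1] - 1), (n[0] - 1, n[1] - 1)) for side, h, n in rss]
    elif kind == "splice_break":
        if inst.gene_type == "V":
            pos = parts["V-INTRON"][0] + 1
        elif inst.gene_type == "J":
            pos = parts["J-REGION"][1] + 2
        else:
            pos = parts["EX1"][1] + 2
        seq = _edit(seq, pos, "C")  # donor GT -> GC
    elif kind == "rss_break":
        side, hept, _ = rss[rng.randrange(len(rss))] if inst.gene_type == "D" else rss[0]
        if side == "three_prime":
            seq = _edit(seq, hept[0], "A")  # heptamer CAC... -> AAC...
        else:
            seq = _edit(seq, hept[1], "T")  # top strand holds the complement
    elif kind == "conserved_aa_change":
        c1, c2, _ = inst.cdr_lengths
        idx = 26 + c1 + 17 + c2 + 38  # the 2nd-CYS
        pos = parts["V-REGION"][0] + 3 * idx
        seq = _edit(seq, pos, "CGG")  # Cys -> Arg

    return replace(
        inst,
        seq=seq,
        parts=parts,
        rss_layout=rss,
        defect=kind,
        functionality="P" if kind in _P_KINDS else "ORF",
    )


def make_cdr2less_v(inst: GeneInstance) -> GeneInstance:
    """Delete 9 codons spanning CDR2 and the adjacent framework, in frame.

    Reproduces the CDR2-less V variants seen in expanded delta-type
    subgroups: 27 nt covering all CDR2 codons plus the leading FR3 codons
    are removed; the reading frame and the numbering anchors stay intact.
    """
    if inst.gene_type != "V" or inst.cdr_lengths is None:
        raise ValueError("not a V gene instance")
    c1, c2, c3 = inst.cdr_lengths
    if c2 == 0:
        raise ValueError("CDR2 already absent")
    if c2 > 9:
        raise ValueError("CDR2 longer than the 9-codon deletion")
    lo, hi = inst.parts["V-REGION"]
    if (hi - lo + 1) % 3 != 0:
        raise ValueError("V-REGION not in frame")
    start_idx = 26 + c1 + 17  # first CDR2 codon (0-based protein index)
    pos = lo + 3 * start_idx
    seq = inst.seq[: pos - 1] + inst.seq[pos - 1 + 27 :]
    parts = dict(inst.parts)
    parts["V-REGION"] = (lo, hi - 27)
    rss = [(side, (h[0] - 27, h[1] - 27), (n[0] - 27, n[1] - 27)) for side, h, n in inst.rss_layout]
    return replace(inst, seq=seq, parts=parts, rss_layout=rss, cdr_lengths=(c1, 0, c3))


# ---------------------------------------------------------------------------
# locus assembly


def _maybe_inject(inst: GeneInstance, cfg: SimConfig, rng: random.Random) -> GeneInstance:
    for kind in DEFECT_KINDS:
        rate = cfg.defect_rates.get(kind, 0.0)
        if rate <= 0.0 or kind not in _APPLICABLE[inst.gene_type]:
            continue
        if rng.random() < rate:
            return inject_defect(inst, kind, rng)
    return inst


class _Assembler:
    def __init__(self, rng: random.Random, cfg: SimConfig):
        self.rng, self.cfg = rng, cfg
        self.chunks: list[str] = []
        self.cursor = 0
        self.truth: list[TruthRecord] = []
        self.gap_budget = cfg.gap_runs

    def emit(self, seq: str) -> int:
        self.chunks.append(seq)
        start = self.cursor + 1
        self.cursor += len(seq)
        return start

    def spacer(self, with_gap: bool = False) -> None:
        n = self.rng.randint(*self.cfg.intergenic_length)
        seg = _random_dna(self.rng, n)
        if with_gap and self.gap_budget > 0:
            g = self.rng.randint(*self.cfg.gap_length)
            mid = n // 2
            seg = seg[:mid] + "N" * g + seg[mid:]
            self.gap_budget -= 1
        self.emit(seg)

    def place(self, inst: GeneInstance, strand: str = "forward", with_gap: bool = False) -> None:
        self.spacer(with_gap)
        if strand == "forward":
            off = self.emit(inst.seq) - 1
            parts = {l: _shift(iv, off) for l, iv in inst.parts.items()}
            rss = [(s, _shift(h, off), _shift(n, off)) for s, h, n in inst.rss_layout]
        else:
            off = self.emit(revcomp(inst.seq)) - 1
            L = len(inst.seq)

            def mp(iv):
                return (off + L - iv[1] + 1, off + L - iv[0] + 1)

            parts = {l: mp(iv) for l, iv in inst.parts.items()}
            rss = [(s, mp(h), mp(n)) for s, h, n in inst.rss_layout]
        self.truth.append(
            TruthRecord(
                gene_id=inst.gene_id,
                gene_type=inst.gene_type,
                locus_tag=inst.locus_tag,
                contig=self.cfg.locus_id,
                strand=strand,
                parts=parts,
                rss=rss,
                intended_functionality=inst.functionality,
                intended_subgroup=inst.subgroup,
                intended_cdr_lengths=inst.cdr_lengths,
                defect=inst.defect,
            )
        )


def simulate_locus(config: SimConfig) -> SimResult:
    """Build a locus and its ground truth, deterministically for a seed."""
    config.validate()
    rng = random.Random(config.seed)
    arch = config.arch
    cfg = config

    def cdr(rng):
        return (rng.randint(*cfg.cdr1_range), rng.randint(*cfg.cdr2_range), rng.randint(*cfg.cdr3_range))

    # V-cluster subgroup founders are generated independently (their mutual
    # identity is background-level, far below the 75% rule); family members
    # derive from the founders at the configured within-subgroup divergence.
    delta_subgroups = set(range(cfg.n_subgroups - cfg.n_trdv_subgroups + 1, cfg.n_subgroups + 1))
    founders, members = [], []
    for sg in range(1, cfg.n_subgroups + 1):
        tag = "TRD" if sg in delta_subgroups else "TRA"
        founder = make_v_instance(rng, cdr(rng), arch, gene_id=f"V{sg:02d}", subgroup=sg)
        founder = replace(founder, locus_tag=tag)
        founders.append(founder)
        n = rng.randint(*cfg.genes_per_subgroup)
        members += make_v_family(founder, n, cfg.within_subgroup_divergence, rng)
    rng.shuffle(members)

    inv_founder = None
    if cfg.include_inverted_v:
        inv_founder = make_v_instance(
            rng, cdr(rng), arch, gene_id="VINV", subgroup=cfg.n_subgroups + 1
        )
        inv_founder = replace(inv_founder, locus_tag="TRD")

    d_units = [make_d_instance(rng, arch, gene_id=f"D{i}") for i in range(1, cfg.d_genes + 1)]
    trdj_founders = [make_j_instance(rng, arch, f"DJ{i}", subgroup=1000 + i) for i in range(1, cfg.trdj_genes + 1)]
    trdj_units = [
        replace(m, locus_tag="TRD")
        for f in trdj_founders
        for m in make_v_family(f, 1, cfg.within_subgroup_divergence, rng)
    ]
    n_sets, dup = cfg.j_block
    traj_founders = [make_j_instance(rng, arch, f"AJ{i}", subgroup=2000 + i) for i in range(1, n_sets + 1)]
    traj_units = []
    for copy in range(1, dup + 1):
        for f in traj_founders:  # tandem cassettes, each holding every set once
            (m,) = make_v_family(f, 1, cfg.within_subgroup_divergence, rng)
            traj_units.append(replace(m, gene_id=f"{f.gene_id}.{copy}"))
    trdc = replace(make_c_instance(rng, arch, "TRDC"), locus_tag="TRD")
    trac = make_c_instance(rng, arch, "TRAC")

    ordered: list[tuple[GeneInstance, str]] = [(m, "forward") for m in members]
    ordered += [(d, "forward") for d in d_units]
    ordered += [(j, "forward") for j in trdj_units]
    ordered += [(trdc, "forward")]
    if inv_founder is not None:
        ordered.append((inv_founder, "inverted"))
    ordered += [(j, "forward") for j in traj_units]
    ordered += [(trac, "forward")]
    ordered = [(_maybe_inject(inst, cfg, rng), strand) for inst, strand in ordered]

    gap_slots = set(rng.sample(range(len(ordered)), min(cfg.gap_runs, len(ordered))))
    asm = _Assembler(rng, cfg)
    markers: list[tuple[str, tuple[int, int]]] = []
    if cfg.include_bornes:
        start = asm.emit(_random_dna(rng, 2000))
        markers.append(("OR10G3", (start + 200, start + 1400)))
    for i, (inst, strand) in enumerate(ordered):
        asm.place(inst, strand, with_gap=i in gap_slots)
    asm.spacer()
    if cfg.include_bornes:
        start = asm.emit(_random_dna(rng, 2000))
        markers.append(("DAD1", (start + 400, start + 1700)))

    locus = LocusSequence(
        locus_id=cfg.locus_id, species=cfg.species, sequence="".join(asm.chunks)
    )
    truth = asm.truth

    contigs = []
    for i in range(1, cfg.n_nonlocalized + 1):
        founder = founders[(i - 1) % len(founders)]
        (inst,) = make_v_family(founder, 1, cfg.within_subgroup_divergence, rng)
        inst = replace(inst, gene_id=f"NL{i}")
        inst = _maybe_inject(inst, cfg, rng)
        ctg_id = f"{cfg.locus_id}_ctg{i}"
        flank5 = _random_dna(rng, 150)
        contigs.append(
            LocusSequence(locus_id=ctg_id, species=cfg.species, sequence=flank5 + inst.seq + _random_dna(rng, 150))
        )
        truth.append(
            TruthRecord(
                gene_id=inst.gene_id,
                gene_type="V",
                locus_tag=inst.locus_tag,
                contig=ctg_id,
                strand="forward",
                parts={l: _shift(iv, len(flank5)) for l, iv in inst.parts.items()},
                rss=[(s, _shift(h, len(flank5)), _shift(n, len(flank5))) for s, h, n in inst.rss_layout],
                intended_functionality=inst.functionality,
                intended_subgroup=inst.subgroup,
                intended_cdr_lengths=inst.cdr_lengths,
                defect=inst.defect,
                localized=False,
            )
        )

    def v_region(inst: GeneInstance) -> str:
        lo, hi = inst.parts["V-REGION"]
        return inst.seq[lo - 1 : hi]

    probes = [
        Probe(f.gene_id, "V", str(f.subgroup), cfg.species, v_region(f)) for f in founders
    ]
    if inv_founder is not None:
        probes.append(Probe("VINV", "V", str(inv_founder.subgroup), cfg.species, v_region(inv_founder)))
    for f in trdj_founders + traj_founders:
        lo, hi = f.parts["J-REGION"]
        probes.append(Probe(f.gene_id, "J", f.gene_id, cfg.species, f.seq[lo - 1 : hi]))
    for cg in (trdc, trac):
        for label, (lo, hi) in cg.parts.items():
            probes.append(Probe(f"{cg.gene_id}:{label}", "C", cg.gene_id, cfg.species, cg.seq[lo - 1 : hi]))

    return SimResult(locus, truth, contigs, probes, markers, cfg)
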