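"""IMGT unique numbering of translated V-REGIONs.

The unique numbering assigns every V-domain residue a fixed position so that
framework (FR-IMGT) and complementarity-determining regions (CDR-IMGT) are
delimited identically across genes and species:

========  ===========  =====
region    positions    width
========  ===========  =====
FR1-IMGT  1-26         26
CDR1-IMGT 27-38        12
FR2-IMGT  39-55        17
CDR2-IMGT 56-65        10
FR3-IMGT  66-104       39
========  ===========  =====

Germline CDR3-IMGT runs from position 105 to the final V-REGION codon.  The
scheme is anchored on three conserved residues: 1st-CYS at 23, CONSERVED-TRP
at 41 and 2nd-CYS at 104.  Sequences shorter than a region are gapped;
gaps inside the CDR loops are created from the loop apex outward in a fixed,
configurable order.

The engine here is anchor-first: it locates the 2nd-CYS as the last cysteine
within a bounded window from the C-terminus, the 1st-CYS 75-95 residues
upstream of it, and the conserved tryptophan 14-22 residues after the
1st-CYS.  This is deterministic and adequate for germline inputs; profile
HMMs are deliberately not used.  Genes whose anchors are themselves mutated
can instead be numbered by alignment transfer from a numbered subgroup
reference (:func:`transfer_numbering`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

__all__ = [
    "NumberingConfig",
    "NumberedVRegion",
    "number_v_region",
    "transfer_numbering",
    "cdr_length_triple",
    "SubgroupProfile",
    "build_subgroup_profile",
    "detect_region_deletion",
    "DeletionFinding",
    "REGIONS",
]

REGIONS: dict[str, tuple[int, int]] = {
    "FR1-IMGT": (1, 26),
    "CDR1-IMGT": (27, 38),
    "FR2-IMGT": (39, 55),
    "CDR2-IMGT": (56, 65),
    "FR3-IMGT": (66, 104),
}
ANCHORS = (23, 41, 89, 104)


@dataclass(frozen=True)
class NumberingConfig:
    min_length: int = 70
    max_cdr3: int = 20  # longest germline CDR3 searched for the 2nd-CYS
    # residue spacing between 1st-CYS and 2nd-CYS is 59 + |CDR1| + |CDR2|
    # (up to 81); the lower bound leaves room for the 9-codon CDR2 deletion
    cys104_window: tuple[int, int] = (48, 81)
    # Trp-41 sits 6 + |CDR1| residues after the 1st-CYS
    trp_window: tuple[int, int] = (6, 18)
    # gap orders: positions left empty first when a region is short
    cdr1_gap_order: tuple[int, ...] = (33, 34, 32, 35, 31, 36, 30, 37, 29, 38, 28, 27)
    cdr2_gap_order: tuple[int, ...] = (60, 61, 59, 62, 58, 63, 57, 64, 56, 65)
    fr1_gap_order: tuple[int, ...] = (10, 1, 2, 3, 4, 5, 6, 7, 8, 9)
    fr3_gap_order: tuple[int, ...] = (73, 84, 83, 82, 81)


DEFAULT_CONFIG = NumberingConfig()


@dataclass
class NumberedVRegion:
    """Per-position numbering of one translated V-REGION."""

    success: bool
    position_map: dict[int, str] = field(default_factory=dict)  # IMGT position -> residue
    cdr_lengths: tuple[int, int, int] | None = None
    reason: str = ""

    @property
    def anchors(self) -> dict[int, str | None]:
        return {p: self.position_map.get(p) for p in ANCHORS}

    @property
    def occupied(self) -> frozenset[int]:
        return frozenset(self.position_map)

    def region_residues(self, region: str) -> str:
        lo, hi = REGIONS[region]
        return "".join(self.position_map[p] for p in range(lo, hi + 1) if p in self.position_map)

    def gapped(self) -> str:
        """Dot-gapped display string through the end of germline CDR3."""
        last = max(self.position_map) if self.position_map else 104
        return "".join(self.position_map.get(p, ".") for p in range(1, last + 1))

    def triple_str(self) -> str:
        c1, c2, c3 = self.cdr_lengths
        return f"[{c1}.{c2}.{c3}]"


def _fill_region(positions: tuple[int, int], residues: str, gap_order: tuple[int, ...]) -> dict[int, str]:
    lo, hi = positions
    width = hi - lo + 1
    gaps = set(gap_order[: width - len(residues)])
    slots = [p for p in range(lo, hi + 1) if p not in gaps]
    return dict(zip(sorted(slots), residues))


def _find_anchor_frame(aa: str, cfg: NumberingConfig) -> tuple[int, int, int] | None:
    """0-based indices of (1st-CYS, Trp, 2nd-CYS), or None."""
    n = len(aa)
    for c2 in range(n - 1, -1, -1):
        if aa[c2] != "C" or n - 1 - c2 > cfg.max_cdr3:
            continue
        lo, hi = cfg.cys104_window
        for c1 in range(min(c2 - lo, 22), c2 - hi - 1, -1):
            # FR1 holds at most 26 positions: at most 22 residues precede 1st-CYS
            if c1 < 0 or aa[c1] != "C":
                continue
            for w in range(c1 + cfg.trp_window[0], min(c1 + cfg.trp_window[1], c2 - 15) + 1):
                if aa[w] != "W":
                    continue
                c1_len = w - c1 - 6  # CDR1 residues between FR1 end and FR2 start
                if not 0 <= c1_len <= 12:
                    continue
                return c1, w, c2
    return None


def number_v_region(aa_sequence: str, config: NumberingConfig | None = None) -> NumberedVRegion:
    """Apply the unique numbering to a translated, in-frame V-REGION.

    Returns a failure result (``success=False`` with a reason) rather than
    raising when the conserved anchors cannot be located or the sequence is
    shorter than the minimal V scaffold.
    """
    cfg = config or DEFAULT_CONFIG
    aa = aa_sequence.replace(".", "").replace("-", "")
    if len(aa) < cfg.min_length:
        return NumberedVRegion(False, reason=f"sequence too short ({len(aa)} aa)")
    if "*" in aa:
        return NumberedVRegion(False, reason="stop codon in translation")
    frame = _find_anchor_frame(aa, cfg)
    if frame is None:
        return NumberedVRegion(False, reason="conserved anchors not locatable")
    c1_idx, w_idx, c2_idx = frame

    pm: dict[int, str] = {}
    fr1 = aa[: c1_idx + 4]  # residues through position 26 (1st-CYS at 23)
    if len(fr1) > 26:
        return NumberedVRegion(False, reason="FR1 exceeds 26 positions")
    pm.update(_fill_region((1, 26), fr1, cfg.fr1_gap_order))
    cdr1 = aa[c1_idx + 4 : w_idx - 2]
    pm.update(_fill_region((27, 38), cdr1, cfg.cdr1_gap_order))
    pm.update(_fill_region((39, 55), aa[w_idx - 2 : w_idx + 15], ()))
    if c2_idx - 38 >= w_idx + 15:
        inter = aa[w_idx + 15 : c2_idx - 38]  # CDR2 residues when FR3 is complete
        if len(inter) > 10:
            return NumberedVRegion(False, reason=f"CDR2 too long ({len(inter)} aa)")
        pm.update(_fill_region((56, 65), inter, cfg.cdr2_gap_order))
        pm.update(_fill_region((66, 104), aa[c2_idx - 38 : c2_idx + 1], cfg.fr3_gap_order))
    else:
        # The span between Trp-41 and the 2nd-CYS is too short even for an
        # empty CDR2: the missing residues form one contiguous absent block
        # covering CDR2 and the leading FR3 positions, as produced by the
        # 9-codon CDR2-spanning deletion seen in expanded TRDV subgroups.
        span = aa[w_idx + 15 : c2_idx + 1]
        deficit = 49 - len(span)  # > 10 by construction of this branch
        absent = set(range(56, 66)) | set(range(66, 66 + deficit - 10))
        slots = [p for p in range(56, 105) if p not in absent]
        pm.update(dict(zip(slots, span)))
    cdr3 = aa[c2_idx + 1 :]
    pm.update({105 + i: r for i, r in enumerate(cdr3)})

    if pm.get(23) != "C" or pm.get(104) != "C" or pm.get(41) != "W":
        return NumberedVRegion(False, reason="anchor placement inconsistent")
    num = NumberedVRegion(True, pm)
    num.cdr_lengths = _triple(num)
    return num


def _triple(num: NumberedVRegion) -> tuple[int, int, int]:
    c1 = sum(1 for p in range(27, 39) if p in num.position_map)
    c2 = sum(1 for p in range(56, 66) if p in num.position_map)
    c3 = sum(1 for p in num.position_map if p >= 105)
    return (c1, c2, c3)


def cdr_length_triple(numbered: NumberedVRegion) -> tuple[int, int, int]:
    """[CDR1.CDR2.CDR3] lengths: non-gap counts per CDR region."""
    if not numbered.success:
        raise ValueError(f"numbering failed: {numbered.reason}")
    return _triple(numbered)


# ---------------------------------------------------------------------------
# Alignment transfer (for members whose own anchors are unusable)

_protein_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=2,
    mismatch_score=-1,
    open_gap_score=-6,
    extend_gap_score=-1,
)


def transfer_numbering(aa_sequence: str, reference: NumberedVRegion) -> NumberedVRegion:
    """Number a V-REGION by global alignment to a numbered subgroup reference.

    Residues aligned to a reference residue inherit its IMGT position;
    insertions relative to the reference cannot be placed and fail the
    transfer.  Anchors are *not* required to be intact, which is the point:
    this is how a gene with a mutated conserved residue is numbered so the
    change can be reported.
    """
    if not reference.success:
        raise ValueError("reference numbering failed")
    ref_positions = sorted(reference.position_map)
    ref_aa = "".join(reference.position_map[p] for p in ref_positions)
    aln = _protein_aligner.align(ref_aa, aa_sequence)[0]
    pm: dict[int, str] = {}
    for (rs, re_), (qs, qe) in zip(*aln.aligned):
        if re_ - rs != qe - qs:
            return NumberedVRegion(False, reason="transfer alignment block mismatch")
        for k in range(re_ - rs):
            pm[ref_positions[rs + k]] = aa_sequence[qs + k]
    if len(pm) != len(aa_sequence):
        return NumberedVRegion(False, reason="unplaceable insertion relative to reference")
    num = NumberedVRegion(True, pm)
    num.cdr_lengths = _triple(num)
    return num


# ---------------------------------------------------------------------------
# CDR2-spanning deletion detection

@dataclass
class DeletionFinding:
    positions: tuple[int, ...]  # absent IMGT positions forming the block
    covers_cdr2: bool
    in_frame: bool
    n_codons: int


@dataclass
class SubgroupProfile:
    """Per-position consensus occupancy of a V subgroup."""

    occupied: frozenset[int]
    reference: NumberedVRegion
    n_members: int


def build_subgroup_profile(members: list[NumberedVRegion], min_members: int = 3) -> SubgroupProfile:
    ok = [m for m in members if m.success]
    if len(ok) < min_members:
        raise ValueError(f"profile needs >= {min_members} numbered members, got {len(ok)}")
    counts: dict[int, int] = {}
    for m in ok:
        for p in m.occupied:
            counts[p] = counts.get(p, 0) + 1
    occupied = frozenset(p for p, c in counts.items() if c * 2 >= len(ok))
    reference = max(ok, key=lambda m: len(m.occupied))
    return SubgroupProfile(occupied, reference, len(ok))


def find_deletion_block_nt(
    member_nt: str,
    reference_nt: str,
    reference: NumberedVRegion,
    min_block: int = 20,
) -> DeletionFinding | None:
    """Locate a large deletion at the nucleotide level and map it to positions.

    For out-of-frame members (whose translation cannot be numbered) the
    member is globally aligned to a full-length reference V-REGION under an
    affine gap penalty (so the deletion stays one block); the longest run of
    reference bases absent from the member is mapped, via the reference
    numbering, to the IMGT positions of the codons it spans.  An
    out-of-frame run (or member) carries ``in_frame=False`` — such a gene is
    a pseudogene by the frameshift rule.
    """
    if not reference.success:
        raise ValueError("reference numbering failed")
    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-1,
        open_gap_score=-10, extend_gap_score=-0.5,
    )
    aln = aligner.align(reference_nt, member_nt)[0]
    ref_blocks, q_blocks = aln.aligned
    best: tuple[int, int] | None = None  # (ref offset, length) of longest deletion
    for i in range(len(ref_blocks) - 1):
        if q_blocks[i][1] == q_blocks[i + 1][0]:  # member does not advance
            off, length = ref_blocks[i][1], ref_blocks[i + 1][0] - ref_blocks[i][1]
            if best is None or length > best[1]:
                best = (off, length)
    if best is None or best[1] < min_block:
        return None
    off, length = best
    ref_positions = sorted(reference.position_map)
    codon_lo, codon_hi = off // 3, (off + length - 1) // 3
    positions = tuple(ref_positions[codon_lo : codon_hi + 1])
    cdr2 = {p for p in reference.position_map if 56 <= p <= 65}
    in_frame = bool(length % 3 == 0 and len(member_nt) % 3 == 0)
    return DeletionFinding(positions, cdr2 <= set(positions), in_frame, len(positions))


def detect_region_deletion(
    member: NumberedVRegion | str,
    profile: SubgroupProfile,
    nt_length: int | None = None,
    block: int = 9,
) -> DeletionFinding | None:
    """Report a member whose gap block spans CDR2 plus adjacent positions.

    ``member`` is a numbered V-REGION, or a raw amino-acid sequence that is
    then numbered by transfer from the profile reference.  A finding is a
    run of ``block`` consecutive profile positions absent from the member
    that covers every CDR2 position occupied in the profile.  The member is
    classified in-frame or out-of-frame from its nucleotide length when
    given (an out-of-frame deletion leaves the gene a pseudogene).
    """
    if isinstance(member, str):
        member = transfer_numbering(member, profile.reference)
    if not member.success:
        return None
    order = sorted(p for p in profile.occupied if p <= 104)
    absent = [p for p in order if p not in member.occupied]
    if not absent:
        return None
    runs: list[list[int]] = [[absent[0]]]
    for p in absent[1:]:
        if order.index(p) == order.index(runs[-1][-1]) + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    cdr2 = {p for p in profile.occupied if 56 <= p <= 65}
    for run in runs:
        if len(run) >= block and cdr2 <= set(run):
            in_frame = True if nt_length is None else nt_length % 3 == 0
            return DeletionFinding(tuple(run), True, in_frame, len(run))
    return None
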