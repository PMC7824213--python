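"""Shared structural conventions for TR gene units.

The locus simulator and the annotator read the same architecture so that
boundary refinement is convention-independent: part lengths that are fixed
here (leader exon, V intron, L-PART2) are used positionally by both sides,
while variable parts (V-REGION, D-REGION, intergenic spacers) are located by
homology or motif.

A V gene unit on the top strand is laid out as::

    L-PART1 .. V-INTRON .. L-PART2+V-REGION .. [23-RSS]

a J unit as ``[12-RSS] .. J-REGION .. donor GT``, a D unit as
``[12-RSS] .. D-REGION .. [23-RSS]`` and a C gene as GT/AG-bounded exons
EX1..EX4UTR, the fourth exon untranslated.  The splicing frame between J and
EX1 is sf1: one nucleotide of the first constant-domain codon is carried
over from the J donor, so EX1 translation starts at offset 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .rss import RSSConfig


@dataclass(frozen=True)
class GeneArchitecture:
    l_part1_len: int = 46  # leader exon; ends one nucleotide into a codon
    v_intron_len: int = 90
    l_part2_len: int = 11  # completes the leader to 19 codons with L-PART1
    j_region_len: int = 55  # 18 codons + 1 nt carried into the C gene (sf1)
    j_motif_codon: int = 9  # 0-based codon index of the F/W-G-X-G motif
    d_region_range: tuple[int, int] = (10, 16)
    c_exon_sizes: tuple[int, ...] = (273, 45, 110, 85)  # EX1..EX3 + EX4UTR
    c_intron_sizes: tuple[int, ...] = (220, 180, 260)
    c_carryover: int = 2  # nt of EX1 completing the sf1 codon
    rss: RSSConfig = field(default_factory=RSSConfig)

    @property
    def leader_len(self) -> int:
        return self.l_part1_len + self.l_part2_len


DEFAULT_ARCHITECTURE = GeneArchitecture()
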