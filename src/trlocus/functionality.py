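"""Functionality classification: functional (F), ORF, pseudogene (P).

The rule set is a strict precedence:

* **P** — the coding region carries stop codon(s) and/or frameshift
  mutation(s).  Any P-level evidence forces P regardless of other findings.
* **ORF** — the reading frame is open but the gene shows alterations in
  splicing sites, recombination signals, or changes of conserved amino
  acids.
* **F** — open reading frame and none of the above defects.

Regulatory-element defects also demote a gene to ORF in the curation
standard this follows, but no sequence model for them exists here; reports
carry a permanent warning to that effect.

A gene with several alleles of different functionalities gets a combined
label (FO, FP, OP, FOP).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .annotate import GeneUnit
from .numbering import NumberedVRegion

__all__ = [
    "FunctionalityCall",
    "call_functionality",
    "check_conserved_aa",
    "combine_alleles",
    "J_MOTIF",
    "REGULATORY_WARNING",
]

REGULATORY_WARNING = "regulatory elements not evaluated (no sequence model)"

# conserved anchors preserved by the unique numbering
CONSERVED_AA = {23: "C", 41: "W", 104: "C"}
J_MOTIF = re.compile(r"[FW]G.G")

_P_EVIDENCE = ("stop_codon", "frameshift")


@dataclass
class FunctionalityCall:
    label: str  # F | ORF | P
    evidence: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def check_conserved_aa(numbered: NumberedVRegion) -> list[str]:
    """Findings for changed conserved anchors (1st-CYS 23, Trp 41, 2nd-CYS 104)."""
    if not numbered.success:
        raise ValueError("numbering did not succeed")
    findings = []
    for pos, expected in CONSERVED_AA.items():
        got = numbered.position_map.get(pos)
        if got != expected:
            findings.append(f"conserved_aa_changed@{pos}")
    return findings


def _translate(nt: str) -> str:
    usable = nt[: len(nt) - len(nt) % 3]
    return str(Seq(usable).translate())


def _stop_evidence(aa: str, allow_terminal: bool = False) -> list[str]:
    stops = [i + 1 for i, r in enumerate(aa) if r == "*"]
    if allow_terminal and stops and stops[-1] == len(aa):
        stops = stops[:-1]
    return [f"stop_codon@{i}" for i in stops]


def _splice_evidence(unit: GeneUnit) -> list[str]:
    out = []
    for kind, _, intact in unit.splice_sites:
        if not intact:
            out.append(f"{kind}_broken")
    return out


def _rss_evidence(unit: GeneUnit, expected: int) -> list[str]:
    if len(unit.rss) < expected or any(h is None or not h.intact for h in unit.rss):
        return ["rss_broken"]
    return []


def call_functionality(unit: GeneUnit, numbering: NumberedVRegion | None = None) -> FunctionalityCall:
    """Classify one gene unit as F, ORF or P.

    Evidence is collected in a fixed order (frame, stop codons, splice
    sites, recombination signals, conserved amino acids) so calls are
    deterministic.  For V genes a numbering attempt should be supplied so
    conserved-anchor changes can be reported; a failed numbering simply
    skips that check.
    """
    evidence: list[str] = []
    if unit.gene_type == "V":
        try:
            coding = unit.part_seqs["L-PART1"] + unit.part_seqs["L-PART2"] + unit.part_seqs["V-REGION"]
        except KeyError as exc:
            # boundary failure: the coding region could not be extracted
            return FunctionalityCall(
                "P", ["frameshift@boundary"],
                warnings=[f"coding region unextractable ({exc})", REGULATORY_WARNING],
            )
        if len(coding) % 3 != 0:
            evidence.append("frameshift@V-REGION")
        evidence += _stop_evidence(_translate(coding))
        evidence += _splice_evidence(unit)
        evidence += _rss_evidence(unit, 1)
        if numbering is not None and numbering.success:
            evidence += check_conserved_aa(numbering)
    elif unit.gene_type == "J":
        aa = _translate(unit.part_seqs["J-REGION"])
        evidence += _stop_evidence(aa)
        evidence += _splice_evidence(unit)
        evidence += _rss_evidence(unit, 1)
        if not J_MOTIF.search(aa):
            evidence.append("j_motif_missing")
    elif unit.gene_type == "D":
        evidence += _rss_evidence(unit, 2)
    elif unit.gene_type == "C":
        exons = [l for l in sorted(unit.parts) if l.startswith("EX") and not l.endswith("UTR")]
        cds = "".join(unit.part_seqs[l] for l in exons)[2:]  # sf1: skip carried-over codon
        if len(cds) % 3 != 0:
            evidence.append("frameshift@CDS")
        evidence += _stop_evidence(_translate(cds), allow_terminal=True)
        evidence += _splice_evidence(unit)
    else:
        raise ValueError(f"unknown gene type {unit.gene_type}")

    if any(e.startswith(_P_EVIDENCE) for e in evidence):
        label = "P"
    elif evidence:
        label = "ORF"
    else:
        label = "F"
    return FunctionalityCall(label, evidence, warnings=[REGULATORY_WARNING])


_COMBINED = {
    frozenset({"F"}): "F",
    frozenset({"ORF"}): "ORF",
    frozenset({"P"}): "P",
    frozenset({"F", "ORF"}): "FO",
    frozenset({"F", "P"}): "FP",
    frozenset({"ORF", "P"}): "OP",
    frozenset({"F", "ORF", "P"}): "FOP",
}


def combine_alleles(calls: list[FunctionalityCall | str]) -> str:
    """Combined label across alleles of one gene (F, ORF, P, FO, FP, OP, FOP)."""
    if not calls:
        raise ValueError("no calls to combine")
    labels = frozenset(c.label if isinstance(c, FunctionalityCall) else c for c in calls)
    try:
        return _COMBINED[labels]
    except KeyError:
        raise ValueError(f"unknown label set {set(labels)}") from None
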