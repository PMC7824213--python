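"""Recovery metrics against simulated ground truth.

These helpers run the full pipeline on a simulated locus and score the
result against the generator's truth records: exact-boundary gene-unit
recovery (precision/recall/F1), functionality confusion, subgroup-partition
agreement and CDR-length-triple recovery.  They serve the test suite and
the reproduction script; they are never part of annotation itself.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import AnnotationConfig, GeneUnit, find_gene_units
from .classify import VGene, cluster_subgroups
from .functionality import FunctionalityCall, call_functionality
from .numbering import NumberedVRegion, number_v_region, transfer_numbering
from .simulate import SimResult, TruthRecord

__all__ = [
    "AnnotatedGene",
    "annotate_simulated",
    "unit_recovery",
    "functionality_confusion",
    "subgroup_partition_ok",
    "cdr_triple_recovery",
    "translate_in_frame",
]


def translate_in_frame(nt: str) -> str | None:
    """Codon-aligned translation, or None when the length breaks the frame."""
    if len(nt) % 3 != 0:
        return None
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


@dataclass
class AnnotatedGene:
    unit: GeneUnit
    call: FunctionalityCall
    numbering: NumberedVRegion | None
    truth: TruthRecord | None = None


def _truth_key(rec: TruthRecord) -> tuple:
    return (rec.contig, rec.gene_type, tuple(sorted(rec.parts.items())))


def _unit_key(unit: GeneUnit) -> tuple:
    return (unit.contig, unit.gene_type, tuple(sorted(unit.parts.items())))


def annotate_simulated(sim: SimResult, config: AnnotationConfig | None = None) -> list[AnnotatedGene]:
    """Run detection + numbering + functionality on a simulated locus.

    V genes are numbered de novo; when the anchors are unusable (for
    example a mutated 2nd-CYS) the numbering falls back to alignment
    transfer from the gene's best probe, so conserved-residue changes can
    still be reported.
    """
    cfg = config or AnnotationConfig()
    units = find_gene_units(sim.locus, sim.probes, cfg)
    for contig in sim.contigs:
        units += find_gene_units(contig, sim.probes, cfg, localized=False)

    probe_numbering: dict[str, NumberedVRegion] = {}
    for probe in sim.probes:
        if probe.gene_type == "V":
            aa = translate_in_frame(probe.sequence)
            if aa is not None:
                probe_numbering[probe.probe_id] = number_v_region(aa)

    by_truth = {_truth_key(t): t for t in sim.truth}
    out = []
    for unit in units:
        numbering = None
        if unit.gene_type == "V":
            aa = translate_in_frame(unit.part_seqs["V-REGION"])
            if aa is not None:
                numbering = number_v_region(aa)
                ref = probe_numbering.get(unit.probe_id)
                if not numbering.success and "*" not in aa and ref is not None and ref.success:
                    numbering = transfer_numbering(aa, ref)
        call = call_functionality(unit, numbering)
        out.append(AnnotatedGene(unit, call, numbering, by_truth.get(_unit_key(unit))))
    return out


def unit_recovery(annotated: list[AnnotatedGene], truth: list[TruthRecord]) -> dict[str, float]:
    """Exact-boundary precision, recall and F1 of gene-unit detection."""
    tp = sum(1 for a in annotated if a.truth is not None)
    fp = len(annotated) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall, "f1": f1}


def functionality_confusion(annotated: list[AnnotatedGene]) -> dict[tuple[str, str], int]:
    """(intended, called) label counts over truth-matched genes."""
    matrix: dict[tuple[str, str], int] = {}
    for a in annotated:
        if a.truth is None:
            continue
        key = (a.truth.intended_functionality, a.call.label)
        matrix[key] = matrix.get(key, 0) + 1
    return matrix


def subgroup_partition_ok(annotated: list[AnnotatedGene], threshold: float = 75.0) -> bool:
    """Does identity clustering reproduce the intended V subgroup partition?"""
    vgenes, intended = [], {}
    for a in annotated:
        if a.truth is None or a.truth.gene_type != "V":
            continue
        gid = a.truth.gene_id
        vgenes.append(VGene(gid, a.unit.core_seq, a.unit.parts["V-REGION"][0]))
        intended[gid] = a.truth.intended_subgroup
    clusters = cluster_subgroups(vgenes, threshold)
    got = {frozenset(g.gene_id for g in sg.members) for sg in clusters}
    want: dict[int, set[str]] = {}
    for gid, sg in intended.items():
        want.setdefault(sg, set()).add(gid)
    return got == {frozenset(v) for v in want.values()}


def cdr_triple_recovery(annotated: list[AnnotatedGene]) -> dict[str, int]:
    """How many in-frame, defect-free V genes yield their intended triple."""
    total = recovered = 0
    for a in annotated:
        t = a.truth
        if t is None or t.gene_type != "V" or t.intended_cdr_lengths is None:
            continue
        if t.defect is not None:
            continue
        total += 1
        if a.numbering is not None and a.numbering.success and a.numbering.cdr_lengths == t.intended_cdr_lengths:
            recovered += 1
    return {"total": total, "recovered": recovered}
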