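"""Subgroup clustering, nomenclature and allele calling for V genes.

Two V genes belong to the same subgroup when their V-REGION nucleotide
identity exceeds 75%.  Because the rule is pairwise and applied
transitively in practice, clustering is single-linkage: connected
components of the graph with an edge wherever identity > threshold.  The
threshold is strict — a tie at exactly 75.0% does not join.

Subgroup numbers are assigned against a reference repertoire (the human
genes, when comparing species): a cluster adopts the reference subgroup of
its best-identity representative when that identity clears the threshold,
otherwise it founds a new subgroup numbered after the largest reference
number.  Within a multi-gene subgroup, genes are distinguished by a hyphen
and a localization number increasing 5' to 3' in the locus; alleles of one
gene are distinguished by nucleotide differences in the core region and
numbered *01, *02, ... with *01 reserved for the reference-locus instance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

logger = logging.getLogger(__name__)

__all__ = [
    "VGene",
    "Subgroup",
    "GeneName",
    "pairwise_identity",
    "cluster_subgroups",
    "assign_subgroup_numbers",
    "assign_gene_names",
    "assign_alleles",
]


def _make_aligner(match: float = 1, mismatch: float = -1, gap: float = -2) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner

_aligner = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two core regions under global (end-to-end) alignment.

    Identity = matches / alignment columns x 100; gap columns count as
    non-matches.  Symmetric; 100 iff the sequences are equal.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    alignment = _aligner.align(a, b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


@dataclass
class VGene:
    """Minimal record clustering needs: an id, a core region, a position."""

    gene_id: str
    core: str
    position: int | None = None  # 5' start in locus frame; None if non-localized
    localized: bool = True


@dataclass
class Subgroup:
    members: list[VGene]
    subgroup_id: str | None = None
    reference_match: tuple[str, float] | None = None  # (reference subgroup, best identity %)

    @property
    def anchor_position(self) -> int:
        localized = [g.position for g in self.members if g.position is not None]
        return min(localized) if localized else 1 << 60


def cluster_subgroups(genes: list[VGene], threshold: float = 75.0) -> list[Subgroup]:
    """Single-linkage connected components of the >threshold identity graph.

    Components are ordered by their 5'-most member; within a component,
    members keep locus order (non-localized members last, in input order).
    The partition is invariant under permutation of the input.
    """
    n = len(genes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: (genes[i].gene_id,))
    for ai in range(n):
        for bi in range(ai + 1, n):
            i, j = order[ai], order[bi]
            if find(i) != find(j) and pairwise_identity(genes[i].core, genes[j].core) > threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[VGene]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(genes[i])
    subgroups = []
    for members in groups.values():
        loc = sorted((g for g in members if g.position is not None), key=lambda g: g.position)
        unloc = [g for g in members if g.position is None]
        subgroups.append(Subgroup(loc + unloc))
    subgroups.sort(key=lambda s: (s.anchor_position, s.members[0].gene_id))
    return subgroups


def assign_subgroup_numbers(
    clusters: list[Subgroup],
    reference: list[tuple[str, str]],
    threshold: float = 75.0,
) -> list[Subgroup]:
    """Label clusters with reference subgroup ids, founding new ones as needed.

    ``reference`` holds one ``(subgroup_id, representative core)`` per
    reference subgroup.  A cluster adopts the reference id of its
    best-identity representative when that identity clears the threshold.
    Two clusters claiming one reference id are resolved best-identity-wins;
    the loser founds a new subgroup.  New ids continue after the largest
    numeric reference id, ranked by the clusters' 5'-most members.
    """
    if not reference:
        raise ValueError("reference repertoire is empty")
    best: list[tuple[str, float] | None] = []
    for cluster in clusters:
        scored = [
            (rid, max(pairwise_identity(g.core, rep) for g in cluster.members))
            for rid, rep in reference
        ]
        rid, ident = max(scored, key=lambda t: t[1])
        cluster.reference_match = (rid, ident)
        best.append((rid, ident) if ident > threshold else None)

    claimed: dict[str, int] = {}
    for i, claim in enumerate(best):
        if claim is None:
            continue
        rid, ident = claim
        if rid not in claimed:
            claimed[rid] = i
        elif best[claimed[rid]][1] < ident:
            logger.info("subgroup %s reassigned: %s outscores previous claimant", rid, ident)
            best[claimed[rid]] = None
            claimed[rid] = i
        else:
            best[i] = None

    numeric = [int("".join(c for c in rid if c.isdigit()) or 0) for rid, _ in reference]
    next_id = max(numeric) + 1
    ordered = sorted(
        (i for i, claim in enumerate(best) if claim is None),
        key=lambda i: clusters[i].anchor_position,
    )
    for i, claim in enumerate(best):
        if claim is not None:
            clusters[i].subgroup_id = claim[0]
    for rank, i in enumerate(ordered):
        clusters[i].subgroup_id = str(next_id + rank)
    return clusters


@dataclass(frozen=True)
class GeneName:
    locus_prefix: str  # TRAV/TRDV/TRAJ/TRDD/TRDJ/TRAC/TRDC
    subgroup_number: str
    localization_number: int | None = None
    allele: int = 1

    def __str__(self) -> str:
        base = f"{self.locus_prefix}{self.subgroup_number}"
        if self.localization_number is not None:
            base += f"-{self.localization_number}"
        return f"{base}*{self.allele:02d}"

    @property
    def gene(self) -> str:
        return str(self).split("*")[0]


def assign_gene_names(subgroups: list[Subgroup], prefix: str = "TRAV") -> dict[str, GeneName]:
    """Name every member: PREFIX + subgroup, plus -n for multi-gene subgroups.

    Localization numbers 1..k follow increasing 5' position; a singleton
    subgroup carries no hyphenated number.  Non-localized members are
    numbered after the localized ones, in input order.
    """
    names: dict[str, GeneName] = {}
    for sg in subgroups:
        if sg.subgroup_id is None:
            raise ValueError("subgroup has no id; run assign_subgroup_numbers first")
        positions = [g.position for g in sg.members if g.position is not None]
        if len(positions) != len(set(positions)):
            raise ValueError(f"duplicate positions in subgroup {sg.subgroup_id}")
        multi = len(sg.members) >= 2
        for k, gene in enumerate(sg.members, start=1):
            names[gene.gene_id] = GeneName(prefix, sg.subgroup_id, k if multi else None)
    return names


def assign_alleles(instances: dict[str, list[tuple[str, str]]]) -> dict[str, int]:
    """Allele numbers per gene: identical core sequences share an allele.

    ``instances`` maps a gene name to ``(instance_id, core sequence)`` pairs,
    the reference-locus instance first; distinct sequences get *01, *02, ...
    in first-seen order.  Differences outside the core region do not
    separate alleles (the caller passes core regions only).
    """
    alleles: dict[str, int] = {}
    for gene, pairs in instances.items():
        seen: dict[str, int] = {}
        for instance_id, core in pairs:
            if core not in seen:
                seen[core] = len(seen) + 1
            alleles[instance_id] = seen[core]
    return alleles
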