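# Methods

This note documents the models, conventions and numerical choices behind
`trlocus`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate frame and locus delimitation

All coordinates are 1-based and inclusive, matching assembly-accession
spans and GFF3. A locus is analysed in its 5′→3′ *locus frame*: the
transcription orientation of the majority of its TR genes. Loci in reverse
(REV) chromosomal orientation are reverse-complemented once on input;
chromosome coordinates are retained for provenance only, and every
annotation downstream refers to the oriented sequence.

Kilobase spans round to the nearest integer (`round((end−start+1)/1000)`),
computed as `floor(x+0.5)` to avoid banker's rounding. Applied to the
bovine and sheep reference accession coordinates this yields 3331 and
2882 kb; truncation would give the same bovine value, so nearest-integer is
the convention that reproduces both printed spans.

The locus is delimited between conserved non-IG/TR marker genes ("bornes"):
the marker nearest upstream of the first gene and nearest downstream of the
last. A marker that is absent from the assembled region yields an explicit
absent flag rather than an error — this occurs in real assemblies (the
sheep locus lacks its upstream marker).

Assembly gaps are maximal runs of ≥ 10 N by default; the threshold
separates scaffold gaps from isolated ambiguous bases and is configurable.

## Gene-unit model and detection

The annotator and the simulator share one `GeneArchitecture` so that
positional conventions cannot drift apart:

* **V**: leader exon L-PART1 (46 nt, ending one nucleotide into a codon),
  V-INTRON (90 nt, GT..AG), L-PART2 (11 nt) contiguous with the V-REGION,
  then a 3′ 23-spacer RSS.
* **J**: 5′ 12-spacer RSS, J-REGION (55 nt = 18 codons + 1 nt carried into
  the C gene, splicing frame sf1), donor GT.
* **D**: 5′ 12-spacer and 3′ 23-spacer RSS around a 10–16 nt core.
* **C**: GT/AG-bounded exons (defaults 273/45/110 nt coding + 85 nt
  untranslated fourth exon, EX4UTR); EX1 translation starts at offset 2
  because one nucleotide of its first codon arrives from the J donor (sf1).

Spacer conventions follow the 12/23 rule; the source text this models does
not state per-type spacer lengths, so they live in the shared config and
tests are convention-independent.

Detection is homology-first: probe core regions (V-REGION, J-REGION,
C exons) are seeded by exact 11-mers on both strands, placed with edlib's
semi-global alignment, and accepted at ≥ 60 % identity over the probe.
The floor sits deliberately below the 75 % subgroup rule so cross-subgroup
homologs still seed candidates. Overlapping candidates are resolved
highest-identity-first, deterministically. Alignment endpoints can be off
by a base or two when a member's terminal bases are mutated, so boundaries
are then pinned to motifs: the V 3′ end to the adjacent RSS heptamer, the
V 5′ end to the acceptor-AG/donor-GT/ATG triplet of offsets, and the
J window (whose length equals the probe's) to its 5′ RSS and donor.

D cores are too short for a 60 % homology floor to mean anything, so D
genes are detected by pairing a 12- and a 23-spacer RSS hit around a short
core. RSS hits inside or within 40 nt of a homology-detected unit are
considered consumed by that unit; this prevents the genuine J and V
recombination signals from seeding spurious D genes. One flank of a D may
be recovered at a relaxed budget anchored on the other, intact flank, so a
D with a mutated recombination signal is still described.

RSS matching treats the first three heptamer bases (CAC) as critical —
no mismatch allowance at the default budget — with one mismatch allowed at
heptamer positions 4–7, two in the nonamer, and ±1 on the spacer, in line
with standard descriptions of RSS conservation. Motif defects never veto a
detection: a broken splice site or RSS is recorded as `intact=False` and
surfaces as a functionality finding.

Every emitted unit must pass its own structural invariant (a V needs its
four parts contiguous and one 3′ RSS; a J its RSS, region and donor; a D
two RSS; a C at least two exons); candidates that fail are dropped. This
is what keeps weak random homology hits out of the result.

## Subgroups, names, alleles

Two V genes share a subgroup when their V-REGION identity exceeds 75 %
under global end-to-end alignment (match +1, mismatch −1, gap −2; identity
= matches / alignment columns, gaps counting as non-matches). The rule is
pairwise, so clustering is single-linkage — connected components of the
> 75 % graph. The threshold is strict: a tie at exactly 75.0 does not
join. Single linkage also reproduces the curatorial practice of keeping
one subgroup when all pairwise identities exceed the threshold even if a
phylogeny splits it in two branches.

Clusters are numbered against a reference repertoire (one representative
per reference subgroup): best-identity match above the threshold adopts
the reference number; conflicts resolve best-identity-wins, the loser
founding a new subgroup; new subgroups continue after the largest
reference number, ranked by their 5′-most member. Within a multi-gene
subgroup, localization numbers 1..k increase 5′→3′; singletons carry no
hyphenated number; non-localized genes are numbered after localized ones.
Alleles are defined by nucleotide differences in the core region only and
numbered \*01, \*02, … in first-seen order with \*01 reserved for the
reference-locus instance (the ordering beyond \*01 is a package
convention; the curation standard does not state one).

## Functionality

Strict precedence: stop codons or frameshifts ⇒ **P**; otherwise any
broken splice site, broken/absent RSS, missing J F/W-G-X-G motif, or
changed conserved anchor (Cys-23, Trp-41, Cys-104) ⇒ **ORF**; otherwise
**F**. Frameshift is detected as assembled coding length ≢ 0 (mod 3).
A stop codon even at the last V-REGION position still yields P: germline
functionality is assessed before rearrangement, although such genes can
rearrange productively when the junction trims the stop. Regulatory
elements are part of the curation standard's ORF criteria but no sequence
model for them is given, so they are not evaluated; every call carries a
permanent warning to that effect. RSS and splice defects weigh equally
(the standard lists them flatly). Combined labels across alleles are the
set map {F}, {ORF}, {P}, {F,ORF}→FO, {F,P}→FP, {ORF,P}→OP, {F,ORF,P}→FOP.

## Unique numbering

Fixed region widths: FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65, FR3
66–104, germline CDR3 from 105 to the final V-REGION codon (a partial
codon before the heptamer is truncated). The engine is anchor-first, not
profile-based: the 2nd-CYS is the last cysteine within 20 residues of the
C-terminus; the 1st-CYS lies 48–81 residues upstream (the spacing is
59 + |CDR1| + |CDR2| for intact genes, less for deletion variants); the
conserved Trp 6–18 residues after the 1st-CYS. Gaps fill CDR loops from
the apex outward in a fixed, config-visible order (CDR1: 33, 34, 32, 35,
…; CDR2: 60, 61, 59, 62, …); small FR shortfalls use designated positions
(10 in FR1; 73, 81–84 in FR3). When the span between Trp-41 and the
2nd-CYS is too short even for an empty CDR2 — the 9-codon CDR2-spanning
deletion seen in expanded TRDV subgroups — the deficit is placed as one
contiguous absent block covering CDR2 and the leading FR3 positions,
which matches how such genes display (no CDR2, part of FR3 missing).

Genes whose anchors are themselves mutated cannot be numbered de novo;
the pipeline numbers them by global-alignment transfer from a numbered
subgroup reference, which is precisely what allows the changed anchor to
be reported as ORF evidence.

The deletion detector works on a subgroup occupancy profile built from at
least three numbered members (consensus = positions occupied in half or
more): a member absent over a run of 9 consecutive profile positions
covering all of CDR2 is flagged, in-frame or out-of-frame by nucleotide
length. Out-of-frame members, which cannot be translated and numbered,
are handled at the nucleotide level by affine-gap global alignment to a
reference member (an edit-distance alignment fragments a 26 nt gap into
pieces; the affine penalty keeps it one block).

## The synthetic locus generator

The generator emits the structures the analysis assumes: an ordered V
cluster of subgroup families, a nested D-J-C cluster, a J-C cluster with
optionally duplicated tandem J cassettes, one inverted V downstream of the
δ-type C gene, N-run assembly gaps inside intergenic spacers, and
non-localized single-gene contigs. Subgroup founders are generated
independently (their mutual identity is background-level, far below the
75 % rule); `make_v_family` additionally supports deriving founders from a
common base at a chosen divergence, which the tests use to place
cross-family identity just below threshold. Family members derive from
founders by per-site substitution at the configured divergence (default
0.05, giving ≥ 90 % expected pairwise identity within a family; 0.25 or
more voids the subgroup guarantee and warns). Mutations are codon-aware:
they never create a stop codon, nor a Cys or Trp inside a V-REGION (which
keeps the numbering anchors unambiguous), and never touch protected motifs
(ATG, GT/AG, RSS, anchor codons, the J motif). Defect-free genes therefore
satisfy the functional-gene rules by construction.

Defect injection is minimal (1–2 nt) and one kind per gene: an in-frame
TAA or a 1 nt deletion in FR3 (→ P), a donor GT→GC, a heptamer CAC
mutation, or 2nd-CYS→Arg (→ ORF). Intergenic spacers are uniform in
700–1500 nt — no biological claim attaches to that distribution, which is
unknown. Base composition, codon usage and RSS variability are not
modelled on data; consequently, passing recovery tests demonstrates the
pipeline's internal consistency on loci obeying its structural
assumptions, not its accuracy on real assemblies with degraded
pseudogenes, nested repeats or diverged leader exons.

Default problem sizes in the test suite and reproduction script — twenty
defect-free loci of roughly 100 genes (~200 kb) each for recovery, two
saturated loci per defect kind (≥ 50 injections per kind), ten engineered
families for the deletion detector — are chosen as the smallest sizes at
which every recovery statistic is measured on hundreds of events.

## Published-table fixtures

`trlocus/data/` transcribes the published human/bovine/sheep TRA/TRD
repertoire tables (gene sets and subgroups by functionality with allele
counts, CDR-length triples by subgroup, locus overview) plus the reference
locus coordinates. Cells use the printed dialect (`2 F (3), 1 P`; `O` for
ORF; `-` for an absent set), parsed by a small grammar in
`trlocus.report`. Totals rows are never transcribed — they are recomputed
from the row cells, and the tests assert they equal the printed totals.
Two transcription notes: the multi-length bovine CDR cells are assigned to
subgroups TRAV10/17/18/20/22/38 (the six subgroups the source text names
as multi-length, TRAV38 carrying three lengths); and the sheep TRAV total
row (293 genes) includes the 16 non-localized genes, consistent with the
per-species prose.

## Known limitations

* No ab initio gene discovery: a V or J gene with no probe above the
  homology floor is invisible (D genes being the RSS-detected exception).
* Leader/intron lengths are positional conventions shared with the
  generator; real loci vary them, and applying the annotator to real
  sequence would require per-gene donor/acceptor search instead.
* C-domain unique numbering and protein display are out of scope; C genes
  carry exon-structure records only.
* Phylogenetic tree construction is out of scope; clustering is
  threshold-based only.
* Regulatory elements are not modelled (see Functionality).
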