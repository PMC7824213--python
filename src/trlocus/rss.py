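"""Recombination signal sequence (RSS) detection.

An RSS is a conserved heptamer--spacer--nonamer motif flanking every
rearranging V, D and J gene; spacers of ~12 or ~23 nt pair under the 12/23
rule.  The heptamer always abuts the coding region, its consensus CACAGTG
read away from the gene, so on the top (locus) strand:

* a 3' RSS (downstream of a V or D region) reads
  ``CACAGTG .. spacer .. ACAAAAACC``;
* a 5' RSS (upstream of a J or D region) reads the reverse complement
  arrangement ``GGTTTTTGT .. spacer .. CACTGTG`` with the complemented
  heptamer adjacent to the gene.

The first three heptamer bases (CAC) are functionally critical and are not
given any mismatch allowance at the default budget; mismatches are tolerated
only at heptamer positions 4-7 and in the nonamer.  The simulator and the
detector share one :class:`RSSConfig` so tests are convention-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RSSConfig", "RSSHit", "scan_rss", "check_rss_at", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RSSConfig:
    heptamer: str = "CACAGTG"
    nonamer: str = "ACAAAAACC"
    v_spacer: int = 23  # V genes carry a 3' 23-spacer RSS
    j_spacer: int = 12  # J genes a 5' 12-spacer RSS
    d_spacer_5: int = 12  # D genes a 5' 12- and a 3' 23-spacer RSS
    d_spacer_3: int = 23
    heptamer_budget: int = 1  # mismatches allowed at heptamer positions 4-7
    nonamer_budget: int = 2
    spacer_tolerance: int = 1


@dataclass
class RSSHit:
    heptamer: tuple[tuple[int, int], str]  # (1-based inclusive interval, sequence)
    spacer_length: int
    nonamer: tuple[tuple[int, int], str]
    side: str  # five_prime | three_prime
    mismatches: int
    intact: bool

    @property
    def start(self) -> int:
        return min(self.heptamer[0][0], self.nonamer[0][0])

    @property
    def end(self) -> int:
        return max(self.heptamer[0][1], self.nonamer[0][1])


def _mismatch_profile(arr: np.ndarray, motif: str) -> np.ndarray:
    """mismatches[i] = Hamming distance of sequence[i:i+len(motif)] to motif."""
    n, m = len(arr), len(motif)
    if n < m:
        return np.empty(0, dtype=np.int32)
    out = np.zeros(n - m + 1, dtype=np.int32)
    motif_b = np.frombuffer(motif.encode(), dtype=np.uint8)
    for j in range(m):
        out += arr[j : n - m + 1 + j] != motif_b[j]
    return out


def _score_pair(hept: str, nona: str, cfg: RSSConfig, strict: bool) -> tuple[int, bool] | None:
    """Mismatch count and intact flag for a candidate heptamer/nonamer pair.

    Returns None when the pair fails even the relaxed detection budget
    (one extra mismatch everywhere, CAC included).
    """
    core = sum(a != b for a, b in zip(hept[:3], cfg.heptamer[:3]))
    tail = sum(a != b for a, b in zip(hept[3:], cfg.heptamer[3:]))
    nmis = sum(a != b for a, b in zip(nona, cfg.nonamer))
    intact = core == 0 and tail <= cfg.heptamer_budget and nmis <= cfg.nonamer_budget
    if strict and not intact:
        return None
    if core + tail > cfg.heptamer_budget + 1 or nmis > cfg.nonamer_budget + 1:
        return None
    return core + tail + nmis, intact


def scan_rss(
    sequence: str,
    spacer: int,
    cfg: RSSConfig | None = None,
    side: str = "three_prime",
) -> list[RSSHit]:
    """Report every heptamer/spacer/nonamer window within the mismatch budget.

    ``side`` selects the top-strand arrangement to scan for (see module
    docstring); hits are sorted by position and scored by total mismatches
    (lower is better).  The spacer may deviate by ``cfg.spacer_tolerance``.
    """
    cfg = cfg or RSSConfig()
    if side not in ("three_prime", "five_prime"):
        raise ValueError(f"unknown side {side!r}")
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    if side == "three_prime":
        left, right = cfg.heptamer, cfg.nonamer
        left_budget = 3 + cfg.heptamer_budget  # CAC handled exactly below
    else:
        left, right = revcomp(cfg.nonamer), revcomp(cfg.heptamer)
        left_budget = cfg.nonamer_budget
    mis_left = _mismatch_profile(arr, left)
    mis_right = _mismatch_profile(arr, right)
    hits: list[RSSHit] = []
    for sp in range(spacer - cfg.spacer_tolerance, spacer + cfg.spacer_tolerance + 1):
        offset = len(left) + sp
        n = min(len(mis_left), len(mis_right) - offset)
        if n <= 0:
            continue
        cand = np.nonzero((mis_left[:n] <= left_budget) & (mis_right[offset : offset + n] <= right_budget(cfg, side)))[0]
        for i in cand:
            i = int(i)
            left_seq = sequence[i : i + len(left)]
            right_seq = sequence[i + offset : i + offset + len(right)]
            if side == "three_prime":
                hept, nona = left_seq, right_seq
                hept_iv = (i + 1, i + len(left))
                nona_iv = (i + offset + 1, i + offset + len(right))
            else:
                hept, nona = revcomp(right_seq), revcomp(left_seq)
                hept_iv = (i + offset + 1, i + offset + len(right))
                nona_iv = (i + 1, i + len(left))
            scored = _score_pair(hept, nona, cfg, strict=True)
            if scored is None:
                continue
            mism, intact = scored
            hits.append(RSSHit((hept_iv, hept), sp, (nona_iv, nona), side, mism, intact))
    hits.sort(key=lambda h: (h.start, h.mismatches))
    # collapse duplicate windows that differ only in tolerated spacer slack:
    best: dict[tuple[int, int], RSSHit] = {}
    for h in hits:
        key = h.heptamer[0]
        if key not in best or h.mismatches < best[key].mismatches:
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.start, h.mismatches))


def right_budget(cfg: RSSConfig, side: str) -> int:
    return cfg.nonamer_budget if side == "three_prime" else 3 + cfg.heptamer_budget


def check_rss_at(
    sequence: str,
    heptamer_start: int,
    spacer: int,
    side: str,
    cfg: RSSConfig | None = None,
) -> RSSHit | None:
    """Examine the expected RSS location of a gene found by homology.

    Uses a relaxed budget (one extra mismatch, CAC included) so that a gene
    whose RSS is mutated is still described, with ``intact=False``; the
    strict budget decides intactness.  ``heptamer_start`` is 1-based.
    """
    cfg = cfg or RSSConfig()
    best: RSSHit | None = None
    for sp in range(spacer - cfg.spacer_tolerance, spacer + cfg.spacer_tolerance + 1):
        h0 = heptamer_start - 1
        if side == "three_prime":
            hept = sequence[h0 : h0 + 7]
            n0 = h0 + 7 + sp
            nona = sequence[n0 : n0 + 9]
            hept_iv, nona_iv = (h0 + 1, h0 + 7), (n0 + 1, n0 + 9)
        else:
            hept = revcomp(sequence[h0 : h0 + 7])
            n0 = h0 - sp - 9
            if n0 < 0:
                continue
            nona = revcomp(sequence[n0 : n0 + 9])
            hept_iv, nona_iv = (h0 + 1, h0 + 7), (n0 + 1, n0 + 9)
        if len(hept) < 7 or len(nona) < 9:
            continue
        scored = _score_pair(hept, nona, cfg, strict=False)
        if scored is None:
            continue
        mism, intact = scored
        hit = RSSHit((hept_iv, hept), sp, (nona_iv, nona), side, mism, intact)
        if best is None or (hit.intact, -hit.mismatches) > (best.intact, -best.mismatches):
            best = hit
    return best
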