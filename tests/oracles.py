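"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations — linear scans, exhaustive window
checks, textbook dynamic programming, BFS components — kept free of any
code path they are used to check.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_loop(seq: str) -> str:
    out = []
    for base in reversed(seq):
        out.append(_COMP[base])
    return "".join(out)


def count_n_runs_scan(seq: str, min_run: int) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, base in enumerate(seq):
        if base == "N":
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_run:
                runs.append((start + 1, i))
            start = None
    if start is not None and len(seq) - start >= min_run:
        runs.append((start + 1, len(seq)))
    return runs


def nw_score(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2) -> int:
    """Global alignment score by textbook Needleman-Wunsch."""
    prev = [j * gap for j in range(len(b) + 1)]
    for i in range(1, len(a) + 1):
        cur = [i * gap] + [0] * len(b)
        for j in range(1, len(b) + 1):
            sub = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            cur[j] = max(sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[len(b)]


def hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def rss_windows(seq: str, spacer: int, side: str, heptamer="CACAGTG", nonamer="ACAAAAACC",
                h_budget: int = 1, n_budget: int = 2, tol: int = 1) -> set[int]:
    """Heptamer start positions (1-based) of every valid window, exhaustively."""

    def mm(x, y):
        return sum(p != q for p, q in zip(x, y))

    hits = set()
    for sp in range(spacer - tol, spacer + tol + 1):
        for i in range(len(seq)):
            if side == "three_prime":
                hept = seq[i : i + 7]
                nona = seq[i + 7 + sp : i + 16 + sp]
            else:
                nona = revcomp_loop(seq[i : i + 9])
                hept = revcomp_loop(seq[i + 9 + sp : i + 16 + sp])
            if len(hept) < 7 or len(nona) < 9:
                continue
            if hept[:3] != heptamer[:3]:
                continue
            if mm(hept[3:], heptamer[3:]) <= h_budget and mm(nona, nonamer) <= n_budget:
                hits.add(i + 1 if side == "three_prime" else i + 9 + sp + 1)
    return hits


def components_bfs(ids: list[str], edge) -> set[frozenset[str]]:
    """Connected components of an arbitrary symmetric predicate, by BFS."""
    remaining = list(ids)
    comps = set()
    while remaining:
        seed = remaining.pop()
        comp, queue = {seed}, [seed]
        while queue:
            cur = queue.pop()
            for other in list(remaining):
                if edge(cur, other):
                    remaining.remove(other)
                    comp.add(other)
                    queue.append(other)
        comps.add(frozenset(comp))
    return comps


def table_totals_loop(rows: dict[str, str]) -> tuple[int, int]:
    """Re-sum printed repertoire cells with an independent parse."""
    import re

    genes = alleles = 0
    for cell in rows.values():
        cell = cell.strip()
        if cell in ("", "-"):
            continue
        for part in cell.split(","):
            m = re.match(r"\s*(\d+)\s+[A-Z]+\s*(?:\((\d+)\))?\s*$", part)
            assert m, part
            genes += int(m.group(1))
            alleles += int(m.group(2) or m.group(1))
    return genes, alleles
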