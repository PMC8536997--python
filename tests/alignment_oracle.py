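"""Independent brute-force global-alignment oracle for tests.

Recursively explores every monotone alignment path with an explicit
affine-gap state machine (first gapped position costs ``gap_open``, each
further one ``gap_extend``), memoizing optimal suffix scores, then
enumerates all co-optimal alignments and collects the substitution count
(number of mismatched residue columns) of each.  Deliberately independent
of the implementation under test.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def brute_force_align(
    a: str, b: str, gap_open: float = 12.0, gap_extend: float = 2.0
) -> tuple[float, set[int]]:
    """Return (optimal score, set of n_sap over all co-optimal alignments)."""

    def sub(x: str, y: str) -> float:
        return float(_BLOSUM62[x, y])

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        # state: previous column type, "M" (residue pair), "A" (gap in b),
        # "B" (gap in a); suffix score of aligning a[i:] with b[j:]
        if i == len(a) and j == len(b):
            return 0.0
        score = NEG
        if i < len(a) and j < len(b):
            score = max(score, sub(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "A" else gap_open
            score = max(score, -cost + best(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if state == "B" else gap_open
            score = max(score, -cost + best(i, j + 1, "B"))
        return score

    optimal = best(0, 0, "M")
    n_saps: set[int] = set()

    def walk(i: int, j: int, state: str, mismatches: int) -> None:
        if i == len(a) and j == len(b):
            n_saps.add(mismatches)
            return
        target = best(i, j, state)
        if i < len(a) and j < len(b):
            if abs(sub(a[i], b[j]) + best(i + 1, j + 1, "M") - target) < 1e-9:
                walk(i + 1, j + 1, "M", mismatches + (a[i] != b[j]))
        if i < len(a):
            cost = gap_extend if state == "A" else gap_open
            if abs(-cost + best(i + 1, j, "A") - target) < 1e-9:
                walk(i + 1, j, "A", mismatches)
        if j < len(b):
            cost = gap_extend if state == "B" else gap_open
            if abs(-cost + best(i, j + 1, "B") - target) < 1e-9:
                walk(i, j + 1, "B", mismatches)

    walk(0, 0, "M", 0)
    return optimal, n_saps
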