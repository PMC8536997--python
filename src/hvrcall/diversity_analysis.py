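"""Pairwise allele diversity: length difference plus substitution count.

For each unordered allele pair the index is ``delta_L + n_sap`` where
``delta_L`` is the absolute residue-length difference and ``n_sap`` the
number of aligned columns holding two differing residues under a global
(end-to-end) protein alignment.  Gapped columns never count toward
``n_sap``; the length difference is captured once, via ``delta_L``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scoring; defaults mirror a common interactive
    viewer's pairwise defaults (BLOSUM62, gap open 12, extend 2)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 12.0
    gap_extend: float = 2.0

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        # first gapped position costs `gap_open`, each further one `gap_extend`
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class PairDiversity:
    peptide_a: str
    peptide_b: str
    delta_l: int
    n_sap: int

    @property
    def total(self) -> int:
        return self.delta_l + self.n_sap


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    median: float
    min: float
    max: float


@dataclass(frozen=True)
class DiversitySummary:
    scope: str  # "global" or a sample id
    n_alleles: int
    n_pairs: int
    total_stats: SummaryStats | None
    delta_l_stats: SummaryStats | None

    @property
    def defined(self) -> bool:
        return self.total_stats is not None


def pair_count(n_alleles: int) -> int:
    """Number of unordered pairs among ``n_alleles`` sequences."""
    return n_alleles * (n_alleles - 1) // 2


def deduplicate(peptides: Iterable[str]) -> list[str]:
    """Exact-identity deduplication preserving first-seen order."""
    seen: dict[str, None] = {}
    for p in peptides:
        seen.setdefault(p)
    return list(seen)


def pair_diversity(
    a: str,
    b: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    _aligner: PairwiseAligner | None = None,
) -> PairDiversity:
    """Align two peptides globally and count substituted residue pairs."""
    if not a or not b:
        raise ValueError("empty peptide")
    aligner = _aligner if _aligner is not None else scoring.make_aligner()
    alignment = aligner.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    n_sap = sum(
        1 for x, y in zip(row_a, row_b) if x != "-" and y != "-" and x != y
    )
    return PairDiversity(a, b, abs(len(a) - len(b)), n_sap)


def _stats(values: Sequence[int]) -> SummaryStats:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        mean=float(arr.mean()),
        sd=sd,
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def all_pairs(
    peptides: Sequence[str], scoring: AlignmentScoring = DEFAULT_SCORING
) -> list[PairDiversity]:
    """PairDiversity for every unordered pair of (deduplicated) peptides."""
    unique = deduplicate(peptides)
    aligner = scoring.make_aligner()
    pairs = []
    for i in range(len(unique)):
        for j in range(i + 1, len(unique)):
            pairs.append(pair_diversity(unique[i], unique[j], scoring, _aligner=aligner))
    return pairs


def summarize(
    peptides: Sequence[str],
    per_sample_sets: Mapping[str, Iterable[str]] | None = None,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> tuple[list[DiversitySummary], list[PairDiversity]]:
    """Global and per-sample diversity summaries.

    Pairwise values are computed once over the global deduplicated set and
    reused for each sample's allele subset.  Scopes with fewer than two
    alleles yield an undefined summary (``n_pairs`` 0, stats ``None``).
    """
    unique = deduplicate(peptides)
    pairs = all_pairs(unique, scoring)
    by_pair = {frozenset((p.peptide_a, p.peptide_b)): p for p in pairs}

    def scope_summary(scope: str, members: Sequence[str]) -> DiversitySummary:
        members = deduplicate(members)
        n = len(members)
        if n < 2:
            return DiversitySummary(scope, n, 0, None, None)
        totals, deltas = [], []
        for i in range(n):
            for j in range(i + 1, n):
                p = by_pair[frozenset((members[i], members[j]))]
                totals.append(p.total)
                deltas.append(p.delta_l)
        return DiversitySummary(scope, n, pair_count(n), _stats(totals), _stats(deltas))

    summaries = [scope_summary("global", unique)]
    if per_sample_sets:
        for sample_id in sorted(per_sample_sets):
            summaries.append(scope_summary(sample_id, list(per_sample_sets[sample_id])))
    return summaries, pairs
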