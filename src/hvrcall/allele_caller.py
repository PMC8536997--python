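"""Allele-level quality control, abundance thresholding, novelty
classification and rarefaction.

A peptide becomes a validated allele when it carries both flank motifs,
contains no stop symbol and is either (a) seen in two or more samples at
any abundance, or (b) seen in a single sample at a within-sample relative
abundance strictly above a threshold.  The threshold defaults to a
data-derived statistic: the median, over all multi-sample peptides, of
each peptide's minimum within-sample relative abundance; a fixed fallback
is used when no peptide is shared between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .motif_model import FlankMotif
from .read_processor import ClusterTranslation

#: Fallback single-sample abundance threshold used when the data contain no
#: multi-sample peptide to derive it from.
FALLBACK_THRESHOLD = 0.0164

DEFAULT_REPLICATES = 100


@dataclass
class SampleAlleleTable:
    """Read counts per peptide within one sample."""

    sample_id: str
    counts: dict[str, int]

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def abundance(self, peptide: str) -> float:
        return self.counts[peptide] / self.total_reads

    @property
    def abundances(self) -> dict[str, float]:
        total = self.total_reads
        return {p: c / total for p, c in self.counts.items()}


@dataclass(frozen=True)
class HVRAllele:
    peptide: str
    samples_present: frozenset[str]
    is_novel: bool | None = None

    @property
    def length_residues(self) -> int:
        return len(self.peptide)

    @property
    def is_private(self) -> bool:
        return len(self.samples_present) == 1


@dataclass
class RarefactionCurve:
    sample_id: str
    percents: tuple[int, ...]
    mean_allele_counts: tuple[float, ...]
    replicates: int
    seed: int | None
    full_allele_count: int

    @property
    def plateau_percent(self) -> int | None:
        """Smallest percent at which the mean equals the full allele count."""
        for p, m in zip(self.percents, self.mean_allele_counts):
            if m == self.full_allele_count:
                return p
        return None


def tabulate(sample_id: str, translations: Iterable[ClusterTranslation]) -> SampleAlleleTable:
    """Sum cluster read counts per peptide (synonymous encodings merge)."""
    counts: dict[str, int] = {}
    for t in translations:
        if not t.accepted:
            continue
        counts[t.peptide] = counts.get(t.peptide, 0) + t.cluster.member_count
    if not counts:
        raise ValueError(f"sample {sample_id!r} has no translated clusters")
    return SampleAlleleTable(sample_id, counts)


def derive_threshold(
    tables: Sequence[SampleAlleleTable], fallback: float = FALLBACK_THRESHOLD
) -> float:
    """Median of the per-peptide minimum abundances over multi-sample peptides.

    Falls back to ``fallback`` when no peptide occurs in two or more
    samples.
    """
    if not tables:
        raise ValueError("no sample tables")
    presence: dict[str, list[float]] = {}
    for table in tables:
        for peptide, ab in table.abundances.items():
            presence.setdefault(peptide, []).append(ab)
    minima = [min(abs_) for abs_ in presence.values() if len(abs_) >= 2]
    if not minima:
        return fallback
    return float(median(minima))


def apply_qc(
    tables: Sequence[SampleAlleleTable],
    threshold: float,
    motif5: FlankMotif | None = None,
    motif3: FlankMotif | None = None,
) -> list[HVRAllele]:
    """Apply the allele-retention criteria and emit allele records.

    Retained iff the peptide carries both flank motifs and no stop symbol
    (guaranteed upstream when motifs are not supplied), and is present in
    >=2 samples (any abundance) or in exactly one sample at abundance
    strictly greater than ``threshold``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    occurrence: dict[str, dict[str, float]] = {}
    for table in tables:
        for peptide, ab in table.abundances.items():
            occurrence.setdefault(peptide, {})[table.sample_id] = ab

    alleles: list[HVRAllele] = []
    for peptide, by_sample in occurrence.items():
        if "*" in peptide:
            continue
        if motif5 is not None and not motif5.admits(peptide[: motif5.width]):
            continue
        if motif3 is not None and not motif3.admits(peptide[-motif3.width :]):
            continue
        if len(by_sample) >= 2:
            retained = True
        else:
            retained = next(iter(by_sample.values())) > threshold
        if retained:
            alleles.append(HVRAllele(peptide, frozenset(by_sample)))
    alleles.sort(key=lambda a: (-len(a.samples_present), a.peptide))
    return alleles


def _load_known_peptides(known) -> set[str]:
    if known is None:
        return set()
    if isinstance(known, (str, Path)):
        return {str(rec.seq).upper() for rec in SeqIO.parse(str(known), "fasta")}
    return {str(p).upper() for p in known}


def classify_novelty(alleles: Sequence[HVRAllele], known=None) -> list[HVRAllele]:
    """Flag alleles absent from a known peptide set as novel.

    ``known`` may be a FASTA path or an iterable of peptides; with no
    known set every allele is novel.
    """
    known_set = _load_known_peptides(known)
    return [
        HVRAllele(a.peptide, a.samples_present, is_novel=a.peptide not in known_set)
        for a in alleles
    ]


def rarefy(
    sample_id: str,
    allele_counts: Mapping[str, int],
    percents: Sequence[int] = tuple(range(1, 101)),
    replicates: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RarefactionCurve:
    """Mean distinct-allele count under subsampling without replacement.

    ``allele_counts`` maps each retained allele of the sample to its read
    count; each read's allele label is fixed by the full-data call.  For
    each percent ``p``, ``replicates`` subsets of ``floor(p*N/100)`` reads
    are drawn without replacement and the number of distinct alleles
    observed is averaged.
    """
    if not allele_counts:
        raise ValueError("empty sample")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if any(not 0 < p <= 100 for p in percents):
        raise ValueError("percents must lie in (0, 100]")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.asarray(list(allele_counts.values()), dtype=np.int64)
    total = int(counts.sum())
    means = []
    for p in percents:
        n_draw = (p * total) // 100
        if n_draw <= 0:
            means.append(0.0)
            continue
        seen = 0
        for _ in range(replicates):
            draw = rng.multivariate_hypergeometric(counts, n_draw)
            seen += int(np.count_nonzero(draw))
        means.append(seen / replicates)
    return RarefactionCurve(
        sample_id=sample_id,
        percents=tuple(int(p) for p in percents),
        mean_allele_counts=tuple(means),
        replicates=replicates,
        seed=seed,
        full_allele_count=len(allele_counts),
    )
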