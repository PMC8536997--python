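"""Read-level processing: motif-anchored trimming, quality filtering,
exact-identity clustering with a minimum-support filter, and translation.

The processing order mirrors the amplicon pipeline: each read is scanned
for the 5' flank pattern followed downstream by the 3' flank pattern
(forward orientation first, then the reverse complement of the read); the
fragment spanning both motifs inclusive is kept, quality-filtered at
every position, clustered by exact DNA identity, and translated.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .motif_model import MotifPatternPair
from .seqtools import revcomp, try_translate

DEFAULT_QMIN = 6
DEFAULT_MIN_CLUSTER = 10


@dataclass(frozen=True)
class ReadRecord:
    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals length mismatch")


@dataclass(frozen=True)
class TrimmedFragment:
    """Motif-to-motif (inclusive) substring of a read, orientation-normalized."""

    source_id: str
    bases: str
    quals: tuple[int, ...]
    orientation: str  # "forward" | "revcomp"


@dataclass(frozen=True)
class FragmentCluster:
    bases: str
    member_count: int
    member_ids: tuple[str, ...]


@dataclass(frozen=True)
class ClusterTranslation:
    """Outcome of translating one cluster: a peptide or a rejection reason."""

    cluster: FragmentCluster
    peptide: str | None
    reason: str | None  # None | "frame" | "stop" | "ambiguous_base"

    @property
    def accepted(self) -> bool:
        return self.reason is None


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate a FASTQ file (gzip-transparent) as :class:`ReadRecord`."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            quals = tuple(ord(c) - 33 for c in qual)
            yield ReadRecord(rid.split()[0], seq.upper(), quals)


def scan_and_trim(read: ReadRecord, patterns: MotifPatternPair) -> TrimmedFragment | None:
    """Locate the 5' then 3' flank patterns and trim inclusive of both.

    Forward orientation is tried first; failing that, the read is
    reverse-complemented (qualities reversed) and rescanned.  The leftmost
    5' match is paired with the rightmost 3' match starting at or after
    its end (maximal span).  Returns ``None`` when no orientation yields
    an ordered pair of matches.
    """
    for orientation in ("forward", "revcomp"):
        if orientation == "forward":
            seq, quals = read.bases, read.quals
        else:
            seq, quals = revcomp(read.bases), read.quals[::-1]
        m5 = patterns.pattern5_fwd.search(seq)
        if m5 is None:
            continue
        m3_last = None
        for m3 in patterns.pattern3_fwd.finditer(seq, m5.end()):
            m3_last = m3
        if m3_last is None:
            continue
        start, end = m5.start(), m3_last.end()
        return TrimmedFragment(read.id, seq[start:end], quals[start:end], orientation)
    return None


def quality_pass(fragment: TrimmedFragment, qmin: int = DEFAULT_QMIN) -> bool:
    """True iff every position of the trimmed span has Phred >= ``qmin``."""
    if not fragment.bases:
        raise ValueError("empty fragment")
    return min(fragment.quals) >= qmin


def cluster_and_filter(
    fragments: Iterable[TrimmedFragment], min_cluster: int = DEFAULT_MIN_CLUSTER
) -> list[FragmentCluster]:
    """Group fragments by exact base-string identity; drop small clusters.

    Clusters with fewer than ``min_cluster`` members are discarded
    (``min_cluster`` itself survives).  Output is ordered by descending
    member count, ties broken by base string for determinism.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for frag in fragments:
        groups[frag.bases].append(frag.source_id)
    clusters = [
        FragmentCluster(bases, len(ids), tuple(ids))
        for bases, ids in groups.items()
        if len(ids) >= min_cluster
    ]
    clusters.sort(key=lambda c: (-c.member_count, c.bases))
    return clusters


def translate_cluster(cluster: FragmentCluster) -> ClusterTranslation:
    """Translate a cluster's bases in frame 0 (the motif anchor fixes frame).

    Rejection reasons: ``frame`` (length not a multiple of 3), ``stop``
    (internal stop codon), ``ambiguous_base`` (any non-ACGT symbol).
    """
    peptide, reason = try_translate(cluster.bases)
    if reason is not None:
        return ClusterTranslation(cluster, None, reason)
    return ClusterTranslation(cluster, peptide, None)


@dataclass
class SampleProcessingResult:
    """Per-sample attrition accounting plus the surviving translations."""

    sample_id: str
    n_reads: int
    n_trimmed: int
    n_quality_passed: int
    n_clustered_reads: int
    translations: list[ClusterTranslation]
    rejection_counts: dict[str, int]

    @property
    def accepted(self) -> list[ClusterTranslation]:
        return [t for t in self.translations if t.accepted]

    @property
    def n_retained_reads(self) -> int:
        return sum(t.cluster.member_count for t in self.accepted)


def process_sample(
    sample_id: str,
    reads: Iterable[ReadRecord],
    patterns: MotifPatternPair,
    qmin: int = DEFAULT_QMIN,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
) -> SampleProcessingResult:
    """Run trim -> quality -> cluster -> translate for one sample."""
    n_reads = n_trimmed = n_passed = 0
    kept: list[TrimmedFragment] = []
    for read in reads:
        n_reads += 1
        frag = scan_and_trim(read, patterns)
        if frag is None:
            continue
        n_trimmed += 1
        if quality_pass(frag, qmin):
            n_passed += 1
            kept.append(frag)
    clusters = cluster_and_filter(kept, min_cluster)
    translations = [translate_cluster(c) for c in clusters]
    rejections: dict[str, int] = defaultdict(int)
    for t in translations:
        if not t.accepted:
            rejections[t.reason] += 1
    return SampleProcessingResult(
        sample_id=sample_id,
        n_reads=n_reads,
        n_trimmed=n_trimmed,
        n_quality_passed=n_passed,
        n_clustered_reads=sum(c.member_count for c in clusters),
        translations=translations,
        rejection_counts=dict(rejections),
    )
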