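"""Conserved flanking-motif inference and DNA-level search patterns.

The hypervariable region of interest is bracketed by short, highly
conserved protein motifs.  This module derives those motifs from a protein
multiple alignment and compiles them into DNA regular expressions that
match every codon-level encoding of the motif, in forward and
reverse-complement orientation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .seqtools import AA_TO_CODONS, STANDARD_AAS, revcomp

#: Exemplar flank peptides used as defaults throughout the pipeline when no
#: alignment is supplied (5' "KIIS", 3' "IEQIP").
DEFAULT_FLANK_5 = "KIIS"
DEFAULT_FLANK_3 = "IEQIP"

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class FlankMotif:
    """An ordered run of residue-sets describing one conserved flank.

    ``side`` is ``"5prime"`` or ``"3prime"``; ``positions[i]`` is the set
    of amino acids admitted at position ``i``.
    """

    side: str
    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if self.side not in ("5prime", "3prime"):
            raise ValueError(f"invalid side {self.side!r}")
        if len(self.positions) < 3:
            raise ValueError("motif must span at least 3 positions")
        for pos in self.positions:
            if not pos:
                raise ValueError("empty residue-set in motif")
            bad = set(pos) - STANDARD_AAS
            if bad:
                raise ValueError(f"non-standard residues in motif: {bad}")

    @property
    def width(self) -> int:
        return len(self.positions)

    def admits(self, peptide: str) -> bool:
        """True iff ``peptide`` lies in the motif's residue-set product."""
        if len(peptide) != self.width:
            return False
        return all(aa in pos for aa, pos in zip(peptide, self.positions))

    @classmethod
    def from_peptide(cls, side: str, peptide: str) -> "FlankMotif":
        """Singleton-set motif from a literal flank peptide."""
        return cls(side, tuple(frozenset(aa) for aa in peptide))


def default_motifs() -> tuple[FlankMotif, FlankMotif]:
    """The exemplar (5', 3') flank motifs used when no MSA is supplied."""
    return (
        FlankMotif.from_peptide("5prime", DEFAULT_FLANK_5),
        FlankMotif.from_peptide("3prime", DEFAULT_FLANK_3),
    )


def _read_alignment(protein_msa) -> list[str]:
    if isinstance(protein_msa, (str, Path)):
        rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(protein_msa), "fasta")]
    else:
        rows = []
        for item in protein_msa:
            rows.append(str(getattr(item, "seq", item)).upper())
    return rows


def infer_flank_motifs(
    protein_msa,
    flank_width: int | tuple[int, int] = (4, 5),
    consensus_fraction: float = 0.05,
) -> tuple[FlankMotif, FlankMotif]:
    """Derive (5', 3') flank motifs from an aligned protein FASTA.

    Parameters
    ----------
    protein_msa:
        Path to an aligned FASTA, or an iterable of equal-length rows.
    flank_width:
        Number of alignment columns per flank; a single int applies to
        both sides, a ``(w5, w3)`` pair sets them independently.
    consensus_fraction:
        A residue enters a position's set iff its frequency among non-gap
        rows of that column is at least this fraction.

    Columns where more than half the rows are gaps are skipped when
    locating flank columns (treated as alignment artifacts).
    """
    rows = _read_alignment(protein_msa)
    if not rows:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("ragged alignment rows")
    if isinstance(flank_width, int):
        w5 = w3 = flank_width
    else:
        w5, w3 = flank_width
    if w5 < 3 or w3 < 3:
        raise ValueError("flank_width must be >= 3")

    usable = []
    for j in range(ncol):
        col = [r[j] for r in rows]
        gaps = sum(c in GAP_CHARS for c in col)
        if gaps * 2 <= len(col):
            usable.append(j)
    if len(usable) < w5 + w3:
        raise ValueError("alignment has too few non-gap-majority columns")

    def column_set(j: int) -> frozenset[str]:
        col = [r[j] for r in rows if r[j] not in GAP_CHARS]
        n = len(col)
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        residues = frozenset(
            aa
            for aa, k in counts.items()
            if aa in STANDARD_AAS and k / n >= consensus_fraction
        )
        if not residues:
            raise ValueError(f"no consensus residue at alignment column {j}")
        return residues

    motif5 = FlankMotif("5prime", tuple(column_set(j) for j in usable[:w5]))
    motif3 = FlankMotif("3prime", tuple(column_set(j) for j in usable[-w3:]))
    return motif5, motif3


def peptide_motif_to_dna_pattern(motif: FlankMotif, orientation: str = "forward") -> str:
    """Regex over {A,C,G,T} matching every codon encoding of the motif.

    For ``orientation="revcomp"`` the positions are reversed and each
    codon is reverse-complemented, so the pattern matches the reverse
    complement of every forward encoding.
    """
    if orientation not in ("forward", "revcomp"):
        raise ValueError(f"invalid orientation {orientation!r}")
    parts = []
    positions = motif.positions if orientation == "forward" else motif.positions[::-1]
    for pos in positions:
        codons = []
        for aa in sorted(pos):
            if aa not in AA_TO_CODONS:
                raise ValueError(f"residue {aa!r} has no codon")
            codons.extend(AA_TO_CODONS[aa])
        if orientation == "revcomp":
            codons = [revcomp(c) for c in codons]
        parts.append("(?:" + "|".join(sorted(codons)) + ")")
    return "".join(parts)


@dataclass(frozen=True)
class MotifPatternPair:
    """Compiled DNA search patterns for both flanks in both orientations."""

    motif5: FlankMotif
    motif3: FlankMotif
    pattern5_fwd: re.Pattern = field(repr=False)
    pattern3_fwd: re.Pattern = field(repr=False)
    pattern5_rc: re.Pattern = field(repr=False)
    pattern3_rc: re.Pattern = field(repr=False)

    def to_json(self) -> str:
        payload = {
            "motif5": ["".join(sorted(p)) for p in self.motif5.positions],
            "motif3": ["".join(sorted(p)) for p in self.motif3.positions],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MotifPatternPair":
        payload = json.loads(text)
        m5 = FlankMotif("5prime", tuple(frozenset(p) for p in payload["motif5"]))
        m3 = FlankMotif("3prime", tuple(frozenset(p) for p in payload["motif3"]))
        return build_pattern_pair(m5, m3)


def build_pattern_pair(motif5: FlankMotif, motif3: FlankMotif) -> MotifPatternPair:
    """Compile all four search patterns (5'/3' x forward/revcomp)."""
    return MotifPatternPair(
        motif5=motif5,
        motif3=motif3,
        pattern5_fwd=re.compile(peptide_motif_to_dna_pattern(motif5, "forward")),
        pattern3_fwd=re.compile(peptide_motif_to_dna_pattern(motif3, "forward")),
        pattern5_rc=re.compile(peptide_motif_to_dna_pattern(motif5, "revcomp")),
        pattern3_rc=re.compile(peptide_motif_to_dna_pattern(motif3, "revcomp")),
    )
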