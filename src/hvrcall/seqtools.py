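"""Shared DNA/protein primitives: the standard genetic code, reverse
complement and frame-0 translation with explicit rejection reasons."""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

STANDARD_AAS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_table = unambiguous_dna_by_id[1]  # the standard code
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, [])
    AA_TO_CODONS[_aa].append(_codon)
AA_TO_CODONS = {aa: tuple(cs) for aa, cs in AA_TO_CODONS.items()}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-transparent)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate ``dna`` in frame 0 with the standard code.

    Raises ``ValueError`` if the length is not a multiple of 3, a codon
    contains a non-ACGT symbol, or a stop codon occurs. Callers that need
    soft rejection should use :func:`try_translate`.
    """
    peptide, reason = try_translate(dna)
    if reason is not None:
        raise ValueError(f"cannot translate: {reason}")
    return peptide


def try_translate(dna: str) -> tuple[str, str | None]:
    """Frame-0 translation returning ``(peptide, reason)``.

    ``reason`` is ``None`` on success, else one of ``"frame"``,
    ``"ambiguous_base"`` or ``"stop"``; the peptide is then ``""``.
    """
    if len(dna) % 3 != 0:
        return "", "frame"
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3].upper()
        if codon in STOP_CODONS:
            return "", "stop"
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            return "", "ambiguous_base"
        out.append(aa)
    return "".join(out), None
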