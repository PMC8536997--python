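"""Synthetic colony amplicon simulator with ground truth.

Generates per-colony allele sets (two queen alleles, several patriline
alleles, optional low-frequency drifted-worker alleles), skewed multinomial
read abundances, A/T-rich repeat alleles encoding mostly N/Y residues
between the conserved flanks, and semiconductor-style sequencing errors:
per-base substitutions plus homopolymer-length indels whose probability
grows with run length, with per-base quality strings."""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .motif_model import DEFAULT_FLANK_3, DEFAULT_FLANK_5
from .seqtools import AA_TO_CODONS, revcomp, translate

#: Residue weights of the repeat region between the flanks (N/Y-heavy).
DEFAULT_REPEAT_WEIGHTS: dict[str, float] = {
    "N": 0.45,
    "Y": 0.30,
    **{aa: 0.25 / 9 for aa in "SKHTCQLIP"},
}


@dataclass(frozen=True)
class ErrorModel:
    """Substitution + homopolymer-indel error process with quality model.

    The indel probability for a homopolymer run of length L is
    ``min(1, homopolymer_indel_base_rate * homopolymer_length_exponent**(L-1))``.
    """

    substitution_rate: float = 0.005
    homopolymer_indel_base_rate: float = 0.005
    homopolymer_length_exponent: float = 1.6
    quality_mean: float = 32.0
    quality_sd: float = 4.0
    error_quality_mean: float = 12.0
    error_quality_sd: float = 4.0

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.homopolymer_indel_base_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must lie in [0, 1)")

    def run_indel_probability(self, run_length: int) -> float:
        return min(
            1.0,
            self.homopolymer_indel_base_rate
            * self.homopolymer_length_exponent ** (run_length - 1),
        )


#: Convenience error-free model for no-noise tests.
NO_ERRORS = ErrorModel(substitution_rate=0.0, homopolymer_indel_base_rate=0.0)


@dataclass
class ColonyTruth:
    """Ground truth for one simulated colony/sample."""

    sample_id: str
    queen_alleles: tuple[str, str]
    patriline_alleles: tuple[str, ...]
    drift_alleles: tuple[str, ...]
    abundance: dict[str, float]
    dna_encodings: dict[str, str]
    seed: int | None = None

    @property
    def all_alleles(self) -> tuple[str, ...]:
        return tuple(self.abundance)

    def __post_init__(self) -> None:
        if self.queen_alleles[0] == self.queen_alleles[1]:
            raise ValueError("queen alleles must be distinct")
        total = sum(self.abundance.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")
        for peptide, dna in self.dna_encodings.items():
            if translate(dna) != peptide:
                raise ValueError("dna encoding does not translate to its peptide")


def _pick_codon(rng: np.random.Generator, aa: str, at_bias: float) -> str:
    """Sample a codon for ``aa``, biased toward the most A/T-rich codon."""
    codons = AA_TO_CODONS[aa]
    if len(codons) == 1:
        return codons[0]
    at_counts = [sum(c in "AT" for c in codon) for codon in codons]
    best = at_counts.index(max(at_counts))
    if rng.random() < at_bias:
        return codons[best]
    rest = [c for i, c in enumerate(codons) if i != best]
    return rest[rng.integers(len(rest))]


def generate_allele(
    rng: np.random.Generator,
    length_range: tuple[int, int] = (32, 55),
    repeat_alphabet_weights: Mapping[str, float] = DEFAULT_REPEAT_WEIGHTS,
    motif5: str = DEFAULT_FLANK_5,
    motif3: str = DEFAULT_FLANK_3,
    at_bias: float = 0.8,
) -> tuple[str, str]:
    """Draw one (peptide, dna) allele: flank + N/Y-rich repeat + flank.

    ``length_range`` bounds the total peptide length in residues and must
    lie within [30, 60].
    """
    lo, hi = length_range
    if lo < 30 or hi > 60 or lo > hi:
        raise ValueError("length_range must lie within [30, 60]")
    weights = dict(repeat_alphabet_weights)
    if any(w < 0 for w in weights.values()) or abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("repeat weights must be non-negative and sum to 1")
    flank_len = len(motif5) + len(motif3)
    total = int(rng.integers(lo, hi + 1))
    repeat_len = total - flank_len
    if repeat_len <= 0:
        raise ValueError("length_range too small for the flank motifs")
    letters = list(weights)
    probs = np.array([weights[l] for l in letters])
    repeat = "".join(rng.choice(letters, size=repeat_len, p=probs))
    peptide = motif5 + repeat + motif3
    dna = "".join(_pick_codon(rng, aa, at_bias) for aa in peptide)
    return peptide, dna


def _draw_fractions(
    rng: np.random.Generator,
    n_alleles_by_group: tuple[int, int, int],
    queen_share: float,
    drift_share: float,
    dirichlet_concentration: float,
    min_allele_fraction: float | None,
    max_tries: int = 1000,
) -> np.ndarray:
    nq, npat, ndrift = n_alleles_by_group
    pat_share = 1.0 - queen_share - (drift_share if ndrift else 0.0)
    for _ in range(max_tries):
        queen = queen_share * rng.dirichlet([10.0, 10.0])
        pat = pat_share * rng.dirichlet([dirichlet_concentration] * npat)
        drift = (
            drift_share * rng.dirichlet([1.0] * ndrift) if ndrift else np.empty(0)
        )
        fractions = np.concatenate([queen, pat, drift])
        if min_allele_fraction is None or fractions.min() >= min_allele_fraction:
            return fractions
    raise ValueError(
        "could not satisfy min_allele_fraction; lower it or reduce patrilines"
    )


def simulate_colony(
    rng: np.random.Generator,
    sample_id: str = "S1",
    n_patrilines: int | None = None,
    population_pool: Sequence[tuple[str, str]] | None = None,
    pool_probability: float = 0.5,
    drift_fraction: float = 0.03,
    n_drift: int | None = None,
    queen_share: float = 0.5,
    dirichlet_concentration: float = 0.8,
    min_allele_fraction: float | None = None,
    allele_kwargs: Mapping | None = None,
) -> ColonyTruth:
    """Simulate one colony's allele set and abundance vector.

    The queen carries two distinct alleles jointly holding ``queen_share``
    of the reads (split near-evenly); each of ``n_patrilines`` fathers
    contributes one allele, with proportions drawn from a symmetric
    Dirichlet (skewed toward many rare patrilines at the default
    concentration); drifted-worker alleles jointly hold ``drift_fraction``.
    With a ``population_pool`` of (peptide, dna) alleles, patriline and
    drift alleles are drawn from the pool with probability
    ``pool_probability``, enabling cross-sample sharing.
    """
    if n_patrilines is None:
        n_patrilines = int(rng.integers(7, 21))  # typical patriline range
    if n_patrilines < 1:
        raise ValueError("n_patrilines must be >= 1")
    if not 0.0 <= drift_fraction < 0.05 + 1e-12:
        raise ValueError("combined drift fraction must be < 0.05")
    if n_drift is None:
        n_drift = int(rng.integers(0, 3)) if drift_fraction > 0 else 0
    akw = dict(allele_kwargs or {})

    def fresh() -> tuple[str, str]:
        return generate_allele(rng, **akw)

    def draw(avoid: set[str]) -> tuple[str, str]:
        if population_pool and rng.random() < pool_probability:
            candidates = [a for a in population_pool if a[0] not in avoid]
            if candidates:
                return candidates[rng.integers(len(candidates))]
        for _ in range(100):
            allele = fresh()
            if allele[0] not in avoid:
                return allele
        raise RuntimeError("failed to generate a distinct allele")

    q1 = fresh()
    q2 = draw({q1[0]})
    used = {q1[0], q2[0]}
    patrilines = []
    for _ in range(n_patrilines):
        a = draw(used)
        used.add(a[0])
        patrilines.append(a)
    drifts = []
    for _ in range(n_drift):
        a = draw(used)
        used.add(a[0])
        drifts.append(a)

    fractions = _draw_fractions(
        rng,
        (2, n_patrilines, len(drifts)),
        queen_share,
        drift_fraction,
        dirichlet_concentration,
        min_allele_fraction,
    )
    ordered = [q1, q2] + patrilines + drifts
    abundance = {pep: float(f) for (pep, _), f in zip(ordered, fractions)}
    encodings = {pep: dna for pep, dna in ordered}
    return ColonyTruth(
        sample_id=sample_id,
        queen_alleles=(q1[0], q2[0]),
        patriline_alleles=tuple(p for p, _ in patrilines),
        drift_alleles=tuple(d for d, _ in drifts),
        abundance=abundance,
        dna_encodings=encodings,
    )


def _homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of every maximal single-base run of length >= 2."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j - i))
        i = j
    return runs


_BASES = "ACGT"


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    bases: str
    quals: tuple[int, ...]
    true_peptide: str


def _apply_errors(
    seq: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, list[bool]]:
    chars = list(seq)
    errors = [False] * len(chars)
    # homopolymer indels first (operate on true-run coordinates), then
    # per-base substitutions on the resulting sequence
    if model.homopolymer_indel_base_rate > 0:
        offset = 0
        for start, length in _homopolymer_runs(seq):
            if rng.random() >= model.run_indel_probability(length):
                continue
            pos = start + offset
            if rng.random() < 0.5 and length > 1:  # deletion of one run base
                del chars[pos]
                del errors[pos]
                offset -= 1
                if pos < len(errors):
                    errors[pos] = True
            else:  # insertion of one extra run base
                chars.insert(pos, seq[start])
                errors.insert(pos, True)
                offset += 1
    if model.substitution_rate > 0:
        hits = np.flatnonzero(rng.random(len(chars)) < model.substitution_rate)
        for pos in hits:
            current = chars[pos]
            alternatives = [b for b in _BASES if b != current]
            chars[pos] = alternatives[rng.integers(3)]
            errors[pos] = True
    return "".join(chars), errors


def _qualities(
    errors: list[bool], model: ErrorModel, rng: np.random.Generator
) -> tuple[int, ...]:
    n = len(errors)
    good = rng.normal(model.quality_mean, model.quality_sd, size=n)
    bad = rng.normal(model.error_quality_mean, model.error_quality_sd, size=n)
    q = np.where(errors, bad, good)
    return tuple(int(v) for v in np.clip(np.rint(q), 2, 40))


def simulate_reads(
    truth: ColonyTruth,
    n_reads: int,
    error_model: ErrorModel = ErrorModel(),
    rng: np.random.Generator | None = None,
    primer_context: tuple[str, str] = ("", ""),
) -> Iterator[SimulatedRead]:
    """Yield FASTQ-ready reads sampled from the colony's abundance vector.

    Each read picks an allele multinomially, optionally gains flanking
    primer context, suffers homopolymer indels and substitutions, and is
    emitted in a random orientation (50% reverse-complemented) with
    per-base qualities (erroneous bases drawn from a lower-quality
    distribution).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    peptides = list(truth.abundance)
    probs = np.array([truth.abundance[p] for p in peptides])
    choices = rng.choice(len(peptides), size=n_reads, p=probs)
    left, right = primer_context
    for i, idx in enumerate(choices):
        peptide = peptides[idx]
        template = left + truth.dna_encodings[peptide] + right
        bases, errors = _apply_errors(template, error_model, rng)
        quals = _qualities(errors, error_model, rng)
        if rng.random() < 0.5:
            bases = revcomp(bases)
            quals = quals[::-1]
        yield SimulatedRead(f"{truth.sample_id}_r{i}", bases, quals, peptide)


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> int:
    """Write reads as FASTQ (gzip if the path ends in .gz); returns count."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n


def write_truth(
    truths: Sequence[ColonyTruth], manifest_path: str | Path, fasta_path: str | Path
) -> None:
    """Serialize colony ground truth: per-allele manifest TSV + allele FASTA."""
    with open(manifest_path, "w") as fh:
        fh.write("sample_id\tpeptide\trole\tabundance\tdna\n")
        for truth in truths:
            roles = {p: "queen" for p in truth.queen_alleles}
            roles.update({p: "patriline" for p in truth.patriline_alleles})
            roles.update({p: "drift" for p in truth.drift_alleles})
            for peptide, frac in truth.abundance.items():
                fh.write(
                    f"{truth.sample_id}\t{peptide}\t{roles[peptide]}\t"
                    f"{frac:.12g}\t{truth.dna_encodings[peptide]}\n"
                )
    seen: dict[str, None] = {}
    for truth in truths:
        for peptide in truth.abundance:
            seen.setdefault(peptide)
    with open(fasta_path, "w") as fh:
        for i, peptide in enumerate(seen, 1):
            fh.write(f">allele_{i}\n{peptide}\n")


def read_truth(manifest_path: str | Path) -> list[ColonyTruth]:
    """Inverse of :func:`write_truth` (manifest only)."""
    rows: dict[str, list[tuple[str, str, float, str]]] = {}
    order: list[str] = []
    with open(manifest_path) as fh:
        header = fh.readline()
        for line in fh:
            sample_id, peptide, role, frac, dna = line.rstrip("\n").split("\t")
            if sample_id not in rows:
                order.append(sample_id)
            rows.setdefault(sample_id, []).append((peptide, role, float(frac), dna))
    truths = []
    for sample_id in order:
        entries = rows[sample_id]
        queens = [p for p, role, _, _ in entries if role == "queen"]
        pats = tuple(p for p, role, _, _ in entries if role == "patriline")
        drifts = tuple(p for p, role, _, _ in entries if role == "drift")
        truths.append(
            ColonyTruth(
                sample_id=sample_id,
                queen_alleles=(queens[0], queens[1]),
                patriline_alleles=pats,
                drift_alleles=drifts,
                abundance={p: f for p, _, f, _ in entries},
                dna_encodings={p: d for p, _, _, d in entries},
            )
        )
    return truths
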