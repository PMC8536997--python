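import numpy as np
import pytest

from hvrcall import allele_caller, read_processor
from hvrcall.amplicon_simulator import (
    NO_ERRORS,
    ColonyTruth,
    ErrorModel,
    generate_allele,
    read_truth,
    simulate_colony,
    simulate_reads,
    write_fastq,
    write_truth,
)
from hvrcall.motif_model import DEFAULT_FLANK_3, DEFAULT_FLANK_5
from hvrcall.seqtools import translate


class TestGenerateAllele:
    def test_flanks_always_present(self, rng):
        for _ in range(200):
            peptide, _ = generate_allele(rng)
            assert peptide.startswith(DEFAULT_FLANK_5)
            assert peptide.endswith(DEFAULT_FLANK_3)

    def test_dna_translates_to_peptide(self, rng):
        for _ in range(200):
            peptide, dna = generate_allele(rng)
            assert translate(dna) == peptide

    def test_lengths_within_range(self, rng):
        lengths = {len(generate_allele(rng, length_range=(33, 40))[0]) for _ in range(300)}
        assert min(lengths) >= 33 and max(lengths) <= 40

    def test_repeat_region_ny_fraction(self, rng):
        """Mean N+Y fraction of the repeat region matches the configured
        0.45 + 0.30 weight mass."""
        fractions = []
        for _ in range(1000):
            peptide, _ = generate_allele(rng)
            repeat = peptide[len(DEFAULT_FLANK_5) : -len(DEFAULT_FLANK_3)]
            fractions.append((repeat.count("N") + repeat.count("Y")) / len(repeat))
        assert np.mean(fractions) == pytest.approx(0.75, abs=0.05)

    def test_invalid_length_range(self, rng):
        with pytest.raises(ValueError):
            generate_allele(rng, length_range=(10, 20))

    def test_invalid_weights(self, rng):
        with pytest.raises(ValueError):
            generate_allele(rng, repeat_alphabet_weights={"N": 0.5, "Y": 0.2})


class TestSimulateColony:
    def test_seed_determinism(self):
        a = simulate_colony(np.random.default_rng(9), "S", n_patrilines=8)
        b = simulate_colony(np.random.default_rng(9), "S", n_patrilines=8)
        assert a == b

    def test_queen_alleles_distinct(self, rng):
        truth = simulate_colony(rng, "S", n_patrilines=5)
        assert truth.queen_alleles[0] != truth.queen_alleles[1]

    def test_distinct_allele_count_bound(self, rng):
        truth = simulate_colony(rng, "S", n_patrilines=9)
        assert len(truth.abundance) <= 2 + 9 + len(truth.drift_alleles)

    def test_abundance_sums_to_one(self, rng):
        truth = simulate_colony(rng, "S", n_patrilines=12)
        assert sum(truth.abundance.values()) == pytest.approx(1.0, abs=1e-12)

    def test_drift_fraction_bounded(self, rng):
        for _ in range(20):
            truth = simulate_colony(rng, "S", n_patrilines=6, drift_fraction=0.04)
            drift_mass = sum(truth.abundance[p] for p in truth.drift_alleles)
            assert drift_mass < 0.05

    def test_default_allele_count_low_twenties(self):
        """Default configuration yields per-colony distinct allele counts
        around the biologically expected low twenties."""
        counts = []
        rng = np.random.default_rng(123)
        for _ in range(40):
            truth = simulate_colony(rng, "S")
            counts.append(len(truth.abundance))
        assert 14 <= np.mean(counts) <= 25

    def test_shared_pool_produces_multi_sample_alleles(self, rng):
        pool = [generate_allele(rng) for _ in range(10)]
        sets = []
        for i in range(6):
            truth = simulate_colony(
                rng, f"S{i}", n_patrilines=8, population_pool=pool, pool_probability=0.8
            )
            sets.append(set(truth.abundance))
        shared = set.union(*[a & b for a in sets for b in sets if a is not b])
        assert shared  # at least one allele occurs in two colonies

    def test_min_allele_fraction_enforced(self, rng):
        truth = simulate_colony(
            rng, "S", n_patrilines=5, drift_fraction=0.0,
            dirichlet_concentration=2.0, min_allele_fraction=0.04,
        )
        assert min(truth.abundance.values()) >= 0.04

    def test_invalid_patriline_count(self, rng):
        with pytest.raises(ValueError):
            simulate_colony(rng, "S", n_patrilines=0)


class TestSimulateReads:
    def test_zero_error_round_trip(self, rng, patterns):
        truth = simulate_colony(rng, "S", n_patrilines=4)
        for read in simulate_reads(truth, 50, NO_ERRORS, rng):
            rec = read_processor.ReadRecord(read.id, read.bases, read.quals)
            frag = read_processor.scan_and_trim(rec, patterns)
            assert frag is not None
            assert translate(frag.bases) == read.true_peptide

    def test_zero_abundance_never_sampled(self, rng):
        p1, d1 = generate_allele(rng)
        p2, d2 = generate_allele(rng)
        p3, d3 = generate_allele(rng)
        truth = ColonyTruth(
            "S", (p1, p2), (p3,), (), {p1: 0.5, p2: 0.5, p3: 0.0},
            {p1: d1, p2: d2, p3: d3},
        )
        peptides = {r.true_peptide for r in simulate_reads(truth, 2000, NO_ERRORS, rng)}
        assert p3 not in peptides

    def test_multinomial_fractions(self, rng):
        p1, d1 = generate_allele(rng)
        p2, d2 = generate_allele(rng)
        truth = ColonyTruth("S", (p1, p2), (), (), {p1: 0.7, p2: 0.3},
                            {p1: d1, p2: d2})
        n = 10_000
        reads = list(simulate_reads(truth, n, NO_ERRORS, rng))
        observed = sum(r.true_peptide == p1 for r in reads) / n
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(observed - 0.7) <= 3 * se

    def test_primer_context_cosmetic(self, rng, patterns):
        truth = simulate_colony(rng, "S", n_patrilines=3)
        reads = simulate_reads(truth, 20, NO_ERRORS, rng,
                               primer_context=("TATCGAGA", "ACCAATGG"))
        for read in reads:
            rec = read_processor.ReadRecord(read.id, read.bases, read.quals)
            frag = read_processor.scan_and_trim(rec, patterns)
            assert frag is not None
            assert translate(frag.bases) == read.true_peptide

    def test_error_bases_get_lower_qualities(self, rng):
        truth = simulate_colony(rng, "S", n_patrilines=3)
        model = ErrorModel(substitution_rate=0.2, homopolymer_indel_base_rate=0.0)
        quals = [q for r in simulate_reads(truth, 100, model, rng) for q in r.quals]
        # bimodal mixture: a visible low-quality mass must exist
        assert np.mean(np.asarray(quals) < 20) > 0.05

    def test_homopolymer_rate_raises_frame_rejections(self, patterns):
        """10x homopolymer indel rate produces more frame/stop rejections."""
        def rejected_clusters(rate, seed):
            rng = np.random.default_rng(seed)
            truth = simulate_colony(rng, "S", n_patrilines=4, drift_fraction=0.0,
                                    min_allele_fraction=0.03)
            reads = [
                read_processor.ReadRecord(r.id, r.bases, r.quals)
                for r in simulate_reads(
                    truth, 3000,
                    ErrorModel(substitution_rate=0.0,
                               homopolymer_indel_base_rate=rate), rng)
            ]
            res = read_processor.process_sample("S", reads, patterns, min_cluster=2)
            return sum(res.rejection_counts.values())

        low = rejected_clusters(0.002, 7)
        high = rejected_clusters(0.02, 7)
        assert high > low

    def test_run_indel_probability_grows_with_length(self):
        model = ErrorModel()
        probs = [model.run_indel_probability(L) for L in range(1, 8)]
        assert all(a <= b for a, b in zip(probs, probs[1:]))

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            ErrorModel(substitution_rate=1.5)


class TestTruthSerialization:
    def test_round_trip(self, tmp_path, rng):
        truths = [
            simulate_colony(rng, f"S{i}", n_patrilines=4, drift_fraction=0.03)
            for i in range(3)
        ]
        manifest = tmp_path / "truth.tsv"
        fasta = tmp_path / "truth.fasta"
        write_truth(truths, manifest, fasta)
        restored = read_truth(manifest)
        assert len(restored) == 3
        for orig, back in zip(truths, restored):
            assert back.sample_id == orig.sample_id
            assert back.queen_alleles == orig.queen_alleles
            assert back.patriline_alleles == orig.patriline_alleles
            assert back.drift_alleles == orig.drift_alleles
            assert back.dna_encodings == orig.dna_encodings
            for p in orig.abundance:
                assert back.abundance[p] == pytest.approx(orig.abundance[p], rel=1e-9)

    def test_fasta_row_count_matches_unique_alleles(self, tmp_path, rng):
        truths = [simulate_colony(rng, f"S{i}", n_patrilines=3) for i in range(2)]
        write_truth(truths, tmp_path / "t.tsv", tmp_path / "t.fasta")
        n_unique = len({p for t in truths for p in t.abundance})
        headers = [l for l in (tmp_path / "t.fasta").read_text().splitlines()
                   if l.startswith(">")]
        assert len(headers) == n_unique

    def test_invalid_truth_rejected(self, rng):
        p1, d1 = generate_allele(rng)
        p2, d2 = generate_allele(rng)
        with pytest.raises(ValueError):
            ColonyTruth("S", (p1, p1), (), (), {p1: 1.0}, {p1: d1})
        with pytest.raises(ValueError):
            ColonyTruth("S", (p1, p2), (), (), {p1: 0.4, p2: 0.4},
                        {p1: d1, p2: d2})


def test_end_to_end_recovery_with_benign_errors(patterns):
    """Pipeline over simulated reads recovers the exact truth allele set."""
    rng = np.random.default_rng(2024)
    truth = simulate_colony(rng, "S", n_patrilines=6, drift_fraction=0.0,
                            dirichlet_concentration=2.0, min_allele_fraction=0.04)
    reads = [
        read_processor.ReadRecord(r.id, r.bases, r.quals)
        for r in simulate_reads(truth, 5000, ErrorModel(), rng)
    ]
    result = read_processor.process_sample("S", reads, patterns)
    table = allele_caller.tabulate("S", result.translations)
    called = {a.peptide for a in allele_caller.apply_qc([table], 0.0164)}
    assert called == set(truth.abundance)
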