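# hvrcall

Motif-anchored amplicon allele calling for the honey bee *csd*
hypervariable region (HVR) from honey environmental-DNA sequencing reads,
plus the downstream allele-diversity and sample-similarity analyses and a
synthetic colony/read simulator with ground truth.

## What it does

1. **Motif model** (`hvrcall.motif_model`) — derives the conserved 5'/3'
   protein flank motifs from a protein multiple alignment (defaults:
   `KIIS` / `IEQIP`) and compiles them into DNA regular expressions that
   match every codon-level encoding, forward and reverse-complement.
2. **Read processing** (`hvrcall.read_processor`) — scans each FASTQ read
   for the 5' then 3' motif pattern (either orientation), trims inclusive
   of both motifs, keeps fragments with Phred >= 6 at every position,
   clusters by exact DNA identity discarding clusters under 10 reads, and
   translates in the motif-anchored frame (rejecting frame-shifted,
   stop-containing or ambiguous sequences).
3. **Allele calling** (`hvrcall.allele_caller`) — merges synonymous
   encodings per sample, derives the single-sample abundance threshold
   (median of multi-sample alleles' minimum within-sample abundances,
   fallback 0.0164), retains alleles seen in >= 2 samples at any abundance
   or in one sample strictly above the threshold, flags private/novel
   alleles, and computes rarefaction curves (100 subsamples without
   replacement per depth).
4. **Diversity** (`hvrcall.diversity_analysis`) — all-pairs index
   `delta_L + n_SAP` (length difference plus substituted residue pairs
   under global BLOSUM62 alignment, gap open 12 / extend 2), globally and
   per sample.
5. **Sample similarity** (`hvrcall.sample_similarity`) — binary
   presence/absence matrix, Jaccard similarity, single/complete-linkage
   clustering (with Newick export), classical (Torgerson) MDS, and a
   majorize-minimize logistic PCA for binary data.
6. **Simulator** (`hvrcall.amplicon_simulator`) — colonies with 2 queen
   alleles + 7–20 patriline alleles + optional drifted-worker alleles
   (<5% combined), skewed Dirichlet abundances, A/T-rich repeat alleles
   encoding mostly N/Y residues, and semiconductor-style errors
   (substitutions + homopolymer-length indels with per-base qualities).
7. **CLI / reports** (`hvrcall.cli_reports`, `hvrcall.cli`) — end-to-end
   pipeline with per-sample summary, abundant-allele (>5%) table and a
   read/allele correlation panel.

## CLI

```sh
# simulate a 12-sample dataset with a shared allele pool
hvrcall simulate --samples 12 --reads 50000 --share-pool 40 --seed 1 --out-dir sim/

# optional: build motif patterns from your own protein MSA
hvrcall motifs build --msa flanks_msa.fasta --out patterns.json

# staged processing
hvrcall reads process --fastq sim/S1.fastq --fastq sim/S2.fastq --out-dir proc/
hvrcall alleles call --in-dir proc/ --threshold auto --seed 1 --out-dir called/
hvrcall diversity --alleles called/alleles.fasta --out div/
hvrcall similarity --alleles presence.tsv --k 2 --m 4 --out sim_out/

# or everything at once
hvrcall report --manifest sim/manifest.tsv --seed 1 --out-dir report/
```

Every run logs per-stage read/allele attrition to stderr; identical
configuration and seed produce a byte-identical output bundle.

## Layout

```
src/hvrcall/       package modules (one per pipeline stage)
tests/             pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py
data/              published per-sample summary + abundant-allele tables
```
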