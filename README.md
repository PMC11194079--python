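# pirnakit

Analyses for PIWI-bound small-RNA (piRNA) libraries:

* **Ping-pong amplification** — opposite-strand 5′–5′ overlap distance
  histograms over a 30-nt window, the 10-nt-overlap z-score, and
  copy-weighted ping-pong pair fractions (homotypic or heterotypic).
* **3′-end trimming** — per-5′-end copy-weighted median read lengths and
  the between-library median-difference histogram.
* **Length / composition / origin profiles** — length histograms,
  positional nucleotide composition (1U bias), and precedence-based
  genomic feature assignment (cluster > gene > repeat > intergenic).
* **Target prediction** — 25-nt genome-derived piRNA representatives,
  ungapped antisense scanning of transcripts (position 1 free, positions
  2–6 exact, ≥14 matches in positions 7–25, G:U = mismatch), predicted
  cleavage between guide nt 10–11, degradome (PARE) 5′-end validation
  requiring support in all replicates, metatranscript (5′UTR/CDS/3′UTR)
  distribution, and repeat sense/antisense annotation.
* **Expression integration** — an expression filter (≥100 reads in ≥1
  sample), a self-contained stand-in negative-binomial DE test with
  Benjamini–Hochberg adjustment (external DE tables accepted too), and the
  final filter nominating genes that are up-regulated while their
  degradome-supported targeting piRNA is down-regulated.
* **Synthetic data** — a fully seeded generator of toy genomes, piRNA
  libraries with planted ping-pong pairs, planted cleavage targets,
  degradome records and count matrices, with a machine-readable
  ground-truth ledger for every planted signal.

Conventions: all coordinates 0-based half-open; plus-strand 5′ end =
`start`, minus-strand 5′ end = `end − 1`; BED6 is the exchange format with
copy numbers in the score column (SAM accepted as input).

## Tests

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, null calibration, planted-signal recovery); the rest are
per-module unit and property tests. All fixtures are generated
programmatically — no binary data.

## CLI

```sh
pirnakit simulate --seed 1 --out-dir sim/            # synthetic dataset
pirnakit pingpong --reads-a sim/reads_MIWI_het_1.bed --out pp.tsv
pirnakit delta-median --reads-a a.bed --reads-b b.bed --out dm.tsv
pirnakit collapse --reads a.bed --genome sim/genome.fa --out reps.tsv
pirnakit scan-targets --reps reps.tsv --transcripts sim/transcripts.fa \
    --min-matches 14 --out sites.tsv
pirnakit degradome-support --sites sites.tsv \
    --degradome sim/degradome_het_rep1.bed --degradome sim/degradome_het_rep2.bed \
    --tolerance 0 --out supported.tsv
pirnakit de --counts sim/gene_counts.tsv --groups groups.tsv --out de.tsv
pirnakit integrate --sites supported.tsv --gene-de gde.tsv --pirna-de pde.tsv \
    --gene-adj-p 0.1 --pirna-adj-p 0.25 --out pairs.tsv
pirnakit run --config config.yaml                    # full pipeline + report
```

Exit codes: 0 success, 2 validation error, 3 stage failure.

A minimal `config.yaml` for `run`:

```yaml
outdir: out
seed: 1
simulate:
  n_reads: 1000
  n_planted_targets: 4
```

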