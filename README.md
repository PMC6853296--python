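# cpseq

Analysis toolkit for 2′,3′-cyclic-phosphate (cP) small-RNA sequencing
libraries. It implements the full desk-side workflow as a tested, reusable
pipeline:

- **`cpseq.simulate`** — ground-truthed read simulator: toy reference
  bundles (spike-in, mature cytoplasmic tRNAs with CCA and a His-like −1
  record, rRNAs, a mitochondrial sequence, mRNAs, a genome decoy) and FASTQ
  libraries whose fragment boundaries follow a C|A-dinucleotide cleavage
  model, with a 20–45 nt insert window, 3′-adapter ligation, substitution
  errors, spike-in doping, and a paired-condition mode that scales cP-RNA
  abundance down by a set factor while spike-in and substrate mRNA levels
  stay constant. Every read gets a truth-table record.
- **`cpseq.preprocess`** — 3′-adapter trimming (≤10% overlap mismatches, no
  indels, configurable minimum overlap) and 20–45 nt length selection.
- **`cpseq.mapping`** — prioritized sequential category mapping
  (spike-in → cyto tRNA → rRNA → mito → mRNA → genome) with a pure Hamming
  model (≤1 mismatch by default, N always mismatches), pigeonhole-seeded and
  exactly equivalent to a brute-force scan; deterministic within-category
  tie-breaking; antisense hits only for genomic-type references.
- **`cpseq.trna`** — tRNA-fragment taxonomy (5′-half / 3′-half / 5′-tRF /
  3′-tRF / i-tRF), 3′-half subtypes (CCA / CC / C / Di by terminal np 76–73),
  and His −1 variant calling (G−1 / U−1 / G1).
- **`cpseq.signature`** — terminal and flanking (±4 nt) nucleotide
  composition matrices, C|A boundary fractions, anticodon-loop cleavage-site
  inference from concordant 5′-/3′-half termini, per-substrate alignment
  profiles (bedGraph/BED), and read-length histograms.
- **`cpseq.quantify`** — spike-in-normalized RPKM
  (`count × 1e9 / (length × spike_count)`), replicate aggregation, and the
  two-condition cP-RNA vs mRNA fold-change table with a 2-D modal summary
  (log2 histogram, bin width 0.25).
- **`cpseq.iolib` / `cpseq.pipeline` / `cpseq.cli`** — FASTA/FASTQ readers
  (gzip-aware), SAM/BED/bedGraph/TSV writers, YAML-configured end-to-end
  pipeline with a reproducibility manifest, and the `cpseq` CLI.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (insert-range
arithmetic, mapping-oracle equivalence, partition/conservation, C|A
signature recovery, cleavage-pair concordance, aging-factor recovery at
100k reads × 2 conditions, spike-in invariance).

## CLI

```sh
# build toy references and simulate a library (or --aging-pair)
cpseq simulate --seed 1 --n-reads 10000 --refdir refs/ --out sim/

# trim + length-select
cpseq trim sim/reads.fastq --adapter TGGAATTCTCGGGTGCCAAG --out trimmed.fastq

# sequential mapping
cpseq map trimmed.fastq --refdir refs/ --out alignments.tsv

# full pipeline from a YAML config
cpseq run-all --config run.yaml

# insert-size window from product/adapter sizes
cpseq insert-range --product-min 140 --product-max 160 --adapter5 55 --adapter3 63
```

`run.yaml` needs `input_fastq`, `reference_dir`, `output_dir` (optional:
`min_len`, `max_len`, `max_mismatch`, `min_adapter_overlap`,
`keep_untrimmed`, `sample_id`). Outputs include trimmed FASTQ, alignment
TSV/SAM/BED, category counts and proportions, fragment-call and cleavage
tables, composition matrices, coverage bedGraphs, normalized RPKM, and
`manifest.json` (config snapshot, input checksums, per-stage read counts);
re-running with the same config reproduces all outputs byte-identically.

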