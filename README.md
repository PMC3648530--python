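# divergescan

Toolkit for comparative genome-alignment divergence scanning. It implements
the bespoke computational stages of a contig-versus-reference analysis as a
tested, reusable pipeline:

- **read_trim** — running-sum (modified-Mott) quality trimming
  (`limit − P_error` with reset-at-zero, default limit 0.05), terminal-N
  removal, and Smith–Waterman adapter removal.
- **align_ingest** — BLAST tabular (outfmt 6) parsing, the E-value
  step-down top-hit workflow (cutoffs 1e-50 → 1e-25 → none) with
  deterministic tie-breaking (E-value, bitscore, alignment length), unique
  chromosome classification, and per-chromosome summaries.
- **divergence** — the composite per-contig statistic
  `(pident/100) / alignment_length` (small = conserved, large = diverged;
  maximum 1/19 ≈ 0.052631579 for a 19-bp perfect hit), nearest-rank
  percentile outlier calling (defaults 99.98 / 0.02, equal-or-more-extreme
  inclusion), Monte-Carlo Lilliefors normality testing, pooled multi-hit
  rescoring of conserved outliers, and alternate-alignment outlier
  refutation.
- **snp_filter** — Neighborhood Quality Standard biallelic SNP filtering
  over samtools-style text pileups (window 11, central/average quality 20,
  ≤2 window mismatches+gaps, qualified coverage 10–60×, variant frequency
  ≥35%), plus per-kb density with sex-chromosome exclusion.
- **qc_stats** — pairwise Pearson/Spearman correlations among contig
  properties, contig-size outlier overlap, and the 2×2 chi-square SNP
  enrichment test (1 df, no continuity correction).
- **synthetic_data** — deterministic generator for contig FASTA, alignment
  tables, FASTQ reads, and pileups with planted ground truth (conserved /
  diverged contigs, adapters, low-quality tails, biallelic variants).
- **pipeline / cli** — file-based orchestration with SHA-256 manifests and
  full end-to-end reproducibility under a fixed seed.

## Test

```sh
python -m pytest -q tests/
```

The suite includes independent oracles (exhaustive max-sum-substring search
for the trimmer, a literal rule-by-rule SNP-filter reimplementation,
single-pass top-hit selection against the step-down, closed-form 2×2
chi-square) and property tests for the documented invariants.

## CLI

```sh
divergescan simulate --config config.yaml --outdir out/
divergescan trim --fastq in.fq --out-fastq out.fq --out-log trim.tsv \
    --limit 0.05 --max-end-n 3 --adapters AGATCGGAAGAGC
divergescan ingest --blast hits.tsv --contigs contigs.fa \
    --cutoffs 1e-50,1e-25 --out-tophits top.tsv --out-summary chrom.tsv
divergescan outliers --tophits top.tsv --upper 99.98 --lower 0.02 \
    --out-scores scores.tsv --out-report report.json
divergescan snps --pileup pile.txt --window 11 --min-cov 10 --max-cov 60 \
    --min-freq 0.35 --out-snps snps.tsv --out-vcf snps.vcf
divergescan all --config config.yaml
```

A YAML config drives `all` (stage toggles, per-stage parameter blocks,
input paths, global seed); see `divergescan.pipeline.PipelineConfig`.

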