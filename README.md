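# sixframe

Build sample-specific six-frame **non-exon** protein databases from a
reference genome, gene annotation and called variants, and verify
mass-spectrometry-derived candidate peptides against them: unique non-exonic
genomic origin, sense/antisense orientation relative to the host gene,
flanking residues and tryptic context, minimal product length, and 8–14-mer
MHC-I epitope window enumeration for an external binding predictor.

## What it does

1. **`build-genome`** — incorporate filtered variants (VCF 4.x or
   VarScan2-style TSV, kept when `p-value < 0.01`) into the reference FASTA,
   producing the sample-specific genome plus a bidirectional liftover table.
2. **`build-sfdb`** — extract each gene's non-exon regions (gene span minus
   the exon union of all its transcripts, from an ENSEMBL-dialect GTF),
   translate them in all six reading frames (`f0 f1 f2` forward,
   `r0 r1 r2` reverse-complement) into stop-delimited segments, deduplicate,
   and write the six-frame database (SFDB) FASTA with genomic provenance.
3. **`verify`** — the exclusion funnel for candidate peptides: drop anything
   occurring in an annotated proteome FASTA (I/L-equivalent matching),
   exhaustively scan all six frames of every chromosome, and classify each
   survivor as `absent`, `multiple_occurrence`, `exonic` or
   `unique_nonexon`; unique hits are annotated with host gene,
   sense/antisense orientation, flanking residues (`X.PEPTIDE.Y`), tryptic
   termini and the minimal product length (peptide through the first
   downstream in-frame stop).
4. **`windows`** — enumerate all 8–14-mer windows over the flanked peptides
   and export them as a predictor peptide list or FASTA.
5. **`simulate`** — deterministic synthetic scenes (genome + GTF + VCF +
   proteome + candidate list + ground-truth manifest) for testing every
   stage offline.
6. **`run-all`** — the whole workflow with a machine-readable funnel summary.

## CLI quick start

```sh
sixframe simulate --out-dir scene --seed 1 --scenario funnel
sixframe run-all \
    --genome scene/genome.fa --gtf scene/genes.gtf \
    --variants scene/variants.vcf --peptides scene/peptides.tsv \
    --proteome scene/proteome.fa --out-dir out
cat out/funnel.json
```

Key options: `--p-threshold` (default 0.01), `--min-len` (default 7 aa),
`--per-frame` (one SFDB per reading frame), `--kmin/--kmax` (default 8/14),
`--minlen-from-upstream-stop`, `--no-cut-before-P`. A flat TOML config file
can hold defaults (`sixframe --config cfg.toml ...`); CLI flags override it.
Exit codes: 0 success, 2 input error, 3 stage failure.

## Layout

```
src/sixframe/
  reference_io.py    FASTA/GTF/variant readers, interval & strand utilities
  sample_genome.py   variant application + sample<->reference liftover
  sfdb_builder.py    non-exon extraction, six-frame translation, SFDB FASTA
  peptide_verify.py  proteome exclusion, genome scan, classification, report
  epitope_windows.py flanked peptides, 8-14-mer windows, predictor export
  synthfix.py        seeded fixture scenes with ground-truth manifests
  cli.py             click front-end
tests/               unit + property (hypothesis) + acceptance suites
scripts/acceptance.py
```

Coordinates are 1-based inclusive throughout, matching GTF.
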