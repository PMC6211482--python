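# File formats

All files are plain text; coordinates in files are **1-based** MSA columns
(the Python API is 0-based). Gap is `-`, unknown is `N`.

## Reference bundle (per gene, written by `IntegratedMsa.write` / `hlabayes simulate`)

- `<gene>.aln.fasta` — aligned FASTA; every record has exactly
  `n_columns` symbols over `ACGTN-`, in the integrated column space.
- `<gene>.meta.tsv` — `gene  allele  level` with `level ∈ {genomic, exonic}`.
- `<gene>.features.tsv` — `column  feature`; feature is `exonK`, `intronK`,
  `utr5`, or `utr3`.
- `<gene>.mask.tsv` — `allele  column  imputed`; only rows with
  `imputed=1` are written (imputed from the most similar genomic allele).
- `truth.json` (simulator only) — `{"alleles": {name: full sequence}}`.

## Reads

- `reads_1.fastq` / `reads_2.fastq` — standard FASTQ, Phred+33; mate ids
  share the stem and carry `/1`, `/2` suffixes.

## Frequency table (optional, `--frequencies`)

- TSV with header `gene  allele  frequency`. Frequencies are smoothed with
  pseudo-count 1e-3 and renormalized per gene.

## Run outputs (per target gene, written by `hlabayes genotype` / `run`)

- `<gene>.genotypes.tsv` — `gene  rank  allele1  allele2
  posterior_fraction`; unordered pairs ranked by posterior sample count.
- `<gene>.consensus.fasta` — the two inferred sequences in MSA columns;
  columns whose modal symbol fell below the support threshold are `N`.
- `<gene>.support.tsv` — `sequence  column  support` (modal fraction).
- `<gene>.placed.tsv` — accepted reads: `read_id  columns  symbols
  qualities`; `columns` is a comma list of covered columns (mates
  concatenated; inter-mate columns are simply absent = uncovered).
- `<gene>.filter.tsv` — `read_id  paired  s_star  s_bar_star  accepted`.
- `<gene>.trace.tsv` — `sweep  log_posterior  temperature  mh_accept` of
  the cold chain, preceded by a `# seed` line; `mh_accept` lists the latest
  Metropolis-Hastings outcomes (`u1`/`u2` = uncovered-position proposal per
  non-decoy component, `d` = decoy swap), `.` when none since last row.
- `manifest.json` — seed, per-stage record counts, software version.

## Reports

- somatic TSV — `gene  column  kind  normal  tumor  normal_support
  tumor_support`.
- germline TSV — `gene  column  kind  ref  obs  support  imputed`.
- LOH TSV — header comments `# flagged=…` and a note that the CI is a
  Woolf normal approximation with Haldane–Anscombe pseudocount 0.5
  (a reconstruction), then `gene  column  normal_a1  normal_a2  tumor_a1
  tumor_a2  log_or  ci_low  ci_high` at heterozygous SNP columns.
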