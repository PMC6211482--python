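# hlabayes

Bayesian HLA genotyping from sequencing reads, with personal HLA sequence
inference and somatic mutation / loss-of-heterozygosity (LOH) analysis of
paired normal–tumor samples.

The method works in two stages:

1. **Read collection.** Every candidate read is scored against every
   reference allele with an alignment log score (quality-weighted
   mismatches, affine gaps, N penalties, a per-base length reward). A read
   is kept for a gene when its best score there is high both absolutely and
   relative to the best score on any other gene; kept reads are realigned
   into an integrated multiple-sequence-alignment (MSA) column space that
   merges genomic and exonic-only reference alleles (missing non-coding
   sequence is imputed from the most similar genomic allele and flagged).
2. **Bayesian inference.** A hierarchical model couples a pair of database
   types `R` (plus decoy components that absorb off-target reads), personal
   sequences `S` generated from the types via a substitution/indel prior
   (looser at imputed reference columns), and per-read indicators `I`.
   The posterior is sampled by Gibbs sweeps plus two tailored
   Metropolis–Hastings proposals (a joint type/sequence jump through the
   sequence masked to `N` at uncovered columns, and a non-decoy/decoy swap),
   under parallel tempering with multi-start and reference-copy burn-in
   heuristics. Genotypes and consensus sequences are called by counting
   cold-chain samples; comparing paired runs yields germline variants,
   somatic mutations, and per-SNP depth log-odds LOH evidence.

A self-contained simulator generates mock allele databases and reads
(with planted somatic indels, allelic imbalance, contamination, and
reference misimputation), so everything installs and tests offline.

## Command line

```bash
# simulate a mock reference bundle + paired reads
hlabayes simulate --out demo --seed 1 --n-alleles 20 --depth 10

# extract candidate reads from an alignment (region + unmapped + mates)
hlabayes extract --alignment sample.bam --out-prefix demo/cand

# genotype (score -> filter -> realign -> MCMC -> calls)
hlabayes genotype --reference demo --reads1 demo/reads_1.fastq \
    --reads2 demo/reads_2.fastq --genes A --all-genes A,B \
    --seed 1 --out demo/normal

# paired-sample analyses
hlabayes somatic  --normal demo/normal --tumor demo/tumor --gene A --out somatic.tsv
hlabayes germline --normal demo/normal --reference demo --gene A --out germline.tsv
hlabayes loh      --normal demo/normal --tumor demo/tumor --gene A --out loh.tsv

# everything from one YAML config
hlabayes run --config run.yaml
```

Output schemas are documented in `FORMATS.md`. Every run writes a
`manifest.json` with the seed and per-stage read counts; identical config
and seed reproduce byte-identical outputs.

## Configuration notes

Scoring constants (`alpha_*`, `beta`, `theta_*`), model rates (`gamma_*`,
`delta_*`, `epsilon`), decoy count, and the MCMC schedule are all exposed
(`ScoreParams`, `Hyperparams`, `SamplerConfig`, or the YAML config). The
shipped defaults are package choices, not published values. Two practical
notes:

- The default pipeline scoring is *MSA-anchored*: one alignment per gene
  (to an anchor allele) projected into MSA columns, then every allele of
  the gene scored through the shared column space. `--full-scoring`
  switches to per-allele alignment (slower; the reference route).
- The alignment search uses stiffer gap costs than the scoring formula
  (`dp_gap_open`, `dp_gap_ext`) so that noisy read tails are not absorbed
  into spurious indels; the reported score still uses the `alpha` values.

Reads are treated strand-less (the simulator emits forward-strand pairs);
map real data to a reference first and extract candidates with
`hlabayes extract`, which is orientation-agnostic on the read sequence
stored in the alignment file.
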