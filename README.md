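# svcohort

Post-calling structural-variant (SV) cohort analysis for two-caller studies,
plus a fully synthetic cohort generator to exercise every stage end-to-end.

The package covers the downstream computations that follow SV calling in a
large diploid cohort:

- **Filtering** (`svcohort.filters`) — site-level rules for Smoove-style
  output (mean het site quality strictly > 3; carrier-median DHFFC < 0.7 for
  deletions, > 1.25 for duplications), universal rules (span > 0.5 Mb,
  off-whitelist contigs, 1-bp deletions), GATK-style hard filters for
  SNPs/indels, and affected-base / percent-of-genome accounting.
- **Sex inference** (`svcohort.sexinfer`) — X:autosome and Y:autosome depth
  ratios from per-chromosome depth summaries, classified into
  XX / XY / XYY-like / ambiguous (thresholds configurable).
- **Shared-SV identification** (`svcohort.concordance`) — same type, same
  chromosome, reciprocal overlap ≥ 90% of each record, genotype match ≥ 90%
  over comparable samples, no opposing homozygotes; greedy one-to-one
  resolution; merged records carry set-A genotypes by default.
- **Kinship-based genotype evaluation** (`svcohort.kinship`) — KING-robust
  kinship from dosages (φ = (N_HetHet − 2·N_OppHom)/(N_Het,i + N_Het,j)),
  and the resampling protocol correlating SV-based with SNP-based kinship
  over all sample pairs (fixed SNP baseline, repeated SV subsamples with
  replacement).
- **Chip overlap and tag SNPs** (`svcohort.ldtags`) — markers inside the
  affected interval; dosage-r² tag scan up to 10 kb from either SV edge,
  r² ≥ 0.8, stopping after five tags; count/percent summary tables.
- **Gene-feature overlap** (`svcohort.features`) — exon/CDS overlaps with a
  ≥ 10 bp minimum, and heuristic flagging of processed-pseudogene deletion
  artifacts (intron-matching deletion series sharing a carrier, het-only
  genotypes, elevated carrier exon coverage).
- **SV cards and tables** (`svcohort.cards`) — per-SV allele frequency,
  genotype counts, exact conditional Hardy–Weinberg p-value (full
  enumeration), shared status, overlap/tag results, optional sex-stratified
  genotype blocks; caller-level count and affected-base tables.
- **Synthetic cohorts** (`svcohort.simulate`) — pedigreed diploid cohort
  with Beta-distributed founder allele frequencies, Mendelian transmission
  with recombination, SV–SNP linkage at a configurable r² target,
  sex-dependent X/Y depth, two configurable pseudo-callers (boundary
  jitter, per-type genotype error, missingness, partial detection,
  DHFFC/MSHQ emission), and intron-matching pseudogene artifact injection.
  All outputs are deterministic given the config seed.

Coordinates are 1-based inclusive throughout; for symbolic DEL/DUP records
POS is the base before the event, so the affected interval is POS+1..END.
Dosages are 0/1/2 with −1 for missing. Samples are always aligned by ID.

## CLI

One entry point with a subcommand per stage:

```sh
svcohort simulate --out cohort/ --seed 1 --n-samples 60
svcohort filter --caller smoove --in cohort/calls_bravo.vcf \
    --out filtered.vcf --report report.tsv --chroms 1,2,3,X,Y
svcohort sex --depth cohort/depth.tsv --out sex.tsv
svcohort shared --a cohort/calls_alpha.vcf --b cohort/calls_bravo.vcf \
    --out shared.vcf --pairs pairs.tsv
svcohort kinship --sv cohort/calls_alpha.vcf --snp cohort/snps.vcf \
    --reps 100 --loci 2000 --baseline 2000 --seed 1 --out corr.tsv
svcohort tags --sv cohort/calls_alpha.vcf --snp cohort/snps.vcf \
    --manifest cohort/chip_dense.tsv --panel dense --out tags.tsv
svcohort overlap --sv cohort/calls_alpha.vcf --gtf cohort/genes.gtf --out ov.tsv
svcohort pseudoflag --sv cohort/calls_alpha.vcf --gtf cohort/genes.gtf --out flags.tsv
svcohort cards --sv cohort/calls_alpha.vcf --pairs pairs.tsv --sex sex.tsv \
    --gtf cohort/genes.gtf --out cards.jsonl
svcohort tables --a cohort/calls_alpha.vcf --b cohort/calls_bravo.vcf \
    --pairs pairs.tsv --genome-length 6000000 --out-dir tables/
```

All subcommands are byte-deterministic for a fixed seed.

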