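# methlink

An integrative epigenomics pipeline that identifies lncRNAs putatively
regulated by nearby differentially methylated regions (DMRs) and the
protein-coding transcripts those lncRNAs may regulate in cis. Starting from
Bismark-style per-cytosine CpG reports and a transcript read-count matrix,
it runs:

1. **Coverage filtering** — observations under 6× are treated as missing;
   sites must reach 6× in ≥50% of both groups.
2. **DMR calling** — smoothed per-CpG group differences, same-sign candidate
   runs, genome-wide max-statistic label permutations, BH q-values
   (externally called DMRs can be imported via `--dmr-bed`).
3. **Differential expression** — median-of-ratios size factors, two-group
   negative-binomial Wald tests with method-of-moments dispersion,
   BH adjustment; DE = padj < 0.05 and |log2FC| > 0.5
   (external DE tables via `--de-table`).
4. **Integration** — DE lncRNAs within 20 kb of a DMR whose expression is
   negatively correlated (p < 0.05) with the DMR's per-sample mean
   methylation, then DE protein-coding transcripts within 500 kb of such a
   lncRNA with a negative expression correlation (p < 0.05); emitted as a
   (DMR, lncRNA, protein) triplet table.
5. **Deconvolution** — cell-type fractions per sample by robust (Huber)
   regression of DMR-level betas on reference profiles, truncated to the
   simplex; rank-sum group comparison per cell type.
6. **Verification** — the lncRNA–protein pairs are re-correlated in
   independent normalized expression matrices and confirmation rates are
   summarized per lncRNA.

A synthetic-data module generates complete joint methylation/expression
studies (beta-binomial CpG counts with planted DMRs, NB expression with
lncRNA levels anti-coupled to DMR methylation and protein levels
anti-coupled to lncRNA levels, decoy transcripts, reference profiles,
external verification matrices) together with a machine-readable truth
table, so the whole pipeline is testable offline.

## CLI

One executable with per-stage subcommands:

```sh
# generate a synthetic study (11 case vs 13 control samples by default)
methlink simulate --seed 1 --out-dir study/

# full pipeline
methlink run-all --study-dir study/ --out-dir results/ --seed 1

# or stage by stage
methlink filter-cpg --meth-dir study/meth --samples study/samples.tsv --out sites.tsv
methlink call-dmrs --sites sites.tsv --samples study/samples.tsv --out-dir dmr/
methlink de --counts study/counts.tsv --samples study/samples.tsv --out-dir de/
methlink integrate --dmr-bed dmr/dmrs.bed --beta dmr/beta.tsv \
    --normalized de/normalized.tsv --de-results de/de_results.tsv \
    --annotation study/annotation.gtf --out-dir integ/
methlink deconvolve --beta dmr/beta.tsv --dmr-bed dmr/dmrs.bed \
    --reference study/reference_profiles.tsv --samples study/samples.tsv --out-dir dec/
methlink verify --pairs integ/triplets.tsv --annotation study/annotation.gtf \
    --dataset ext1=study/external_ds1.tsv --out-dir ver/
```

`simulate` accepts a YAML config (`--config cfg.yaml`) overriding any
`SimulationConfig` field (sample counts, genome, planted DMR geometry,
effect sizes, couplings, decoy counts, ...).

## Conventions

- All internal interval coordinates are 0-based half-open (BED-style); GTF
  input is converted on read; cytosine positions stay 1-based until the
  interval-overlap boundary.
- Strand is carried but ignored by distance/overlap computations.
- Correlation p-values are used raw for the discovery filters (matching the
  published rule); BH-adjusted values are reported as extra columns.

## Layout

```
src/methlink/
  io_formats.py     # readers/writers: CpG reports, GTF/BED, count matrices, DMR BED
  synthetic.py      # synthetic study generator + truth table
  methylation.py    # coverage filter, DMR caller, region beta matrix
  expression.py     # size factors, NB Wald DE, BH, DE selection
  integration.py    # windowed DMR->lncRNA->protein correlation cascade
  deconvolution.py  # reference-based robust-regression cell fractions
  verification.py   # cross-dataset confirmation of lncRNA-protein pairs
  pipeline.py       # run-all orchestration
  cli.py            # click CLI
tests/              # unit, property and acceptance tests
scripts/acceptance.py
```
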