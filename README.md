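# epilink

Integrative analysis linking chromatin-accessibility peaks to an
image-derived epithelial-tissue-proportion phenotype, mapping significant
peaks to candidate target genes, and stratifying patient prognosis from the
resulting gene set plus the image feature.

Stages (each is a module and a CLI subcommand):

1. **image_quant** — epithelial proportion from segmentation label masks
   (`Area_epi / (Area_epi + Area_stro)`), high/low classification at an
   inclusive 0.5 cutoff.
2. **screen** — per-peak Spearman correlation of accessibility with the
   proportion across samples; two-tailed p-values (exhaustive permutation
   enumeration for n ≤ 8, t-approximation with df = n−2 otherwise, seeded
   Monte-Carlo permutation on request); Benjamini–Hochberg FDR; significant
   set at FDR < 0.05 with sign classification.
3. **linking** — strand-aware promoter windows (100–1000 bp upstream of the
   TSS, summit containment, nearest-TSS tie-break) plus correlation-based
   distal links (< 500 kbp summit-to-TSS, BH FDR ≤ 0.01 across all candidate
   pairs) with copy-number-attenuation and promoter-overlap filters;
   collapse to signed target genes.
4. **enrichment** — one-sided hypergeometric over-representation of the
   positive/negative target-gene groups against GMT gene sets.
5. **survival** — univariate median-split Kaplan–Meier / log-rank screening
   of target genes and the image feature, then k-means (k=2, z-scored,
   seeded, 10 restarts) risk grouping of the significant features with a
   log-rank comparison.
6. **synthetic** — generators for cohorts, peak atlases, accessibility /
   expression / copy-number matrices, label masks, and proportional-hazards
   survival times with planted, recoverable structure and a JSON ground truth.

## CLI

```sh
# write a fully synthetic study bundle (TSVs + truth.json [+ masks])
epilink simulate --outdir demo --seed 1 --n-survival-samples 600 --masks

# individual stages
epilink quantify-image --masks-dir demo/masks --out demo/cohort_from_masks.tsv
epilink screen --accessibility demo/accessibility.tsv --cohort demo/cohort.tsv \
    --peaks demo/peaks.tsv --out demo/screen.tsv
epilink link --screen-results demo/screen.tsv --peaks demo/peaks.tsv \
    --genes demo/genes.tsv --accessibility demo/accessibility.tsv \
    --expression demo/expression.tsv --copy-number demo/copy_number.tsv \
    --cohort demo/cohort.tsv --links-out demo/links.tsv --targets-out demo/targets.tsv
epilink survive --features demo/survival_expression.tsv --survival demo/survival.tsv \
    --cohort demo/survival_cohort.tsv --out demo/univariate.tsv

# everything at once from a YAML config (see epilink.pipeline.PipelineConfig
# for the keys; thresholds default to the published analysis constants)
epilink run-all --config config.yaml
```

Exit codes: 0 ok, 2 validation failure, 3 stage error. `run-all` writes
per-stage TSVs, the resolved config, and `report.json` with the stage funnel
counts.

## File formats

Plain text throughout: peaks as a headered TSV (`peak_id chrom start end
summit`; BED 0-based half-open, absolute summit) or BED6+1 (7th column =
summit offset); genes as `gene_id chrom tss strand` (1-based TSS; a
GFF3 converter is provided as `epilink.io.gff3_to_genes`); matrices as
feature × sample TSV; cohort as `sample_id proportion [group]`; survival as
`sample_id time_days event`; gene sets as GMT; masks as 8-bit label PNGs
(0 = background, 1 = epithelial, 2 = stromal).

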