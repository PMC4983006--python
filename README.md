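# isoscope

Isoform-level expression analysis for tumor/normal cohorts:

* **Expression summaries** — ingest RSEM-style fraction-of-transcripts
  matrices (values in [0, 1]) with a sample sheet, average per-patient
  replicates, and compute per-group boxplot statistics (Tukey fences,
  type-7 quantiles) and median TPM (group median × 10⁶).
* **Major-isoform calling** — per gene and (cohort, tumor/normal) group, the
  isoform with the highest median TPM wins; all-zero medians fall back to Q3,
  residual ties to the lexicographically smallest transcript id.
* **Tumor-specific isoform screening** — *type1* isoforms are expressed in
  tumor (median TPM > 1e-6) and absent in the matched normal, subdivided into
  strong (≥ 1.0 TPM and ≥ 10 % of the gene's tumor expression, both inclusive)
  and weak; *type2* isoforms are tumor-major but not normal-major with a
  median-TPM fold change strictly > 2. Screening requires ≥ 10 normal
  patients. All thresholds are configurable.
* **Consistency census** — per group, genes partition into silent, matched
  (major isoform equals at least one of the UniProt/UCSC canonical or APPRIS
  principal isoforms), mismatched, and no-canonical-defined buckets, with
  parallel subcounts for genes whose major isoform has median TPM ≥ 1, plus a
  percent-increase report (one decimal, half away from zero).
* **Variant annotation** — map VCF variants onto transcript structure
  (E#/I# numbered from the transcription start site, 5U/3U, OTR), predict SNV
  consequences (synonymous/missense/nonsense/stop-lost) against any
  transcript backbone, and emit nine `IE_*` VCF fields: four header-level
  (`IE_TS`, `IE_CA`, `IE_SA`, `IE_SN`) and five per-record (`IE_GE`, `IE_UP`,
  `IE_UC`, `IE_AP`, and the expression-sorted isoform list `IE_IS`).
  A backbone-comparison module tallies how interpretation shifts between the
  canonical and the major isoform (concordant, amino-acid change,
  relocation to intron/5U/3U/OTR, exon renumbering).
* **Synthetic fixtures** — deterministic generators (genome FASTA, genePred
  models, canonical/xref TSVs, expression matrix, sample sheet, VCF) with
  designed structure so every stage is testable offline.

Inputs are plain text: genePred TSV (0-based half-open coordinates), FASTA,
header-bearing TSV side tables, and VCF 4.x. VCF positions are converted to
0-based exactly once, at ingestion.

## CLI

```sh
# write a complete synthetic input set
isoscope simulate --out demo --seed 7

# per-gene expression view (TSV + JSON)
isoscope view --models demo/models.genepred --expression demo/expression.tsv \
    --samples demo/samples.tsv --canonical demo/canonical.tsv \
    --xrefs demo/xrefs.tsv --gene-info demo/gene_info.tsv \
    --gene FOXT1 --out view.tsv

# tumor-specific isoform screening
isoscope tsi --models demo/models.genepred --expression demo/expression.tsv \
    --samples demo/samples.tsv --cohort LUAD --out tsi.tsv

# major-vs-canonical consistency census
isoscope consistency --models demo/models.genepred \
    --expression demo/expression.tsv --samples demo/samples.tsv \
    --canonical demo/canonical.tsv --cohort LUAD --class tumor --out census.tsv

# expression-prioritized VCF annotation
isoscope annotate --models demo/models.genepred \
    --expression demo/expression.tsv --samples demo/samples.tsv \
    --canonical demo/canonical.tsv --xrefs demo/xrefs.tsv \
    --vcf demo/variants.vcf --genome demo/genome.fa \
    --cohort LUAD --class tumor --out annotated.vcf
```

Every command accepts `--config config.yaml` (flags win over config values;
unknown keys are rejected), logs to stderr only, and removes partial outputs
on failure. `isoscope tsi --help` documents every screening threshold and its
default.

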