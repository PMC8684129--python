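# chromstrat

Unsupervised stratification of tumor cohorts by chromatin accessibility,
with downstream signature, motif and association analyses — plus a
synthetic-cohort generator so the entire pipeline can be verified at desk
scale without any data downloads.

## The problem

Bulk ATAC-seq of tumor cohorts (e.g. breast carcinomas) yields per-sample
accessibility tracks and peak calls. Accessibility patterns alone can
stratify tumors into biologically meaningful groups — basal-like vs
luminal programs, invasive-lobular-like subsets — and localize the
differences to transcription-factor motifs (SOX in basal-like tumors, FOX
in hormone-receptor-positive tumors), whose accessibility can in turn
track disease stage and the expression of chromatin regulators such as
the H2A.Z chaperone ANP32E. `chromstrat` implements that analysis as a
tested, reusable pipeline:

1. **Union peak matrix** — merge per-sample peak calls into the base-pair
   union (book-ended intervals merge) and score each tumor's
   read-normalized track over every union region (length-weighted mean).
2. **Rank normalization** — within each tumor, regions are ranked from
   minimum to maximum accessibility (fractional ranks; ties get the mean
   rank), removing per-sample scale.
3. **Stratification** — 2-D UMAP of the rank columns
   (`n_neighbors = 10`), then k-means on the embedding (default `k = 3`)
   with labels ordered by separation along UMAP dimension 2.
4. **Chromatin signatures** — for group *g*, per-region
   `log2FC = log2((mean_in + 1) / (mean_out + 1))` of raw accessibility
   (pseudo-count 1); the signature is every region with `log2FC > 2.5`
   (strict). Annotations: distance from region midpoint to nearest TSS,
   CpG dinucleotide density, genes with a TSS within 1 Mb of the
   midpoint, and a size-matched random background (length-decile strata,
   default n = 5000).
5. **Motifs** — PWM/consensus scanning of accessible regions (log-odds vs
   background base frequencies, both strands, hits at ≥ 80 % of the
   maximum score; N windows never hit), binomial enrichment of signatures
   vs background, per-sample *motif accessibility* (mean accessibility
   over motif-bearing regions), and binned profile matrices around motif
   centers (all-zero windows excluded from column means).
6. **Associations** — one-tailed Welch t-tests across tumor stages
   (stars: `*` p<0.01, `**` p<0.001, `***` p<0.0001), Pearson
   correlations of regulator expression vs motif accessibility, the
   luminal-marker exclusion filter (drop samples in the bottom quartile
   of **both** FOXA1 and GATA3; type-7 quantile, `≤ cut`), divergent-gene
   lists, and top/bottom expression-decile tables prepared as input for
   gene-set enrichment scoring.

The synthetic generator (`chromstrat.simulate`) plants all of this
structure — latent groups with private open regions, motif consensi
written into a generated genome, a stage-graded accessibility increase at
one motif family's sites, and a regulator gene anticorrelated with that
family's accessibility — and stores the ground truth, so group recovery,
signature precision/recall, stage trends and the regulator correlation
are all checkable quantities.

## Worked example

```yaml
# example.yaml
seed: 7
outdir: example_out
simulate:
  n_tumors_per_group: [20, 20, 20]
  n_regions: 2000
  n_signature_per_group: 100
  genome_length: 1600000
  chrom_count: 3
  region_length: 400
  n_genes: 100
analysis: {n_neighbors: 10, k_groups: 3, background_n: 1000}
```

```bash
chromstrat run-all --config example.yaml
```

writes the cohort, matrices, groups, signatures and report under
`example_out/` and prints the summary, including (seed 7):

```
"group_sizes":       {"1": 20, "2": 20, "3": 20}
"signature_counts":  {"1": 100, "2": 100, "3": 100}
"motifs": {
  "SOX":  {"group1_fold": 2.2989, "group1_p": 2.5e-20, ...},
  "FOX":  {"group2_fold": 2.4024, "group2_p": 1.2e-21, ...},
  "CEBP": {"group3_fold": 2.2599, "group3_p": 8.3e-20, ...}}
"ANP32E_vs_FOX_accessibility": {"r": -0.5402, "p": 8.4e-06}
"basal_filter": {"kept": 49, "removed": 11}
```

Reading this: the three chromatin groups are recovered at their planted
sizes; each group's signature contains exactly its 100 planted regions;
each motif family is enriched in its owning group's signature relative to
the size-matched background (fold ≈ 2.3 ≈ the planted 0.8 in-signature
carrier rate over the 0.35 background rate); ANP32E expression is
anticorrelated with FOX-motif accessibility near the planted coupling of
−0.5; and the marker-quartile filter removes predominantly the basal-like
group's tumors.

Every stage is also available as its own subcommand
(`simulate`, `build-matrix`, `rank`, `stratify`, `signatures`,
`motifs scan|enrich|access`, `assoc stage|corr|basal-filter|divergent|deciles`);
see `chromstrat --help`.

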