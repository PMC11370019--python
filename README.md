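# vgccraft

Headless toolkit for exploring cohort VCF files: sidecar indexing,
gene/range/batch variant queries, local ClinVar-style pathogenicity
annotation, gnomAD link construction, and case–control association via
Fisher's exact test (exact enumeration and Monte Carlo, default 2000
iterations). It also builds the data models behind histogram, node-graph
and heat-map views (no rendering), and ships a deterministic synthetic
cohort generator so the whole pipeline is testable offline.

## Concepts

* **Sidecar index** — `vgccraft index cohort.vcf --root DIR` writes
  `DIR/VGCGeneratedFiles/VGC_cohort/info_cohort.txt` (file-level summary,
  key=value) and `index_cohort.txt` (TSV: per-chromosome line span,
  position span, PASS count, pathogenic count). Subsequent queries read
  only the relevant chromosome's line span. The index is invalidated
  automatically when the VCF's size or mtime changes.
* **Filters** — every query accepts `--filter all|pass|pathogenic`.
  `pathogenic` requires a local ClinVar-style TSV
  (`chrom pos ref alt clinical_significance [condition review_status]`);
  the labels Pathogenic, Likely pathogenic and
  Pathogenic/Likely pathogenic count as pathogenic.
* **Association** — per variant, a groups × {HOM_REF, HET, HOM_ALT}
  contingency table is built from a phenotype TSV (`sample_id group`);
  missing genotypes are excluded and tallied. The two-sided p-value is
  computed under the fixed-margin hypergeometric null, by Monte Carlo
  sampling with the (1+k)/(B+1) estimator (never 0, deterministic per
  seed) and optionally by exact enumeration (`--exact`, table totals
  ≤ 500). Raw p-values only; no multiple-testing correction is applied.
* **Genotype classes** — multi-allelic calls collapse by alt-allele
  count (0 → HOM_REF, 1 → HET, 2 → HOM_ALT); haploid calls are treated
  as homozygous; any `.` allele is MISSING and >2 alleles per call is an
  error.

## CLI

```bash
vgccraft simulate --preset preeclampsia-shape --seed 1 --out sim/
# -> sim/cohort.vcf (143 samples: 61 cases / 82 controls), phenotypes.tsv,
#    genes.tsv, clinvar.tsv, genesets.gmt, truth.json

vgccraft index  sim/cohort.vcf --clinvar sim/clinvar.tsv --root sim/
vgccraft info   sim/cohort.vcf --root sim/
vgccraft query  sim/cohort.vcf --gene TTN --catalog sim/genes.tsv \
                --clinvar sim/clinvar.tsv --root sim/ --out ttn.csv
vgccraft query  sim/cohort.vcf --range 1:1-2000000 --filter pass --root sim/
vgccraft assoc  sim/cohort.vcf --pheno sim/phenotypes.tsv --range 1:1-2000000 \
                --seed 1 --iterations 2000 --root sim/ --out assoc.csv
vgccraft hist   sim/cohort.vcf --root sim/ --json hist.json
vgccraft graph  sim/cohort.vcf --pheno sim/phenotypes.tsv --range 1:1-2000000 \
                --root sim/ --json graph.json
vgccraft plan show plan.txt
```

Query results export to csv/tsv/xlsx (`--out`, format from extension);
`--save-plan FILE` writes a reusable key=value analysis plan. Batch files
hold one gene symbol or `chrom:start-end` per line (`#` comments allowed).
Chromosome names match with or without a `chr` prefix everywhere.

## Layout

| module | role |
|---|---|
| `vcf_model` | VCF header/data-line parsing, genotype classes, sortedness checks |
| `indexer` | sidecar index build / persist / load |
| `gene_catalog` | gene spans + exons, exonic/intronic classification |
| `query_engine` | gene/range/batch queries, filters, analysis plans |
| `annotation` | ClinVar-style join, gnomAD URLs, GMT gene sets |
| `association` | contingency tables, exact & Monte Carlo Fisher tests |
| `viz_data` | histogram + zoom, node graph, genotype matrix models |
| `export` | csv/tsv/xlsx result tables |
| `fixtures` | deterministic synthetic cohort generator |
| `cli` | `vgccraft` entry point |
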