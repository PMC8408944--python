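# sibflow

Lineage-resolved single-cell bifurcation analytics for early-embryo
scRNA-seq, plus a synthetic-data generator with machine-readable planted
truth so the whole pipeline is testable offline.

The package covers five analysis stages and one data stage:

| module        | what it does |
|---------------|--------------|
| `syndata`     | lineage-structured negative-binomial UMI counts with per-mother batch offsets and treatment-dependent state ablation; per-mother SNP genotypes with dropout/error; promoter sequences with planted motif densities; plain-text fixture bundles |
| `core_expr`   | per-stage detected-gene cell filtering, median-depth log1p normalization with per-gene batch-mean equalization, pseudo-bulk, Wilcoxon rank-sum DE (exact for small groups), PCA with a deterministic sign convention, nearest-centroid label transfer |
| `demux`       | mother-of-origin assignment: pairwise Ajk relatedness from SNP dosages, agglomerative clustering cut at the known number of adults, within-cluster outlier flagging, mother-batch regression |
| `bifurcation` | lineage-tree analytics: chi-square treatment-sensitivity scores with descendant summation and exclusion propagation, the five-way trio mechanism classifier (±0.3475 log2 thresholds), the induction metric (per-sibling share of TF upregulation mass), sibling centroid distances, response-TF fold-change matrices |
| `motif`       | log-odds PWMs from JASPAR PFMs, exact p-value calibration by dynamic programming, double-stranded scanning, best-in-window hit de-duplication, binomial enrichment z-scores on dual region sets (1500-bp upstream windows + overlapping ATAC peaks) with z averaging, peak-to-nearest-gene tallies, the 4-variable direct-vs-relay signature |
| `waves`       | per-stage enriched-gene unions, Ward clustering of pseudo-bulk temporal profiles into expression waves, motif-enrichment time courses |

## CLI

Every stage is exposed under a single `sibflow` entry point:

```sh
# write a synthetic fixture bundle (MTX counts, dosage TSV, FASTA/GFF3/BED,
# JASPAR PFMs, lineage edge list, truth JSON)
sibflow simulate --seed 17 --outdir fixtures/

# mother-of-origin demultiplexing from a dosage TSV or VCF
sibflow demux --genotypes fixtures/dosages.tsv --k 3 --out labels.tsv

# Wilcoxon DE between two cell states
sibflow de --counts fixtures/ --group-a A1 --group-b A2 --min-lfc 0.3 \
    --alpha 0.05 --out de.tsv

# sensitivity scores, trio mechanism categories, induction metrics
sibflow bifurcate --tree fixtures/lineage.tsv --counts fixtures/ --outdir bif/

# motif over-representation of target vs control gene sets
sibflow tfbs --genes-up up.txt --genes-down down.txt --genome fixtures/genome.fa \
    --gff fixtures/models.gff3 --peaks fixtures/peaks.bed \
    --pwm fixtures/motifs.jaspar --out tfbs.tsv

# temporal wave clustering of a gene x stage pseudo-bulk table
sibflow waves --profiles noto.tsv --k 5 --out waves.tsv
```

`sibflow simulate --config sim.json` accepts a JSON object overriding any
simulation field (cell numbers, mothers, dispersion, planted effects, ...).

## Notes

- All file formats are plain text: Matrix Market + TSV for counts, TSV
  dosages with `NA` for missing, BED is 0-based half-open, GFF3 is 1-based
  on disk and converted on read, dendrograms serialize to Newick.
- Determinism: every stochastic routine takes an explicit seed; identical
  seeds give byte-identical fixture bundles.
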