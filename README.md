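# leafatac

Integrative analysis of chromatin-accessibility dynamics and gene expression
across staged leaf development, driven by a synthetic-data generator that
plants known ground truth.

Chromatin accessibility — measured by ATAC-seq as accessible chromatin
regions (ACRs) — shapes where transcription factors can bind, and changes in
promoter accessibility across developmental stages track changes in gene
expression.  `leafatac` implements the full analysis arc of such a study for
a three-stage (BBCH_11, BBCH_13, BBCH_17), two-replicate design:

* **ACR landscape** — replicate consolidation (≥1 bp reciprocal overlap,
  union merge), feature-category classification (promoter > 5'UTR > 3'UTR >
  exon > intron > intergenic at the peak summit; promoter = 2 kb upstream of
  the TSS), fold enrichment against a length-matched random-placement null
  (empirical p with +1 correction), and the chromosome-density relation
  *normalized chromatin length = total peak count × chromosome length /
  genome length* correlated with per-chromosome ACR counts.
* **Stage specificity** — the tri-stage peak union partitioned into common
  (all stages), stage-specific (one stage) and partial (two stages) ACRs.
* **Differential testing** — a self-contained negative-binomial Wald test
  (median-of-ratios size factors, trend-shrunk method-of-moments
  dispersions, BH adjustment) applied to common-ACR Tn5 counts
  (differential peak intensity, DPI) and to exon counts (differential
  expression, DEG), significant at adjusted p < 0.05 and |log2FC| > 1.
* **Promoter–expression coupling** — promoter-ACR assignment (nearest TSS on
  conflicts), expression by ACR count {0,1,2,3+}, tie-balanced ACR-length
  tertiles, expression-bin × association-class tables, and per-gene Pearson
  correlation of stage-level peak intensity with stage-level FPKM.
* **Clustering & integration** — k-means clustering of the DEG union into
  eight expression patterns (archetype-matched labels), Fisher overlap of
  stage-specific-ACR genes with clusters, DPI × DEG concordance quadrants
  (discordant genes suggesting repressor binding), and IUPAC consensus-motif
  enrichment in target promoter ACRs.

Because the original study's raw libraries are not deposited, the package is
organised as an analysis over synthetic data: `leafatac.simulate` generates
a miniature genome, peak calls, NB count matrices, coupled expression
tables, fragment files and motif-bearing sequences with every effect planted
and recorded in a truth set, so each analysis stage is validated by how well
it recovers what was planted.

## Worked example

```python
from leafatac.simulate import SimConfig, generate_dataset
from leafatac.pipeline import run_pipeline, evaluate_recovery

ds = generate_dataset(SimConfig(seed=0))      # 2 Mb genome, 300 genes, 600 ACRs
res = run_pipeline(ds, seed=0)
print(res.partition.sizes())
print(evaluate_recovery(res, ds.truth).as_dict())
```

prints

```
{'common': 500, 'partial': 0, 'specific:BBCH_11': 60, 'specific:BBCH_13': 20,
 'specific:BBCH_17': 20}
{'specificity_recall': 1.0, 'common_recall': 1.0,
 'promoter_assignment_recall': 1.0, 'cluster_ari': 0.988,
 'discordant_recovery': 0.933, 'dpi_recall': 0.928,
 'dpi_sign_agreement': 1.0, 'fraction_positive': 0.824, 'median_r': 0.951}
```

— the consolidated tri-stage partition recovers every planted shared and
stage-specific ACR; 92.8% of planted intensity effects are called
significant with the right sign; the eight planted expression archetypes are
recovered at adjusted Rand index 0.99; 14 of the 15 planted
accessible-but-repressed genes land in the discordant integration quadrants;
and among genes with a common promoter ACR, 82% correlate positively
(median r = 0.95) between stage-level promoter intensity and expression.

The numbered scripts under `analysis/` walk the same pipeline step by step
(`01_simulate.py` … `06_cluster_integration.py`), printing what each stage
found and writing tables under `results/`.  Each takes an optional seed
argument (default 0).

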