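# sepalcoord

Analysis toolkit for studying how plant hormone signaling coordinates sepal
growth in *Arabidopsis* flower buds, built around comparative single-cell /
spatial transcriptomics of a wild-type vs. mutant contrast (e.g. the
*drmy1* loss-of-robustness mutant) and confocal reporter imaging.

## Who this is for

Plant developmental biologists who have:

- cellranger-style single-cell count matrices (MatrixMarket triplet) with
  per-cell genotype/cluster labels,
- hormone-response gene sets (genes up- or down-regulated by exogenous
  hormone application),
- spatial (Visium-style) spot counts with a spots-by-clusters
  prediction-score matrix from reference-based deconvolution,
- per-nucleus ratiometric reporter tables (e.g. BES1/H2B) exported from
  mesh software, and/or
- lineage-tracked per-sepal area time series,

and want the downstream statistics: per-cell hormone signature scoring,
cluster-level genotype contrasts with family-wise error control, spot
cluster-proportion summaries, per-sepal reporter mean/CV comparisons, and
sepal growth-coordination metrics.

## The statistics at the core

**Hormone signature fraction.** For cell $c$ and gene set $S$,

$$f_{c,S} = 100 \cdot \frac{\sum_{g \in S} x_{gc}}{\sum_g x_{gc}}$$

the percentage of the cell's raw transcripts originating from $S$. Higher
signaling of a hormone raises $f$ for its up-regulated set and lowers $f$
for its down-regulated set; discordant shifts of the two sets are read as a
directional signaling change.

**Cluster contrasts.** Within each cluster, mutant and reference cells are
compared per gene set with a two-sided Wilcoxon rank-sum test (exact null
enumeration for combined $n \le 20$ without ties, otherwise the normal
approximation with tie and continuity corrections). With $K$ clusters and
$m$ sets the per-row significance threshold is the Bonferroni-corrected
$\alpha/(K m)$; a 17-cluster, 12-set analysis at $\alpha = 0.05$ tests at
$p < 0.000245$. Dot-plot statistics follow the same convention: size
$= \log_{10}(1/p)$, color $=$ mutant-minus-reference mean difference, and
star annotations use nested per-cluster thresholds $\{0.05, 0.01, 0.001,
0.0001\}/K$.

**Cell-cycle variance filter.** Cells are phase-scored with a binned
control-gene module score on $\ln(1 + \mathrm{CP10K})$ expression; any gene
whose one-way ANOVA $R^2$ on phase exceeds 3% is deleted (plus all
mitochondrial genes) before hormone scoring, so proliferation signal cannot
masquerade as a genotype effect.

**Reporter and growth metrics.** Per nucleus, the ratio of a
hormone-responsive nuclear signal to a constitutive one (BES1/H2B); per
sepal, the mean ratio and its CV (sample sd / mean). Per bud interval, each
sepal's absolute area increase divided by the summed increase of all sepals
(growth contribution, summing to 1), and outer/inner area ratios with two
inner sepals merged before division.

A synthetic-data generator (`sepalcoord.synthetic`) emulates all of these
inputs with recorded ground truth, so the full pipeline runs and is tested
without any external download.

## Worked example

Simulate a two-genotype, five-cluster dataset in which the mutant carries a
raised latent brassinosteroid signaling level in cluster 1, then run QC and
the cluster contrast:

```python
import sepalcoord as sc

matrix, truth = sc.simulate_sc(sc.ScSimConfig(seed=1))
retained, removals = sc.filter_cells(matrix)
matrix = matrix.select_cells(retained)

fractions = sc.score_cells(matrix, truth.universe.gene_sets())
table = sc.contrast_clusters(
    fractions, matrix.cell_meta["cluster"], matrix.cell_meta["genotype"],
    reference="WT", mutant="drmy1")
print(f"Bonferroni family: {table.attrs['n_tests']} tests, "
      f"threshold p < {table.attrs['bonferroni_threshold']:.3g}")
print(table[table["significant"]]
      [["cluster", "hormone", "direction", "diff", "p", "stars"]]
      .to_string(index=False))
```

prints

```
Bonferroni family: 20 tests, threshold p < 0.0025
 cluster         hormone direction      diff            p  stars
       1 brassinosteroid        up  0.571855 1.829869e-32      4
       1 brassinosteroid      down -0.393733 2.243211e-31      4
```

Exactly the planted (cluster, hormone) pair is flagged, with the up-set
fraction higher and the down-set fraction lower in the mutant — the
signature of elevated brassinosteroid signaling — and no false calls in the
18 null rows. `sc.infer_direction` turns such a concordant pair into a
strong `higher_in_mutant` call.

The same analyses are available from the shell:

```bash
sepalcoord simulate sc --seed 1 --out sim/
sepalcoord qc --matrix sim/ --out out/qc
sepalcoord score --matrix sim/ --sets sim/hormone_sets.tsv --out out/score
sepalcoord run --seed 1 --out out/full     # all seven stages end-to-end
```

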