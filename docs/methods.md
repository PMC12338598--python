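# Methods

This note documents the models, conventions, and numerical choices behind
`sepalcoord`, and what the synthetic-data suite does and does not
demonstrate.

## The fraction statistic and its contrasts

All expression scoring rests on one primitive: the percentage of a cell's
(or spot's) raw transcripts that originate from a gene set. It is computed
on raw counts — the statistic is a within-cell composition, so library-size
normalization is unnecessary by construction, and no log transform is
applied. Unknown gene-set identifiers are ignored with a warning rather
than raised, so published set lists containing genes absent from a given
reference still run.

Genotype contrasts treat cells as the sampling units within each cluster
(a replicate-aware mode is deliberately out of scope; replicate labels are
carried through for inspection). The Wilcoxon rank-sum test switches
between exact null enumeration and the normal approximation at a combined
sample size of 20: below it, and only for tie-free data, the exact
distribution is used; otherwise the approximation with tie-corrected
variance and continuity correction. The switch point keeps the exact branch
exhaustively testable (all tie-free shapes with combined n ≤ 10 are checked
against an independent enumeration oracle) while matching how the test is
normally run on hundreds of cells.

Two Bonferroni families coexist, both always derived from the inputs rather
than hard-coded: the per-row significance threshold divides alpha by
(number of clusters × number of sets) — with 17 clusters and 12 hormone
sets at alpha = 0.05 this is 0.05/204 ≈ 0.000245 — while the nested star
annotations divide the base levels {0.05, 0.01, 0.001, 0.0001} by the
number of clusters only (0.00294, 0.00059, 0.000059, 0.0000059 at 17
clusters). Both family sizes are written into the output header. P-values
are never clipped; p = 1 gives a dot size of exactly 0.

Directional inference reads the up/down set pair jointly: a significant
rise of the up set or fall of the down set in the mutant is evidence for
higher signaling (symmetrically for lower); concordant evidence from both
sets gives a strong call, one set a weak call, conflict or silence an
inconclusive one.

## QC conventions

All four cell filters are strict inequalities — detected genes strictly
greater than `min_genes` (default 600) and strictly less than `max_genes`
(6000), mitochondrial percentage strictly below 10, chloroplast strictly
below 20 — applied symmetrically because the gene-count rule is stated as
a strict bound and the organelle rules give no reason to differ. Detected
genes means count > 0, with no minimum-count threshold. Protoplast-artifact
candidates are the set difference between genes detected in the single-cell
data (count > 0 in at least `min_cells` cells, default 1) and genes
expressed in a bulk reference.

## Cell-cycle scoring and filtering

Phase scores use a binned control-gene module score on ln(1 + CP10K)
expression: genes are ranked by mean expression into `n_bins` = 24
equal-frequency bins, and each target gene draws `n_ctrl` = 100 control
genes uniformly from its bin excluding all targets (with replacement only
when the bin is smaller than `n_ctrl`). The score is the mean target
expression minus the mean of all drawn controls, per cell. Control sampling
is seeded and the seed is recorded in the report header. Phase calls: G1
when neither score is positive, otherwise the larger score's phase, with a
positive tie going to S — a deterministic rule; ties are measure-zero on
real data.

The filter deletes any gene whose one-way ANOVA R² (SS_between/SS_total,
computed on the same log-normalized scale; the scale choice is logged in
the report header) against phase labels strictly exceeds the threshold
(default 0.03), plus all mitochondrial genes. R² of a constant gene is
defined as 0. The rule is deletion, not regression of residuals: regressing
out phase was considered and rejected in favor of the simpler, more
transparent filter.

## Spatial conventions

Deconvolution itself is an input: the module consumes a spots × clusters
prediction-score matrix and takes the per-spot argmax (ties to the lowest
cluster label in sort order, logged; all-zero rows labeled `unassigned`).
Cluster proportions per genotype are fractions of **all** spots of that
genotype, including spots of clusters that the < `min_spots` (default 10)
rule omits from the output table — omission affects what is reported, not
the denominators — and including `unassigned` spots (choice logged).
Capture-area QC flags an area when its median spot mitochondrial fraction
exceeds `area_flag_factor` (default 2.0) times the median of the other
areas' medians; the published analysis made this call visually, so the
factor is exposed and logged. Spot coordinates are carried as 0-based
(col, row) array indices; no hexagonal geometry is computed.

## Reporter summaries

Per-nucleus ratio = responsive signal / constitutive signal, requiring a
strictly positive denominator. Per-sepal CV uses the sample (n − 1)
standard deviation because per-sepal nucleus counts are small; sepals with
fewer than `min_nuclei` = 5 nuclei are dropped with a warning (a floor
against degenerate CVs; the choice is recorded in the output header).
Group comparisons are two-sided Wilcoxon rank-sum tests on per-sepal
values, overall and stratified by sepal position.

## Growth metrics

Absolute growth per sepal over consecutive observed intervals is
A(t1) − A(t0) with no interpolation; time is in hours, areas in μm².
Negative deltas are clamped to zero and flagged: sepals at these stages
grow monotonically, so shrinkage indicates segmentation error. Growth
contributions divide each sepal's delta by the bud-interval total and sum
to 1 exactly whenever total growth is positive. In outer/inner **area**
ratios, two inner sepals are first summed into one (preventing a split
inner from inflating the ratio); outer/lateral ratios are per lateral
sepal. Single-timepoint **length** ratios use the single measured inner
length. Buds with no inner sepal observed by the second timepoint are
excluded from growth analysis (initiation variability, not elongation, is
then the dominant signal). Per-cell growth ratios over a lineage map
preserve raw values and add a display column clamped to (0, 2.5) for
heat-map rendering only.

## The synthetic-data generator

`simulate_sc` draws each cell's counts as a multinomial over genes given a
log-normal library size. Expected proportions are a per-cluster baseline
profile (gamma(2,1) gene weights with per-cluster log-normal jitter,
sd 0.4) modified by (i) a multiplicative phase effect (default 3×) on the
phase gene sets in cells of the matching phase, and (ii) hormone folds
1 + βh on up sets and max(0.05, 1 − βh) on down sets, where h is the cell's
latent signaling level ~ Normal(μ[genotype][cluster], 0.5). The 0.05 floor
keeps all rates positive however large βh grows. Organelle genes are
pinned to fixed expected fractions (3% mito, 5% chloroplast). The
multinomial-given-library-size model (rather than per-gene negative
binomial) directly matches the compositional fraction statistic under
test; overdispersion beyond the multinomial is not simulated. Defaults —
1200 genes, 5 clusters × 150 cells per genotype, genotypes WT and drmy1,
libraries ~ lognormal(log 6000, 0.25), brassinosteroid β = 0.25 with a
latent shift of +1.0 in mutant cluster 1, auxin β = 0 as an
in-simulation null — are sized so the full seven-stage pipeline runs in a
few seconds while cells still pass the 600-gene QC floor, as real cells
do.

`simulate_spots` mixes the cluster profiles (evaluated at each genotype's
latent means, so a planted single-cell effect surfaces in the spot
mixtures) with Dirichlet(0.5) weights, draws Poisson counts, and emits
prediction scores as Dirichlet-resampled true weights with concentration
50 (infinite/None concentration returns the true weights — the noiseless
limit). `simulate_nuclei` draws per-nucleus ratios from a gamma
distribution with the group's exact target mean and CV (gamma keeps ratios
positive and parameterizes both moments directly; CV = 0 degenerates to a
constant), H2B totals log-normal, and BES1 = ratio × H2B.
`simulate_growth` uses A(t) = A(0)·e^{gt} with multiplicative log-normal
noise (default sd 2%) and per-position rates (default outer 0.06, inner
0.02, lateral 0.03 per hour from equal 100 μm² initial areas).

One global seed feeds every generator through deterministically derived
substreams, so identical seeds give byte-identical outputs.

**What the generator does not emulate:** read-level noise, UMI errors,
doublets, ambient RNA, overdispersion beyond multinomial/Poisson sampling,
spatial autocorrelation between neighboring spots, imaging point-spread or
segmentation artifacts, and real gene–gene correlation structure. Tests
passing on this suite show the statistics are implemented correctly and
calibrated under their own model assumptions — not that those assumptions
hold in any particular real dataset.

## Problem sizes and calibration experiments

The validation experiments run at desk scale, chosen once for statistical
adequacy:

- **Null calibration**: 200 replicate datasets (3 clusters × 40 cells per
  genotype, 200 genes, all β = 0). Under the all-null simulation the
  Bonferroni-corrected contrast's family-wise error sits slightly below
  alpha (the continuity-corrected normal tail is mildly conservative at
  n = 40 per group), and the acceptance check asks it to land in the
  binomial 95% envelope around 0.05.
- **Effect recovery**: 20 seeds of a planted latent shift Δμ = 1.0 with
  β = 0.2 at 300 cells per cluster per genotype (4 clusters, 400 genes) —
  sized so the planted (cluster, hormone) pair is called with the correct
  signs essentially always while the 14 null rows stay silent.
- **Cell-cycle filter**: a transcriptome-scale simulation (2000 genes,
  1500 cells, 20 planted phase genes at 3×, no organelle genes). The scale
  matters: with only a few hundred genes the boosted phase-gene mass
  mechanically depresses every other gene's within-cell fraction in S/G2M
  cells, a compositional coupling that does not vanish with more cells and
  can push null genes over a 3% threshold. At realistic gene counts the
  phase sets are a tiny fraction of total mRNA and the coupling is
  negligible. The filter-recovery check uses true phase labels to isolate
  the deletion rule; a companion check confirms the module-score phase
  caller drives the same removals end-to-end. (Phase calls feed back into
  the null genes' R² slightly — control genes drawn during scoring
  correlate with the calls — which is why the rule-isolation and
  end-to-end checks are kept separate.)
- **Reporter**: 20 seeds × (20 sepals per group × 50 nuclei), targets
  mean 1.0 vs 1.3 and CV 0.2 vs 0.35; recovery tolerances 5% (mean) and
  10% (CV) comfortably exceed the sampling error at these sizes.
- **Growth**: a single 12-hour interval for the closed-form comparison
  (exp-increment shares are interval-dependent under compounding, so the
  closed form is evaluated per interval), 20 buds at 2% noise.

## Known limitations

- The Wilcoxon exact branch requires tie-free data; fraction statistics on
  small libraries can tie, in which case the corrected approximation is
  used even at small n.
- `contrast_clusters` infers reference/mutant from labels (WT-like names
  preferred, else lexicographic) unless given explicitly; supplying
  `reference=` is recommended in scripts.
- The per-hormone coupling β ties all of a hormone's up and down genes to
  one latent level with a single slope; real response magnitudes vary per
  gene.
- Proportion summaries include `unassigned` spots in denominators; with
  very noisy prediction scores this can dilute cluster proportions.
- No effect-size estimates exist for the latent hormone shifts in real
  tissue; the generator defaults are chosen for testability of the
  statistics, not biological fidelity.
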