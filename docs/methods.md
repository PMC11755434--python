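# Methods

## Overview

`emstate` quantifies where cells sit on the epithelial–mesenchymal (E/M)
axis of log-normalized single-cell expression data, and how that position
relates to stemness. The pipeline is deliberately simple and transparent:
plain panel means, pseudobulk averaging, Pearson correlation with average
linkage, PCA + 2-means, OLS, and one-way ANOVA. No step re-normalizes,
batch-corrects or QC-filters the input; matrices are consumed as provided.

## Scores

For each cell (one matrix column), with a mesenchymal panel M and an
epithelial panel E:

- `mean_mes` = mean expression over the present genes of M,
- `mean_epith` = mean over the present genes of E,
- `mes_epith_ratio` = `mean_mes / (mean_epith + ε)`,
- `stem_score` = mean over the organ-specific STEM panel whose
  `(tissue_class, organ)` key matches the cell; absent otherwise.

The default MES panel is {SNAI1, SNAI2, SNAI3, CDH2, CDH3, ZEB1, ZEB2, FN1,
VIM, TWIST1, TWIST2} and the default EPITH panel {CDH1, KRT8, KRT18} —
the canonical EMT transcription factors and structural markers on one side,
E-cadherin and keratins 8/18 on the other. Tight-junction genes and
organ-specific stem panels are dataset-dependent and loaded from a YAML/JSON
config. There are no rank-based or background-corrected variants: scores are
plain means, which keeps them comparable across panels and datasets that
share a normalization.

Panel genes missing from a matrix are dropped with a warning and the score
is the mean over present genes; imputation is never attempted. Gene symbols
are matched case-insensitively after stripping Ensembl-style version
suffixes, so human (CDH1) and mouse (Cdh1) annotations interoperate. This
matching rule is a package choice; curated ortholog maps would be stricter
but require external resources.

### Ratio guard

Mean EPITH can be exactly zero in sparse data, so the ratio is guarded with
ε = 1e-8 (configurable). Cells with `mean_epith < 10·ε` are flagged
`unstable_ratio`; their ratios are reported but should not be averaged
naively. Group-level ratios are therefore recomputed from collapsed means
(ratio of means), which is stable even when individual cells have zero
EPITH expression.

## Pseudobulk collapsing

`collapse` averages expression gene-wise over all cells sharing an
annotation and averages the per-cell scores alongside; the group ratio is
recomputed from the collapsed means. A second-level collapse by embryonic
origin weights member profiles by their cell counts, which makes the
two-level collapse conserve the global mean expression exactly (an invariant
the tests check). Mean aggregation is used throughout; median or
variance-stabilized pseudobulk variants are out of scope.

## Similarity analyses

**Correlation matrix.** Pairwise Pearson correlation between collapsed
profiles, over the whole transcriptome or restricted to the MES∪EPITH
genes. Constant profiles are uncorrelatable; their entries are set to 0 and
the profile is flagged. Hierarchical clustering uses average linkage (UPGMA)
on distance d = 1 − r. d = 1 − |r| would fold anti-correlated profiles
together; the plain form keeps them apart. Profiles are pre-sorted
lexicographically so tied merges resolve deterministically.

**PCA + 2-means gradient.** Cells (restricted to the MES∪EPITH panel genes)
are centered gene-wise — not scaled, since panel genes share units — and
projected onto the top 5 principal components (capped at
min(genes, cells) − 1). k-means with k = 2 and 10 restarts runs on the PC
coordinates. Cluster labels are arbitrary under relabeling, so they are
oriented deterministically: cluster 0 is the cluster with the higher mean
`mean_epith`, making 0 the epithelial pole. The per-type gradient is the
mean cluster label over a cell type's cells, a number in [0, 1]. PCA and
clustering operate per cell; the gradient is the per-type aggregate.

## Stemness inference

**OLS.** Per tissue class, `stem_score` is regressed on
`[1, mean_mes, mean_epith]` over individual cells. The fit also reports the
pairwise Pearson correlations r(stem, mes) and r(stem, epith), which carry
the directional claims: in the adult-tissue scenario epithelial precursors
correlate positively with MES and negatively with EPITH, while muscle and
connective precursors correlate positively with both. Nearly collinear
predictors (|r| > 0.9999) are rejected rather than silently fitted.

**Stem/mature classification.** Threshold mode labels a cell stem if
`stem_score > 0` and mature if `< 0`. An exact zero is excluded by that
rule; it is assigned mature with a `boundary_zero` flag so the output is
deterministic on measure-zero inputs. Annotation mode passes through an
existing metadata column.

**ANOVA.** Group comparisons use classic one-way fixed-effects ANOVA with
no unequal-variance correction and no post-hoc pairwise tests. Stars follow
a deliberate, nonstandard ladder: * p < 0.05, ** p < 0.001, *** p < 0.0001,
**** p < 0.00001, with strict inequalities. If all observations are
identical the test degenerates to F = 0, p = 1.

## Synthetic data generator

The generator produces the structure the analyses assume, with ground
truth, so the pipeline is fully testable offline.

**Noise model.** Per gene g and cell c, counts are drawn
NegBin(mean = s_c·μ_{p,g}, dispersion θ) — variance μ + μ²/θ — with
s_c ~ LogNormal(0, σ) a library-size factor, followed by Bernoulli dropout
and CP10K + log1p normalization. Defaults: θ = 10, σ = 0.3, dropout = 0.1,
50 background genes with log-normal baseline means. All population
differences are multiplicative shifts (in log units) from a single shared
baseline, so zeroing every shift yields exchangeable populations — the null
configuration used for calibration checks.

**Adult-tissue scenario.** Six populations: mature and precursor pairs in
an epithelial (lung), skeletal-muscle and connective (skin) lineage.
Relative to its mature counterpart, the basal epithelial population is
shifted +1.0 (MES), −0.5 (EPITH), +1.5 (own STEM panel); satellite and
connective precursors +0.8 on both MES and EPITH and +1.5 on STEM. Mature
baselines separate the lineages (epithelium EPITH-high, connective
MES-high). The shipped STEM panels (TP63/KRT5/SOX2/ITGA6/NGFR;
PAX7/MYF5/CD34/VCAM1/CALCR; PDGFRA/LEPR/GREM1/CXCL12) are synthetic stand-ins
built from canonical field markers, not a transcription of any published
organ panel.

**Development scenario.** Five stages (zygote, four-cell, eight-cell,
morula, trophectoderm). MES shifts are constant through the eight-cell
stage and then fall (+1.1 → +0.4 → −0.5) while EPITH shifts rise
(−0.2 → +0.7 → +1.4): a mesenchymal-to-epithelial transition that begins at
compaction.

**What the generator does not emulate:** batch effects, doublets, ambient
RNA, gene–gene correlation beyond the panel structure, realistic gene-count
scale (tens of genes, not tens of thousands), or the empirical distributions
of any real atlas. Passing tests therefore demonstrate that the pipeline
recovers programmed structure under standard single-cell noise — not that
any particular biological dataset will show that structure.

## Problem sizes and numerical choices

- Direction-recovery analyses run at 500 cells/population (power > 0.99 at
  the default shifts); shared test fixtures use 300.
- ANOVA null calibration uses 1000 replicates of the zero-shift generator at
  100 cells/population. The omnibus F-test is asymptotically calibrated but
  measurably anti-conservative on the skewed score distribution at very
  small groups (we observed ≈0.07 rejection at α = 0.05 with 20
  cells/group); calibration claims hold for the ≥100-cell regime.
- The developmental monotonicity check uses 100 replicates at 200
  cells/stage.
- Determinism: every stochastic step flows through one integer seed via
  `numpy.random.default_rng`; fixed seed ⇒ bit-identical matrices. k-means
  uses 10 restarts with the seed as `random_state`.
- Ties and degenerate inputs: UPGMA ties broken by lexicographic label
  order; `stem_score == 0` → mature + flag; constant profiles → correlation
  0 + flag; cells with zero total counts normalize to all-zero; groups need
  ≥2 members for ANOVA and SE is undefined for singletons.

## Known limitations

- Plain mean scores are sensitive to panel composition and to the input
  normalization; scores from differently normalized datasets are not
  comparable.
- The ratio is reported per cell but is unstable when EPITH expression is
  near zero; prefer collapsed ratios for group statements.
- Only the omnibus ANOVA is computed; per-pair contrasts shown in typical
  bar-plot figures would need post-hoc tests that are out of scope.
- The h5ad reader loads the full matrix into memory; it is intended for
  desk-scale subsets, not atlas-scale files.
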