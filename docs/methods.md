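# Methods

This note documents the statistical procedures implemented in
`stylemorph`, the choices that were genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Normalization (counts → normalized counts)

Median-of-ratios: for gene *i* with strictly positive counts in every
sample, the geometric mean g_i = (∏_j K_ij)^(1/m) is computed in log
space; the size factor of sample *j* is the median over these reference
genes of K_ij/g_i, with midpoint interpolation for even reference sets.
Genes with any zero count are excluded from the reference set (their
geometric mean would be zero); genes with zero counts in all samples are
dropped up front and logged. Normalized counts are K_ij/s_j with no
pseudocount; log2 transforms downstream add an explicit +1 only where
stated. The estimator is checked against pydeseq2's implementation of
the same convention.

A subtlety worth knowing: scaling one sample's column by c scales its
size factor by c only *relative to the other samples* — because every
gene's geometric mean absorbs a factor c^(1/m), all normalized values
shift by a common constant c^(1/m). Relative expression, fold changes,
CV and τ are unaffected.

## Atlas statistics

- **Expressed call**: tissue mean (arithmetic, over that tissue's
  replicates; tissues may have unequal replicate numbers) ≥ threshold.
  The default threshold of 4 normalized counts sits in the valley of the
  typical bimodal log2 distribution of normalized counts; a diagnostic
  log2(x+1) histogram export (`log2_expression_histogram`) lets users
  justify a different cut. The call is ≥ (inclusive) at the boundary.
- **CV** is computed across all individual samples (not tissue means),
  with the sample (n−1) standard deviation; genes with zero mean are
  flagged undefined and excluded from constitutive candidacy. The
  constitutive filter is CV ≤ 0.15 by default, CV-only; τ is reported as
  supporting annotation and becomes a second filter only when `tau_max`
  is passed.
- **τ** is computed on untransformed per-tissue mean normalized counts
  (no log pre-transform). On log-transformed input τ would compress
  toward 0; the untransformed convention matches the index's original
  definition and keeps τ scale-invariant per gene.
- **Sample similarity** is Spearman's ρ with average ranks for ties;
  clustering/PCA of the similarity matrix is left to the user's plotting
  stack and is deliberately not part of the tested surface.

## Differential expression

A deliberately transparent negative-binomial Wald analogue:

- Dispersion per gene by method of moments on normalized counts pooled
  within the two groups: α = max((v − m)/m², 10⁻⁸) with v the pooled
  within-group variance and m the base mean. No shrinkage toward a
  fitted trend.
- NB GLM with log link, design intercept + group indicator, size factors
  as offsets, variance μ + αμ²; Fisher-scoring IRLS, convergence at max
  coefficient change < 10⁻⁸ within 100 iterations. log2FC is the group
  coefficient / ln 2; two-sided p from the Wald z against the standard
  normal; BH over tested genes only. Genes with an all-zero group mean
  are flagged (signed-infinite log2FC, untested); non-converged genes
  are flagged untested, never silently dropped.
- DEG status applies the morph-contrast filter: up if log2FC ≥ 1 and
  padj ≤ 0.05, down mirrored. Both thresholds are parameters since the
  floral/non-floral contrast of the original analysis used significance
  only.

Consequences, stated plainly: without dispersion shrinkage, outlier
handling and independent filtering, DEG lists on real data will differ
from shrinkage-based packages at equal thresholds. The test suite
therefore validates this stage by its statistical properties on
simulated data, not by reproducing any published DEG count.

Calibration designs used in the tests (sizes chosen to make the checks
meaningful, and kept fixed): the null type-I check uses 2,000 NB genes
(α = 0.1, lognormal means) at 30 samples per group — large enough that
the asymptotic normal reference for the Wald statistic is adequate; at
10–20 per group the plug-in method-of-moments dispersion makes the test
mildly anticonservative (attained level ≈ 0.055), which is inherent to
the estimator, not a bug. Fold-change recovery uses 500 single-gene
replicates at 20 vs 20, μ = 100 vs 400, α = 0.1; truth-table recovery
plants 100 genes at log2FC 2 among 2,000 at 10 vs 10.

## Cross-species intersection

Orthogroup tables use the tab-separated dialect (comma-space gene
lists; empty cell = species absent); genes may belong to at most one
orthogroup, and violations are integrity errors. Reciprocal-best-hit
maps keep a pair iff each gene is the other's unique best score; ties
for best remove the gene entirely.

For one stratum (organ class × direction), an orthogroup is tagged for a
species iff it contains ≥ 1 of that species' stratum DEGs; the seven
Venn cells over three species partition the tagged orthogroups. Each
stratum is analyzed separately, which enforces direction concordance
within a stratum. Organ-class mapping of tissues is configuration (the
default maps style/pistil/carpel to female, filament/stamen/corolla-tube
to male, and lets a whole-flower DEG set contribute to both); DEGs found
in no orthogroup are reported in an "unassigned" sidecar, never silently
dropped.

## Enrichment

Fisher's exact test is computed from hypergeometric log-probabilities
(gammaln). The two-sided p-value follows the minimum-likelihood rule
with a relative tie tolerance of 10⁻⁷; one-sided tails are cumulative
sums. The implementation is verified against exact rational-arithmetic
enumeration for every margin configuration up to table total 60, and
against scipy.

The label scan (PIF-style) builds, per species sample, the universe of
genes possessing a one-to-one outgroup ortholog, labels a gene by its
ortholog's list membership, and tests the DEG × label table. The scan
defaults to the one-sided enrichment tail: on the published contingency
tables this choice reproduces all ten printed p-values at printed
precision (including the non-significant ones, which a two-sided rule
does not reproduce), so the sidedness is validated by, not assumed from,
the published numbers. The cross-product odds ratio is reported as a
descriptive effect size only. Generic term enrichment uses one-sided
tests with BH across terms, per over-representation convention; terms
are flat gene sets (no ontology DAG propagation).

## Synthetic data

The generator mirrors the emulated study's shape with every dimension
configurable: a 20-sample atlas (7 tissues × 3 replicates, 2 for floral
bud), plus a 3 L vs 3 S morph contrast in a floral tissue; NB counts
with gene-wise lognormal baselines (median ≈ 150 counts, log-sd 1.5) and
lognormal dispersions (median 0.1); 20% tissue-specific genes (8-fold
boost in one tissue), 5% morph-responsive genes (|log2FC| = 2, half up,
half down), 5% constitutive genes (high baseline, α = 0.005, unit tissue
and morph effects); library-size multipliers log-uniform on [0.5, 2] so
size-factor recovery is a real test. Orthology: 600 orthogroups over
three species plus an outgroup, 70% single-copy (these define the true
one-to-one chains), the rest with shifted-Poisson per-species sizes.
Labels are drawn on outgroup genes at base rate 0.05, with the odds
multiplied by θ on orthologs of morph-responsive genes. Planted shared
orthogroups are simulated as strong, expressed responders (log2FC 3,
baseline at least the median), because with 3+3 replicates a weaker
planted signal would make the planted truth statistically ill-posed.
All randomness derives from the single config seed via per-stage
spawned generators; outputs are bit-reproducible.

What the synthetic tests show: that each estimator recovers the quantity
it targets under its own model assumptions, and that the stages compose
correctly end to end. What they do not show: robustness to features of
real RNA-seq the generator omits — outlier samples, batch effects,
gene-length and GC biases, correlated genes, dispersion–mean trends, and
multi-mapping artifacts.

## Pipeline

`stylemorph run --config cfg.yaml` executes normalize → atlas → DE →
cross-species → enrichment, re-validating intermediates on load, logging
surviving-gene counts at each filter, and writing a `manifest.json`
without timestamps; identical config + inputs give byte-identical
outputs. Any stage failure aborts with a stage-named error. The
subcommands (`normalize`, `atlas`, `de`, `crossspecies`, `enrich`,
`pifscan`, `simulate`) expose the same operations individually.

## Known limitations

- The DE stage is intentionally a minimal NB-Wald model: no multi-factor
  designs, covariates, paired models, or shrunken LFC estimators.
- τ's behavior on log-transformed input is not implemented; users who
  prefer that variant can transform tissue means before calling
  `tau_index`, at the cost of scale invariance.
- The exact test enumerates the full support per table; for table totals
  in the millions this is still fast (the support is bounded by the
  smaller margin), but no asymptotic approximation is provided.
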