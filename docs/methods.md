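# Methods

`pdxmatch` implements the inference chain linking a bulk tumour's immune
state to the behaviour of its xenograft: reference-based two-stage
deconvolution, hot/cold stratification, cancer-cell-intrinsic
differential expression and enrichment, correlation-ratio matching of
PDX cancer-cell profiles to the hot/cold archetypes, and an exact
binomial test of engraftment bias. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Mixture model and two-stage deconvolution

A bulk expression column is modelled as a convex mixture of cell-type
intrinsic profiles in **linear** expression space,

    b_s = Σ_k π_{sk} · f_k + noise,     π_{sk} ≥ 0,  Σ_k π_{sk} = 1,

because transcript abundance, not its logarithm, mixes additively.
Log2(x+1)-scale inputs (the common public-repository dialect) are
converted with 2^x − 1 on load; the container records the conversion.

**Stage 1 (proportions).** For each sample, the bulk column restricted
to an informative gene set is regressed on the reference profiles
subject to non-negativity and sum-to-one. The simplex-constrained
least-squares problem is solved *exactly* by enumerating coefficient
supports: for each non-empty support the sum-to-one
equality-constrained problem is solved through its KKT system, and the
feasible candidate with the smallest residual is the global minimiser.
Enumeration is exponential in the number of cell types, which is the
intended regime (3–11 compartments; a hard cap of 15 applies). We chose
this over the common soft-constraint trick (appending a heavily
weighted unit-sum row to a non-negative least-squares problem and
renormalising) because the soft constraint perturbs the objective by
more than the tolerance at which we verify monotonicity of the
alternating fit, whereas the exact solver makes each half-step a true
block minimisation.

**Informative genes.** Genes are ranked by the coefficient of variation
of their value across reference cell types (between-type spread over
mean level); ties break lexicographically. The selection keeps the
top-k genes (default k = 1000) but, inside `deconvolve`, drops genes
scoring below 25% of the median score of the strongest 50 genes
(`min_contrast_ratio = 0.25`, with a floor of max(10, 2·K) genes kept).
The filter is load-bearing: alternating updates on genes without real
between-type contrast allow the factorisation to absorb cell-type
*extrinsic* heterogeneity — in particular, distinct cancer-cell states —
into the proportion estimates. In simulation this manifests as the
objective continuing to fall while the proportions drift far from the
reference-anchored solution; with the filter the refinement converges
to the generating proportions at every seed we examined. The rule is
self-calibrating (relative to the observed score distribution), so on
references with uniformly moderate contrast it keeps most of the top-k.

**Stage 2 (profiles).** For each gene, the bulk row across samples is
regressed on the proportion matrix by non-negative least squares
(scipy's active-set NNLS). Standard errors use the unconstrained OLS
covariance, se²_k = s² [(PᵀP)⁻¹]_{kk} with s² = RSS/(n − K); entries
clipped at the non-negativity bound keep the same formula and are
flagged `at_bound` rather than given a special treatment. The group
sample size n is stored with the profiles because downstream contrasts
need it for degrees of freedom.

**Alternation.** `deconvolve` iterates Stage 1 and Stage 2 on the
informative genes from an initial reference until the relative change
of the residual sum of squares falls below `tol` (default 1e-6, at most
`max_iter` = 1000 alternations), then re-estimates profiles on all
genes with the converged proportions. Because both half-steps are exact
constrained minimisations, the objective trace is monotone
non-increasing; the fit object raises if it is not. Non-convergence
returns results with `converged=False`. All-zero samples are dropped
with a warning.

## Immune profiling

Immune cell fractions are estimated quanTIseq-style from a marker-gene
× cell-type signature (ten TIL10-like types). The real TIL10 matrix is
not bundled — it is third-party content the user supplies — so the
signature is a required input and the simulations generate a synthetic
stand-in with the same structure. Each sample's bulk sub-vector over
the shared signature genes is decomposed on the signature columns plus
an explicit background pseudo-type whose profile is the per-gene cohort
median; the coefficients live on the unit simplex, so named immune
fractions sum to at most one and the shortfall is reported as `other`
(uncharacterised, non-immune). This makes the remainder explicit and
testable rather than implicit in a ≤1 constraint. quanTIseq's mRNA-
content scaling and tumour-mode gene exclusions are not reproduced.
Total immune infiltration is the sum of the named fractions. A marker
panel (Tregs: FOXP3, CTLA4, HPGD, IKZF2; CD4 T: GZMB, NKG7, CD40LG;
M2: CD163; M1: CD68, CD86; B: MS4A1) supports heatmap-style exports of
bulk marker expression on the log2(x+1) display scale.

## Stratification, differential expression, enrichment

Samples are ranked by immune fraction (Stage-1 immune proportion by
default; signature-based totals as an alternative source) and the
bottom floor(n/4) labelled **cold**, the top floor(n/4) **hot**, ties
broken by sample identifier so the partition is deterministic.

Cancer-cell profiles are re-estimated by Stage 2 *separately* on the
hot and cold samples; intermediate samples contribute to neither. Per
gene, the contrast uses

    fold = (hot + 1) / (cold + 1)        (linear units; the pseudo-value
                                          guards division by zero)
    t    = (hot − cold) / sqrt(se_h² + se_c²)

with two-sided p from the t distribution at Welch–Satterthwaite degrees
of freedom built from the per-group fit sizes (n_g − K). A gene is
called at fold ≥ 5 in either direction and raw p < 0.05; no multiple-
testing correction is applied by default (Benjamini–Hochberg is behind
a flag) because the thresholding convention this mirrors used raw
p-values. Note the +1 pseudo-count biases fold changes toward 1, so a
gene whose true ratio is exactly 5 sits strictly below the threshold in
expectation — only effects above the threshold are reliably detected
(see Benchmarks).

Gene-set over-representation of the called genes uses the upper-tail
hypergeometric probability P(X ≥ overlap) with the universe defaulting
to all genes present in both group profiles; gene sets are read from
standard GMT. Group differences in immune cell-type fractions use
two-sided Welch t-tests and accept any binary labelling (hot/cold,
engrafted/failed).

## Xenograft matching and the engraftment-bias test

Each PDX cancer-cell profile (assumed already separated from host
reads) is Pearson-correlated on log2(x+1) values against the hot and
cold cancer-cell profiles over their shared genes (≥ 50 required;
zero-variance columns are errors, not silent NaNs). When both
correlations are positive the ratio r_cold / r_hot labels the model
(cold iff ratio > 1; an exact tie counts as hot — conservative against
the expected direction). When the signs differ the positive correlation
wins; when both are non-positive the less negative wins; in both cases
the ratio is reported as undefined and tallied separately by the
histogram.

The correlation gene set defaults to **all shared genes**. A mode
restricted to the differentially expressed genes exists, but it is a
poor default for the ratio presentation: on genes selected to maximise
the hot/cold contrast the two archetype profiles are anti-correlated
after log-centring, so one correlation is typically negative and every
ratio is undefined. With all genes the shared expression backbone keeps
both correlations positive and the ratio interpretable.

Cohort-level bias is tested exactly: P(X ≥ k_cold) for
X ~ Binomial(n, p0) by direct summation of the probability mass
function with exact integer binomial coefficients (no normal
approximation); the default null p0 = 0.64 is the cold/basal share
expected if xenografts sampled the primary tumour population without
bias, and is a configuration parameter. The two-sided alternative uses
the minimum-likelihood rule. Against an arbitrary-precision rational
oracle the summation agrees to 12 significant digits for n ≤ 1000.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with ground
truth recorded for every draw:

- **Reference profiles** for cancer/immune/stroma: a shared log-normal
  base level per gene (median ≈ e³ ≈ 20 linear units, log-sd 1.0) with
  ~10% between-type jitter, plus disjoint marker blocks (5% of genes
  per type) expressed ≥ 10-fold above the other types by construction.
- **Archetypes**: two copies of the cancer profile differing in 438
  planted genes (half up in hot, half up in cold) by the configured
  fold (default exactly 5; optionally log-uniform in
  [fold, fold_max]). Planted genes are drawn from non-marker genes
  with above-median cancer expression, since the +1 pseudo-count makes
  a 5-fold change on a sub-unit expression level undetectable by
  design.
- **Bulk cohort**: 50 hot + 50 cold samples; Dirichlet proportions
  with mean immune fraction 0.45 (hot) vs 0.05 (cold), concentration
  25, mixing the sample's archetype; i.i.d. multiplicative log-normal
  noise with unit mean and configured CV (default 5%) applied after
  mixing — preserves non-negativity and mimics RNA-seq overdispersion.
- **PDX profiles**: 166 noisy copies of one archetype (94% cold by
  default, rounded to the nearest count) with zero immune/stromal
  content, emulating ideal post-separation purity.
- **Immune signature**: the immune marker genes partitioned round-robin
  across ten TIL10-like subtypes with a fixed intra-immune composition;
  each gene's value in its own subtype is the immune profile divided by
  the subtype share, so the cohort's immune profile is exactly the
  composition-weighted subtype mixture and signature totals recover the
  true immune fraction.

All randomness derives from a single seed through named substreams, so
reference, archetype, cohort, and PDX draws are individually
reproducible and every output is bit-identical under a fixed seed.

What the generator does **not** emulate: count noise at low expression
(no Poisson/NB layer), gene–gene correlation beyond the mixture
structure, batch effects, partial host-read contamination of PDX
profiles (available as zero by default only), intra-tumour continua
between archetypes, or real marker-gene identities. Passing benchmarks
therefore demonstrate correctness of the estimators under the stated
generative model, not performance on real cohorts.

## Benchmarks and problem sizes

The test suite and the acceptance script run three seeded studies,
sized to the cohort scale the analysis targets:

- **Recovery** (3 types, 2000 genes, n = 100, noise CV 5%, no planted
  archetype difference): Stage-1 mean absolute proportion error < 0.02
  (typically ≈ 0.005) and Stage-2 per-type profile Pearson r > 0.98
  (typically > 0.998).
- **Differential expression** (438 genes planted at folds log-uniform
  in [5, 20], 50 samples per group, noise CV 5%): recall ≥ 0.9 and
  false-positive rate ≤ 0.01 among unplanted genes. The fold range
  reflects that a 5-fold *threshold* identifies genes whose true folds
  lie above 5; planting every gene exactly at the boundary would make
  any unbiased detector recover ~50% by symmetry.
- **End to end** (166 PDX, 94% cold-derived, noise CV 10%): classifier
  accuracy vs truth ≥ 0.98 and the bias test rejecting at p < 0.001.

Oracle checks accompany them: Stage 1 against exhaustive simplex grid
search (step 1e-3, agreement within 2e-3 per coordinate), the
hypergeometric tail against complete enumeration for universes ≤ 20,
the Welch p against a 20 000-draw permutation oracle (±0.01), and the
binomial tail against exact rational arithmetic.

## Degenerate inputs and edge rules

- Identical reference profiles: feature selection raises (no contrast).
- Rank-deficient profile submatrix in Stage 1: warning, pseudo-inverse
  path; results may be non-unique.
- Fewer samples than cell types in Stage 2: error naming the group.
- All-zero bulk samples: dropped with a warning; all-zero signature
  expression: fractions 0, `other` = 1.
- Zero combined standard error in the DE contrast: p = 1 when the
  estimates agree, 0 when they differ (no 0/0 NaNs).
- Duplicate gene rows on load: summed with a warning; negative values:
  error naming gene and sample; tables that look transposed (hundreds
  of columns, a handful of rows) are rejected with guidance.

## Known limitations

- The sub-simplex immune fit depends on the cohort median being a fair
  background proxy; cohorts dominated by high-infiltration samples bias
  the `other` column and hence the totals.
- Stage-2 standard errors ignore the non-negativity constraint's effect
  on the sampling distribution; near the bound they are approximate.
- The support-enumeration solver is exponential in the number of cell
  types and capped at 15; beyond that a different solver is required.
- The exact-fold planting mode and the +1 pseudo-count interact as
  described above; detection at the threshold boundary is, by design,
  not claimed.
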