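# Methods

This note documents the models and procedures `luniche` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Land-use intensity index

Plot-year management records (fertilization F in kg N ha⁻¹ yr⁻¹, mowing M
in cuts yr⁻¹, grazing G in livestock-unit grazing days ha⁻¹ yr⁻¹) are
standardized by regional component means and combined as
`LUI = sqrt(F/F_R + M/M_R + G/G_R)`; the square root evens out the
right-skewed raw distribution. Choices:

* **Year aggregation.** A plot's multi-year LUI is the arithmetic mean of
  its yearly square-root indices (`aggregate="indices"`, the default),
  i.e. a mean of LUI values rather than an index of mean components. The
  alternative — square root of the time-averaged standardized component
  sum — is available as `aggregate="components"`; the two coincide when
  management is constant across years.
* **Regional means** default to the pooled mean over all supplied
  (plot, year) records. When published region-wide means exist, pass a
  `RegionMeans` directly so plots are standardized against the full region
  rather than the sampled subset.
* **Degenerate components.** A regional mean of zero (a component never
  used anywhere) makes the index undefined and raises, naming the
  component; it is never silently dropped.

## Count-table processing

* **Rare-taxon filter**: taxa with fewer than 4 reads in total (singletons
  through tripletons) are removed before any analysis.
* **Rarefaction** subsamples each sample to a common depth without
  replacement by index permutation — each read is an urn ball labeled with
  its taxon — giving exact multivariate-hypergeometric marginals; column
  sums equal the target depth exactly. Seeded and deterministic.
* **TMM normalization** computes per-sample scaling factors from trimmed,
  precision-weighted means of pairwise log-ratios against a reference
  sample (the one whose 75th-percentile proportion is closest to the mean),
  with the standard 30% trim on log-ratios (M), 5% on average log-abundance
  (A), and inverse delta-method-variance weights. Factors are rescaled to
  geometric mean 1; normalized abundances are counts divided by
  (library size × factor), rescaled to the mean library size. A sample
  sharing no nonzero taxa with the reference gets factor 1 with a warning.
* **Venn partition** assigns each taxon to the set of factor levels where
  its total count is positive, on the rarefied table; percentages are
  rounded to the nearest integer, halves away from zero, matching how such
  shares are conventionally printed.

## Alpha diversity

Observed richness, Shannon entropy in nats, Pielou evenness H/ln S, and the
abundance-based coverage estimator (ACE) with rare cutoff 10. When every
rare taxon is a singleton the ACE coverage term is zero and the estimator is
undefined; the implementation falls back to Chao1 with a logged warning.
Rarefaction curves use the closed-form hypergeometric expectation with
binomial coefficients evaluated in log space, stable at depths in the tens
of thousands.

## Beta diversity

* **PERMANOVA** uses the Gower-centered inner-product matrix of squared
  Bray–Curtis dissimilarities and sequential (Type-I) sums of squares:
  terms are fitted in the order given, each charged with the variation left
  by its predecessors, so term R² plus residual R² sum to 1. Categorical
  factors become treatment-coded dummies, numeric columns (e.g. LUI) enter
  as covariates, `a:b` builds interactions. p-values come from freely
  permuting sample identities; permuted pseudo-F values are compared to the
  observed with a small relative tolerance so permutations that merely
  reproduce the observed partition (equal up to float summation order)
  count as ties. Free permutation matches the unstratified design; a
  future strata option would permute within blocks.
* **Dispersion homogeneity** embeds samples by principal coordinates and
  measures each sample's distance to its group centroid with the
  imaginary-axis correction: squared distances along negative-eigenvalue
  axes subtract, truncated at zero before the square root. Centroids are
  spatial means in the embedding (not spatial medians). A one-way ANOVA F
  on the distances is tested by permuting group labels.
* **SIMPER** decomposes mean between-group Bray–Curtis dissimilarity into
  per-taxon contributions averaged over all between-group sample pairs; the
  contributions sum to the mean dissimilarity exactly, which the tests
  assert as an algebraic identity. Input is the TMM-normalized genus table
  by default (the same scale as the other beta statistics); ranking is by
  descending contribution with lexicographic tie-break for determinism.
  The top-k discriminant list skips `unclassified_*` bins.

## Niche statistics and null model

For genus j, the weights p_{j,s} are its abundance shares across plots
(summing to 1 per genus); μ_j is then a weighted mean lying inside the
gradient's range, σ_j the population-style weighted SD (no small-sample
correction), and CV_j = σ_j/μ_j. Samples are aggregated to plots by
summation within the analyzed subset (total, per plant type, or per
species).

The null model holds the genus's occupancy k fixed and asks where its
abundance mass would sit if plots were interchangeable: each iteration
draws k of the n plots uniformly without replacement and places the
observed nonzero abundance profile on them in random order. Re-placing the
*profile* (not just presences) keeps σ and CV on the same footing in
observed and null communities, which the CV-based mid-specialist test
requires; an occupancy-only variant (equal weights on k random plots) is
available via `mode="occupancy"`. When the number of ordered placements
n!/(n−k)! is at most 10,000 the model enumerates all of them, making the
p-values exact; otherwise 10,000 Monte-Carlo iterations are used with the
+1-corrected one-tailed estimator p = (1 + #extreme)/(n_iter + 1), which is
a valid permutation p bounded away from zero.

**Classification rule.** `winner` if p_high < α, else `loser` if
p_low < α, else `mid_specialist` if p_cv_low < α (the "μ similar to
expected" gate is operationalized as non-significance in both μ tails,
which is exactly the state reaching this branch), else `neutral`; α = 0.05
one-tailed. A genus significant in both μ tails is impossible for a valid
permutation p at α ≤ 0.5 and triggers a defensive error. Equality in the
tail counts is resolved toward the extreme side with a 1e-12 tolerance so
degenerate nulls (e.g. full occupancy with equal abundance) give p = 1, not
a float-dependent value.

Trophic-mode annotation is a case-insensitive genus lookup against a
user-supplied guild table, with per-genus overrides applied last (the
pipeline default overrides *Paraphoma* → pathotroph); multi-mode strings
like `pathotroph/saprotroph` are preserved verbatim and flagged, never
interpreted.

## Synthetic communities

The generator emulates the factorial study the pipeline targets: 13 plots ×
2 plant species × 2 plant types = 52 samples, one per cell; a 9-year
land-use history whose mean LUI spans roughly 0.7–2.6 with median ≈1.6
(right-skewed, like managed-grassland gradients; low-intensity plots are
unfertilized and sometimes unmown in a given year, so exact zeros occur);
and ~60 genera with lognormal base abundances split into archetypes —
winners and losers with loglinear responses exp(±strength·(L−L̄)) at
strength 2, mid-specialists with Gaussian responses (breadth 0.35 on the
LUI scale, optima jittered around mid-gradient), and a neutral majority.
Species and plant-type effects multiply a random half of the genera by
exp(effect); the defaults (species 0.5, plant type 0) mirror a design where
plant species structure the community but plant types do not. Counts are
multinomial given a per-sample depth drawn uniformly from 2,000–5,000 —
scaled down from field depths in the tens of thousands; compositional
signal, not absolute depth, drives the niche statistics, and the test suite
runs in seconds at this size. Optional layers: gamma (negative-binomial
style) over-dispersion, and Bernoulli presence thinning per plot to create
the structural zeros the occupancy-aware null model responds to.

What the simulator does **not** emulate: sequence-level noise (PCR bias,
chimeras, OTU clustering artifacts), taxonomic misassignment, spatial or
temporal autocorrelation between plots, and correlated responses among
genera. Passing recovery tests therefore demonstrate the statistical
machinery — not robustness to upstream bioinformatic error.

**Compositional caveat.** In a mixed community, strong winners depress the
relative abundance of everything else at high LUI, so flat-response genera
acquire a mild apparent "loser" signal. The null-model calibration is
therefore assessed on an all-neutral community (where nominal one-tailed
false-positive rates near 0.05 are recovered); in mixed communities the
classification reads on relative, not absolute, abundance — the same caveat
that applies to any compositional amplicon analysis.

## Pipeline and reproducibility

The pipeline runs rare-taxon filtering once, then two branches that never
exchange tables: (A) rarefy → alpha diversity and Venn partition on integer
counts; (B) TMM → (optional genus aggregation) → Bray–Curtis → PERMANOVA +
dispersion + SIMPER → top-30 discriminant genera → niche classification per
subset, followed by a cross-subset agreement table. Every stochastic stage
derives its seed as `sha256(master_seed/stage_name)` truncated below 2³¹,
so stages are decoupled and a rerun with the same master seed is
byte-identical (the manifest records per-stage seeds and output hashes).

Default problem sizes (13 plots, 60 genera, depths 2,000–5,000; 10,000 null
iterations; 1,000 PERMANOVA permutations) were chosen as the package's
standard operating point: large enough for stable p-value grids, small
enough that the full test suite and the acceptance script run in well under
a minute each.

## Known limitations

* PERMANOVA permutes freely; nested/split-plot designs need strata support.
* The mid-specialist test has modest power at occupancy near the plot
  count and moderate breadth: a Gaussian responder whose optimum sits
  off-center often resolves into the winner or loser tail instead. The
  recovery rates reported by `scripts/acceptance.py` quantify this.
* TMM assumes most taxa are non-differential between samples; with very
  strong gradient responses the factors absorb part of the signal.
* The guild lookup is genus-level only and does not resolve within-genus
  trophic heterogeneity.
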