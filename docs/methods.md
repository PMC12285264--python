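# Methods

This note documents the models and procedures implemented in meadownet, the
choices made where conventions diverge, and what the synthetic-data tests do
and do not demonstrate about real data.

## Data model

A `FeatureTable` is a samples × taxa matrix in `count` or `relative` mode;
relative rows must sum to 1 within 1e-9. On disk the package reads the
common taxa-as-rows TSV export and a BIOM-style JSON (plain JSON with
`rows` / `columns` / `data`; the binary HDF5 BIOM variant is out of scope).
Taxonomy lineages use the `d/k/p/c/o/f/g/s` rank prefixes; the domain label
(fungi / bacteria / archaea) is derived from the top ranks. Aggregation at a
rank collapses taxa unclassified at that rank into one bucket per deepest
classified ancestor, labelled `"<rank>__<name> (unclassified)"`, so
per-sample totals are conserved exactly and the "merged as other" behaviour
of published composition plots can be reproduced losslessly.

Compartment-level mean relative abundances are means of per-sample
fractions, not pooled-count fractions — the semantics SIMPER and the
fold-change screen assume. (`taxon_share_within_group` pools counts across
samples instead, because "proportion of the genus community" is a question
about total abundance.)

## Rarefaction and diversity

Rarefaction subsamples each sample without replacement
(`numpy`'s multivariate hypergeometric) to a common depth, defaulting to the
minimum sample total; samples below the depth are dropped with a logged
warning. Shannon uses the natural logarithm (the vegan/phyloseq default).
Bray–Curtis is computed by scipy; it is bounded in [0, 1] but not a metric
(no triangle inequality), which is why ordination uses PCoA rather than a
metric embedding. PCoA eigendecomposes the double-centred Gower matrix;
negative eigenvalues (expected for Bray–Curtis) are reported but contribute
no axis, and no Cailliez correction is applied. Proportions explained are
relative to the positive-eigenvalue total.

## Permutation tests

All permutation p-values use `(b + 1) / (m + 1)` with the observed statistic
included, so the minimum attainable p at 999 permutations is 0.001 and every
p is strictly positive. All tests take explicit seeds and are exactly
reproducible.

PERMANOVA uses the McArdle–Anderson trace formulation
(`SS = tr(H G H)` with G the Gower-centred squared-distance matrix and H a
hat matrix), which handles dummy-coded categorical factors and centred
continuous covariates in one framework. With several factors the sums of
squares are sequential (Type I) in the order given — the adonis default —
and a marginal single-factor mode is provided, since published tables often
do not state which was used. Permutations shuffle the rows/columns of the
distance matrix jointly and recompute every factor's pseudo-F.

ANOSIM ranks the condensed distance vector once and recomputes R per label
permutation. Kruskal–Wallis and the Wilcoxon rank-sum screens delegate to
scipy (tie-corrected, asymptotic); constant taxa are degenerate and reported
as H = 0, p = 1. Significance stars follow the conventional four-threshold
scheme (`* < 0.05` through `**** < 0.0001`, `ns` otherwise).

A practical caveat verified during calibration: with very small groups the
permutation space collapses (5 + 5 samples admit only 126 distinct
bipartitions) and p-value distributions visibly discretize and shift
conservative. The calibration nulls therefore use two groups of 8; the
"minimum p attainable" property likewise needs group sizes for which the
probability of re-drawing the observed split is negligible.

## SIMPER and the enrichment screen

The per-taxon contribution of taxon *i* to the between-group dissimilarity
is the mean over all inter-group sample pairs (x, y) of
`|xᵢ − yᵢ| / Σₖ(xₖ + yₖ)`. The permutation test compares these **raw**
contributions against label permutations (one-sided ≥), matching vegan's
semantics; reported contributions are normalized to fractions summing to 1.
Testing normalized shares instead would mask moderately enriched taxa
whenever one dominant taxon absorbs most of the dissimilarity — a failure
mode we observed directly.

The screen computes the fold change of mean relative abundance from
denominator group A to numerator group B. A zero denominator mean is
replaced by the smallest non-zero taxon mean in A; a zero numerator yields
FC = 0 (log₂FC = −∞) and is in practice removed by the abundance filter,
which keeps only taxa above 0.01 % mean relative abundance in B. Enrichment
requires log₂FC strictly above the kingdom cutoff (0 for fungi, 2 for
prokaryotes) **and** p < 0.05 on the raw (uncorrected) p-value; a
Benjamini–Hochberg switch exists but is off by default to match the
published screen. The four canonical comparisons pool bulk + rhizosphere
sediment as "seagrass sediment" and root + rhizome as "below-ground
tissues"; pooling is configurable since the published description leaves it
ambiguous.

## SparCC

For D taxa, the variation matrix `t_ij = var(log xᵢ/xⱼ)` is computed from
the log-fraction covariance matrix. Under the sparsity approximation the
row sums satisfy `Σ_{j≠i} t_ij = (D − 2) wᵢ + Σⱼ wⱼ`, a linear system solved
for the basis variances `wᵢ`; correlations follow as
`r_ij = (wᵢ + wⱼ − t_ij) / (2√(wᵢwⱼ))`, clipped to [−1, 1]. The strongest
pair above the exclusion threshold is then removed from the system and it is
re-solved, up to the iteration limit; a component may lose at most D − 3
pairs, and if the reduced system turns singular the last valid solution is
kept. At D = 3 the system is exactly determined, which provides the
closed-form oracle used in the tests.

Defaults (all configurable): pseudocount 1, 20 Dirichlet resamples of the
per-sample fractions with the element-wise median taken, exclusion threshold
0.1, 10 exclusion iterations. `n_resamples=0` switches to pseudocounted
empirical fractions — deterministic, and what the permutation p-values use
by default for speed. P-values shuffle every taxon's counts across samples
independently and are two-sided with the `(b + 1)/(m + 1)` rule; at the
default 100 permutations the minimum p is ~0.0099, below the 0.05 edge
threshold.

Networks keep edges with |r| > 0.2 and p < 0.05 (both strict) after a
prevalence filter that retains taxa present in **strictly more than** 50 %
of the group's samples (18 of 36 is removed, 19 of 36 kept). Whole networks
are inferred once on the concatenated fungal + prokaryotic count table of a
compartment group; interdomain networks are derived by edge filtering
(fungus↔bacteria/archaea only), not re-inference. Module detection is
Louvain on the unweighted, unsigned graph (networkx, seeded); signed-aware
modularity was deliberately not used, as standard pipelines report plain
modularity. Zi is the within-module degree z-score (0 when the module's
degree sd is 0, covering singleton and regular modules); Pi is the
participation coefficient `1 − Σ_m (k_im/kᵢ)²`. Categories use strict
thresholds Zᵢ > 2.5 and Pᵢ > 0.62.

## Robustness

One removal draw deletes ⌈f · n_fungi⌉ uniformly chosen fungal nodes, then
iterates secondary extinction to a fixed point: a node dies when it has no
remaining edges, or when its abundance-weighted mean interaction strength
`sᵢ = (1/kᵢ) Σⱼ r_ij aⱼ` over remaining neighbours is ≤ 0 (both
sub-criteria individually switchable; the exact formula in the robustness
literature varies, so it is isolated in one function). Robustness is the
fraction of the original nodes remaining. A removal fraction of 0 returns
exactly 1 without running the cascade — a network with many negative edges
could otherwise lose nodes "spontaneously", which would contradict the
definition of robustness as a response to removal. Curves average 1,000
independent removal replicates per grid point (default grid 0–1 in steps of
0.05), interpreting "randomly generated networks" as removal replicates of
the same inferred network rather than re-inferred networks — the standard
protocol. The decline rate is |R(0.5) − R(0)| / 0.5, bounded by [0, 2].

## Synthetic communities

Each taxon has latent log-abundance `μ_t + δ_{c(s),t} + σ z_t`: a taxon base
level (normal, sd 1.5), a compartment shift applied to a configurable
fraction of taxa (default 30 % of taxa, shift sd 1.0), and a standard
multivariate normal whose correlation matrix carries the planted edges (a
Gaussian copula on the log scale; positive-definiteness is checked before
sampling). Counts are multinomial per sample and marker at a depth drawn
uniformly from 2,000–10,000, so depths are uneven and rarefaction is
exercised; per-sample totals equal the drawn depths exactly. The keystone
fungus is pinned to a target relative abundance within the fungal community
per compartment (defaults 0.90 rhizome, 0.80 root, ~0.55 in other
plant-associated compartments, ≤ 0.15 in water and non-seagrass sediment,
emulating a dominant host-restricted endophyte) while keeping its copula
variate, so planted keystone edges survive the pinning. Replicate defaults
follow the emulated survey design: 36 per plant compartment, 20 water, 12
non-seagrass sediment.

What the generator does **not** emulate: sequence-level noise (chimeras,
denoising artefacts), phylogenetic correlation between taxa, taxon-specific
amplification bias, zero-inflation beyond what multinomial sampling of
log-normal fractions produces, and temporal autocorrelation across months.
Passing tests therefore demonstrate correctness of the statistical machinery
under a clean compositional model, not robustness to every artefact of real
amplicon data.

## Pipeline and reproducibility

`run_pipeline` executes simulate/ingest → rarefy (per marker, to each
table's minimum depth unless overridden) → diversity → enrichment (four
canonical comparisons × both kingdoms) → networks per compartment group
(default groups: leaf, root, rhizome, phylloplane, sediment = {bk, rp}) →
Zi–Pi roles, ego network of the keystone, robustness. Per-stage seeds are
CRC32 hashes of `"<master>:<stage>"`, so adding a stage never perturbs the
randomness of earlier stages; identical config + seed gives byte-identical
TSV outputs. Every stage logs input dimensions and filter survivor counts.

## Problem sizes in validation

The validation experiments use synthetic communities of 50 taxa × 60
samples for planted-edge recovery (planted |ρ| = 0.8, 10 independent runs;
recall and sign accuracy of the full chain at |r| > 0.2, p < 0.05), 16
samples × 8–10 taxa for the 200-replicate null calibrations of PERMANOVA /
ANOSIM / Kruskal–Wallis / SIMPER (199 permutations each, KS test against
uniform), and small constructed graphs for the robustness and Zi–Pi closed
forms. These sizes were chosen as the smallest at which the asymptotic
behaviour being tested is cleanly visible.

## Known limitations

- SparCC assumes a sparse true correlation structure; dense strong
  correlation networks bias the basis-variance approximation.
- The permutation p-values for SparCC edges recompute correlations under
  column-wise shuffles with the deterministic fraction estimate by default;
  bootstrap-style p-values over Dirichlet resamples are available via
  `n_resamples` but cost proportionally more.
- Louvain is stochastic across seeds; modularity values are reproducible
  only with the seed fixed (the pipeline fixes it).
- No phylogenetic diversity metrics (no UniFrac), no raw-read processing,
  no visual layout computation.
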