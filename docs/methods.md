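# Methods

## Model and assumptions

The integration model is deliberately simple: each molecular data type is
an independent noisy view of the same latent sample structure. Per-type
PCA removes feature-level redundancy; dividing each block's scores by the
square root of its total retained variance puts all types on an equal
footing (total variance exactly 1 per block), so the concatenated space
weights types equally regardless of how many features each measures. The
t-SNE step then optimizes *local* neighborhood preservation of that
concatenated space - the method's premise is that sample-to-sample
similarity, not global geometry, is what matters for subtyping. Axes of
the resulting map carry no meaning; only neighborhoods do.

Because t-SNE is stochastic, an embedding is defined as the best of
`n_restarts` runs seeded `seed, seed+1, ...` (lowest final KL divergence
wins). This makes the whole pipeline a deterministic function of
(data, config). The embedding backend is scikit-learn's Barnes-Hut t-SNE.

## The local-similarity score

For maps X, Y of the same n samples, with `r^x_ij` the rank of j among
i's Euclidean distances in X (nearest = 1, ties broken by ascending
sample index):

    s_xy(kx, ky) = (1 / (n · min(kx, ky))) · Σ_i Σ_{j≠i} 1[r^x_ij ≤ kx ∧ r^y_ij ≤ ky]

Properties (all property-tested): range [0, 1]; s = 1 exactly when each
sample's kx nearest neighbors in X are among its ky nearest in Y or vice
versa; symmetry s(X,Y,kx,ky) = s(Y,X,ky,kx); under independent random
maps with kx = ky = k the expectation is k/(n−1). The conjunctive
indicator with min-normalization is this package's documented reading of
the score; it is the unique choice we found that satisfies all of the
above simultaneously. The per-sample k-NN overlap percentage used by the
contribution analysis is the same quantity before averaging: the mean
per-sample overlap at k equals 100 · s(·,·,k,k) (asserted as a
cross-module test).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_pcs` | 50 | components per data type; `retain_variance=0.95` is the alternative rule |
| `perplexity` | 30 (n/10 if n < 100) | t-SNE neighborhood scale; must be < n/3. For very small re-embeddings (e.g. COP dissection of ~15 samples) pass it explicitly - n/10 is too small there |
| `n_restarts` | 10 | restart budget; a production pan-cancer map is worth ~1000 restarts. Restart seeds fan out deterministically as seed+i |
| `min_samples` | 5 | DBSCAN density threshold (unstated in the protocol; 2D maps are dense) |
| `max_noise` | 0.10 | cap on the non-clustering fraction during eps selection |
| eps grid | 50 log-spaced values, 1st-50th percentile of pairwise distances | covers sub-cluster to half-data scales |
| `alpha` | 0.001 | cluster-tissue enrichment threshold |
| `k` | 20 | neighborhood size for overlap/contribution analysis |
| `remove_pcs` (ME) | 1 | components stripped as technical variation; 0 disables. The protocol names no count; one is the smallest intervention consistent with the step's purpose |
| imputation `k` | 3 | nearest samples for missing-value imputation (nan-Euclidean distance, uniform weights) |
| `r_threshold`, `min_partners` | 0.6, 2 | co-expression edges use \|r\| > 0.6 (both signs kept); nodes need ≥2 partners |

Eps selection follows the silhouette criterion (computed on clustered
samples only, requiring ≥2 clusters, ties to the smaller eps) under the
noise cap; a Davies-Bouldin score is recorded alongside as a diagnostic
because the two criteria can disagree and the discrepancy is worth
surfacing rather than hiding.

COP calling: a clustered sample is a COP iff its own tissue is not among
its cluster's significantly enriched labels; noise samples are COPs by
definition and are attached to the nearest cluster centroid only to
decide COP-I (cluster enriched for some tissue) versus COP-II candidate
(no enriched tissue). Candidates are confirmed by re-running the full
pipeline on the COPs in isolation (skipped below 10 COPs): isolation
clusters with no enriched tissue are confirmed COP-II groups. When the
isolated COPs are so homogeneous that no two-cluster solution is
admissible, they are treated as one cluster for the enrichment step.

## Survival and enrichment statistics

Kaplan-Meier curves and the log-rank test come from lifelines; the Cox
proportional-hazards model uses statsmodels' partial likelihood with
Breslow tie handling (recorded on the result), reference-coded
categorical covariates, and Wald intervals. Annotation comparisons:
two-sided Mann-Whitney U for continuous variables, one-sided Fisher
exact for 2×2 categorical tables (the tested direction is
over-representation of group A's first-observed category). Gene-set
enrichment is the upper-tail hypergeometric test against a background
universe (default: all genes measured on the expression platform after
filtering), corrected by Benjamini-Yekutieli, selected at adjusted
p < 0.05. Differential expression is Welch's t-test with Holm
correction - a deliberate, labeled substitution for a moderated-variance
model: the pipeline contract (gene list in, corrected DE list out) is
what downstream steps consume, and the output carries
`method = "welch-t + holm"` so results are self-describing.

## The synthetic-data generator

`SynthSpec` plants `n_clusters` latent clusters. Cluster c's center is
drawn N(0, effect²) per feature *only in its driver types*; non-driver
types share the common (zero) center, so a cluster is invisible to any
combination made solely of its non-drivers - this is what makes
driver-attribution testable. Within-cluster noise is standard normal, so
`effect_size` is the center spread in within-cluster SD units on the
latent scale. Emission: GE/MIR = 2^(z + baseline) with per-gene baselines
N(6, 2) / N(4, 2) (non-negative, log2(x+1) recovers the latent scale);
ME = logistic(z + offset), offsets N(0, 1.5) (beta-like values in [0, 1]);
CN = 2 · 2^(0.25 z) (positive, diploid-centered). A configurable fraction
of features (default 5%) sits on chrX/chrY with a sex-linked shift of 2;
cells go missing independently at the missing rate (default 1%). Planted
COPs copy a target cluster's latent signal *in every data type* while
keeping the source tissue label; the target may be the reserved "novel
signature" shared by all planted COPs, which is how COP-II groups are
planted. Survival times are exponential with a per-cluster event rate
(defaults 1/2000, 1/1000, 1/500 per day), censored uniformly on
[0, 2000] days.

Defaults are the reference study conditions used throughout the tests:
three clusters of 50 samples, drivers {GE}, {ME}, {all four}, effect
4 SD, 400/300/300/100 features.

What the generator does *not* emulate: real covariance among genes,
platform batch effects, heavy-tailed count noise, and realistic
missingness mechanisms (missingness is completely at random). Passing
tests therefore demonstrate that the pipeline recovers structure of the
planted kind at the planted strength - not that any particular real
cohort contains such structure.

## Numerical choices

- Distance rank ties break by ascending sample index (determinism).
- Quantile normalization maps each sample onto the mean-of-sorted-rows
  reference; ties receive average ranks with linear interpolation.
- Permutation p-values use the add-one estimator (1 + hits)/(1 + n_perm),
  so p = 0 is unattainable.
- Hypergeometric enrichment is the upper tail P(X ≥ overlap).
- The 1-NN label AUC is macro one-vs-rest on the margin score
  d(nearest other-class) − d(nearest same-class), leave-one-out;
  singleton classes are skipped. The construction string travels with
  the result.
- Silhouette/Davies-Bouldin are NaN when fewer than two clusters exist;
  a NaN silhouette is inadmissible during eps selection.
- Co-expression pruning iterates removal of under-connected nodes to a
  fixed point; NaN correlations (constant genes) never form edges.
- Centering steps are idempotent to 1e-8; scaled blocks are fixed points
  of the scaling.

## Problem sizes

All shipped analyses run at desk scale, chosen so the full suite and the
reproduction script complete quickly on one CPU: cohorts of 60-150
samples, a few hundred features per type, 1-3 t-SNE restarts in tests
(the tool default is 10; a production map deserves ~1000), and 20
replicates for null calibration. The effect-size monotonicity check
runs at reduced dimensionality (12/10/10/8 features) because with
hundreds of features recovery saturates already at 1 SD and the
interesting ramp (chance → partial → full recovery) would not be visible
over the tested grid.

## Known limitations

- t-SNE coordinates are only reproducible bit-wise on the same library
  build and platform; across builds, neighborhoods are stable but exact
  coordinates are not.
- Eps selection by silhouette on clustered samples tends to prefer
  trimming boundary points up to the noise cap when clusters are
  Gaussian; the cap, not the silhouette, is then the binding constraint.
- The Cox model assumes proportional hazards and uses Wald inference;
  no robust or time-varying extensions.
- The ME technical-variation step removes a fixed number of components;
  it does not model beadchip batches explicitly.
- Network modules default to connected components; a greedy-modularity
  refinement is available but no resolution tuning is offered.
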