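# Methods

`micronetstab` implements a desk-scale soil-microbiome analysis pipeline:
diversity profiling of an ASV count table, signed Spearman co-occurrence
network inference, cohesion/robustness/vulnerability-based community
stability analysis, and PLS path modeling linking treatment, soil chemistry,
community structure and plant performance. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic communities

The generator (`synthetic_data`) emulates a three-treatment field experiment
(labels CK, M, bioM; six replicate plots each) so that every downstream
stage has a recoverable planted answer.

**Count model.** Each taxon *t* carries a latent Gaussian factor with block
correlation structure: `z_t = sqrt(rho_out)·g + sqrt(rho_in − rho_out)·u_m(t)
+ sqrt(1 − rho_in)·e_t`, giving within-module correlation `rho_in` and
between-module correlation `rho_out`. The latent is exponentiated into a
log-normal relative abundance around a taxon-specific baseline
(`base_log_sd = 1.5`, a realistic spread of two to three orders of magnitude
in mean abundance), shifted by `effect_logfc` (natural-log units, default
1.0) for a random `effect_taxa_frac = 0.2` of taxa in the non-reference
groups, and sampled as a gamma–Poisson (negative binomial,
`var = mu + dispersion·mu²`, `dispersion = 0.5`) at a sample-specific
log-normal library size (`depth_mean = 40,000`, `depth_cv = 0.3`, bracketing
the study-scale rarefaction depth so rarefaction is exercised nontrivially).
Because rank correlations survive monotone transforms, the planted blocks
remain detectable by Spearman-based inference; zero inflation arises from
the counting process, with no separate zero component.

**Metadata model.** Latent scores follow the acyclic chain treatment → soil
→ community → plant. The planted path coefficients are standardized: each
endogenous latent's structural noise variance is chosen (by path-tracing the
population covariance) so the latent has unit variance, which makes the
generative coefficients directly comparable with fitted standardized path
coefficients. Manifest columns (nine soil covariates, two community axes,
biomass and yield) are affine rescalings of their latent — the soil
covariates use field-realistic units — plus independent measurement noise
(`meta_noise_sd = 0.3`). Paths whose implied variance exceeds 1 are
rejected. Default inner coefficients: treatment→soil 0.6,
treatment→community 0.5, soil→community 0.4, soil→plant 0.3,
community→plant 0.5.

**Trees** are random coalescent-style bifurcating topologies with
unit-exponential branch lengths — adequate for exercising Faith's PD, with
no pretence of realistic phylogenetic signal.

**What the generator does not emulate:** taxonomic structure, phylogenetic
conservation of abundance, PCR/primer bias, true compositional interaction
networks (blocks are correlation, not ecological interaction), or the
spatial structure of field plots. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the stated
generative model, not performance on real amplicon data.

## Diversity

Rarefaction is a single multivariate-hypergeometric draw per sample to a
common depth (recorded seed); columns sum exactly to the depth. Alpha
indices use natural-log Shannon, the bias-corrected Chao1
`S_obs + F1(F1−1)/(2(F2+1))` (defined when doubletons are absent), Simpson
concentration and its inverse, and Faith's PD under the rooted convention
(the root-to-subtree path counts; unrooted conventions differ). All-zero
samples yield NA, not 0. By default the pipeline computes alpha diversity on
rarefied counts.

Beta diversity uses Bray–Curtis on (rarefied) counts. PCoA performs Gower
double-centering of −D²/2 with an `eigh` decomposition; coordinates are
eigenvectors scaled by √λ for positive eigenvalues, negative eigenvalues are
dropped from the variance denominator, and a Cailliez correction is
available by flag.

PERMANOVA is implemented directly: `SS_total = Σ_{i<j} d²_ij/N`, within-group
sums scaled by group size, `pseudo-F = (SS_between/(k−1))/(SS_within/(N−k))`,
and a label-permutation p-value with the (1+x)/(1+n) convention so p never
reaches 0. The permutation null is vectorized over all permutations at once.
Pairwise comparisons reuse the same machinery with BH adjustment. Note that
permutations preserving the group partition tie the observed F exactly, so
the attainable p floor is slightly above 1/(n+1) in balanced designs.

## Co-occurrence networks

Edges are Spearman correlations (mid-rank Pearson, two-sided t-approximation
p-values) with |ρ| strictly above `rho_min = 0.8` and BH-adjusted p strictly
below `alpha = 0.05`; the BH adjustment spans all upper-triangle pairs
jointly, the conservative standard scope. Isolated taxa are excluded from
the node set. Zero-variance taxa must be filtered first (prevalence and
mean-relative-abundance thresholds are available); with six samples per
group the Spearman p-value grid is coarse, which is why per-treatment
networks at the default thresholds are sparse at desk scale.

Topology metrics are computed on the unweighted simple graph, with sign and
ρ as edge attributes only: average degree 2E/N, density 2E/(N(N−1)), global
clustering as the mean of local coefficients (0 for degree<2 nodes), average
path length and hop-count diameter on the largest connected component
(component count reported alongside), and modularity as the Newman Q of the
best of ten seeded Louvain restarts (networkx implementation, resolution 1).
`*_per_node` diagnostic rescalings of path length and diameter are emitted
because some published tables print these quantities on a sub-1 scale that
is inconsistent with hop counts; they are diagnostics, not targets.

**Planted-module recovery harness.** Counting noise attenuates a latent
within-module correlation of 0.9 to roughly 0.5–0.6 in realized count-rank
correlation (depth 20,000, dispersion 0.3), so the recovery tests build the
network at `rho_min = 0.6`, `alpha = 1e−3` — chosen from this attenuation
argument when the harness was designed — and then require Louvain to match
the planted assignment at adjusted Rand ≥ 0.8. The 0.8 edge rule remains
the pipeline default for analysis.

## Stability

**Cohesion** follows the connectedness approach: Pearson correlations of
relative abundances (a deliberate contrast to the Spearman edge rule — the
two serve different computations), optionally corrected by subtracting each
pair's mean correlation under `n_null = 200` independent per-taxon shuffles
across samples (`taxa_shuffle`, the default; `none` enables exact
hand-checkable arithmetic). connectedness⁺ of a taxon is the mean of its
positive corrected correlations with the others (connectedness⁻ likewise for
negative), and cohesion⁺/cohesion⁻ of a sample weight connectedness by
relative abundance. Because connectedness⁺ averages only positive values it
is non-negative by construction, so positive cohesion is, too; under pure
independence the corrected pairwise correlations retain only the
compositional closure bias of about −1/(k−1). The stability index is
|cohesion⁻|/cohesion⁺ per sample (NA when positive cohesion is not
positive), summarized as group mean ± SE.

**Robustness** removes ⌊f·N⌋ nodes per repetition — uniformly at random, or
highest-degree-first (betweenness optional) with random tie-breaking — and
reports the fraction of surviving nodes that keep at least one edge, as
mean ± SD over 100 repetitions across a 0–0.95 fraction grid; the f = 0.5
point is the headline value. Alternative statistics (giant-component
fraction) were considered and rejected as defaults because the
retains-an-edge fraction is the most direct reading of "changes in
connectivity".

**Vulnerability** is the worst-case relative drop in global efficiency
(mean inverse shortest-path length over all ordered pairs, 0 for
disconnected pairs) caused by deleting a single node; it lies in [0,1].
**Complexity** is reported as linkage density (average degree), the standard
proxy when no explicit definition is given.

## PLS path modeling

The classical Lohmöller iteration: manifests standardized (ddof 1), outer
weights initialized equal; each round performs the inner approximation
(path weighting by default — regression on predecessors, correlation with
successors; centroid and factorial available), the outer update (mode A
correlations by default, mode B regressions), and rescaling of scores to
unit variance, until the largest outer-weight change falls below 1e−7
(cap 300 iterations). The sign ambiguity is resolved by forcing each
latent's correlation with its first manifest positive, making fits
deterministic and invariant to sample order. Path coefficients are OLS among
latent scores; GoF = √(mean manifest communality × mean endogenous R²).
Single-manifest-per-block models collapse exactly to standardized path
analysis. Missing data are handled by listwise deletion only — at a study
scale of 18 samples, imputation would be invention. Uncertainty comes from a
percentile bootstrap over samples (default 500 replicates); a path is
flagged significant when its 95% CI excludes zero, and replicates producing
a constant manifest are skipped and counted.

## Numerical and degenerate-input choices

- Strict inequalities in the edge rule, exactly as specified (|ρ| > 0.8,
  p_adj < 0.05).
- Empty networks are explicit empty results; topology on an empty graph is
  an error.
- Bray–Curtis between two all-zero samples is an error (undefined), a single
  all-zero sample against a non-empty one is 1.
- Two-taxon Spearman matrices handle scipy's scalar-collapse case.
- All stochastic operations take explicit seeds and record them in their
  result objects; pipeline reruns with the same config are byte-identical.

## Problem sizes

Tests and the acceptance script run at desk scale: 40–200 taxa, 18–60
samples, library depths of 2,000–20,000, 199-permutation PERMANOVA inside
calibration loops (999 in the pipeline default), 199-replicate bootstraps in
the false-positive-rate simulation and 10 seeds for module recovery. The
study-scale configuration (thousands of taxa, depth 34,234, 999
permutations, 500 bootstrap replicates) is the documented default of the
pipeline config, not of the test suite.

## Known limitations

- Spearman edge inference ignores compositionality; SparCC-style approaches
  are out of scope by design.
- With n = 6 samples per group the p-value grid is coarse and the default
  0.8/0.05 edge rule yields very sparse desk-scale networks; the bundled
  demo therefore builds a pooled 18-sample network at rho_min 0.6.
- "Relative modularity" is reported as plain Newman Q; Louvain is stochastic
  and only deterministic given the recorded seed and restart count.
- The PLS-PM block membership of real indicator variables is
  user-configurable; the bundled spec reflects the synthetic generator's
  latent structure, not a claim about any real dataset.
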