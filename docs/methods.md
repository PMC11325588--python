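# Methods

This note documents the statistical procedures implemented in
`invanet`, the defaults and numerical choices behind them, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## Diversity

Alpha diversity is reported as Hill numbers
`D_q = (Σ p_i^q)^{1/(1−q)}` with the q→1 limit `exp(−Σ p_i ln p_i)`.
We deliberately report the *effective-species* (Hill) form at every
order — "Shannon" in the output is `exp(H)`, not raw entropy — because
effective numbers are comparable across orders (richness ≥ q1 ≥ q2) and
across studies.  No rarefaction is applied anywhere: relative abundances
are computed per sample from raw counts, and the generator controls
library size explicitly instead.

Bray–Curtis dissimilarity defaults to relative abundances (flag
`use_relative=False` for raw counts); with unequal library sizes raw
counts would conflate depth with turnover.

The Wilcoxon rank-sum test uses full enumeration when the pooled sample
is ≤ 20 values without ties, otherwise the normal approximation with
midrank tie correction and continuity correction.  A constant pooled
sample is degenerate and returns p = 1 with a warning.

Duncan's multiple range test orders the group means and tests each range
of `p` means against the studentized-range quantile at the protected
level `1 − (1 − α)^{p−1}`, with the harmonic mean of group sizes in the
standard error and critical values from `scipy.stats.studentized_range`
(numerical quadrature — no printed tables).  A range declared
non-significant protects all of its sub-ranges (step-down); maximal
non-separated runs share a letter.

## Ordination and permutation tests

NMDS minimises Kruskal stress-1 by SMACOF with isotonic regression of
configuration distances on dissimilarity ranks (scikit-learn's
`smacof(metric=False, normalized_stress=True)` as the inner solver).
Defaults: 20 uniform random starts plus one classical (Torgerson)
metric start, 500 iterations, tolerance 1e-12; the lowest-stress restart
is reported and runs are deterministic under the seed.  An all-equal
dissimilarity matrix cannot be ordinated meaningfully; it returns the
metric configuration with stress 0 and a warning.

ANOSIM uses midranks computed once on the condensed dissimilarity
vector; `R = (r̄_B − r̄_W)/(M/2)`, `M = n(n−1)/2`.  PERMANOVA uses
`SS_total = Σ_{i<j} d²_ij / n`, within-group sums scaled by group size,
pseudo-F with (a−1, n−a) degrees of freedom, and R² = SS_B/SS_T.
P-values: when the number of distinct label assignments is ≤ 10,000 the
full set is enumerated and p is the exact proportion (observed included)
with a statistic ≥ the observed; otherwise p = (1 + b)/(1 + m) over m
sampled permutations so p is never zero.  Permuted statistics are
compared to the observed with a 1e-12 tolerance to make tied statistics
deterministic across platforms.

## Co-occurrence networks

Per habitat, the core-taxon filter keeps ASVs with nonzero counts in at
least the `prevalence` fraction of that habitat's samples (default 1.0 —
present everywhere) and then the `top_k = 200` by summed relative
abundance.  Spearman ρ is the Pearson correlation of per-taxon midranks;
two-sided p-values use the t-approximation on n−2 df, with p = 0 at
|ρ| = 1 as the limiting case.  BH adjustment runs over the off-diagonal
upper triangle of each habitat's matrix separately — each network is its
own family of tests.  Edges require |ρ| > 0.7 **and** q < 0.05, both
strict, so boundary values are excluded and tightening either threshold
can only remove edges.

Node counts are reported two ways: all retained taxa, and non-isolated
nodes (the convention of network viewers that drop unconnected taxa);
averages and densities use the non-isolated count.  Average path length
is the mean unweighted shortest-path length over all *reachable* pairs
pooled across components — a convention chosen because per-component
averages are unstable for the very sparse networks small designs
produce.

## Stability

Natural connectivity is `ln((1/N) Σ e^{λ_i})` over the eigenvalues of
the unsigned, unweighted adjacency, computed with a log-sum-exp to avoid
overflow; the (N − ln N)-normalised variant is available by flag but not
used by default, since normalisation conventions vary and the plain
value is what node-removal curves compare.  Robustness curves remove
`floor(f·N)` uniformly chosen nodes per replicate on a default grid of
0–0.8 in steps of 0.05 with 50 replicates, reporting mean ± SD per
fraction; replicates whose induced subgraph is empty are recorded as
missing.  Stability is evaluated on the non-isolated subgraph of the
thresholded network.

Cohesion follows the null-corrected connectedness construction: for
focal taxon i and partner j, the observed Pearson correlation of
relative abundances (Spearman by flag) minus the mean correlation over
`n_null = 200` randomisations that independently permute every partner
column across samples.  A taxon's positive (negative) connectedness is
the mean of its strictly positive (negative) corrected correlations —
the original convention of the cohesion method — and a sample's cohesion
is the abundance-weighted sum `C± = Σ a_j c±_j`.  For ≤ 8 samples an
exhaustive mode enumerates all n! permutations, which the test suite
checks against a brute-force per-pair oracle.  n_null = 200 keeps the
null-mean standard error an order of magnitude below typical corrected
correlations at study-scale sample sizes.  Cohesion is computed per
habitat on all taxa present there (not just network taxa), matching how
per-habitat cohesion panels are usually produced.

## Synthetic generator

The generator emulates a two-habitat, site-nested field design: 5
invaded and 3 native sites, 3 replicates each, 300 taxa.  Per habitat a
signed Erdős–Rényi backbone (density 0.08 native / 0.03 invaded, 20%
negative edges) defines a target latent correlation of ±0.6 per edge;
the matrix is repaired to positive definite by eigenvalue clipping at
1e-8 and rescaling to unit diagonal.  Latent MVN draws get a shared
scalar site intercept (sd 0.25) modelling site-level efficiency shifts;
each latent value is quantile-mapped through a negative-binomial
marginal (size k = 1.0, moderate amplicon-like overdispersion) whose
mean is the taxon's log-normal relative abundance (σ = 1.2) times the
sample's library size, drawn uniformly in 20,000–50,000.  Because raw
negative-binomial draws do not sum to the drawn depth, each sample is
rescaled to its exact library size by largest-remainder rounding, which
preserves composition and structural zeros.  The invaded habitat loses
a random 25% of taxa outright (structural zeros), making the richness
ground truth exact.  Soil covariates are Gaussian per habitat with
means/SDs taken from field measurements under invasive vs native
vegetation (ammonium up, salinity and pH down with invasion).

What it does **not** emulate: taxon-specific site preferences (species
sorting along environmental gradients), spatial autocorrelation,
phylogenetic structure, or sequencing error.  This matters for
interpreting the network stage: real site-structured data contain many
near-perfect pairwise correlations, which is how field studies obtain
networks with hundreds of FDR-significant edges from as few as 9
samples.  Under this generator the backbone correlation of 0.6 maps to
a count-scale Spearman of ≈ 0.58, whose t-approximation p at n = 9 is
≈ 0.1 — far above the ≈ 1e-5 that BH over ~20,000 pairs demands — so
per-habitat networks are honestly near-empty and node-level network
metrics frequently tie between habitats.  Passing tests on synthetic
data therefore validate the estimators, thresholds and direction of the
diversity/cohesion contrasts, not the edge *counts* a field dataset
would produce.

## Design choices and degenerate inputs

- Orientation of count files is auto-detected against metadata sample
  ids (flag to override); unannotated taxa aggregate into
  "Unclassified" so per-sample totals are conserved.
- Functional-group aggregation gives each taxon's full relative
  abundance to every group it maps to (overlapping guilds do not sum to
  one); presence weighting is available by flag.
- The percent-change table uses the native habitat as reference
  (configurable), matching the "decreased by X% with invasion" reading.
- BH families: one per correlation matrix, one across each covariate /
  taxon heatmap table.
- Degenerate inputs fail loudly and specifically: all-zero samples are
  named, constant covariates/taxa are masked with warnings, a missing
  habitat column downgrades to a single-community run with a warning.

## Problem sizes used in the test suite

Structural and oracle tests use toy fixtures (≤ 12 samples, ≤ 60 taxa).
Calibration of the permutation tests uses 1,000 null simulations of a
12-sample two-group design with exhaustive (924-assignment) enumeration.
The contrast-recovery check runs the full pipeline on the default
300-taxon design over 20 seeds with reduced robustness replicates (the
intact-network natural connectivity it compares is unaffected by
replicate count).  These sizes were chosen to exercise every code path
with exact or near-exact references.
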