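# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter.

## Data model and conventions

The analysis operates on four tables and a tree: an individual-level trait
table (site, habitat ∈ {SEF, OGF}, species, individual, seven leaf
traits), a site × species abundance matrix L, a site × environment matrix
R, a species × mean-trait matrix Q (derived from the trait table), and a
rooted ultrametric phylogeny with branch lengths in Myr. Conventions used
throughout:

- All sample statistics use the n−1 denominator. This choice is validated
  by the bundled published CWM table: the printed habitat SDs and F row
  reproduce exactly at 2 decimals only with n−1 (see
  `tests/test_acceptance.py`).
- Missing trait cells are allowed; each trait is analysed on its own
  complete subset of individuals, with no imputation.
- Species enter the analysis through the abundance rule: per site, species
  are ranked by descending abundance (ties broken lexicographically) and
  the smallest prefix reaching ≥ 70 % of the site's individuals is
  retained. The comparison is inclusive ("at least 70 %"); the output is
  canonical, i.e. independent of input species order.
- Trees that fail the ultrametricity check (relative root-to-tip spread
  > 1e-6) are accepted with a warning flag rather than rejected, because
  prunings of large time-calibrated trees are routinely only numerically
  ultrametric; signal results carry the flag.
- Species-mean standard errors are sample SD/√n; single-individual species
  get SE = 0 with an explicit flag so downstream error models do not treat
  an unknown SE as zero information silently.

## Phylogenetic signal

Moran's I uses a proximity matrix W with zero diagonal, row-normalized;
the default proximity is 1/patristic distance. Abouheif's C_mean is the
same statistic on the Abouheif proximity: for tips i, j, the inverse of
the product of the number of direct descendants over the internal nodes on
the i–j path (MRCA included). Both are the conventional constructions for
this index family; the proximity is configurable because field studies
rarely state it.

Blomberg's K is (MSE0/MSE)/E[MSE0/MSE | BM], where MSE is the GLS mean
squared error under the Brownian covariance C (C_ij = shared root-to-MRCA
path length) and MSE0 the ordinary mean squared deviation from the
phylogenetically corrected (GLS) mean; the Brownian expectation is
(tr C − n/(1'C⁻¹1))/(n−1). The K* variant deviates only in the
standardisation: MSE0* is taken about the arithmetic mean and the
expectation becomes (tr C − ΣC/n)/(n−1). Both are 1 in expectation under
Brownian motion (verified by simulation: mean K over 200 replicates of
50-tip trees falls in [0.8, 1.2]).

Pagel's λ rescales the off-diagonal of C; the likelihood profiles out the
mean (GLS) and rate (σ̂² = q/n), leaving a 1-D bounded ML problem on
[0, λ_max] with λ_max = depth / deepest internal node (the largest value
keeping C(λ) positive definite), shrunk by 1e-8 to stay strictly inside
the PD region. Significance is a 1-df likelihood-ratio test against λ = 0
— λ is likelihood-based, so an LRT is more natural than forcing it into
the permutation framework used for the other indices. The boundary at
λ = 0 makes the LRT slightly conservative there, which is acceptable for a
screening battery.

Permutation indices use tip-label shuffles with the add-one rule
p = (#more-extreme + 1)/(n_perm + 1), two-sided as
2·min(P(null ≤ obs), P(null ≥ obs)) capped at 1; the add-one correction
avoids p = 0 at finite n_perm. Default n_perm = 999.

## Phylogeny-aware trait correlation

The species-level correlation between two traits models each trait's
covariance as σ²·C(λ̂) + diag(SE²) (λ fitted per trait by 2-parameter ML),
and the cross block as ρ·σ_A·σ_B·C(√(λ_A λ_B)). Given the per-trait λ̂'s,
(σ²_A, σ²_B, ρ) are re-estimated jointly by ML (L-BFGS-B with a tanh
parameterisation of ρ, then a Nelder–Mead polish so the optimum is pinned
to ~1e-10); ρ is tested with a 1-df LRT against ρ = 0. Exact published
algorithms for this class of estimator differ in details that the
literature does not always pin down; this λ-GLS-with-measurement-error
reading is documented as the package's interpretation. Two exact limits
anchor it: with a star phylogeny and zero SEs the estimate equals the
ordinary Pearson correlation to 1e-8, and affine relationships return ±1.

Individual-level correlations are Spearman's rank coefficient, pooled or
per species (minimum 5 individuals per species by default). The full
pairwise matrix reports raw and Holm-adjusted p side by side; raw is the
default to match common practice for these correlograms, with the
adjustment available for the reader who wants family-wise control.

## Community composition

CWM = Σᵢ Wᵢ Xᵢ with weights renormalized over the retained (70 %-rule)
species subset — the retained subset is the only computable choice because
it is the set with measured traits. Habitat contrasts are classical
one-way ANOVAs with site-level CWMs as replicates (n = 4 per habitat in
the reference design). Degenerate inputs are defined explicitly: identical
group means give F = 0, p = 1; zero pooled within-group variance with
unequal means gives F = ∞, p = 0.

NMDS z-scores the traits, builds Euclidean distances, and minimizes
Kruskal stress-1 by SMACOF with monotone (pool-adjacent-violators)
regression; the first restart starts from classical (Torgerson) scaling
and the rest from seeded random configurations, which combines fast
convergence with an escape from local minima. The reported stress is
recomputed from the final configuration as
√(Σ(d − d̂)²/Σd²) × 100 (0–100 scale). The minimum input size is
max(3, k+1) points: three points always embed exactly in the plane.

The centroid test statistic is a PERMANOVA-style
r² = SS(between centroids)/SS(total) of the configuration, with a
one-sided add-one permutation p over label shuffles. r² is bounded by 1 by
construction; published centroid "r²" values above 1 cannot be a
sum-of-squares ratio and are not imitated.

## T-statistics and null models

Variance components (all n−1): σ²_IP is the unweighted mean of
per-population sample variances over populations with ≥ 2 individuals
(populations below that size are excluded rather than contributing zero);
σ²_IC and σ²_IR are plain variances over the community / regional
individuals; σ²_PC and σ²_PR are variances of population means. The
pooling rule for σ²_IP is not standardised in the literature, so a
size-weighted alternative — Σ(nₚ−1)sₚ²/(N−1), which together with the
weighted between-population term reconstructs σ²_IC exactly (law of total
variance, tested to 1e-9) — is computed alongside and available behind
``weighted=True``.

The three null models permute exactly what each ratio conditions on:
"local" shuffles trait values among the community's individuals with
species composition fixed (null for T_IP/IC); "regional.ind" shuffles all
individuals across the region with community sizes fixed (T_IC/IR);
"regional.pop" shuffles population means across the regional pool with the
number of populations per community fixed (T_PC/PR). Implementations are
vectorized over permutations and verified against exhaustive enumeration
on ≤ 6-individual communities (mean and SD within Monte-Carlo error at
10⁴ draws). SES = (T_obs − T̄_null)/SD_null; p is two-sided with the
add-one rule. Degenerate communities (a single species after filtering, or
< 2 individuals) yield NaN rows with notes in the dataset driver instead
of aborting the whole analysis. Null-envelope summaries (0.025–0.975
quantiles of null SES) support forest-plot style displays.

## Fourth-corner and RLQ

The fourth-corner r_P for an (environment, trait) pair is the Pearson
correlation over the inflated table (one row per individual, pairing the
site's environment value with the species' trait value); it is computed in
closed form as Rs'(P − rc')Qs with P = L/Σ L, r and c the
correspondence-analysis row/column weights, and Rs/Qs weighted z-scores —
verified against a brute-force inflated-table oracle to 1e-12. The
permutation model permutes whole site rows of L ("sites", the default
reading of "randomize the distribution of species across sites"), whole
species columns ("species"), or reports the larger p of the two sequential
tests ("combined", the conservative modern recommendation). Each scheme
draws from its own seed stream so "combined" reproduces the sequential
tests exactly. Constant environment or trait columns are reported as
undefined, not silently dropped.

RLQ decomposes the same cross matrix by SVD; eigenvalues are squared
singular values, their sum equals the total co-inertia ‖M‖²_F (tested to
1e-9), and loadings are orthonormal. The extended variant encodes the
phylogeny as principal coordinates of the square-root patristic distance,
retaining axes to ≥ 95 % of the positive eigenvalue mass, appends them to
the trait block, and splits each species' axis-1 score into trait-block
and phylogeny-block contributions, which sum to the global score exactly
(identity by construction, asserted to 1e-12). One caveat is documented
rather than hidden: a star phylogeny has constant patristic distances,
whose Gower matrix is T(I − 11'/n) with n−1 equal positive eigenvalues —
the encoding then carries no *preferred* axis but is not the zero matrix,
so the phylogeny-based component of a star tree is small only in
expectation, not identically zero.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

- **Phylogeny**: pure-birth (Yule) trees conditioned on the tip count,
  built from exponential waiting times with total rate k·birth_rate plus a
  final exponential hold so terminal branches are positive. Extinction is
  omitted — it adds realism to tree shape but no power to any test here.
- **Species means**: multivariate normal with covariance σ²·C(λ), i.e.
  Brownian motion with a tunable Pagel λ. Traits are mutually independent
  unless a trait-correlation matrix is supplied (used by the
  correlation-recovery tests). Simulated traits live on the unconstrained
  Brownian scale (think log-transformed concentrations), so real-data
  nonnegativity constraints do not apply to them and the generic names
  trait1..traitN are used.
- **Communities**: species enter a site with probability ∝
  exp(−(mean − optimum)²/(2·external_filter_sd²)) on a designated filter
  trait — a Gaussian external filter whose width is the single knob for
  filter strength (∞ disables). A minimum-spacing internal filter walks
  species in decreasing admission probability and drops any candidate
  within ``internal_filter`` trait units of an admitted one — the simplest
  mechanism that produces the niche-packing (T_IP/IC) signature.
  Individuals are Normal(species mean, intraspecific_sd) for every trait.
- **Environment**: the filter optimum itself plus one correlated and one
  pure-noise covariate, mimicking a small site-level logger/soil table.

Defaults (8 sites in two habitat classes, 30 species, 40 individuals per
site, σ² = 1, λ = 1, intraspecific SD 0.5, site optima spanning ±1.5
regional trait SD) are a desk-scale analogue of an eight-site two-habitat
forest survey; validation experiments use smaller per-replicate sizes
(stated below) so that hundreds of replicates stay cheap. Everything is
deterministic given ``seed``; sub-streams come from ``SeedSequence`` so
the tree, trait and assembly stages are independent.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about field data: non-Gaussian and zero-inflated trait
distributions, covariance between intraspecific variance and the mean,
spatial autocorrelation among sites, dispersal limitation, species
interactions beyond pairwise trait spacing, and observational error in
abundances.

## Validation experiment sizes

The test suite and the acceptance script rerun these experiments from
scratch (sizes chosen to balance statistical resolution against cheap
replication):

- Null calibration: 500 replicates of a fully exchangeable design (8
  species, 4 sites, 12 individuals/site, σ² = 0 so species carry no mean
  differences and all three null models are exactly true), n_perm = 199.
  Two-sided type-I error at α = 0.05 must land in [0.03, 0.07] and SES
  means within ±0.15 of 0. Note σ² = 0 is required for the "local" model's
  null to hold: with interspecific mean differences present, T_IP/IC is
  genuinely below its local-permutation null even without filters.
- Filter recovery: 200 replicates each; external filter (width 0.25,
  optima ±1.5) must give mean SES(T_IC/IR) < 0 in ≥ 90 % of replicates;
  internal spacing filter (1.0 trait units) must give mean SES(T_IP/IC)
  < 0 in a majority.
- Signal recovery: Blomberg K averaged over 200 replicates of 50-tip
  Brownian simulations must fall in [0.8, 1.2]; Pagel λ̂ medians over 100
  replicates must be within 0.1 of the truth at λ ∈ {0, 1}.

## Known limitations

- The λ-GLS correlation is a two-step estimator (λ's fixed from univariate
  fits before the joint covariance step); a fully joint ML over all five
  parameters would be slightly more efficient but materially slower and
  was not needed for the recovery targets.
- Permutation p-values are granular at 1/(n_perm+1); studies needing
  p < 0.001 must raise n_perm.
- The Abouheif proximity is computed by explicit path products, O(n²) in
  the number of species — fine for community-scale pools (≤ a few
  hundred), not for megaphylogenies.
- Categorical traits and environment variables are out of scope; all
  association machinery assumes quantitative columns.
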