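# Methods

## Problem and model

Bulk tissue expression is modeled as a linear mixture of cell-type
profiles: for a bulk sample **m** over a set of signature genes,
`m ≈ S f` with **S** the signature matrix (genes × K cell types, mean
linear-scale expression of isolated cell types) and **f** a vector of
non-negative fractions summing to one. The linearity assumption holds on
the linear intensity scale only, which is why all inputs are coerced to
linear scale first (below). Estimated fractions are *relative to the
transcriptomic mass* captured by the signature genes; they are not
absolute cell counts, and cell types absent from the signature are
silently absorbed by the fitted ones.

## Scale handling

Matrices whose maximum value is below 50 are treated as log2 and
exponentiated; this threshold is the convention of the deconvolution
family this package follows, and is overridable (`assume_log2`).
Duplicate feature rows (array probes mapping to one identifier) are
collapsed by their mean on read. Missing values are rejected rather than
imputed — no defensible imputation rule exists for arbitrary platforms.

## Signature construction

For each cell type, features are scored by a two-sided unequal-variance
(Welch) t-test of that type's reference samples against all other samples,
adjusted per type with Benjamini–Hochberg; features with q ≤ `q_threshold`
(default 0.3) and fold-change ≥ `min_fold` (default 1.0) are ranked by
decreasing fold-change. Defaults are deliberately permissive: the
condition-number sweep, not the test threshold, does the final selection.
The per-type marker-set size G is swept over `[g_min, g_max]` (defaults
50–150, chosen to bracket the marker-set sizes typical for references
with tens of samples per type; the tests here use smaller ranges matched
to the synthetic reference sizes). At each G the union of every type's
top-G features indexes a submatrix of the mean-profile matrix; its
condition number κ (ratio of extreme singular values) measures how
distinguishable the cell-type columns are, and the minimal-κ union wins,
ties to the smaller G (compact signatures). A rank-deficient candidate
reports κ = ∞ (singular values below `1e-12` of the largest count as
zero); if the best candidate is still ∞ — e.g. two labels denote
identical sample sets — the signature is returned with κ = ∞ and a
warning rather than an error, since the diagnostic value of seeing the
divergence exceeds the value of refusing to answer.

Cell types with a single reference sample have no within-type variance;
their t-tests substitute the residual variance pooled across all other
types (df = 1, conservative) and log a warning. This is an extension
beyond the usual N ≥ 2 setting and should be treated as exploratory.

## Deconvolution

Mixture and signature are restricted to their shared features (an error
below 50% overlap — cross-platform use degrades gracefully down to that
floor, not beyond); the signature is z-scored over all entries jointly
(preserving relative column geometry) and the mixture over its own
entries, which makes fractions invariant to global scaling of either
side. A linear-kernel ν-SVR (regularization C = 1.0) is fitted for each
ν in {0.25, 0.5, 0.75}; the fit with smallest reconstruction RMSE on the
standardized scale is kept. Negative coefficients are clipped to zero and
the remainder normalized to sum to one. ν bounds the support-vector
fraction, i.e. how many genes actively constrain the fit; sweeping it
adapts the robustness/efficiency trade-off per sample. An optional
permutation p-value shuffles the mixture across features and recomputes
the reconstruction correlation (`p = (#{r_perm ≥ r_obs}+1)/(n_perm+1)`).

On well-conditioned signatures the ν-SVR solution agrees with constrained
non-negative least squares to within 0.05 (L∞); the NNLS route is kept as
an independent oracle in the tests, never as the implementation.

Archetype roll-up (`aggregate_archetypes`) sums detailed fractions into
the four coarse classes used for adipose tissue — immune, stem/stromal,
adipocyte, other — under a user-supplied total mapping. Blood-lineage
control types (platelets, erythroblasts) default to "immune" in the
examples on lineage grounds, but the mapping is always explicit and
overridable since reasonable taxonomies differ.

## Marker criteria

Both criteria operate on the mean-profile matrix g′ (feature × type means
over reference samples) on the linear scale, consistent with g′ as used
by the deconvolution basis; a log2 transform of the input is available
upstream for users who prefer compressed dynamics. The primary criterion
`g′_ij − max_{k≠j} g′_ik` and secondary criterion
`g′_ij − mean_{k≠j} g′_ik` are reported in expression units. Identities
used as test invariants: primary ≤ secondary everywhere (max ≥ mean),
secondary rows sum to zero, both criteria are invariant to adding a
constant to a feature's row and scale linearly with positive row scaling.
Ranking is by decreasing score with lexicographic tie-break on feature id;
negative top scores are flagged — the type has no marker of that kind.
Merging labels (e.g. depot-specific adipocytes) before scoring removes
within-group penalties from the primary criterion; merging must leave
at least two groups.

## Literature unit conversion

Two parameters must be supplied explicitly (no defaults): the adipocyte
fraction *a* of total cells and the total cells per gram *c*. The four
convertible units map linearly: per-100-adipocytes `x·a` (100 adipocytes
represent 100/a total cells), per-gram `100·x/c`, percent-of-SVF
`x·(1−a)` (the SVF is the non-adipocyte share), per-total-nuclei `100·x`
with x given as a fraction (one nucleus per cell assumed). These are the
unique linear conversions consistent with the two parameters. sd/se
convert by the same factor, without distributional adjustment.
Per-high-power-field and per-mm² counts depend on section geometry and
always return status `excluded`. Conversion preserves min ≤ mean ≤ max
and is exactly invertible.

## Phenotype statistics

Fractions are bounded in [0, 1] and typically skewed, so all tests are
rank-based: Wilcoxon signed rank for paired designs (zero differences
dropped; exact p for n ≤ 25 without ties, normal approximation with
continuity correction otherwise), Wilcoxon rank sum for independent
groups (exact for small untied samples, tie-corrected otherwise), and a
permutation test on the Spearman correlation for continuous covariates
(two-sided, `p = (#{|ρ_perm| ≥ |ρ_obs|}+1)/(n_perm+1)`, default
n_perm = 10,000, seeded; the permutation loop is vectorized over a
permutation-index matrix). The whole cell-type × trait grid is adjusted
jointly with Benjamini–Hochberg. The reported z-score is the difference
of group means divided by the pooled (both groups together) standard
deviation of the fraction — a standardized separation for heatmap
display, not a test statistic.

## Synthetic data

The generator emulates the structure the real analyses rely on: a shared
log-normal baseline per feature (log-mean ln 100, log-sd 1 — a right-
skewed intensity distribution with a few orders of magnitude of dynamic
range), disjoint planted markers per type raised by a fold-change
(default 8), replicates and mixtures perturbed by multiplicative
log-normal noise parameterized by its CV (default 0.05), and mixture
fractions drawn from a Dirichlet. For four types the default Dirichlet
weights are proportional to the average archetype composition of
subcutaneous adipose tissue (adipocytes 74%, stem/stromal 14.9%, immune
7.4%, other 3.7%); otherwise flat. All generators are bit-reproducible
under a fixed seed.

What the generator does *not* emulate: platform-specific probe effects,
correlated marker blocks, partially overlapping marker sets between
related types (except where a test constructs them explicitly),
compositional noise in the reference labels, or unmodeled cell types in
mixtures. Passing tests therefore demonstrate correctness of the
machinery under the linear-mixing model, not field performance on real
cross-platform data, where accuracy is known to degrade when reference
and mixture platforms differ.

## Numerical choices and degenerate inputs

- Rank deficiency: singular values ≤ 1e-12 × σ_max count as zero; κ = ∞.
- Welch test with zero variance in both groups: p → 0 if the means
  differ, 1 otherwise (the noiseless-reference limit).
- All-zero coefficient vector after clipping raises "no admissible
  composition" rather than returning an arbitrary vector.
- Constant signature columns make correlations undefined and are
  rejected in `signature_correlation`.
- Fractions are validated to sum to 1 within 1e-9 at construction.
- TSV floats are written at 6 significant digits; read–write round-trips
  are exact to that precision.

## Problem sizes

The test-suite and acceptance scenarios use a 300-feature, 6-type
reference with 10 markers/type, fold-change 8, CV 0.05, 5 replicates/type
and 100 mixtures; statistical calibration uses 1000 null replicates of
n = 30 with 999 permutations each. These sizes give stable estimates of
every reported quantity (recovery MAE ~0.007 with binomial-scale
uncertainty well below the 0.05 acceptance bound) while keeping a full
run in seconds.

## Known limitations

- Relative fractions only; no absolute abundance.
- Accuracy depends on reference quality and platform match; the 50%
  feature-overlap floor is a guard, not a fix, and no quantile
  renormalization is applied by default.
- Single-sample cell types use a pooled-variance fallback that
  underestimates type-specific variability.
- The exact marker lists of any published signature depend on the
  reference cohorts used to build it and are not reproduced here.
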