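# Methods

## Model and estimands

Each study i contributes an effect estimate β̂_i, assumed unbiased and
normal with sampling variance σ_i², independent across studies and
independent of its own variance estimate s_i². Writing σ_i² = (n_i φ_i)⁻¹
with φ_i the per-subject information, the package's estimands are the
precision-weighted average β_F = Σσ_i⁻²β_i / Σσ_i⁻² and the
precision-weighted heterogeneity ζ² = Σσ_i⁻²(β_i − β_F)² / Σσ_i⁻². Both are
functionals of the studies at hand; no population of studies is postulated.
The estimate-variance independence assumption is natural for linear-model
effect measures (mean differences, regression slopes) and is the reason
effect measures with strong mean-variance coupling (log odds ratios, rates)
are out of scope.

Key identities the code relies on (and the tests verify independently):

- the minimum-variance affine combination of correlated estimates has
  weights Σ⁻¹1/(1ᵀΣ⁻¹1), reducing to inverse-variance weights for diagonal Σ;
- ζ² equals a precision-product-weighted mean of pairwise squared effect
  differences (no reference to β_F);
- under normality, Q ~ χ²_{k−1}(λ) with λ = Φζ², Φ = Σσ_i⁻², and Q is
  independent of the pooled estimate.

## Estimators and intervals

**Location.** The plug-in pooled estimate uses weights 1/s_i². Its naive
variance 1/Φ̂ ignores weight estimation; its true asymptotic variance is
inflated by `1 + Σ n_i(β_i−β_F)² f_i / Σ n_i φ_i`, where f_i is the
asymptotic variance of √n_i(φ̂_i − φ_i). Intervals:

- *naive*: normal quantiles on 1/Φ̂ (the common-effect benchmark — exact
  when the σ_i are truly known);
- *LSSA*: normal quantiles on the plug-in inflated variance;
- *quasi-F*: Patnaik moment matching approximates χ²_{k−1}(λ̂) by a scaled
  central χ² with scale 1 + λ̂/((k−1)+λ̂) and df (k−1) + λ̂²/((k−1)+2λ̂);
  the signed root of the ratio statistic is referred to Student t with that
  (continuous, non-integer) df. λ̂ uses the truncated ζ̂²₀ ≥ 0 as Patnaik
  requires. Q = 0 to machine precision is rejected as undefined;
- *parametric bootstrap*: effects from N(β̂_i, s_i²), variances from
  s_i²·χ²(df_i)/df_i (per-arm draws on n_j − 1 df recombined for
  Welch-type studies; variances held fixed for known-σ rows). Four interval
  constructions (normal, percentile, bootstrap-t with naive and with LSSA
  standardization); the studentized replicates are centered at the original
  estimate, the standard bootstrap-t form, without which the intervals would
  not be location-equivariant.

**Heterogeneity.** ζ̂² = (Q−(k−1))/Φ̂, reported raw and truncated at 0
(truncation is applied only at the reporting boundary: bootstrap replicates
stay untruncated so their distribution is not distorted). Intervals: the
inverted noncentral-χ² probability interval (endpoints solve
P(χ²_{k−1}(λ) ≤ Q) = 1−α/2 and α/2 on λ, divided by Φ̂; endpoint 0 when Q
falls below the corresponding central quantile), and bootstrap normal /
percentile intervals with endpoints truncated at 0.

**Comparator.** The DerSimonian-Laird random-effects estimator (moment τ̂²
truncated at 0, re-weighted mean, normal interval) is included because its
behaviour under a fixed-effects generating process — overcoverage from
modelling sampling of effects that is not occurring — is part of the story.

## Information-variance functions f_i

With unknown σ_i the package needs f_i per variance model:

- `known`: f = 0 by definition;
- `pooled_normal` / `linear_regression`: the residual variance estimate is
  ς̂² ~ ς²χ²_df/df, so Var(ς̂²) = 2ς⁴/df and the delta method gives
  f̂ = 2φ̂²·(n/df). The n/df factor is kept (rather than the large-n limit
  2φ̂²) because it is the exact variance of the χ²-based precision estimate;
  at n = 100 the difference is 2%;
- `welch_normal`: φ = (n(ς₁²/n₁ + ς₂²/n₂))⁻¹ and each arm variance has
  Var(ς̂_j²) = 2ς_j⁴/(n_j−1), combined by the delta method. Using per-arm
  df n_j − 1 (which sum to n − 2) makes the equal-arms, equal-variance limit
  coincide exactly with the pooled formula.

Normality of outcomes is assumed throughout these forms; excess kurtosis
would enter f additively. For non-normal outcomes a per-study `f_override`
can be supplied instead of the model-based value.

## Simulation design

The generator emulates balanced two-arm trials with normal outcomes and a
mean-difference effect: σ_i² = 4ς²/n, β̂_i ~ N(β_i, σ_i²), residual
variances ς̂_i² ~ ς²χ²(n−2)/(n−2), hence s_i² = 4ς̂_i²/n with n − 2
residual df. True effects are uniformly spaced around β_F with spacing
d = √(12ζ²/(k²−1)), which makes the (equal-precision) weighted mean squared
deviation exactly ζ². "n" is the per-study total, balanced across arms.

Default grids span k ∈ {3,5,7,15}, n ∈ {20,40,60,100,400},
ζ² ∈ {0,0.25,1,2.25} with equal per-study n; unequal sizes are supported but
not default. The harness reports binomial Monte-Carlo standard errors so
coverage claims carry their own uncertainty. Routine runs use 1000–2000
outer replicates with B = 500 bootstrap draws — enough to resolve coverage
to better than one percentage point — while B = 2000 is the analysis-time
default for a single data set.

What the generator does *not* emulate: unbalanced arms, non-normal outcomes
(kurtosis ≠ 0 changes f_i), mean-variance coupling, correlated studies, or
publication selection. Passing coverage here therefore demonstrates
correctness of the inferential machinery under the stated sampling model,
not robustness to those departures.

## Numerical choices

- Noncentrality root-finding: the ncx2 cdf at fixed Q is strictly decreasing
  in λ, so the bracket [0, hi] is grown by doubling until the sign changes,
  then solved by Brent's method to 1e-8 on λ.
- Empirical quantiles are type-1 (inverse ecdf, ceiling indexing): the
  p-quantile of B values is the ⌈pB⌉-th order statistic — unambiguous and
  directly testable against a sort-based oracle.
- Bootstrap randomness comes from one PCG64 stream per draw set: the B×k
  effect matrix is filled replicate-major in one call, then replicate
  variances study-by-study, so (input, B, seed) reproduces results
  bit-for-bit. The harness derives per-replicate bootstrap seeds from its
  own seeded stream.
- I² is truncated at 0; ζ̂² is reported raw and truncated; replicate
  variance draws enter weights as drawn (χ² draws are a.s. positive).
- Single-study inputs are rejected everywhere: pooling one study is not a
  supported degenerate case.
- The quasi-F statistic uses plain Q computed with the estimated s_i; the
  inflation-factor center is the plug-in pooled estimate itself.

## Known limitations

- The f_i catalogue covers normal-theory mean differences (pooled and
  Welch) and linear regression; other effect measures need `f_override`.
- The noncentral-χ² interval for ζ² assumes known σ_i; with estimated
  standard errors it is applied with Φ̂ in plug-in spirit, and simulation
  shows it holds its coverage at moderate n (≥ 40 per study) but it carries
  no small-sample guarantee.
- Bootstrap percentile intervals for ζ² undercover when heterogeneity is
  low and k is large, a known consequence of the statistic's non-normal
  distribution there; the noncentral-χ² interval is the recommended default.
- No BCa or nonparametric (study-resampling) bootstrap; no ML/REML τ²
  estimators beyond DerSimonian-Laird.
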