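# Methods

## The two-sample MR model

For each instrument k, the exposure GWAS provides an effect β̂ₓₖ with
standard error σₓₖ and the outcome GWAS provides β̂ᵧₖ with σᵧₖ, both in SD
units of their trait per effect allele, estimated in non-overlapping
samples.  Under the instrumental-variable assumptions (relevance,
independence from confounders, exclusion restriction) each Wald ratio
β̂ᵧₖ/β̂ₓₖ estimates the same causal effect β, and the estimators differ in
how they pool ratios and in which violations they tolerate:

- **Fixed-effect IVW** weights each ratio by (β̂ₓₖ/σᵧₖ)², equivalent to
  weighted least squares of β̂ᵧₖ on β̂ₓₖ through the origin with weights
  σᵧₖ⁻².  It is efficient when every instrument is valid.  The reported
  standard error is √(1/Σβ̂ₓₖ²σᵧₖ⁻²) — the standard IVW form; note the
  variance, not its square root, equals 1/Σβ̂ₓₖ²σᵧₖ⁻².
- **Random-effects IVW** uses a multiplicative overdispersion model: the
  fixed SE is inflated by √(Q/(K−1)) when Cochran's Q exceeds its degrees
  of freedom, and never deflated (floor at 1).
- **Weighted median**: order the ratios, accumulate normalized weights
  wₖ = (β̂ₓₖ/σᵧₖ)² (each ratio centred on its own mass, Sₖ = Σ_{j≤k}wⱼ −
  wₖ/2), and linearly interpolate the ratio at cumulative weight 0.5.
  Consistent as long as valid instruments carry more than half of the total
  weight.  Its SE comes from a parametric bootstrap: each β̂ₓₖ and β̂ᵧₖ is
  resampled from a normal distribution at its observed value and SE, the
  median is recomputed, and the SD over 1,000 (default) replicates is
  reported.  The bootstrap seed is a mandatory argument.
- **MR-Egger**: orient instruments so β̂ₓₖ ≥ 0 (a joint sign flip leaves the
  Wald ratio unchanged), then fit β̂ᵧₖ = α + β·β̂ₓₖ by WLS with weights
  σᵧₖ⁻².  The intercept α estimates the average directional pleiotropic
  effect under InSiDE (pleiotropy independent of instrument strength); the
  slope is a pleiotropy-adjusted causal estimate.  SEs carry the same
  multiplicative overdispersion floor; inference uses t with K−2 df, the
  small-K regression convention, whereas IVW and Wald use the normal.

Confidence intervals default to 95%.  Significance in the pipeline is
declared at α_overall/bonferroni_k (default 0.05/2 = 0.025), the Bonferroni
rule for testing two exposures against one outcome.

## Harmonization rules

Exposure and outcome tables are joined on rsid only (no proxy lookup).
With the exposure's allele pair as reference, an outcome record is: kept
as-is when alleles match; beta-negated (and EAF reflected) when they are
swapped; complemented first when they match only on the opposite strand.
Palindromic pairs (A/T, C/G) are strand-ambiguous, so orientation comes
from allele frequency: the SNP is kept only when both EAFs lie on the same
side of 0.5 *and* outside the ambiguity band [limit, 1−limit] (default
limit 0.42); missing EAF, in-band, or opposite-side frequencies drop the
SNP — the conservative choice, since a frequency conflict may be a
population difference rather than a strand flip.  Dropped records are
returned with `action_taken="dropped"` for the run log but are filtered out
of every estimator.  Within one file, a duplicated rsid keeps the
lowest-p-value row (lead-SNP semantics) with a warning.

## Clumping

Greedy selection: repeatedly keep the remaining SNP with the lowest p-value
(≤ 5×10⁻⁸ by default), then discard every remaining SNP on the same
chromosome within 1 Mb (inclusive) whose r² with it is ≥ 0.01.  Ties break
by (chromosome, position, rsid).  In-window pairs absent from the LD matrix
are treated as r² = 0 with a warning (the matrix is supplied by the user or
the generator; the tool runs offline), or raise in `missing_ld="error"`
mode.  The output is idempotent under re-clumping and monotone in the r²
threshold.

## Power

Treating the IVW estimate as asymptotically normal with non-centrality
λ = |β|·√(N_outcome · r²_exposure), two-sided power at level α is
1 − Φ(z₁₋α/₂ − λ) + Φ(−z₁₋α/₂ − λ), and the minimal detectable effect at a
target power inverts the dominant term:
β_min = (z₁₋α/₂ + z_power)/√(N·r²).  The neglected far tail is < 10⁻⁴ at
the λ of interest, so `mr_power(min_detectable_effect(...))` returns the
target to ~10⁻³.  With N = 264,498 and r² = 0.094 (resp. 0.048) at 80%
power, β_min = 0.0178 (resp. 0.0249) SD/SD.

## The synthetic-data generator

The generator works at the summary level, which matches the two-sample
sampling model exactly and keeps runtime at desk scale; no individual-level
genotypes are simulated.

Defaults (the study conditions every simulation-based test runs under):
K = 40 instruments; exposure GWAS n = 72,167; outcome GWAS n = 264,498;
total exposure variance explained r² = 0.094 (an FT4-like preset gives
K = 21, r² = 0.048); MAF uniform on (0.05, 0.5); per-SNP target F
statistics log-uniform on [64, 496] before rescaling to the total r²;
causal effect 0; no pleiotropy.  Per-SNP standard errors are the
standardized-trait forms σ = 1/√(2p(1−p)n); observed effects are
independent normal draws around the truth, with two-sided normal p-values.

Horizontal pleiotropy is parameterized **in the exposure-increasing allele
frame**: a directional mean μ_α would otherwise be washed out by the
arbitrary sign of each effect allele (Egger regression orients instruments
before fitting, so only frame-consistent pleiotropy is directional).
Modes: `none`; `balanced` (mean-zero normal); `directional` (mean μ_α,
InSiDE holds); `inside_violating` (α coupled to |γ|, violating InSiDE).

Allele perturbations (`swap`, `strand_flip`, `palindromic`) are applied to
the outcome table's encoding with the ground-truth label stored, so tests
can assert that harmonization recovers every injected change; palindromic
variants resolve exactly when the MAF lies outside the ambiguity band.

What the generator does **not** emulate: realistic LD (blocks are exactly
block-diagonal), winner's curse in instrument discovery, sample overlap
between the two GWAS, population stratification, or allele-frequency
differences between studies.  Passing simulation tests therefore
demonstrate correctness of the estimators and plumbing under the stated
sampling model, not robustness to those real-data complications.

## Numerical and design choices

- Wald SE uses the first-order form σᵧₖ/|β̂ₓₖ| (no second-order term),
  consistent with the IVW weights.
- Fixed-effect IVW accepts a single instrument, where it reduces exactly to
  the Wald ratio; the random-effects variant needs K ≥ 2 (Q has K−1 df),
  the weighted median and Egger need K ≥ 3.
- In the Egger fit, exact or under-dispersed data would give residual
  variance < 1; the floor keeps SEs at or above the analytic weighted-LS
  values (and keeps them positive for an exact fit).
- The weighted-median bootstrap may produce zero SD only when all resampled
  medians coincide; the SE is then set to the smallest positive float so CI
  invariants hold.
- Variance explained is computed from frequencies, r² = Σ2p(1−p)β̂ₓₖ², when
  every EAF is present; otherwise the F-based approximation F/(F+n−2) is
  used and the report records which formula applied.
- Summary tables are written with `repr` floats, so write→read round-trips
  are bit-exact.
- All stochastic operations (bootstrap, generator) take an explicit seed;
  pipeline outputs are byte-identical under a fixed seed (the run log,
  which carries timestamps, is the one exception).

## Known limitations

- At realistic instrument strength (mean F ≈ 200) the MR-Egger intercept
  shows a small finite-sample inflation: measurement error in β̂ₓₖ dilutes
  the slope, and the lost slope mass appears in the intercept
  (≈ β(1−I²_GX)·E[|β̂ₓ|]; about +5% of μ_α = 0.01 in the recovery
  simulations).  This is a property of the estimator, not of the
  implementation, and the recovery tests budget for it.
- The Q test inherits slight anti-conservatism from using estimated β̂ₓₖ in
  the weights (first-order weights); modified second-order weights are out
  of scope.
- Binary outcomes, MR-PRESSO, mode-based estimators, multivariable and
  non-linear MR are not implemented.
- Power simulation sizes: recovery/coverage use 400–500 replicates and the
  calibration checks 1,000, sized to keep Monte-Carlo error a small
  fraction of the tested tolerances.
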