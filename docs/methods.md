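# Methods

## Causal model and estimators

The package implements two-sample MR: genetic variants serve as
instrumental variables for a modifiable exposure, with exposure and
outcome associations taken from non-overlapping GWAS. For instrument j
with harmonized effects (β_exp,j, SE_exp,j) and (β_out,j, SE_out,j), the
per-SNP causal estimate is the Wald ratio

    β̂_j = β_out,j / β_exp,j,    SE(β̂_j) = SE_out,j / |β_exp,j|

(first-order delta approximation: exposure-side noise is ignored in the
ratio SE, the convention of summary-data MR; its consequence — a small
regression-dilution of IVW of order 1/F̄ — is measured in the tests).

**IVW.** The precision-weighted mean of the Wald ratios with weights
w_j = 1/SE(β̂_j)², algebraically the weighted least-squares slope of
β_out on β_exp through the origin with weights 1/SE_out². Fixed-effects
SE is (Σw_j)^(−1/2); the default multiplicative random-effects variant
scales it by √(max(1, Q/(k−1))), so heterogeneity widens but never
narrows the interval. With k = 1 both reduce to the Wald ratio.

**MR-Egger.** The same weighted regression with a free intercept, after
orienting every instrument so β_exp,j > 0. The slope is a causal estimate
robust to directional pleiotropy under the InSIDE assumption; the
intercept estimates the mean (oriented) direct effect, and its two-sided
normal test flags directional pleiotropy. Parameter SEs use the
multiplicative random-effects convention with the residual variance
factor floored at 1.

**Weighted median.** The value at cumulative standardized weight 1/2
across the sorted Wald ratios (linear interpolation; the plain median
under equal weights), consistent while valid instruments carry a
majority of weight. Its SE comes from a seeded parametric bootstrap
(default 5,000 redraws of β_exp,j and β_out,j from their sampling
distributions).

p-values use the normal reference distribution throughout — the choice
that reproduces the OR/CI/p consistency of published summary-data MR
tables — and 95% CIs use the conventional 1.96 multiplier on the log-odds
scale. No multiple-testing correction is applied by default (a
Benjamini–Hochberg gate can be enabled); the screening significance level
is two-sided α = 0.05.

## Instrument selection and harmonization

Instruments pass p < 1 × 10⁻⁵ (strict inequality) and greedy LD clumping:
repeatedly keep the smallest-p remaining SNP (ties broken by snp_id for
determinism) and drop same-chromosome SNPs within 10,000 kb whose r² with
it is ≥ 0.001. The window is center-to-center; LD comes from an explicit
reference (coordinate TSV + symmetric r² matrix), never a remote panel.
Per-SNP strength is R² = 2·EAF·(1−EAF)·β² (additive biallelic variant in
HWE on a unit-variance trait) and F = R²(N−2)/(1−R²); F < 10 flags — but
does not remove — weak instruments, with an optional `min_f` filter.

Harmonization aligns the outcome to the exposure's effect allele: swapped
alleles negate β_out and complement the frequency; strand complements are
re-matched; palindromic SNPs are aligned by which side of 0.5 the two
frequencies fall on, and dropped when either frequency is within 0.08 of
0.5 (or missing) — the window inside which strand cannot be inferred.
Indels match by exact string equality only. Every action (kept, flipped,
dropped_palindromic, dropped_mismatch) is logged per SNP.

## Two-step mediation

For exposure X, mediator Z, outcome Y:

* step 1: a = effect of X on Z, estimated with X's instruments;
* step 2: b = effect of Z on Y, estimated with **Z's own instruments** —
  using X's instruments here would return c/a, not b, because their
  effect on Z runs entirely through X;
* total effect c from X's instruments against Y.

Indirect effect = a·b with delta-method SE √(a²SE_b² + b²SE_a²) (a seeded
Monte-Carlo product-of-normals CI is available for weak paths); direct
effect c′ = c − a·b, so direct + indirect = total holds exactly; mediated
proportion = 100·a·b/c. A mediator enters the scan table only when steps
1 and 2 are both significant at α. Two suppression rules are provided:
`footnote` (suppress when the indirect effect's 95% CI includes zero or
the proportion is negative — the stricter published convention) and
`negative_only` (suppress only sign-inconsistent mediation). The
reference 15-metabolite table reproduces its printed reported/suppressed
pattern under `negative_only`; under a literal reading of `footnote`
every row would be suppressed, which is why both rules are exposed.

The full study pipeline screens every taxon forward (IVW primary; Egger
and weighted median as complements; heterogeneity/pleiotropy/outlier
battery), excludes taxa whose reverse-direction estimate (disease as
exposure, same selection threshold) is significant — a bidirectional
relationship cannot be decomposed this way — and runs the mediator scan
for the carried-forward taxa. The pipeline is a pure function of
(inputs, config, seed); a run manifest records the seed, config hash and
package version.

## Synthetic-data generator

The generator encodes the mediation path diagram as a linear structural
model over unlinked HWE SNPs (g for the exposure's instruments, h for the
mediator's):

    X = Σ γ_j g_j + ε_x
    Z = a X + Σ δ_k h_k + ε_z
    Y = c′ X + b Z + Σ_{invalid} α_j g_j + ε_y

so c = c′ + a·b and the true proportion is 100·a·b/c. Summary statistics
are produced analytically: expected marginal effect plus Gaussian noise
with SE = 1/√(2·MAF(1−MAF)·n_eff), independent across the three cohorts
(the two-sample design), where n_eff = n for quantitative traits and
n·cf(1−cf) for a binary outcome with case fraction cf. Effect alleles are
randomly re-oriented in the mediator and outcome files so harmonization
is exercised end to end. A genotype-level mode validates the analytic
shortcut at small n.

Defaults (the benchmark study conditions): 50 instruments each for
exposure and mediator with per-SNP effects of random sign and magnitude
uniform in [0.5, 1.5] × 0.12 (≈ 28% exposure variance explained, mean
single-SNP F ≈ 150 — strong-instrument territory); cohort sizes 20,000
(exposure), 20,000 (mediator) and 350,000 balanced case-control
(outcome); MAF uniform on [0.05, 0.5]; structural coefficients a = 0.3,
b = 0.2, c′ = 0.1. These sizes were chosen so that estimator properties
(CI coverage, per-replicate proportion recovery) are measured at good
power rather than drowned in outcome-side noise; a `finngen_like()`
preset (410k participants, case fraction 0.005) reproduces the
rare-disease imbalance of biobank case-control GWAS for realism studies,
at which scale single-study mediated-proportion estimates are very noisy.
The mediator cohort is deliberately not larger: at ~20k the exposure
SNPs' induced effects on the mediator (a·γ_j) stay below the selection
threshold, keeping the mediator's instrument set uncontaminated; much
larger mediator GWAS would admit shared instruments whose step-2 ratios
estimate c/a and bias b upward — a real phenomenon users should be aware
of.

Directional pleiotropy is injected aligned with each instrument's
exposure-effect sign (α_j = sign(γ_j)·N(scale, scale²) on the invalid
fraction): after the standard β_exp > 0 orientation the direct effects
share a sign, which is what makes the bias directional and detectable by
an Egger intercept. Orientation-independent injection would be balanced
by construction. Optional LD blocks place SNPs 100 kb apart with a given
pairwise r² to exercise clumping; they do not model true signal tagging.

What the generator does **not** emulate: genome-wide LD structure and
proxy SNPs, sample overlap between cohorts, population stratification,
binary-trait liability-scale nonlinearity (outcome betas are treated as
log-odds with the SE model above), and selection of instruments from
scans of millions of SNPs (panels contain the instruments plus the other
traits' instruments). Passing tests therefore demonstrate correctness of
the estimators and pipeline logic under the stated model, not robustness
to those real-data complications.

## Numerical choices and edge cases

* p-values of exactly 0 on input are clamped to the smallest positive
  double (downstream −log₁₀ displays); alleles are uppercased on read.
* Clumping removes at r² ≥ threshold (strictly-below survives), matching
  common clumping semantics; p-ties break lexicographically.
* MR-PRESSO: observed statistic is the leave-one-out weighted residual
  sum of squares; the null is rebuilt by parametric simulation (default
  1,000 draws, floor 100), global p = (1 + #{sim ≥ obs})/(n_sim + 1),
  per-SNP outliers at Bonferroni 0.05/k, distortion test omitted.
  Bit-identical results for identical (inputs, seed).
* Degenerate inputs: β_exp = 0 instruments raise a degenerate-instrument
  error; < 3 instruments disable Egger/median; a zero total effect makes
  the mediated proportion undefined (suppressed with reason); exposures
  with no surviving instruments are recorded as not-analyzable, never
  fatal to a study run.
* The weighted-median bootstrap SE guards against zero/NaN degeneracies
  by flooring at the smallest positive double.

## Known limitations

* The Wald-ratio SE ignores exposure-side noise; with weak instruments
  IVW attenuates toward zero by ≈ 1/F̄ (measured at ~1% at the benchmark
  defaults). MR-RAPS-style corrections are out of scope.
* The mediated-proportion estimator is a ratio of noisy quantities: its
  small-sample distribution is skewed, and at biobank-realistic outcome
  power (see `finngen_like`) single-study proportions should be read as
  order-of-magnitude statements.
* Confounder screening of instruments (e.g. against external phenotype
  databases) is supported only as a user-supplied exclusion list; no
  external service is queried.
* Only the two-step/product-of-coefficients mediation decomposition is
  implemented; multivariable-MR difference methods are not.
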