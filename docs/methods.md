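# Methods

This note records the models, conventions, parameter choices and known
limitations behind `tsmr`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study design being modelled

Two-sample summary-data Mendelian randomization: genetic variants
robustly associated with a continuous exposure (PM2.5 per SD, GWAS
n = 423,796) serve as instruments for its effect on a binary outcome
(gestational diabetes; 6,033 cases / 123,000 controls), with exposure
and outcome effects taken from non-overlapping samples. Causal
estimates are log odds ratios per SD of exposure. The instrument
assumptions are the usual three (relevance, independence from
confounders, no direct outcome pathway); the estimator battery exists
precisely because the third is untestable SNP by SNP.

## Instrument selection

- p-value screen, default p < 1e-5. The lenient threshold (rather than
  genome-wide 5e-8) reflects exposures with few genome-wide-significant
  hits; both thresholds are plain parameters.
- Greedy LD clumping: SNPs ranked by ascending p; a SNP is discarded
  iff some retained SNP on the same chromosome lies within the window
  (default 10,000 kb) and has r² > 0.001 with it. Pairs outside the
  window are treated as independent whatever the LD table says; a
  missing LD entry is r² = 0. Ties in p break by smaller position, then
  lexicographic rsid, making output deterministic and order-invariant.
- Phenome-screen exclusions are an offline rsid list: a live
  web-service query is version-dependent and irreproducible, so the
  caller supplies the list of variants flagged as pleiotropic.
- Proxy search (for instruments absent from the outcome file) takes the
  candidate with maximal r² among those ≥ 0.8, ties by base-pair
  distance (when the query coordinates are supplied) then rsid.
- Instrument strength: r²ⱼ = β²/(β² + n·se²), Fⱼ = r²ⱼ(n−2)/(1−r²ⱼ);
  with unknown n the large-sample fallback F ≈ (β/se)² is used and
  flagged. Total variance explained is Σr²ⱼ, valid because instruments
  are approximately independent after clumping.

## Harmonization

Effects are expressed on the exposure file's effect allele; the
exposure orientation is never flipped, so γ keeps its original units.
Non-palindromic variants: direct match → copy; swapped alleles → negate
the outcome beta and mirror its frequency; otherwise strand-complement
the outcome alleles and retry; failing all three, drop as allele
mismatch. Palindromic variants (A/T, C/G) cannot be resolved from
alleles: they are aligned purely by effect-allele frequency (opposite
sides of 0.5 ⇒ flip) and only kept when MAF < 0.3 in **both** datasets
— the two-sided ambiguity window [0.3, 0.7] operationalizes "retain
palindromes when MAF < 0.3", and a missing frequency drops the variant
(conservative). Every input SNP is accounted for exactly once as kept
or dropped.

## Estimators

All five operate on the harmonized pairs (γ̂ⱼ, Γ̂ⱼ); ratio-based
methods use first-order SEs sⱼ = se(Γ̂ⱼ)/|γ̂ⱼ|.

- **IVW**: weights se(Γ̂ⱼ)⁻², slope through the origin. Default flavor
  is multiplicative random effects — SE scaled by max(1, σ̂) with σ̂²
  the weighted residual mean square on J−1 df — which equals the
  fixed-effect SE under homogeneity and never undercuts it;
  fixed-effect is available by flag. p-values from the normal.
- **MR-Egger**: pairs oriented so γ̂ⱼ ≥ 0, weighted regression with
  intercept; slope and intercept use t(J−2), SEs scaled by max(1, σ̂).
  The intercept is the directional-pleiotropy estimate/test.
- **Weighted median**: mid-cumulative convention pⱼ = cumⱼ − wⱼ/2 with
  linear interpolation at 0.5, inverse-variance weights.
- **Mode estimators**: Gaussian kernel over the ratios, bandwidth
  h = φ·0.9·min(sd, mad/0.6745)·J^(−1/5) (φ default 1); if sd or mad
  collapses to zero the other is used; all ratios identical returns the
  common ratio with SE 0. The argmax is taken on an evenly spaced grid
  (default 10,000 points) over [min−2h, max+2h]; grid ties take the
  lowest value.
- **Bootstrap SEs** (median and modes): parametric — resample
  b̂ⱼ* ~ N(b̂ⱼ, sⱼ), re-estimate, SD over n_boot draws (default 1000,
  always seeded); p-values from the normal approximation.
- Odds-ratio scale: OR = exp(β), CI = exp(β ∓ z·se) at 95%; the
  exponential saturates to 0/∞ rather than overflowing for the extreme
  SEs that near-zero exposure effects can produce.

### Known inferential properties

- The parametric bootstrap over-disperses when instruments are of
  similar strength: under homogeneity the scatter of the observed
  ratios already equals their sampling noise, so resampling around them
  roughly √2-inflates the SE. Consequence (computed in the acceptance
  suite): at the default study conditions the weighted median rejects a
  true null at ~1.8% and the modes at well under 1% at nominal 5% —
  conservative, never anticonservative. IVW is calibrated (~3.5–5%).
- First-order SEs ignore exposure-side noise (the NOME approximation).
  At the default study scale (mean F ≈ 290) this inflates Cochran's Q
  by about 1/F·β²·(se ratio)² ≈ 1.7% and attenuates regression slopes
  by ~1/F, shifting the Egger intercept by the corresponding amount.
  Calibration simulations that test these approximations (Q uniformity,
  intercept recovery, MVMR recovery) therefore run at 10× exposure
  sample size, the regime the approximations assume; the paper-scale
  recovery and coverage checks run at study scale, where the ~0.4%
  slope attenuation is inside their tolerance.

## Sensitivity diagnostics

Cochran's Q uses the Wald-ratio form around the fixed-effect IVW
estimate (its minimizer), χ²(J−1); I² = max(0, (Q−df)/Q) is reported as
a free extra. The Egger intercept block is re-exposed as a standalone
test. Leave-one-out re-runs IVW J times plus the all-SNP row; the
forest table is the per-SNP Wald ratios plus the pooled IVW row; the
funnel table pairs each ratio with its precision 1/sⱼ and carries the
IVW and Egger reference lines. Plot rendering is deliberately left to
the caller — the TSV tables are the canonical outputs.

## Multivariable MR

MVMR-IVW regresses Γ̂ on the J×K exposure-effect matrix with no
intercept, weights se(Γ̂ⱼ)⁻², SEs scaled by max(1, σ̂) on J−K df,
t-based p-values. K = 1 reduces exactly to univariable IVW (tested to
machine precision). Instrument assembly selects per exposure, pools,
clumps jointly on the minimum p across exposures (the assembly rule is
this package's choice — there is no universal convention), requires a
beta in every exposure and the outcome, and aligns all files to the
first exposure's allele orientation. Collinear exposure columns are a
hard error naming the offending exposures. Weights use outcome SEs
only; conditional-F weak-instrument corrections are out of scope.

## Power

The binary-outcome non-centrality approximation:
power = Φ(|ln OR|·√(n·R²·p(1−p)) − z_{1−α/2}), two-sided α, positive
tail. At OR = 1 this returns the α/2 tail (0.025), not 0. The default
outcome denominator is cases + controls (129,033); the control-cohort
total (123,000) gives the same rounded answer at the study
configuration. `minimum_detectable_or` inverts the formula by monotone
root-finding on ln OR (relative tolerance 1e-6).

## Synthetic data generator

Summary statistics are simulated directly at the summary level — no
individual-level genotypes — because two-sample MR consumes only
summary data and this keeps thousand-replicate studies at desk scale.
Per SNP: maf ~ U(0.05, 0.5); genotype variance 2·maf(1−maf); exposure
SE 1/√(2maf(1−maf)·n_X); outcome SE uses the harmonic effective size
n_eff = 4/(1/cases + 1/controls). True effects carry a share
~ U(0.5, 1.5) of the total R² with random sign: the generator emulates
*post-screen* instruments of comparable, genuinely strong effect (the
default configuration yields per-SNP F in the hundreds), and does not
model the discovery screen or its winner's curse. Planted pleiotropy
αⱼ enters as Γⱼ = β·γⱼ + sign(γⱼ)·αⱼ — directional with respect to the
exposure-increasing allele, the orientation in which directional
pleiotropy is defined. Allele bookkeeping plants a configurable
fraction of palindromic SNPs and of swapped outcome codings; LD blocks
(for clumping/proxy tests) are emitted as an explicit pairwise r²
table. The two samples are independent by construction.

Defaults are the study conditions: 85 SNPs, n_X = 423,796,
6,033/123,000 outcome, total R² = 5.85%, true log-OR 0.551,
palindromic fraction 0.1, swapped fraction 0.2, no pleiotropy.

What passing simulation tests do **not** show about real data: no
genome-wide LD background, no winner's curse from the discovery
threshold, no sample overlap, allele frequencies identical across
cohorts (up to planted recodings), and exactly the assumed SE model.
A note on internal consistency of the emulated study: a total R² of
5.85% over 85 instruments at n = 423,796 implies mean per-SNP F near
290, which cannot coexist with a per-SNP F range of 19.6–69.9; the
generator follows the stated total R², so its simulated F statistics
and IVW standard errors are correspondingly larger/smaller than the
published per-SNP range and SE.

## Weighted-median breakdown region

The interpolated weighted median has an exact finite-sample containment
property only on a restricted region: perturbing a minority subset S of
instruments cannot move the estimate outside the unperturbed ratio
range provided weight(S) ≤ 1/2 − max_j(w_j)/2. Outside that region the
interpolation segment adjacent to a perturbed point can straddle the
0.5 quantile and the estimate tracks the perturbation; the familiar
"50% breakdown" is asymptotic (individual weights → 0). The acceptance
suite verifies containment exhaustively on 5-SNP instances inside the
region (hundreds of thousands of cases).

## Problem sizes and numerical choices

Simulation studies in the tests and acceptance script use 200–500
replicates, bootstrap count 100 and a 1,000-point mode grid — sizes
chosen to keep a full run at desk scale while leaving Monte-Carlo SEs
an order of magnitude below the tolerances tested. Production defaults
(n_boot = 1000, grid 10,000) are used everywhere a single analysis is
run. All randomness flows through explicit integer seeds; a fixed seed
makes every pipeline output byte-identical on rerun, bootstrap SEs
included (floats are written with shortest round-trip repr). p-values
from simulated z-scores are floored at 1e-300 to stay inside (0, 1].

## Known limitations

No GWAS-VCF parsing, liftover, or remote data access; LD comes from a
user-supplied table, never computed from reference panels; no
MR-PRESSO/radial/Steiger-style outlier or directionality filtering; no
conditional-F or MVMR-Egger; continuous-outcome power is not
implemented. Positions are treated as opaque 1-based coordinates
assumed consistent between files.
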