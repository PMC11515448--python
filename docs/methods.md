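# Methods

## Model and estimators

All estimators act on a harmonized instrument set: per-SNP quadruples
(γ̂ⱼ, σ_Xⱼ, Γ̂ⱼ, σ_Yⱼ) with the outcome effect expressed for the exposure's
effect allele, both effects on the log-odds scale. The working causal model
is linear on the liability scale, Γⱼ = θ·γⱼ + αⱼ, where αⱼ is a direct
(pleiotropic) effect; a valid instrument has αⱼ = 0.

**Radial IVW (principal estimator).** With ratio estimates θⱼ = Γ̂ⱼ/γ̂ⱼ and
weights Wⱼ, the radial parameterization regresses yⱼ = √Wⱼ·θⱼ on
xⱼ = √Wⱼ with zero intercept; the slope equals ΣWⱼθⱼ/ΣWⱼ and each SNP's
squared residual is its Cochran Q contribution qⱼ = Wⱼ(θⱼ − θ̂)². Modified
second-order weights Wⱼ(θ) = γ̂ⱼ²/(σ_Yⱼ² + θ²σ_Xⱼ²) account for sampling
error on both axes; because they depend on θ, the fit is a fixed point,
iterated from the first-order solution with tolerance 1e-10 and a cap of
100 iterations (non-convergence is an error carrying the iterate trail; in
practice convergence takes < 10 iterations because θ²σ_X² ≪ σ_Y²).
The SE is (ΣWⱼ)^(−1/2) inflated by max(1, √(Q/df)) — a multiplicative
random-effects convention whose floor at 1 prevents shrinkage below the
fixed-effect SE under homogeneity; `random_effects=False` gives the plain
fixed-effect SE. Inference is two-sided normal.

**Radial MR-Egger.** The same radial variables with a free intercept β₀,
which absorbs directional pleiotropy; the slope is consistent under the
InSIDE assumption (instrument strength independent of direct effects).
Residual squares define Rücker's Q′ on df = L − 2. The Egger SEs use the
regression dispersion √(Q′/df) *without* a floor: this keeps the intercept
t-test (df = L − 2) exactly calibrated under homogeneity, which is the
property the intercept test exists for. (Flooring the dispersion at 1, as
is sometimes done for the causal-estimate SE, makes the intercept test
conservative — roughly 2% type-I error at nominal 5% in our null
simulations — so the package deliberately uses the standard weighted-least-
squares convention for the Egger fit.) A numerically perfect fit
(Q′ below round-off scale) is reported with zero SEs and p = 1.

**Weighted median.** Ratios ordered ascending; with first-order weights
wⱼ = γ̂ⱼ²/σ_Yⱼ², the estimate interpolates the ordered ratios at
standardized cumulative weight 0.5. Consistent while valid instruments hold
more than half the weight. SE by parametric bootstrap: (γ̂*, Γ̂*) drawn
normal around the observed effects with their SEs (default 2000 draws,
explicit seed).

**Weighted mode.** Gaussian-kernel weighted density of the ratios with
bandwidth h = φ·0.9·min(sd, 1.4826·MAD)·L^(−1/5) (φ = 1 by default),
evaluated on a 512-point grid spanning the ratios ± 3h; the estimate is the
density argmax (exact ties resolve to the peak with larger local weight,
with a warning). Zero-spread degenerates to the common ratio. Bootstrap SE
as for the median.

**MR-RAPS.** Solves the profile-score equation Σⱼ ψ(tⱼ)·∂tⱼ/∂θ = 0 with
standardized residuals tⱼ = (Γ̂ⱼ − θγ̂ⱼ)/√(σ_Yⱼ² + θ²σ_Xⱼ² + τ²); ψ is the
identity (`plain`) or Huber with k = 1.345 (`huber`). The overdispersion
parameter τ² ≥ 0 (systematic balanced pleiotropy) is profiled out by
matching the second moment of ψ(t)·t to its standard-normal expectation
E[ψ(Z)Z] (= 2Φ(k) − 1 for Huber), using nested Brent root-finding bracketed
around the IVW estimate (the bracket widens once before erroring). SE by
the sandwich formula with E[ψ(Z)²] computed in closed form. The default
variant is overdispersion on with Huber loss — the configuration that
motivates using RAPS at all (weak instruments, extreme outliers under
balanced pleiotropy) — and the fitted variant plus τ̂² are recorded in the
estimate's diagnostics.

**Fixed-effect meta-analysis.** Inverse-variance pooling
b = Σ(b_k/se_k²)/Σ(1/se_k²), se = (Σ1/se_k²)^(−1/2), Wald p; inputs must
share method and outcome labels.

## Heterogeneity and pleiotropy diagnostics

Q refers to the zero-intercept radial model (χ², df = L − 1), Q′ to the
Egger model (df = L − 2); because the Egger model nests the IVW model under
shared weights, Q′ ≤ Q always, their difference is tested on χ²(1), and the
ratio Q′/Q is reported descriptively only (no accepted reference
distribution; defined as 1 when Q = 0). Per-SNP qⱼ are referred to χ²(1).

MR-PRESSO uses leave-one-out residuals: RSS = Σⱼ (Γ̂ⱼ − θ̂₍₋ⱼ₎γ̂ⱼ)²/σ_Yⱼ²
with first-order leave-one-out IVW estimates — the outcome-variance-
weighted (simple) variant of the published test. The null is built by
parametric bootstrap under the no-pleiotropy model (Γ* centred on
θ̂₍₋ⱼ₎γ̂ⱼ); all bootstrap p-values use the add-one rule and are therefore
bounded below by 1/(B+1), never exactly zero (B = 1000 by default).
Per-SNP outlier p-values are Bonferroni-adjusted by L. The distortion
coefficient is 100·(θ̂_all − θ̂_without)/|θ̂_without|, with a p-value from
random same-size removals. Distortion is reported but never feeds back into
which estimate is primary.

## Iterative pipeline

Each pass fits the radial IVW, removes **all** SNPs with per-SNP Q p < α_Q
(= 0.01) at once — one-at-a-time removal is available via
`remove_one_at_a_time` — and stops when the global Q p-value is ≥ α_Q, no
SNP breaches, the cap of `max_iterations` (default 3) is reached, or
removal would leave fewer than two instruments (the previous fit is kept
and flagged `floor_reached`). The trace records every iteration's SNP set,
estimate and removals, so the full audit trail is recoverable; the
first-vs-last comparison reports Δθ̂, the estimate ratio, and a consistency
flag (same sign and overlapping 95% CIs; only sign agreement gates the
`consistency_check` between primary and plausibility exposures, an exactly
zero estimate counting as consistent).

The estimator battery and the diagnostic bundle run on the **final**
(post-removal) set; MR-PRESSO additionally runs on every iteration's set.
Estimators whose instrument minimum is not met (Egger, median, mode, RAPS
need 3; PRESSO needs 4) are reported as not-applicable without aborting the
run. Bonferroni adjustment uses m = 44 by default — the 4 exposure sets × 11
outcomes of the reference study grid (strict-definition and replicate
exposure datasets serve plausibility/meta-analysis within a set rather than
adding hypotheses). ORs are exp(β) with exp(β ± 1.96·se) CIs, read as the
change per e-fold (2.72×) increase in exposure prevalence.

## Instrument selection and harmonization conventions

Selection keeps P strictly < 5e-8. Clumping is greedy by ascending p-value
(ties: lexicographic SNP id), removing candidates on the same chromosome
within ±10,000 kb whose r² ≥ 0.001; positions are 1-based and a candidate
missing from the LD reference is a hard error. Proxy search requires
r² strictly > 0.8 and takes the argmax (ties: smaller id). Palindromic
(A/T, G/C) variants are dropped when MAF > 0.42 on either side; at
MAF ≤ 0.42 they are kept and aligned by allele frequency (a
`drop_all_palindromic` switch removes them all instead). Non-palindromic
alleles are reconciled directly, by order swap (negating β, reflecting
EAF), or by strand complement; irreconcilable pairs are dropped. Proxy
variants cannot be allele-matched to the instrument, so they are oriented
by frequency matching, and near-0.5 palindromic proxies are dropped. Every
exclusion appears exactly once in the drop log with a machine-readable
reason code.

## Synthetic data generator

The generator emulates consortium case-control GWAS pairs: standard errors
follow the binary-trait approximation se ≈ 1/√(2·N·p(1−p)·c(1−c)) with p
the effect-allele frequency and c the case fraction. Defaults mirror the
reference study conditions: L = 14 instruments, θ = ln(1.03), a
FinnGen-like exposure GWAS (N = 270,000, 1% cases) and a consortium-like
outcome GWAS (N = 66,000, 38% cases), MAF uniform on (0.05, 0.5], 20%
palindromic variants. Instrument effects are half-normal (SD 0.35),
oriented to the exposure-increasing allele as is conventional in MR
simulation studies — without orientation, a constant direct effect would
produce ratio shifts of random sign and "directional" pleiotropy would not
be directional. Genome-wide significance is enforced by construction:
when a realized exposure estimate misses the 5e-8 threshold, the true γⱼ is
shifted so the estimate lands at the boundary while keeping the same noise
draw; the truth record flags enforced SNPs. Pleiotropy regimes: none,
balanced N(0, σ_α²), directional N(μ_α, σ_α²), or InSIDE-violating with
exact target correlation to the (standardized) instrument effects. Planted
gross outliers set αⱼ = `outlier_magnitude` outright. One master seed is
split into named per-stage sub-streams, so identical configs and seeds give
byte-identical tables and adding SNPs does not reshuffle earlier stages.

What the generator does **not** emulate: individual-level genotypes,
realistic LD (blocks are exchangeable with jittered constant r²), allele-
frequency differences between cohorts, winner's-curse bias in instrument
discovery, or sample overlap. Passing tests therefore demonstrate
correctness of the estimators and the pipeline under the stated generative
model, not robustness to every artefact of real consortium data.

## Problem sizes used in tests

The test-suite simulations use 200–1000 replicates of 14-instrument
datasets (500 for recovery/bias comparisons, 1000 for test calibration,
200 for MR-PRESSO power), sizes at which Monte-Carlo standard errors are
small relative to the tolerances asserted; the whole suite runs in well
under a minute on one CPU. The acceptance script uses 200–500 replicates
per quantity.

## Known limitations

* The MR-PRESSO implementation is the outcome-variance-weighted (simple)
  variant; it does not reproduce the published implementation's exact
  bootstrap scheme, only its logic and calibration guarantees.
* MR-RAPS SEs come from a first-order sandwich; for very small L they can
  be optimistic.
* The weighted-mode estimate is resolved to the 512-point grid; its
  bootstrap SE inherits that granularity.
* Multivariable MR, Steiger filtering and contamination-mixture estimators
  are out of scope, as are forest-plot graphics.
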