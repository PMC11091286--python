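# Methods

## The problem

Observational associations between an exposure (here, the motivating case
is intrahepatic cholestasis of pregnancy, ICP) and later-life outcomes
(cardiovascular disease, hypertension, coronary artery disease) are
confounded and subject to reverse causation. Two-sample Mendelian
randomization (MR) sidesteps both by using genetic variants as
instruments: alleles are assigned at meiosis, independently of later
confounders, so a variant that raises the exposure can only associate
with the outcome through the exposure — provided the instrument
assumptions hold. The package estimates these causal effects from GWAS
summary statistics alone (per-SNP beta, SE, allele frequency), never
individual-level data, and extends the analysis to two-step mediation:
how much of the exposure's total effect travels through an intermediate
trait such as LDL cholesterol.

## Instrument selection

Instruments are screened in four steps, each recorded in provenance with
before/after counts:

1. **Significance**: keep SNPs with exposure p strictly below 5e-8
   (genome-wide convention; configurable).
2. **LD clumping**: greedy by ascending p-value (ties broken by rsID), a
   SNP is pruned when it lies within 10 Mb of an already-kept SNP on the
   same chromosome and their r² ≥ 0.001. We read the conventional
   "R² ≥ 0.001 within 10 Mb" phrasing as this standard clumping criterion.
   No LD panel is bundled: r² comes from a user-supplied table/matrix, or
   clumping is distance-only.
3. **Risk-locus exclusion**: user-supplied blocklist of rsIDs or 1-based
   closed genomic intervals (variants already established as outcome risk
   loci violate the exclusion restriction).
4. **Instrument strength**: per-SNP F statistic, weak instruments
   (F < 10) removed. Default formula is the squared Wald statistic
   F = (beta/se)², which needs only the columns every summary file has.
   A second form computes the variance explained R² = 2·eaf·(1−eaf)·beta²
   and F = R²(n−k−1)/(k(1−ΣR²)) from sample size n, instrument count k and
   allele frequency; it assumes standardized traits and errors out when
   ΣR² ≥ 1. Which of the two a given published analysis used is often
   unstated, so both are available and the choice is recorded.

## Harmonization

Exposure and outcome records are joined by rsID and aligned to the
exposure's effect allele. Outcome records listed for the opposite allele
get beta negated and eaf mirrored. Strand-complement listings (A/G vs
T/C) are resolved by complementing before comparison (on by default).
For palindromic SNPs (A/T, C/G) the letters carry no strand information,
so orientation is inferred from allele frequency: effect-allele
frequencies on the same side of 0.5 mean aligned, opposite sides mean
flipped, and the SNP is dropped when either minor-allele frequency is
≥ 0.42 (the inference is unreliable near 0.5). The limit is configurable;
0.42 mirrors common two-sample MR practice. Harmonization is idempotent,
and recoding alleles on either side never changes a downstream estimate.

## Estimators

With per-SNP Wald ratios θ_j = Γ_j/γ_j (outcome over exposure beta) and
first-order SE σ_j = se(Γ_j)/|γ_j|, weights w_j = 1/σ_j²:

- **IVW**: β = Σw_jθ_j / Σw_j, algebraically the weighted through-origin
  regression of outcome on exposure betas with weights 1/se(Γ_j)². The
  default model is multiplicative random effects: the fixed SE (Σw)^-1/2
  is inflated by max(1, √(Q/(J−1))), so heterogeneity widens the interval
  but can never narrow it.
- **MR-Egger**: weighted least squares with intercept, weights
  1/se(Γ_j)², SNPs internally oriented so every γ_j > 0 (the fit is not
  invariant to allele coding). The intercept estimates directional
  pleiotropy; slope and intercept use t inference with J−2 df and a
  multiplicative residual scale floored at 1.
- **Weighted median**: ratios ordered, estimate interpolated at
  cumulative normalized weight 0.5 using the midpoint convention
  s_j = (Σ_{i≤j} w_i − w_j/2)/Σw. Consistent when valid instruments
  carry > 50% of the weight.
- **Weighted mode**: maximizer of a weighted Gaussian KDE over the
  ratios; bandwidth = factor × 0.9·min(sd, normalized MAD)·J^(−1/5)
  (fixed rule, so results reproduce bit-for-bit). Degenerate case (all
  ratios equal) returns the common value exactly.
- **Multivariable IVW**: WLS of outcome betas on the J×K exposure-beta
  matrix without intercept, weights 1/se(Γ_j)²; used for step two of
  mediation (mediator effect conditional on the exposure). An all-zero
  exposure column yields a null estimate rather than a rank error;
  genuine collinearity among non-zero columns errors out.

Median and mode SEs come from a parametric bootstrap (default 1000
draws) that redraws every exposure and outcome beta from its sampling
distribution; the seed is a required argument — there is no hidden
global RNG anywhere in the package. IVW/median/mode p-values are
two-sided normal; Egger uses t. Every 95% CI uses the multiplier
1.959964 for cross-method consistency. Two-sided normal p-values are
computed through the log survival function so that genome-scale signals
(p < 1e-300) remain representable, floored at the smallest positive
float.

## Sensitivity diagnostics

- **Cochran's Q** at an estimate β: Σw_j(θ_j−β)², chi-square with J−1
  df. At the fixed-effect IVW estimate it equals the weighted RSS of the
  through-origin regression (asserted numerically in the tests).
- **MR-PRESSO**: observed RSS sums each SNP's squared deviation from the
  prediction of the leave-that-SNP-out fixed-effect IVW slope. The null
  distribution comes from parametric simulations (default 1000) redrawing
  exposure and outcome betas around the no-pleiotropy prediction; the
  global p uses the add-one estimator (1+#{sim ≥ obs})/(n_sim+1), so it
  is bounded below by 1/(n_sim+1) and never zero. Per-SNP outlier tests
  compare each SNP's own residual term to its simulated distribution,
  Bonferroni-adjusted at alpha 0.05 by default. When outliers are
  flagged, the corrected IVW estimate excludes them, and the distortion
  is reported as a descriptive percent change (no distortion p-value).
- **Leave-one-out**: one re-estimate per omitted SNP plus the all-SNP
  row. A SNP is "influential" when its omission estimate escapes the
  full-set 95% CI, when the full-set estimate escapes the omission
  row's CI, or when the sign flips. The symmetric check matters under
  the random-effects default: a contaminated SNP inflates the full-set
  interval, so the one-way escape alone can miss exactly the SNP that
  causes the trouble.
- **Reverse MR**: the pipeline re-run with roles swapped — the former
  outcome is screened for its own instruments; if none survive selection
  the result is a structured no-instruments record, not an error.

## Two-step mediation

Step one estimates βa (exposure → mediator) by IVW of the exposure's
instruments against the mediator GWAS. Step two estimates βb
(mediator → outcome) by multivariable IVW including the exposure — the
conditional effect is what mediation needs — with a univariable fallback
mode for comparison. Then

    IE = βa·βb,  DE = TE − IE,  prop = IE/TE,

where TE is the total-effect estimate. IE + DE = TE holds to machine
precision by construction. The indirect-effect SE is the delta-method
(Sobel) form √(βb²se_a² + βa²se_b²); an optional second-order term
+se_a²se_b² (off by default) makes it the exact SD of a product of
independent normals. The proportion's SE treats IE and TE as independent
(they come from separate two-sample fits):
se_prop = √(se_IE²/TE² + IE²·se_TE²/TE⁴). A zero TE suppresses the
proportion with a structured flag; proportions outside [0, 1] are
flagged "inconsistent-mediation" but reported. The screen requires
p < 0.05 for βa, βb and IE jointly; no multiplicity correction across
candidate mediators by default (a Bonferroni switch exists). Published
mediation tables print ratios computed from unrounded effects, so the
package never targets ratios recomputed from rounded table entries.

## Synthetic data generator

The generator stands in for real GWAS downloads and emulates the
post-clumping state of a two-sample analysis: independent instruments
(no LD), per-SNP exposure effects γ_j ~ N(0, gamma_sd²), true outcome
effects θ·γ_j plus optional pleiotropy offsets (balanced or directional,
on a configurable fraction of SNPs, with an optional correlation with
γ_j to violate InSIDE deliberately), and observed betas drawn around the
truth with SE = 1/√(2·eaf(1−eaf)·n). Binary outcomes are approximated on
the log-odds scale with the same normal model, which is all the
estimators ever see. Mediation chains give the mediator its own disjoint
instruments δ_k; outcome effects are (direct + βa·βb)γ_j on exposure
instruments and βb·δ_k on mediator instruments, so the implied total
effect is direct + βa·βb.

Reference conditions (the defaults): 50 instruments, 1e5 samples per
study, gamma_sd = 0.05 (mean instrument F ≈ 125), eaf uniform on
(0.05, 0.95), 30% of outcome records allele-swapped and 10% of SNPs
palindromic so harmonization is always exercised. Palindromic SNPs draw
their frequency outside (0.40, 0.60), since real pipelines cannot rescue
ambiguous palindromes either; both studies report the true frequency.
The random stream for effect sizes is separated from the stream for
allele bookkeeping, so toggling the harmonization stress cannot change
the simulated effects — the basis of the round-trip test.

What the generator does **not** emulate: LD between instruments,
winner's-curse selection bias, sample overlap between studies,
population stratification, and frequency estimation noise. Passing tests
therefore certify the estimators and their calibration under the stated
sampling model, not robustness to those additional real-data features.

The packaged ICP-like study config (`examples/icp_like_study.yaml`) sets
11 instruments, exposure n = 154,780, outcome n = 484,598, instrument
effects of SD 0.5 (the scale of the published instrument table) and a
true log-odds effect of 0.004, i.e. OR ≈ 1.004 — the magnitude reported
for the ICP → CVD relation.

## Numerical and design choices

- Positions are 1-based everywhere, matching the published instrument
  table.
- The join key is rsID; chrom:pos joining is available as a dialect.
- Row-level validation failures skip and count by default (large files
  degrade gracefully); `strict` makes them fatal.
- Stage seeds derive from the master seed as the first word of
  `SeedSequence([master, stage_code])` mod 2³¹ with fixed stage codes, so
  bootstrap, PRESSO and reverse stages can be re-run in isolation.
- Monte-Carlo p-values use the add-one estimator to avoid zeros.
- The weighted-mode maximizer is located by a 512-point grid plus a
  bounded scalar refinement; two independent optimizers of the same KDE
  can only agree to the float-flatness width near the peak (~√ε·h), which
  is why mode comparisons in the tests use 1e-8 rather than the 1e-10 the
  closed-form estimators achieve.
- Problem sizes in the test-bed: calibration uses 200 replicates
  (bias, type-I error, coverage), 500 for the Egger intercept null, 200
  simulated mediation chains; chosen as the smallest sizes at which the
  binomial/Monte-Carlo error of the checked rates is comfortably inside
  the asserted bands.

## Known limitations

- No proxy-SNP lookup, no liftover, no VCF-encoded summary statistics,
  no LD computation from genotype panels.
- The F statistic's `r2_based` form assumes standardized traits.
- Mediation treats IE and TE as independent; with overlapping samples
  the proportion's SE is optimistic.
- MR-RAPS, contamination mixture, Steiger filtering, radial MR and
  multi-mediator joint decomposition are out of scope.
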