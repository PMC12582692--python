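# Methods

`protmr` implements the staged statistical design of a proteome-wide
two-sample Mendelian randomization (MR) drug-target scan: plasma-protein
GWAS summary statistics (pQTLs) serve as exposures, a disease GWAS as the
outcome, and genetic variants as instrumental variables. This note records
the models, the numerical choices, what the synthetic generators do and do
not emulate, and the design decisions taken where the design was open.

## The causal model and its assumptions

For each protein, instruments are SNPs satisfying the three IV assumptions:
(1) robustly associated with the protein level; (2) independent of
confounders of the protein-disease relationship; (3) affecting the disease
only through the protein. Assumption (1) is enforced empirically
(p < 5×10⁻⁸, strict, then LD clumping); (2) is untestable and taken on the
usual grounds of Mendelian inheritance; (3) is probed by the sensitivity
battery (Egger intercept, MR-PRESSO, Steiger directionality, bidirectional
MR).

With harmonized per-SNP effects (β̂ₓᵢ, β̂ᵧᵢ) and outcome SEs σᵢ, the
estimators are:

* **Wald ratio** (single instrument): θ̂ = β̂ᵧ/β̂ₓ, SE σ/|β̂ₓ| (first-order
  delta; exposure-side uncertainty ignored, the standard two-sample
  convention — a conservative alternative would add the second-order term).
* **IVW**: weighted regression through the origin with wᵢ = 1/σᵢ²;
  θ̂ = Σwβ̂ₓβ̂ᵧ / Σwβ̂ₓ². Fixed-effect SE (Σwβ̂ₓ²)^(-1/2); under detected
  heterogeneity (Cochran Q p < .05) the multiplicative random-effects
  (MRE) model scales the SE by max(1, √(Q/(k−1))). The truncation at 1
  means underdispersion never shrinks the SE, matching common
  implementations; consequently Q = (k−1)·scale² whenever scaling is
  active.
* **MR-Egger**: weighted LS of β̂ᵧ on β̂ₓ with intercept, instruments
  oriented so all β̂ₓ ≥ 0 (the ratio's sign ambiguity). The slope is the
  causal estimate; the intercept estimates average directional pleiotropy.
  SEs carry the max(1, residual scale) factor; inference uses t(k−2).
* **Weighted median**: weight-interpolated 50th percentile of the per-SNP
  ratios with wᵢ = β̂ₓᵢ²/σᵢ²; SE by seeded parametric bootstrap
  (default 1000 draws resampling both sides from their reported SEs).
* **Mode estimators** (simple/weighted): Gaussian-kernel density mode of
  the ratios with bandwidth h = φ·0.9·min(sd, 1.4826·MAD)·k^(−1/5)
  (φ = 1 by default), maximized on a 2048-point grid spanning the ratios
  ±3h; degenerate all-equal ratios return the common ratio. SE by
  parametric bootstrap.

p-values are two-sided normal except Egger's t(k−2). Results are reported
as OR = exp(β) with 95% CI exp(β ± 1.959964·SE). For a rare binary outcome
analyzed by linear regression on 0/1 (the scale of biobank disease GWAS
with a fraction of a percent cases), exp(β) is a labeling convention;
effects stay near-null ORs (≈1 ± 0.005).

The scan's primary estimator is IVW (Wald ratio when only one instrument
survives), and the FDR is taken over the primary p-values across all
proteins in the scan (Benjamini-Hochberg step-up, strict q < .05, via
statsmodels behind `bh_fdr`).

## Instrument processing

* **Selection**: strict p < 5×10⁻⁸.
* **Clumping**: greedy p-ordered pruning (PLINK convention): keep the best
  remaining SNP, discard same-chromosome SNPs within ±10,000 kb whose r²
  with it exceeds 0.001; ties in p broken by (chrom, pos) so the result is
  order-independent. LD must be supplied as a correlation matrix — no
  reference-panel computation.
* **Harmonization**: intersect on rsID; swapped outcome alleles flip β̂ᵧ
  and EAF; strand flips are resolved by complementing. Palindromic SNPs
  (A/T, C/G) carry no strand information, so they are oriented by EAF
  concordance and dropped as ambiguous when either EAF lies in
  [0.42, 0.58] (a symmetric default, configurable). Harmonization is
  idempotent and invariant to simultaneous allele swap + β negation.
* p-values of exactly 0 in input are clamped to 1e-300 (Steiger's p→r²
  conversion needs p > 0); coordinates are 1-based; only single-base ACGT
  alleles are kept.

## Sensitivity battery

* **Cochran's Q** around the fixed-effect IVW slope, χ²(k−1).
* **Egger intercept test**: p > .05 read as no directional pleiotropy.
* **MR-PRESSO**: observed RSS from leave-one-out IVW residuals; the null
  distribution is built by parametric simulation (default 1000 draws)
  around the leave-one-out predictions; empirical p-values use
  (1 + count)/(n + 1) so they are never zero. Per-SNP outlier p-values are
  Bonferroni-multiplied by k and flagged below .05. When outliers exist,
  the corrected estimate is IVW on the remainder, and the distortion
  p-value compares the original-vs-corrected slope gap against IVW slopes
  on 1000 bootstrap resamples of the outlier-free SNPs (the exact
  resampling scheme of the original method is unspecified in the source
  design; this is the package's choice, seeded).
* **Steiger filtering**: per-SNP variance explained recovered from p and n
  as r² = F/(F + n − 2), F the (1−p) quantile of F(1, n−2) (falling back
  to t² and z² quantiles where F's inverse survival function overflows at
  extreme p). A SNP's direction is TRUE iff r²(exposure) > r²(outcome);
  the overall test is a two-sample Fisher-z on the correlations implied by
  summed r². Binary traits use the same observed-scale approximation as
  quantitative traits — a documented simplification.
* **Bidirectional MR**: the identical selection pipeline run with disease
  as exposure. Reverse instruments are themselves Steiger-filtered, so a
  disease-significant SNP that is really a pQTL is not misread as reverse
  causation; with no surviving reverse instruments the reverse analysis is
  reported "not estimable" (not an error).

## Colocalization

Single-causal-variant Bayesian colocalization from per-SNP Wakefield log
approximate Bayes factors, lABF = ½(log(1−r) + r·z²) with
r = sd²/(sd² + se²). Prior effect SD 0.15 (quantitative) / 0.2 (binary);
per-SNP priors p1 = p2 = 1e-4, p12 = 1e-5 — the field-standard defaults,
all exposed. Hypothesis evidence uses S1, S2, S12 sums accumulated in log
space (log-sum-exp); H3's S1·S2 − S12 difference uses log1p(−exp(gap)) and
is exactly zero for single-SNP regions. A positive gap beyond 1e-9 raises a
numerical-failure error. PPH4 ≥ 0.8 (inclusive) is the colocalization
call; no alternative decision rule is implemented, and a low PPH4 with low
PPH3 should be read as limited power rather than evidence of absence. The
pipeline's region is ±500 kb around the lead pQTL (chosen by |z|, since
p-values underflow for strong pQTLs); region choice is otherwise the
caller's.

## Mediation

Two-step MR with the product method on log-scale effects: indirect =
β₁·β₂ (exposure→mediator times mediator→outcome), direct = total −
indirect (difference form, so the decomposition is exact by construction),
mediated proportion = 100·indirect/total. Delta-method SEs:
SE(indirect)² = β₂²se₁² + β₁²se₂²; the proportion's SE adds the total's
uncertainty through the ratio delta method. Chains are screened: both the
exposure→mediator and mediator→outcome estimates must have p < .05.
Inconsistent mediation (opposite signs) yields a negative proportion with
a warning. Published OR tables can be fed in directly
(`mr_result_from_or` recovers β = ln OR and SE from the CI width); because
published ORs are rounded, recomputed proportions match printed ones only
to ~±0.1 percentage points.

## Synthetic data: what it emulates, and what it does not

Two tiers, all pure functions of their arguments including the seed (one
root seed, fixed child-stream offsets):

* **Summary-level instruments** (`simulate_instruments`,
  `simulate_mediation_triplet`): true exposure effects uniform on
  (0.15, 0.5) with observed effects normal around them; effects are
  rescaled once so every observed exposure association clears 5×10⁻⁸ by
  construction. Defaults emulate the study conditions: exposure n =
  35,559 with se_x = 0.005 (≈1/√n), outcome n = 462,933 with 1908 cases
  and linear-scale se_y = 1.5e-4, which reproduces ORs within ≈1 ± 0.005
  of unity. Pleiotropy models: none; balanced (zero-mean normal, sd
  3·se_y); directional (common mean 3·se_y); outlier (one SNP at
  10·se_y). Calibration studies in the tests use se_y = 0.002 so that the
  small regression-dilution bias from exposure measurement error
  (≈θ·se_x²/E[βₓ²], a NOME violation of order 10⁻⁴) is negligible
  against the estimator SEs.
* **Individual-level regions** (`simulate_region_pair`): standardized
  Gaussian genotype dosages with AR(1) correlation ρ^|i−j| for two
  independent cohorts (default L = 50, ρ = 0.8, n = 20,000), phenotype =
  effect·dosage at the scenario's causal SNP(s) + unit noise, summarized
  by per-SNP marginal OLS — so colocalization sees realistic LD-induced
  correlation between Bayes factors. Scenarios: shared / distinct /
  exposure_only / null. Binary regional traits are supported through a
  liability threshold (default prevalence 0.4%), but the default scenario
  studies use quantitative traits: at that prevalence a desk-scale cohort
  yields almost no cases, so the binary outcome's scale is emulated at
  summary level instead.
* **Protein panels** (`simulate_protein_panel`): disjoint per-protein
  instrument sets (one instrument per locus, 25 Mb apart, so the coloc
  window isolates the lead variant and clumping never merges loci) sharing
  one outcome GWAS; identity LD across the panel.

Not emulated: genome-wide LD structure, imputation quality, sample overlap
between cohorts, allele-frequency-dependent power, population
stratification, or winner's-curse selection of instruments. Passing tests
therefore validate the estimators and the pipeline plumbing under the
stated generative model, not robustness to those real-data artifacts.

## Numerical and design choices

* Empirical p-values are (1 + count)/(n + 1); bootstrap and simulation
  counts default to 1000 with per-protein child seeds derived from the run
  seed, so the pipeline is byte-deterministic given (config, seed) and
  invariant to the order of input files (proteins are processed in sorted
  name order).
* The sensitivity battery and colocalization run only for FDR-significant
  proteins, and mediation only for colocalization-supported proteins — the
  staged design keeps compute proportional to discoveries.
* Output tables are tab-separated with 12-significant-digit floats
  (round-trips to ≥10 digits); input delimiters are auto-detected.
* Degenerate inputs: all-equal ratios give zero bandwidth (the common
  ratio is returned); zero total effects make the mediated proportion
  undefined (error); a protein failing selection/harmonization becomes a
  "failed" scan row, never a crash.
* Problem sizes used by the validation studies (10,000 null replicates for
  type-I error, 200 replicates for recovery means, 100 for MR-PRESSO
  rates, 20 regional replicates per coloc scenario, a 20-protein panel)
  were chosen so that Monte-Carlo error is small relative to the tested
  tolerances while the full suite stays fast on a laptop.

## Known limitations

* No multivariable MR, CAUSE, or contamination-mixture estimators; no
  SuSiE-style multi-causal colocalization; no multiple-mediator joint
  decomposition.
* The Wald-ratio and IVW SEs ignore exposure-side uncertainty (NOME); with
  very precise outcomes and strong effects this produces a small
  attenuation bias, quantified above.
* Steiger's r²-from-p conversion treats binary traits on the observed
  scale.
* BH-FDR at 5% admits an occasional null protein into small panels by
  design; the scan surfaces raw p, q, and all diagnostics so such rows are
  visible rather than hidden.
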