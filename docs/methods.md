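# Methods

`mrkit` implements two-sample summary-statistic Mendelian randomization
(MR) for a pair of correlated continuous exposures — educational attainment
(EA) and intelligence (IQ), both analysed in SD units — and a binary
late-life outcome (Alzheimer's disease, AD) on the log-odds scale, together
with a generative simulator used to validate every estimator by parameter
recovery.

## Estimation model

For SNP *j*, let β̂_Xj (SE σ_Xj) be its association with the exposure and
β̂_Yj (SE σ_Yj) with the outcome, harmonized to a common effect allele.

* **Wald ratio**: β̂_Yj / β̂_Xj with first-order (delta-method) SE
  σ_Yj / |β̂_Xj|. Uncertainty in β̂_Xj is ignored, the usual approximation
  for instruments at genome-wide significance; with weak instruments it
  produces regression dilution toward the null (see *Known limitations*).
* **IVW**: weighted least squares of β̂_Yj on β̂_Xj through the origin with
  weights w_j = 1/σ_Yj². Algebraically identical to the inverse-variance
  meta-analysis of the Wald ratios (asserted to 1e-10 in the tests). The
  zero intercept encodes the no-horizontal-pleiotropy assumption.
* **MR-Egger**: the same regression with a free intercept, after orienting
  every β̂_Xj ≥ 0 (flipping the paired β̂_Yj); the intercept estimates the
  average directional pleiotropic effect per SNP, the slope a
  pleiotropy-adjusted causal effect. Results are invariant to the input
  orientation given this convention (property-tested).
* **Multivariable IVW**: joint no-intercept WLS of β̂_Yj on both exposures'
  betas; each coefficient is that exposure's direct effect conditional on
  the other. A weighted-design condition number above 1e8 raises a
  rank-deficiency error rather than silently splitting an effect. An
  exactly zero exposure column is treated as the degenerate univariable
  reduction (that exposure unidentified, SE = ∞).

**Standard errors.** Default is multiplicative random effects: the
fixed-effect SE scaled by the residual SD of the weighted regression,
floored at 1 so underdispersion never shrinks an SE. The floor matters:
heterogeneity is the norm in real applications of this design, and
fixed-effect SEs would be anti-conservative; point estimates are identical
under both weightings (asserted). 95% CIs use the normal quantile 1.96 and
p-values are two-sided normal throughout — no t correction — so
reproduction of any number is exact arithmetic.

## Harmonization dialect

Direct allele match → copy; swapped alleles → negate β̂_Y, EAF → 1−EAF;
complement match (tried only after direct and swapped matching fail) →
strand flip; irreconcilable → dropped. Palindromic (A/T, C/G) SNPs are
never resolved by strings: under the default `drop_ambiguous` policy they
are dropped when either trait's EAF lies in (0.42, 0.58) and otherwise
aligned by EAF concordance; `infer_by_eaf` always aligns by concordance and
treats a missing EAF as a hard error. Near 0.5 frequency-based inference is
unreliable, hence the conservative default band. Every shared SNP is
accounted for (retained + dropped + missing-from-outcome = input), and the
whole rule table is enumerated exhaustively in the tests against an
independently coded oracle.

Greedy clumping retains the smallest-p SNP and removes same-chromosome
SNPs within a 10 Mb window at r² ≥ 0.01 (the thresholds used to define the
source instrument lists), ties broken by (chrom, pos) for cross-platform
determinism. Without LD information a table is treated as pre-clumped —
published lead-SNP lists are approximately independent by construction —
with a logged notice, never silently.

## Diagnostics

* Per-SNP variance explained: r² = 2·EAF·(1−EAF)·β² for SD-unit traits
  (the default when EAF is available), else r² = t²/(t²+n−2).
* **Steiger filtering** keeps SNPs with r²(exposure) > r²(outcome) — a
  plain comparison, not a significance test, matching how directionality
  filtering is used in this design; the two-sample Steiger z (Fisher-z
  difference of the implied correlations) is reported alongside.
* **Cochran's Q** uses first-order Wald-ratio weights (the same weights as
  IVW) about the fixed-effect estimate, χ²(k−1) p-values. Null calibration
  (5% ± 3 binomial SE over ≥1000 replicates) is part of the test suite.
* **Leave-one-out** re-fits IVW omitting each SNP; an omission is flagged
  when the estimate moves more than one full-sample *fixed-effect* SE or
  changes sign. The fixed-effect SE is the yardstick deliberately: an
  outlier inflates the random-effects SE and would otherwise mask itself.
* **Funnel data**: per-SNP Wald estimate vs precision (1/SE), with a
  precision-weighted free-intercept regression of estimate on precision as
  the asymmetry summary (slope ≈ 0 under balanced pleiotropy).
* **F statistic**: F = (r²/(1−r²))·((n−1−k)/k), weak-instrument flag at
  F ≤ 10. The conditional (multivariable) instrument strength is *not*
  computed — no satisfactory two-sample definition exists — and this is
  deliberate, not an omission.

## The generator

Genotypes are independent biallelic SNPs, g_j ~ Binomial(2, MAF_j) with
MAF ~ U(0.1, 0.5); non-palindromic allele pairs by default, emulating the
standard exclusion of strand-ambiguous variants from instrument lists
(palindrome handling is exercised by handcrafted tables in the tests).
Exposures are linear structural equations with a shared N(0,1) confounder
U and Gaussian residuals scaled so each exposure has **unit marginal
variance** — all path coefficients are per SD. A variance budget over 1 is
a configuration error listing the contributions.

The reciprocal EA↔IQ relationship is realized as a two-step assignment
(IQ₁ first, then EA, then IQ ← IQ₁ + t·(EA − its IQ₁ part), rescaled to
unit variance); a simultaneous loop would need an equilibrium convention
the causal diagrams do not supply. Trait↔trait coefficients are specified
on the *realized* per-SD scale and the internal coefficients plus the
rescaling factor are solved in closed form, so ground-truth implied
effects equal the configured values exactly.

AD is Bernoulli with logit = α + θ_EA·EA + θ_IQ·IQ + Σγ_j g_j + c·U and
α = logit(base prevalence). **Ground truth on the AD scale is the marginal
log odds ratio**: odds ratios are non-collapsible, and the estimand of a
per-SNP logistic GWAS — hence of summary-statistic MR built on it — is the
marginal coefficient, attenuated relative to the conditional one by a
factor computed here by Gauss–Hermite quadrature over the analytic
variance of the non-SNP linear predictor (≈ 0.96 at the default settings).
Defining truth on this scale is what makes "recovery within Monte-Carlo
error" a fair test; the residual weak-instrument regression dilution
(~2–4% toward the null at the default instrument strength) is estimator
bias and is deliberately *not* absorbed into the truth.

Per-SNP association estimation is closed-form simple OLS (continuous
traits, t p-values) and univariate logistic regression by Newton scoring
(binary outcome, Wald p-values), vectorized across SNPs; both are checked
against statsmodels fits to 1e-6–1e-8. Monomorphic SNPs are emitted with
β = 0, SE = ∞, p = 1 and a `monomorphic` flag and are never selected.
Two-sample estimation draws disjoint samples: exposure associations from
sample 1, outcome associations from sample 2. Instruments are selected at
a p-value threshold in sample 1 (default 1e-4, a desk-scale stand-in for
5e-8) or taken as the designed panel lists ("oracle" selection, emulating
published lead-SNP tables, which are discovery+replication meta-analyses
and therefore essentially free of winner's curse; winner's curse under
p-value selection is demonstrated by its own replication-sample test).

### Scenario library

Scenarios a–h realize the catalogue of causal structures relating EA, IQ
and AD: (a) the EA-panel SNPs act through IQ and IQ alone affects AD —
confounding of the EA–AD association; (b) its mirror; (c) EA → IQ → AD
full mediation; (d) its mirror; (e/f) horizontal pleiotropy through the
other exposure (cross-loaded SNP effects); (g) SNPs with independent
effects on all three traits but no causal links among them; (h) joint
direct effects with reciprocal EA↔IQ. Two structures require a design
choice the diagrams leave open:

* In (a) and (c) as literally drawn, every instrument's effects on the two
  exposures are exactly proportional, so the multivariable model is
  unidentified (rank-1 design). Scenario a therefore includes a small
  fraction of genuinely EA-specific instruments (15 of 100, matching the
  share of education instruments that directionality filtering leaves in
  real data), and scenario c gives IQ its own instrument panel — both
  realistic, since both traits are heritable in their own right.
* In (g), univariable IVW converges to zero whenever per-SNP outcome
  effects are independent of exposure effects, whatever the per-SNP
  pleiotropy; no coherent generative model makes univariable MR "detect"
  both exposures while multivariable MR shows nothing. Scenario g is
  therefore checked for its multivariable verdict (no independent effects)
  and calibration only.

Default scenario conditions: 100 instruments, h² = 0.15 per panel
(per-SNP z ≈ 5.5, comparable to real lead-SNP lists), 20 000 individuals
per sample, base "prevalence" 0.3 emulating a case-enriched outcome sample,
confounder loadings 0.2, effect sizes −0.45 (single AD path) or
(−0.2, −0.3) (joint effects), trait↔trait effects 0.5 (or 0.51/0.57 in the
reciprocal scenario). Seed 20200131 everywhere by default.

### The study replica

`replica_study_config()` is a **synthetic stand-in** for the study's
per-SNP instrument tables, which are not redistributable. Its generative
truths are the study's reported effects — IQ→EA 0.51 SD/SD, EA→IQ 0.57
SD/SD (the directionality-filtered value, which the study argues is the
right magnitude), a direct IQ→AD effect of log(0.62) and no direct EA→AD
effect (full mediation) — and its panels mirror the reported composition:
148 education instruments of which 125 act IQ-first, 180 intelligence
instruments, 9 shared. Effect magnitudes are equal per SNP (lead-SNP lists
are significance-thresholded and have no weak tail), with the exposure
sample size (63 000) and panel h² (0.016 / 0.33) chosen so per-instrument
F matches the reported instrument strength (≈ 43.5 and 50.45); the outcome
sample (25 000, case fraction 0.314) preserves the case-control balance of
the outcome GWAS at desk scale. What recovery of this replica demonstrates
is that the *pipeline* — harmonization, IVW, Steiger filtering,
multivariable estimation, odds-scale reporting — reproduces the study's
quantitative pattern from data generated under its own conclusions; it is
not a re-analysis of the original summary statistics.

### What the generator does not emulate

No linkage disequilibrium between instruments (the analysis setting is
post-clumping), no population stratification, no sample overlap between
the two samples, no survival/attrition processes, no genotyping or
imputation error. Passing tests therefore validate the estimators and the
pipeline logic under the stated model, not robustness to those features of
real data.

## Problem sizes and numerics

Validation runs use 200 replicates per scenario (100 in the reproduction
script) at 100 instruments × 20 000 individuals per sample, and a single
seeded replica run at 63 000/25 000 — sizes chosen so the whole suite
completes comfortably on one CPU while leaving Monte-Carlo SEs several
times smaller than the effects under test. Coverage of nominal 95% CIs is
pooled across all estimands with well-defined per-SNP truths
(heterogeneous-mixture panels are checked for detection, not coverage)
because per-estimand coverage at 200 replicates has binomial noise of
±1.5%. Numerical choices: weighted normal equations solved by
`numpy.linalg.solve`; Newton scoring with step tolerance 1e-10, ≤40
iterations; p-values clipped to [1e-300, 1]; Gauss–Hermite with 64 nodes;
clumping tie-break by genomic coordinate.

## Known limitations

Wald/IVW first-order SEs ignore exposure-side sampling error, so weak
instruments dilute estimates toward the null and CIs undercover slightly
— visible in the validation suite as a ~0.2–0.4 SE mean shift at default
instrument strength. MR-Egger's intercept test has low power at realistic
SNP counts. The marginal/conditional log-OR distinction means simulated
"true" odds ratios are a few percent closer to 1 than the structural
coefficients that generated them; real analyses have the same property.
Proxy SNPs must arrive pre-substituted; LD lookups, genome-build liftover
and multiple-testing adjustment (the analyses report unadjusted CIs) are
out of scope.
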