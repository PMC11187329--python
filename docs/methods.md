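# Methods

## Model and assumptions

The package estimates the causal effect of pharmacologically modulating
a drug-target protein on a disease outcome, using two-sample Mendelian
randomization with cis instruments.  A variant j is a valid instrument
for target gene G when it (i) associates strongly with the lipid
exposure through G (relevance), (ii) shares no confounder with the
outcome (independence), and (iii) affects the outcome only through the
exposure (exclusion restriction).  Restricting instruments to a window
around the gene body makes the exposure a proxy for modulation of that
specific target rather than of lipid levels generally.

Under these assumptions each SNP supplies a Wald ratio
θ̂_j = β̂_Yj / β̂_Xj.  The first-order delta-method standard error
se(θ̂_j) = se_Yj / |β̂_Xj| ignores the exposure-side sampling variance;
this is accurate when instruments are strong (the neglected term is of
relative order θ²·se²_X/β²_X ≈ θ²/F).  The IVW estimate is the
precision-weighted mean of the ratios.  In the multiplicative
random-effects mode (default) the standard error is inflated by
max(1, Q/(J−1))^½, so between-SNP overdispersion widens the interval
but can never narrow it; the point estimate is identical in both modes.
MR-Egger fits weighted least squares of β̂_Y on β̂_X with an intercept
(weights 1/se²_Y) after orienting all exposure effects non-negative; the
slope is a pleiotropy-robust causal estimate under InSIDE, and the
intercept estimates average directional pleiotropy.  Egger inference
uses t with J−2 degrees of freedom and the same max(1, residual mean
square) variance scaling.

## The gated two-stage design

Drug-target instruments are validated against a positive-control
outcome before the outcome of interest: lipid-lowering has an
established effect on coronary heart disease, so a target whose
instruments show no control effect is not a credible proxy for the
therapy.  The gate is control IVW p < 0.05 with a nonempty instrument
set.  Applied to the shipped reported control estimates, this threshold
admits five of eight LDL targets and two of five TG targets — the
reported ANGPTL3 control p of 0.064 is excluded, and targets with zero
surviving instruments (PPARA and, per trait, LPL/LDLR) render as blank
rows.  Instruments are re-harmonized per outcome, so instrument counts
may differ between the control and disease stages.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p_threshold` | 5×10⁻⁸ | genome-wide significance filter on the exposure (strict <) |
| `window_bp` | 100 000 | cis window each side of the gene body, boundaries inclusive |
| `r2_threshold` | 0.001 | greedy clumping cut-off on r² |
| `f_threshold` | 10 | mean-F weak-instrument flag (flag only; sets are not auto-excluded, since published tables print F without stating exclusion) |
| `gate_alpha` | 0.05 | positive-control gate level |
| `palindrome_eaf_window` | 0.08 | A/T–C/G variants with exposure eaf in [0.42, 0.58] are dropped |
| `ivw_mode` | multiplicative random effects | fixed-effect available; J = 1 falls back to the Wald ratio |
| `presso_n_sim` | 1000 | MR-PRESSO simulation count |

Clumping is greedy by ascending p (ties: position, then snp_id) —
retain the best remaining SNP, discard all remaining SNPs with
r² ≥ threshold against it.  Its output is verified in the tests against
an exhaustive oracle on random instances.  F statistics default to the
squared Wald form (β/se)²; the variance-explained form
F = R²(n−2)/(1−R²) with R² = 2·eaf(1−eaf)·β² is available as an option.
95% intervals use z = 1.959964 throughout so interval arithmetic
reproduces printed precision.

MR-PRESSO follows the parametric-simulation structure: leave-one-out
IVW residuals r_j = β̂_Yj − θ̂₋ⱼβ̂_Xj, observed weighted RSS compared
with its simulated null distribution, (1 + #exceedances)/(n_sim + 1)
empirical p-values, Bonferroni-by-J outlier calls, and a distortion
test against random outlier-sized subset removals.  All stochastic
routines take an explicit seed; the pipeline derives per-target,
per-stage seeds deterministically from the study seed.

## The synthetic-data generator

`lipidmr.synthetic` simulates summary statistics directly — no
individual-level genotypes — because the analysis consumes only summary
data.  For SNP j with effect-allele frequency f_j (uniform on
[0.05, 0.95]) and sample size n, the standard error of a standardized
per-allele effect is se_j = 1/√(2 f_j (1−f_j) n); estimates are normal
draws around the truth, independently for the exposure and each outcome
(the non-overlapping two-sample design).  Outcomes follow
β_Yj = θ·β_Xj + α_j with pleiotropy α_j ~ none / balanced N(0, σ²) /
directional N(μ, σ²); offsets (and planted outliers) act on the
exposure-increasing allele orientation, which is what makes
"directional" pleiotropy directional regardless of arbitrary allele
coding.  Defaults: exposure |β_X| ~ U[0.08, 0.15] with random sign and
sample sizes 188 577 (exposure), 184 305 (control outcome), 212 231
(disease outcome), chosen so planted instruments are genome-wide
significant with overwhelming probability and per-SNP F sits in the
10²–10³ range typical of strong cis instruments for lipids.  The
control effect defaults to θ_control = 0.4 so the positive-control gate
behaves as designed.  LD enters only through a block-diagonal r² matrix
handed to clumping (decoy SNPs are null or out-of-window and never
become clumping candidates, so the matrix covers the plantable
instruments); estimator noise stays independent across SNPs.
Palindromic instruments receive frequencies at least 0.15 from 0.5 so
frequency-based strand alignment stays unambiguous, and outcome rows
are written in a random allele orientation to exercise harmonization.

What the generator does *not* emulate: realistic lipid genetic
architecture, LD-induced correlation of effect estimates, sample
overlap, case/control imbalance (outcome sample sizes are totals, so
synthetic outcome SEs are far smaller than those of a 1 092-case
disease GWAS), population stratification, or missingness patterns.
Passing tests therefore demonstrate correctness of the estimators and
pipeline mechanics under the stated statistical model, not performance
on real cohort data.

## Numerical choices and degenerate inputs

- p-values are clamped to the smallest positive double rather than 0.
- A zero exposure effect raises a degenerate-instrument error in the
  Wald ratio; instrument sets below a diagnostic's minimum (2 for Q and
  leave-one-out, 3 for Egger, 4 for MR-PRESSO) yield a missing entry in
  the sensitivity report rather than an error.
- Zero cis-significant SNPs is a valid outcome: the pipeline renders a
  blank table row and closes the gate.
- Rendering: β, se, OR and CI bounds at 3 decimals; p at 3 decimals or
  2-digit scientific notation below 0.001 (e.g. `1.18E-07`).
- Reported confidence-interval *digits* in the shipped reference rows
  are not always re-derivable from the printed 3-decimal (β, se) pairs;
  the machine-checked reporting surface is OR = exp(β) and the Wald p.

## Known limitations

- Cochran's Q with first-order weights is mildly anti-conservative when
  the causal effect is nonzero (neglected θ²/F variance share; ~7–8%
  rejection at θ = 0.3, J = 10, F ≈ 10³).  The calibration checks
  therefore run under the complete null θ = 0, where first-order
  weights are exact and rejection sits at the nominal 5%.
- No LD-proxy lookup: SNPs missing from an outcome are dropped and
  counted, which mirrors instrument-count attrition across outcomes but
  discards information a proxy search could recover.
- No Steiger directionality filtering, no reverse-direction analysis,
  no weighted-median/mode estimators, no multivariable MR.
- The positive-control gate tests a one-sided scientific expectation
  with a two-sided p-value; a strongly protective control effect would
  also pass the gate.
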