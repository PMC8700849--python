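# Methods

`prseval` evaluates a *fixed, externally supplied* polygenic risk score
(PRS) in a case-control cohort. It deliberately contains no score
training: the weight table is an input, and every analysis downstream
treats it as given.

## Score computation and standardization

For individual *i* with effect-allele dosages `d_ij ∈ [0, 2]` and
per-allele log-odds weights `w_j`, the raw score is `PRS_i = Σ_j w_j d_ij`
over the variants that match the genotype panel. Matching is by
(chromosome, position) with the additional requirement that the weight
table's allele pair equals the panel's {ref, alt} as a set; variants are
excluded when the panel minor-allele frequency is below 0.01 or, when an
imputation info score is available, below 0.7. Unmatched variants are
reported with a reason (absent, allele-mismatch, maf-filtered,
info-filtered), never silently dropped. When the effect allele is the
panel's *ref* allele the dosage is re-oriented as `2 − d`. Strand-ambiguous
(A/T, C/G) pairs are matched as-is with a warning; frequency-based strand
flipping would invent information and is not attempted.

Scores are standardized by subtracting the mean and dividing by the
sample standard deviation (n−1 denominator) of the raw score among
*controls*; the parameters are stored so new individuals can be placed on
the same scale. The SD convention is not identifiable from downstream
results — any fixed rescaling is absorbed by thresholds — so the
conventional sample SD is used.

Missing dosages default to mean imputation with twice the effect-allele
frequency among controls (panel-wide if no cohort is supplied); a
`drop` policy (zero contribution for that individual/variant) is
available. After imputation-based pipelines missingness is rare, but a
defined policy must exist.

## Discrimination statistics

* **Logistic regression** (`fit_logistic`) is a maximum-likelihood fit
  (Newton-type IRLS via statsmodels; relative tolerance 1e-10, max 100
  iterations) with two-sided Wald tests per coefficient. Separation or
  non-convergence raises an error naming the suspect covariate. The
  headline case-control model is
  `status ~ PRS + sex + age-at-sampling + PC1–3`.
* **Nagelkerke pseudo-R²** rescales Cox–Snell
  `R²_CS = 1 − exp(2(ℓ0 − ℓ1)/n)` by its maximum `1 − exp(2 ℓ0/n)`.
  Model fits with and without the PRS are each referred to the
  intercept-only model.
* **ROC/AUC**: the AUC is the Mann–Whitney statistic scaled to [0, 1]
  with ties counted 1/2 (the probability a random case out-scores a
  random control). Curve thresholds are midpoints between consecutive
  distinct scores with ∓∞ sentinels; "test-positive" means strictly
  above threshold. The 95% CI uses DeLong's structural-components
  variance — verified against R pROC's `ci.auc(method = "delong")` to
  ten decimals on a frozen instance.
* **Decile odds ratios**: cut points are control-score quantiles at
  10%…90% (linear-interpolation/type-7 convention; ties at a boundary
  fall to the lower decile). ORs for deciles 2–10 against decile 1 are
  plain 2×2 cross-product ratios with Wald CIs
  `exp(log OR ± 1.96·√(Σ 1/cell))`; they are *not* covariate-adjusted,
  and the result object says so.
* **Age-at-onset (AAO) quartiles**: among cases, the earliest quartile
  (AAO ≤ Q1) is contrasted with the latest (AAO > Q3); quartile
  membership is regressed on PRS + sex + PC1–3 (age-at-sampling is
  excluded by design, as it is collinear with onset age), and the PRS's
  ROC/AUC for early vs late onset is reported.

## Most-relevant SNPs

Step 1 computes, for each SNP, the AUC of the score with that SNP left
out ("AUC-SNP"). Step 2 greedily removes the SNP whose exclusion lowers
the residual AUC most, recomputing leave-one-out AUCs over the
*remaining* set at every iteration, until the DeLong 95% CI of the
residual score's AUC first includes 0.5 (checked before each removal, so
a null score removes nothing); the removed set, in order, is the
"most-relevant" set. If the CI still excludes 0.5 with one SNP left, the
procedure stops with an `exhausted` flag. Step 3 ranks SNPs by AUC-SNP
and cross-classifies them against an external genome-wide-significance
annotation (both / gs-only / most-relevant-only / neither).

Numerics: leave-one-out scores use an exclusive prefix/suffix
cumulative-sum update (O(SNPs × individuals) per sweep). Unlike
subtracting a SNP's contribution from a running total, this preserves
*exact* score ties between individuals whose contributions differ only
at the excluded SNP, so results are bit-identical to explicit rescoring
(oracle-tested). Ties in the steepest decline are broken by (chromosome,
position); reruns are deterministic. The full greedy recomputation costs
O(removals × SNPs × n log n) and is the dominant cost at biobank scale;
leave-one-out ranking alone is a cheap proxy when only step 1 is needed.

## Prognostic value

A threshold turns the standardized PRS into a screening test. The
operating point maximizes the weighted Youden index
`costs·sensitivity + specificity`, `costs ≥ 1` being the relative harm
of a false negative; ties go to the higher-sensitivity (lower) threshold.
The cost grid spans [1, 5] in steps of 1e-4 (40001 points, generated by
integer indexing to avoid floating-point drift); sensitivity is
non-decreasing and specificity non-increasing along the grid, which the
implementation asserts.

Predictive values use Bayes' formula with the **residual lifetime
incidence** in place of prevalence: for 5-year age intervals [50–54] …
[95+] with interval onset probability `I_k` and annual death probability
`D_k`, interval survival is approximated as `S_k = (1 − D_k)^5` and the
residual incidence evaluated by the backward recursion
`R_last = I_last`, `R_k = I_k + S_k (1 − I_k) R_{k+1}`, equivalent to the
telescoping sum over later intervals discounted by all earlier survival
and disease-free factors (oracle-tested). The open-ended terminal
interval contributes its incidence once, with no further survival
weighting; interval bounds printed as [d, d+5]-style in common notation
are implemented as contiguous [d, d+4] bins, which the life-table
definition forces. Degenerate predictive values (0/0, e.g. npv of an
all-positive test) are reported as undefined (NaN), never as 0.

## Synthetic data: what it does and does not emulate

The generator produces the four analysis inputs with known truth:

* **Genotypes**: independent Hardy–Weinberg dosages, `Binomial(2, MAF)`,
  MAFs uniform on (0.05, 0.5) by default; optional truncated-Gaussian
  dosage noise (off by default — integer allelic counts suffice to test
  the downstream arithmetic).
* **Weights**: Gaussian log-odds (SD 0.03) with a 2.7% fraction of
  larger effects (SD 0.12), mimicking a few genome-wide-significant hits
  among many small contributors (≈47/1743).
* **Status**: logistic with linear predictor
  `α + β·Z + 0.35·(sex − ½) + 0.05·(age − midrange)`, where Z is the
  theoretically standardized true score. β defaults to 0.60 log-odds per
  SD, chosen so the case-control AUC of the true score sits near 0.65 at
  the default study shape (binormal start `√2·Φ⁻¹(0.645) ≈ 0.53`,
  adjusted upward because the logistic tilt at a 30% case fraction is
  weaker than the probit approximation). α is calibrated by
  Gauss–Hermite × Gauss–Legendre quadrature so the population case
  fraction equals `n_cases/(n_cases + n_controls)`; exact case and
  control counts are then taken from sequential population batches
  (case-control sampling).
* **Age-at-onset**: cases draw `N(62 + slope·Z, 10²)` years with slope
  −1.3 years per score SD, which puts the early- vs late-onset quartile
  AUC near 0.59 — below the case-control AUC, the qualitative ordering
  such validation studies report.
* **Life table**: the packaged default rises to an incidence plateau
  around age 80 and falls in the oldest groups, with an all-cause-like
  mortality gradient, giving a residual lifetime incidence of ≈1.7% at
  50–54 declining to ≈0.3% at 95+ — the magnitude regime in which
  PRS-based ppv stays at a few percent.

Ages at sampling are uniform over (50, 85) for cases and controls alike
(a convention; no source distribution exists for this design), sexes are
balanced, and PC1–3 are pure noise. Not emulated: linkage
disequilibrium, population stratification, relatedness, genotyping or
imputation error structure, and any AAO–age-at-sampling consistency
(onset may exceed sampling age). Passing tests therefore demonstrate the
*statistical machinery* on data satisfying the model's assumptions, not
robustness to the confounding real cohorts carry.

One global seed fans out through `numpy.random.SeedSequence` children,
so stages are independently reproducible; identical seeds give
bit-identical studies.

## Problem sizes used in the shipped tests

Oracle-equivalence suites run at exhaustive-checkable sizes (≤ 8 SNPs,
n ≤ 300 for the greedy path; n ≤ 200 for AUC pair counting). Parameter
recovery runs at n = 20 000 with 200 SNPs; the study-shape check runs at
the full default shape (1914/4464, 1743 SNPs). These sizes make every
claim checkable in seconds to minutes while leaving the full-scale
pipeline exercised end to end.

## Known limitations

* Sensitivity/specificity of a chosen operating point are reported
  without confidence intervals (the bootstrap machinery this would
  require is out of scope), as are ppv/npv.
* Decile ORs are unadjusted; covariate-adjusted decile contrasts would
  need a model-based definition the 2×2 construction does not provide.
* The greedy elimination's stopping rule inherits the DeLong CI's
  normal approximation; with very few informative SNPs the residual AUC
  can sit exactly at 0.5 with zero variance (constant score), which is
  treated as "CI includes 0.5".
* The packaged life table is a synthetic stand-in calibrated to
  plausible magnitudes, not a published registry table.
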