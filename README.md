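# prseval

Validation and prognostic-value evaluation of polygenic risk scores
(PRS) in case-control cohorts.

A published PRS assigns each individual the weighted sum
`PRS_i = Σ_j w_j d_ij` of effect-allele dosages `d_ij ∈ [0, 2]` with
per-allele log-odds weights `w_j`. Before such a score can be trusted as
a research instrument — let alone a clinical one — it must be
re-assessed in data independent of its training set. `prseval` packages
that re-assessment for biostatisticians and genetic epidemiologists:

* **Scoring** — match score variants to a dosage panel by position and
  allele pair (with MAF/info-score filters and an explicit omission
  report), compute the raw score, standardize it to mean 0 / SD 1 among
  controls.
* **Discrimination** — logistic regression with Wald tests, Nagelkerke's
  pseudo-R², ROC curves and AUC with DeLong 95% CIs, decile odds ratios
  against the lowest control decile, and early- vs late-onset quartile
  discrimination among cases.
* **SNP relevance** — leave-one-out "AUC-SNP" values and greedy
  steepest-AUC-decline elimination until the residual score's AUC CI
  includes 0.5: the removed SNPs are the "most relevant" set.
* **Prognosis** — optimal thresholds under a weighted Youden index
  `max(costs·sensitivity + specificity)` across a cost grid, residual
  lifetime incidence from a 5-year life table via
  `R_k = I_k + (1 − D_k)^5 (1 − I_k) R_{k+1}`, and Bayes positive/negative
  predictive values using that incidence as the pre-test probability.
* **Synthetic data** — Hardy–Weinberg genotypes, a logistic disease
  model driven by the true score, onset ages negatively correlated with
  genetic burden, and a realistic life table, all with exported ground
  truth so every stage is testable.

File formats are plain text: a tab-separated weight table
(`chrom, pos, effect_allele, other_allele, weight`), dosages as
variants-by-individuals TSV or VCF with a `DS` FORMAT field, phenotypes
as CSV, and a 10-interval life-table CSV ([50–54] … [95+]). See
`docs/methods.md` for the statistical details and design choices.

## Worked example

`examples/02_validation_metrics.py` simulates a study of 1914 cases and
4464 controls scored on 300 SNPs, then validates the score:

```
n = 6378 (1914 cases / 4464 controls)
case-control AUC: 0.656 [0.641, 0.670]
Nagelkerke R2 with PRS 0.164, without PRS 0.077
PRS per-SD log-OR 0.602, Wald p = 5.60e-86
decile ORs (vs 1st control decile): 2nd 1.76 ... 10th 8.62 [6.25, 11.88]
onset-quartile AUC (earliest vs latest onset): 0.576 [0.540, 0.612] - genetic burden separates early-onset cases, but less well
```

The AUC of 0.656 says a random case out-scores a random control about
two times in three — useful at a group level. The decile gradient (an
eight-fold odds difference between top and bottom control deciles) shows
the same signal as a dose-response. The onset-quartile AUC of 0.576
shows higher genetic burden also marks earlier onset, but less sharply.

`examples/04_prognostic_value.py` then asks what this score would be
worth as a screening test. With a residual lifetime incidence of ~1.6%
at age 50, even generous operating points leave the positive predictive
value at 1–3% while the negative predictive value sits near 0.99 —
essentially the 98%+ a test that calls *everyone* negative would achieve.
High npv here is a property of a rare outcome, not of the score; the
score alone is a research tool, not an individual prognostic.

The other examples cover scoring round-trips (`01`) and most-relevant-SNP
identification with planted large effects (`03`).

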