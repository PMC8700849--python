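"""Theoretical prognostic value of a PRS-based screening test.

Sweeps the relative cost of false negatives vs false positives over
[1, 5], picking the threshold that maximizes the weighted Youden index
at each cost; then combines the resulting sensitivity/specificity with
the residual lifetime incidence from the packaged life table to get age-
and cost-specific predictive values. The punchline mirrors what such
analyses typically show: npv is high (most people will not develop the
disease), but ppv stays at a few percent, so a high score alone is a
poor individual prognosis.
"""

import prseval as pe

study = pe.simulate_case_control_study(
    pe.SimulationConfig(n_cases=1914, n_controls=4464, n_snps=300, seed=4)
)
match = pe.match_variants(study.weights, study.panel)
std = pe.standardize(
    pe.compute_prs(study.panel, study.weights, match), study.cohort
)
roc, auc = pe.roc_and_auc(std.standardized, study.cohort.is_case.astype(int))
print(f"case-control AUC {auc.auc:.3f}")

grid = pe.cost_grid(roc)  # costs 1..5 in steps of 1e-4
residual = pe.residual_lifetime_incidence(study.life_table)
print("residual lifetime incidence: "
      + ", ".join(f"{lab} {v:.4f}" for lab, v in
                  zip(residual.labels[:3], residual.values[:3]))
      + " ... 95+ " + f"{residual.values[-1]:.4f}")

report = pe.prognosis_report(grid, residual)
print("operating points (costs, threshold, sens, spec):")
for _, op in report.operating_points.iterrows():
    print(f"  {op['costs']:.0f}  {op['threshold']:+.3f}  "
          f"{op['sensitivity']:.3f}  {op['specificity']:.3f}")
print("predictive values by age group:")
print(report.table.round(3).to_string())
print("(a NaN npv marks a cost level whose optimum is the all-positive "
      "test: with no negative results, npv is undefined rather than 0)")
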