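"""Diagnostic performance of the two published AF panels.

First checks the metric definitions against the published LR-3/4 outcome
distributions, then applies both panels to a simulated cohort and compares
them (kappa, McNemar) with an internal 7:3 validation of the screened model.
"""

from liradsaf import (
    AF_HCC_PANEL,
    AF_LR_PANEL,
    PrevalenceSpec,
    categorize_cohort,
    compare_methods,
    performance_from_outcomes,
    sample_cohort,
    screen_panel,
    published_prevalence_spec,
    published_outcome_fixture,
    validate_model,
)

# 1. Published outcome distributions -> published sensitivities
for method in ("AF-HCC", "AF-LR"):
    rep = performance_from_outcomes(published_outcome_fixture(method))
    print(f"{method}: sensitivity {100 * rep.sensitivity:.2f}% "
          f"({rep.outcome_counts['HCC']['upgrade']}/{rep.n_hcc} upgraded HCC)")
# 84.96% and 85.71%: the fraction of HCC LR-3/4 lesions the panel upgrades.

# 2. The same machinery on a simulated cohort at 4x the published size
spec = published_prevalence_spec()
big = PrevalenceSpec(
    prevalence=spec.prevalence,
    diameter_bins=spec.diameter_bins,
    group_sizes={"HCC": 311 * 4, "nonHCC": 162 * 4},
    agent_hba=spec.agent_hba,
)
cohort = categorize_cohort(sample_cohort(big, seed=0))
res = compare_methods(cohort, AF_HCC_PANEL, AF_LR_PANEL)
print(f"\nsimulated cohort ({len(cohort)} lesions, features independent):")
for label, rep in (("AF-HCC", res.report_a), ("AF-LR", res.report_b)):
    print(f"  {label}: sensitivity {rep.sensitivity:.3f}, "
          f"specificity {rep.specificity:.3f} "
          f"on {rep.n_hcc}+{rep.n_nonhcc} LR-3/4 lesions")
print(f"  kappa between methods {res.kappa:.3f} "
      f"(>0.6 = substantial agreement); "
      f"McNemar p (sens, Bonferroni) {res.p_sensitivity_bonferroni:.4f}")

# 3. Internal 7:3 validation of the screened multivariable model
screened = screen_panel(cohort, contrast="all")
df = cohort.data
val = validate_model(df[screened.stepwise.selected].astype(float),
                     (df.group == "nonHCC").to_numpy(float), seed=0)
print(f"\n7:3 validation of the screened model: "
      f"train AUC {val.train_auc.auc:.3f}, "
      f"validation AUC {val.validation_auc.auc:.3f}")
# Close train/validation AUCs indicate the selected panel is not overfit.
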