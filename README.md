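# liradsaf

Screening high-yield ancillary features (AFs) to sharpen LI-RADS LR-3/LR-4
categorization of liver lesions on MRI.

In patients at high risk for hepatocellular carcinoma (HCC), the Liver
Imaging Reporting and Data System (LI-RADS v2018) assigns each observation a
category — LR-3 (intermediate probability of malignancy), LR-4 (probable
HCC), LR-5 (definite HCC) — from a small set of *major features* (MFs):
nonrim arterial-phase hyperenhancement (APHE), lesion diameter,
nonperipheral washout and enhancing capsule. The 16 *ancillary features*
(AFs) — signs such as restricted diffusion, mild–moderate T2
hyperintensity, marked T2 hyperintensity or hepatobiliary-phase (HBP)
isointensity — may then move an LR-3/4 category by at most one step, never
up to LR-5. Because assessing all 16 AFs on every lesion is costly, a
natural question is which small AF panel carries the diagnostic signal.

`liradsaf` is a tested, reusable implementation of that analysis for
biostatisticians and imaging researchers. It provides:

- **`liradsaf.cohort`** — synthetic lesion cohorts (311 HCC / 162 non-HCC by
  default) whose per-feature marginal prevalences match the published
  frequency table, plus deterministic fixtures that reproduce the published
  counts exactly for unit-testable statistics;
- **`liradsaf.engine`** — the v2018 MF decision table (LR-3/4/5) and the
  upgrade / retain / degrade adjustment rule: only-malignant AFs present →
  upgrade (capped at LR-4), only-benign → degrade one step, both or neither
  → retain;
- **`liradsaf.screening`** — 2×2 frequency tests (Pearson χ² or Fisher exact
  by expected counts), odds ratios with Woolf CIs
  (`SE = √(1/a + 1/b + 1/c + 1/d)`), an IRLS logistic fitter with
  separation detection, univariable filtering at p < 0.10 and forward
  stepwise selection by likelihood-ratio entry tests, on two contrasts: all
  lesions (panel **AF-HCC**) or LR-3/4 lesions only (panel **AF-LR**);
- **`liradsaf.performance`** — sensitivity/specificity of a panel on LR-3/4
  lesions, Cohen's κ and McNemar comparison of two panels (Bonferroni ×2
  across the sensitivity/specificity pair), stratified 7:3 internal
  validation with Mann–Whitney AUC and Hanley–McNeil CIs, calibration bins
  and decision-curve net benefit `NB(t) = TP/n − FP/n · t/(1−t)`;
- **`liradsaf.pipeline`** — a seeded, hash-stamped end-to-end run
  (simulate/load → categorize → screen → adjust → evaluate) plus a thin
  `lirads-af` command-line wrapper.

## Worked example

```python
from liradsaf import (marginal_fixture, feature_contingency, woolf_or,
                      performance_from_outcomes, published_outcome_fixture)

fixture = marginal_fixture()          # counts match the published table exactly
est = woolf_or(feature_contingency(fixture, "marked_T2"))
print(f"OR {est.or_value:.2f} (95% CI {est.ci_low:.2f}-{est.ci_high:.2f})")

rep = performance_from_outcomes(published_outcome_fixture("AF-HCC"))
print(f"sensitivity {100 * rep.sensitivity:.2f}%")
```

prints

```
OR 28.29 (95% CI 8.55-93.66)
sensitivity 84.96%
```

The first line is the univariable odds ratio for marked T2 hyperintensity —
the odds of carrying the feature among non-HCC versus HCC lesions
(3/311 vs 35/162), so OR ≫ 1 marks a benignity feature. The second is the
fraction of HCC LR-3/4 lesions the AF-HCC panel upgrades (113/133).

The scripts in `examples/` walk through each capability: cohort simulation,
categorization and adjustment, panel screening, and performance evaluation.
A full pipeline run is one call:

```bash
lirads-af run-all --seed 7 --out results/
```

## Limitations

The generator reproduces published *marginal* prevalences; the joint
feature structure of the real cohort was never deposited, so quantities
that depend on it (multivariable ORs, the exact κ = 0.695, AUCs ≈ 0.93–0.95)
are echoed qualitatively, not numerically. See `docs/methods.md` for the
model, parameter choices and known departures.
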