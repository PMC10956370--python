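# Methods

## Problem and pipeline

The package analyses hepatic observations in patients at high risk for
hepatocellular carcinoma (HCC), imaged with contrast-enhanced MRI and
categorized under LI-RADS v2018. The pipeline has four stages:

1. **Cohort** — one row per lesion: group (HCC / non-HCC), diameter, three
   major-feature (MF) flags, sixteen ancillary-feature (AF) flags, contrast
   agent.
2. **Categorization** — LR-3/4/5 from MFs alone via the v2018 decision
   table; AFs then move LR-3/4 lesions one step (upgrade / retain /
   degrade), never to LR-5.
3. **Screening** — which AFs discriminate HCC from non-HCC, on all lesions
   (AF-HCC) or LR-3/4 lesions only (AF-LR): univariable tests and odds
   ratios, then forward stepwise logistic selection.
4. **Performance** — sensitivity/specificity of a panel's adjustment,
   agreement and paired comparison of two panels, 7:3 internal validation.

## Synthetic cohort generator

No per-lesion dataset was deposited with the source analysis, so the
generator emulates the published *marginal* structure: group sizes 311/162,
per-feature prevalences, diameter-bin frequencies (<10, 10–19, ≥20 mm), and
the per-group hepatobiliary-agent fractions (98/302, 40/158).

Choices, with rationale:

- **Independent features by default.** Only marginal frequencies are
  published, so features are drawn independently per lesion. A Gaussian-
  copula variant (`latent_loading`) adds a single shared severity factor for
  robustness experiments. Consequence: any statistic driven by the joint
  distribution (multivariable coefficients, between-method κ, AUC) is
  reproduced qualitatively, not numerically, and the package's tests treat
  those quantities as qualitative checks only.
- **Diameters** are uniform within the drawn bin; the open ≥20 mm bin is
  capped at 80 mm (cohort mean 3.34 ± 1.75 cm) and the <10 mm bin starts at
  3 mm (smaller foci are not reliably characterizable).
- **Mutually exclusive pairs** (mild–moderate vs marked T2; HBP hypo- vs
  isointensity) are drawn as one three-way categorical (neither / first /
  second), which preserves both marginals exactly while guaranteeing
  exclusivity. Rejection or repair schemes would bias the commoner member
  (for mild–moderate T2 in non-HCC lesions, by up to ~0.1).
- **Contrast agent.** Transitional-phase and HBP features exist only under a
  hepatobiliary agent. The published phase-feature counts in the non-HCC
  group (21 + 24 + 27 incidences) exceed the ~41 lesions that the published
  agent mix allows, so feature marginals and the printed agent fractions
  cannot both hold. The generator prioritizes the feature marginals — they
  are what every downstream statistic consumes — by forcing the agent to
  hepatobiliary whenever a phase feature is drawn and sampling it at the
  published baseline fraction otherwise; the realized agent fraction
  therefore exceeds the printed one. No analysis stage reads the agent
  column.
- **The marginal fixture** assigns each feature to the first *k* lesions of
  its group (last *k* for the second member of each exclusive pair), making
  every per-feature count exact. Its joint structure is an arbitrary
  deterministic artifact; it exists for exact contingency-table tests, not
  as a realistic cohort.

## Categorization and adjustment

The decision table is encoded with threshold growth removed (a 12-month
observation window cannot assess it), so with nonrim APHE at 10–19 mm the
LR-5 cell is reachable only through washout; capsule alone gives LR-4.
Diameter bins are left-closed ([10, 20) is "10–19 mm"), matching integer-mm
clinical reporting. The adjustment rule is one step at most: upgrade is
capped at LR-4 (LI-RADS never upgrades to LR-5 — an upgraded LR-4 lesion
keeps its category but records the upgrade outcome, which is how 113
upgrades can occur among 133 LR-3/4 HCC lesions of which only 44 are LR-3);
a degraded LR-3 lesion is recorded as LR-2, terminal in this pipeline.

## Screening statistics

- **Test choice:** Fisher's exact (two-sided, by point-probability
  summation) when any expected cell count is below 5, otherwise Pearson
  chi-square without continuity correction.
- **Odds ratios** are oriented as the odds of the feature in the *non-HCC*
  group over the HCC group — the orientation under which the published
  univariable estimates for the benignity-favoring AFs equal the marginal
  cross-products exactly. Woolf CI on the log scale with the exact normal
  quantile 1.959964 (the rounded 1.96 changes a printed bound at two
  decimals). Zero cells take the Haldane–Anscombe +0.5 on all four cells,
  applied only when a zero is present and flagged on the estimate.
- **Logistic regression** is plain Newton–Raphson/IRLS on the Bernoulli
  log-likelihood; convergence when the gradient max-norm < 1e-8 (default)
  within 100 iterations. A coefficient excursion beyond |β| = 15 on a
  binary predictor marks (quasi-)complete separation: the fit is returned
  non-converged with a `separation` flag and near-1 Wald p-values, so
  separated features (an AF absent from one group) are filtered out the
  same way they appear in standard software output.
- **Stepwise selection:** candidates are AFs with univariable Wald p < 0.10
  (a `bypass_univariable_filter` switch exists because the source analysis
  demonstrably admitted at least one feature past its stated filter); entry
  is by likelihood-ratio test at `p_enter = 0.10`, smallest p first, ties
  broken by the canonical feature order. Selected features go to the
  malignant set when more prevalent in HCC, else to the benign set.

## Performance metrics

Sensitivity = upgraded HCC LR-3/4 lesions / all HCC LR-3/4 lesions.
Specificity = non-upgraded non-HCC LR-3/4 lesions / all non-HCC LR-3/4
lesions — the principled complement of the sensitivity definition. The
published specificity column (133/149 = retain + upgrade counts) is
arithmetically inconsistent with any standard definition we could
reconstruct, so printed specificities are not used as oracles anywhere.

Cohen's κ uses the usual marginal-product chance correction over the
three-level outcome labels. McNemar's test is the exact two-sided binomial
for fewer than 25 discordant pairs, else χ² = (b−c)²/(b+c) without
continuity correction (no variant is named in the source); a Bonferroni
factor 2 covers the sensitivity/specificity pair. The stratified 7:3 split
takes per-class ⌊0.7·n⌋ with leftover slots by descending fractional part
(deterministic; 311/162 gives 218+113 training lesions). AUC is the
Mann–Whitney rank estimator with tie correction; its CI is Hanley–McNeil by
default with a seeded bootstrap option. Net benefit and equal-width
calibration bins follow the standard decision-curve definitions.

## Problem sizes in tests and the acceptance script

Deterministic checks run on the 473-lesion fixtures. Stochastic checks use
cohorts simulated at 4× the published group sizes (1892 lesions, 10 seeds)
for screening recovery and between-method agreement, 500/group for the
two-informative/eight-noise selection design, and 10,000/group for
marginal-convergence checks — sizes at which the binomial noise on every
tested quantity is comfortably below the asserted tolerances.

## Known limitations

- Joint feature correlations of the real cohort are unknown; the default
  independence assumption inflates the frequency with which simulated HCC
  lesions carry some malignant AF, so simulated sensitivities run higher
  (and specificities lower) than the published ones. These are properties
  of the generator's study conditions, not of the estimators.
- Patient-level clustering (2–3 lesions per patient) is not modeled; all
  analyses are per-lesion, as in the source.
- LR-1/LR-2 diagnostic pathways, LR-M/LR-TIV, and inter-reader agreement
  (no two-reader data) are out of scope.
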