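"""Categorize lesions from major features and adjust with an AF panel.

Shows the LR-3/4/5 decision table on three hand-built lesions, then the
one-step upgrade/degrade/retain rule with the published AF-LR panel.
"""

from liradsaf import (
    AF_LR_PANEL,
    LiradsCategory,
    adjust_category,
    categorize_mf,
)

lesions = [
    # (APHE, washout, capsule, diameter mm)
    (True, True, True, 25.0),    # everything present, large
    (False, False, False, 15.0), # no major features
    (True, False, True, 15.0),   # APHE + capsule only at 10-19 mm
]
for aphe, washout, capsule, diam in lesions:
    cat = categorize_mf(aphe, washout, capsule, diam)
    print(f"APHE={aphe!s:<5} washout={washout!s:<5} capsule={capsule!s:<5} "
          f"{diam:>5.1f} mm -> {cat}")

# Ancillary features then move LR-3/4 lesions by at most one category.
print(f"\nadjusting with panel {AF_LR_PANEL.label}: "
      f"malignant={sorted(AF_LR_PANEL.malignant_afs)}, "
      f"benign={sorted(AF_LR_PANEL.benign_afs)}")
for initial, flags, label in [
    (LiradsCategory.LR3, (True, False), "only malignant AFs"),
    (LiradsCategory.LR4, (True, False), "only malignant AFs (capped: never LR-5)"),
    (LiradsCategory.LR4, (False, True), "only benign AFs"),
    (LiradsCategory.LR3, (True, True), "both kinds present"),
]:
    res = adjust_category(initial, *flags)
    print(f"  {initial} + {label:<40} -> {res.outcome:<8} final {res.final}")
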