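"""LI-RADS v2018 categorization and ancillary-feature category adjustment.

Categories LR-3 (intermediate probability of malignancy), LR-4 (probable
HCC) and LR-5 (definite HCC) are assigned from the major features alone:
nonrim arterial-phase hyperenhancement (APHE), lesion diameter, nonperipheral
washout and enhancing capsule. Threshold growth is not modeled (it cannot be
assessed with a 12-month window), so the one-additional-feature LR-5 cell of
the 10-19 mm row is reachable only through washout.

Ancillary features then adjust LR-3/4 lesions by at most one category:
only-malignant AFs present -> upgrade, only-benign AFs -> degrade, both or
neither -> retain. Per the LI-RADS application rules an upgrade can never
reach LR-5, so an upgraded LR-4 lesion keeps category LR-4 while still being
recorded as an upgrade outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping

import pandas as pd

from .cohort import CohortTable
from .features import AF_NAMES, check_af_names


class LiradsCategory(IntEnum):
    """LR category; the integer value is the category number."""

    LR2 = 2
    LR3 = 3
    LR4 = 4
    LR5 = 5

    def __str__(self) -> str:  # "LR-4"
        return f"LR-{int(self)}"


def size_bin(diameter_mm: float) -> str:
    """Diameter bin with left-closed bounds: [0,10) / [10,20) / [20,inf)."""
    if diameter_mm <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_mm}")
    if diameter_mm < 10:
        return "<10"
    if diameter_mm < 20:
        return "10-19"
    return ">=20"


def categorize_mf(
    aphe_nonrim: bool,
    washout_nonperipheral: bool,
    capsule_enhancing: bool,
    diameter_mm: float,
) -> LiradsCategory:
    """Assign LR-3/4/5 from major features via the v2018 decision table."""
    bin_ = size_bin(diameter_mm)
    k = int(bool(washout_nonperipheral)) + int(bool(capsule_enhancing))
    if not aphe_nonrim:
        if bin_ == ">=20":
            return LiradsCategory.LR4 if k >= 1 else LiradsCategory.LR3
        return LiradsCategory.LR4 if k == 2 else LiradsCategory.LR3
    if bin_ == "<10":
        return LiradsCategory.LR4 if k >= 1 else LiradsCategory.LR3
    if bin_ == "10-19":
        if k == 0:
            return LiradsCategory.LR3
        # one additional feature: washout reaches LR-5, capsule alone LR-4
        if washout_nonperipheral:
            return LiradsCategory.LR5
        return LiradsCategory.LR4
    # APHE and >=20 mm
    return LiradsCategory.LR5 if k >= 1 else LiradsCategory.LR4


@dataclass(frozen=True)
class AfPanel:
    """A screened ancillary-feature panel.

    ``malignant_afs`` upgrade, ``benign_afs`` degrade; the sets are disjoint
    and drawn from the 16-AF vocabulary.
    """

    malignant_afs: frozenset[str]
    benign_afs: frozenset[str]
    label: str = "custom"

    def __post_init__(self) -> None:
        check_af_names(self.malignant_afs)
        check_af_names(self.benign_afs)
        overlap = set(self.malignant_afs) & set(self.benign_afs)
        if overlap:
            raise ValueError(f"AF(s) in both panel sets: {sorted(overlap)}")

    @classmethod
    def from_sets(
        cls, malignant: Iterable[str], benign: Iterable[str], label: str = "custom"
    ) -> "AfPanel":
        return cls(frozenset(malignant), frozenset(benign), label)


#: Panel screened on all lesions (HCC vs non-HCC), as published.
AF_HCC_PANEL = AfPanel.from_sets(
    malignant=("mild_moderate_T2", "restricted_diffusion", "tp_hypointensity"),
    benign=("marked_T2", "hbp_isointensity"),
    label="AF-HCC",
)

#: Panel screened on LR-3/4 lesions only, as published.
AF_LR_PANEL = AfPanel.from_sets(
    malignant=("restricted_diffusion", "mosaic", "fat_in_mass"),
    benign=("marked_T2", "hbp_isointensity"),
    label="AF-LR",
)


def af_flags(lesion: Mapping[str, object], panel: AfPanel) -> tuple[bool, bool]:
    """(has_malignant, has_benign): does the lesion carry any panel AF?"""
    has_mal = any(bool(lesion[name]) for name in panel.malignant_afs)
    has_ben = any(bool(lesion[name]) for name in panel.benign_afs)
    return has_mal, has_ben


@dataclass(frozen=True)
class AdjustmentResult:
    initial: LiradsCategory
    outcome: str  # upgrade | retain | degrade
    final: LiradsCategory
    triggering_afs: frozenset[str] = field(default_factory=frozenset)


def adjust_category(
    initial: LiradsCategory,
    has_malignant: bool,
    has_benign: bool,
    triggering_afs: Iterable[str] = (),
) -> AdjustmentResult:
    """Apply the one-step adjustment rule to an LR-3/4 lesion.

    Only-malignant -> upgrade (capped at LR-4: LI-RADS never upgrades to
    LR-5); only-benign -> degrade one step (LR-3 goes to LR-2); both or
    neither -> retain.
    """
    if initial not in (LiradsCategory.LR3, LiradsCategory.LR4):
        raise ValueError(
            f"adjustment applies to LR-3/LR-4 lesions only, got {initial}"
        )
    if has_malignant and not has_benign:
        outcome = "upgrade"
        final = LiradsCategory(min(int(initial) + 1, int(LiradsCategory.LR4)))
    elif has_benign and not has_malignant:
        outcome = "degrade"
        final = LiradsCategory(int(initial) - 1)
    else:
        outcome = "retain"
        final = initial
    return AdjustmentResult(
        initial=initial,
        outcome=outcome,
        final=final,
        triggering_afs=frozenset(triggering_afs),
    )


def adjust_lesion(lesion: Mapping[str, object], panel: AfPanel) -> AdjustmentResult:
    """Adjust one categorized lesion record (needs an ``lr_initial`` field)."""
    initial = LiradsCategory(int(lesion["lr_initial"]))
    has_mal, has_ben = af_flags(lesion, panel)
    present = [
        name
        for name in AF_NAMES
        if name in (panel.malignant_afs | panel.benign_afs) and bool(lesion[name])
    ]
    return adjust_category(initial, has_mal, has_ben, triggering_afs=present)


def categorize_cohort(cohort: CohortTable) -> CohortTable:
    """Append ``lr_initial`` (MF-only category, 3/4/5) to a cohort."""
    df = cohort.data.copy()
    df["lr_initial"] = [
        int(
            categorize_mf(
                row.aphe_nonrim,
                row.washout_nonperipheral,
                row.capsule_enhancing,
                row.diameter_mm,
            )
        )
        for row in df.itertuples()
    ]
    return CohortTable(data=df, provenance=cohort.provenance)


def apply_panel(cohort: CohortTable, panel: AfPanel) -> CohortTable:
    """Append ``outcome``, ``lr_final`` and ``triggering_afs`` columns.

    LR-5 lesions are left unadjusted (outcome ``retain``, final LR-5): the
    adjustment rule is defined on LR-3/4 observations only.
    """
    df = cohort.data.copy()
    if "lr_initial" not in df.columns:
        raise ValueError("cohort not categorized: run categorize_cohort first")
    outcomes, finals, triggers = [], [], []
    for _, row in df.iterrows():
        if int(row["lr_initial"]) == int(LiradsCategory.LR5):
            outcomes.append("retain")
            finals.append(int(LiradsCategory.LR5))
            triggers.append("")
            continue
        res = adjust_lesion(row, panel)
        outcomes.append(res.outcome)
        finals.append(int(res.final))
        triggers.append("|".join(sorted(res.triggering_afs)))
    df["outcome"] = outcomes
    df["lr_final"] = finals
    df["triggering_afs"] = triggers
    return CohortTable(data=df, provenance=cohort.provenance)
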