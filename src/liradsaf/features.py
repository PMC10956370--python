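"""Feature vocabulary for the LI-RADS v2018 MRI analysis.

Major features (MFs) drive the LR-3/4/5 decision table; the 16 ancillary
features (AFs) are the candidates for the screening and category-adjustment
pipeline. Threshold growth and the stability/size-reduction AFs are outside
this vocabulary: with a 12-month observation window they cannot be assessed,
so they never enter any calculation.
"""

from __future__ import annotations

#: Major features, in decision-table order.
MF_NAMES: tuple[str, ...] = (
    "aphe_nonrim",
    "washout_nonperipheral",
    "capsule_enhancing",
)

#: The 16 ancillary features, in canonical order (malignancy in general,
#: HCC in particular, benignity). This order breaks ties everywhere a
#: deterministic feature ordering is needed.
AF_NAMES: tuple[str, ...] = (
    "mild_moderate_T2",
    "fat_sparing",
    "iron_sparing",
    "corona_enhancement",
    "tp_hypointensity",
    "hbp_hypointensity",
    "restricted_diffusion",
    "nodule_in_nodule",
    "mosaic",
    "blood_products",
    "fat_in_mass",
    "nonenhancing_capsule",
    "parallel_blood_pool",
    "undistorted_vessels",
    "marked_T2",
    "hbp_isointensity",
)

#: AFs defined on the transitional or hepatobiliary phase; these phases exist
#: only with a hepatobiliary (gadoxetic acid) contrast agent, so the flags are
#: necessarily absent under an extracellular agent.
HEPATOBILIARY_ONLY: tuple[str, ...] = (
    "tp_hypointensity",
    "hbp_hypointensity",
    "hbp_isointensity",
)

#: Mutually exclusive AF pairs: a lesion's T2 signal is either mild-moderate
#: or marked, and its hepatobiliary-phase signal is either hypo- or
#: isointense.
EXCLUSIVE_PAIRS: tuple[tuple[str, str], ...] = (
    ("mild_moderate_T2", "marked_T2"),
    ("hbp_hypointensity", "hbp_isointensity"),
)

GROUPS: tuple[str, str] = ("HCC", "nonHCC")

DIAMETER_BINS: tuple[str, str, str] = ("<10", "10-19", ">=20")

AGENTS: tuple[str, str] = ("hepatobiliary", "extracellular")


def check_af_names(names) -> None:
    """Raise ``ValueError`` if any name is outside the 16-AF vocabulary."""
    unknown = set(names) - set(AF_NAMES)
    if unknown:
        raise ValueError(f"unknown ancillary feature(s): {sorted(unknown)}")
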