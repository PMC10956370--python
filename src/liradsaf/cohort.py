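"""Synthetic lesion cohorts for the LI-RADS ancillary-feature analysis.

The study data behind the published prevalence table were never deposited, so
this module provides two stand-ins:

* :func:`sample_cohort` — a seeded generator drawing lesions whose per-feature
  marginal prevalences match a :class:`PrevalenceSpec` (by default the
  published HCC / non-HCC frequencies, 311 vs 162 lesions);
* :func:`marginal_fixture` — a deterministic cohort whose per-feature,
  per-group *counts* equal the published numerators exactly, for exact unit
  tests of contingency-table statistics. Its joint feature structure is an
  arbitrary deterministic artifact and carries no clinical meaning.

:func:`published_outcome_fixture` reconstructs the published upgrade / retain /
degrade outcome distributions for the LR-3/4 sub-cohort, used to check the
performance metrics downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    AF_NAMES,
    AGENTS,
    DIAMETER_BINS,
    EXCLUSIVE_PAIRS,
    GROUPS,
    HEPATOBILIARY_ONLY,
    MF_NAMES,
)

#: Published feature counts: ``name -> (count_in_HCC, count_in_nonHCC)`` with
#: group sizes 311 / 162. Diameter bins are stored separately.
PUBLISHED_FEATURE_COUNTS: dict[str, tuple[int, int]] = {
    # major features
    "aphe_nonrim": (248, 90),
    "washout_nonperipheral": (186, 17),
    "capsule_enhancing": (177, 18),
    # ancillary features favoring malignancy in general
    "mild_moderate_T2": (252, 81),
    "fat_sparing": (28, 16),
    "iron_sparing": (15, 1),
    "corona_enhancement": (32, 16),
    "tp_hypointensity": (79, 21),
    "hbp_hypointensity": (80, 24),
    "restricted_diffusion": (271, 95),
    # ancillary features favoring HCC in particular
    "nodule_in_nodule": (3, 0),
    "mosaic": (36, 0),
    "blood_products": (55, 0),
    "fat_in_mass": (95, 18),
    "nonenhancing_capsule": (42, 6),
    # ancillary features favoring benignity
    "parallel_blood_pool": (3, 15),
    "undistorted_vessels": (11, 1),
    "marked_T2": (3, 35),
    "hbp_isointensity": (5, 27),
}

#: Published diameter-bin counts per group, bins (<10, 10-19, >=20) mm.
PUBLISHED_DIAMETER_COUNTS: dict[str, tuple[int, int, int]] = {
    "HCC": (13, 78, 220),
    "nonHCC": (41, 68, 53),
}

PUBLISHED_GROUP_SIZES: dict[str, int] = {"HCC": 311, "nonHCC": 162}

#: Fraction of patients scanned with a hepatobiliary agent, per group
#: (98/302 HCC patients, 40/158 non-HCC patients).
AGENT_HBA_FRACTION: dict[str, float] = {"HCC": 98 / 302, "nonHCC": 40 / 158}

#: Sampling ranges (mm) for the three diameter bins; the open-ended bin is
#: capped at 80 mm (cohort mean size 3.34 +/- 1.75 cm).
_BIN_RANGES: tuple[tuple[float, float], ...] = ((3.0, 10.0), (10.0, 20.0), (20.0, 80.0))

#: Published LR-3/4 outcome distributions per adjustment method:
#: method -> group -> (n_degrade, n_retain, n_upgrade).
PUBLISHED_OUTCOME_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "AF-HCC": {"HCC": (0, 20, 113), "nonHCC": (16, 72, 61)},
    "AF-LR": {"HCC": (1, 18, 114), "nonHCC": (14, 65, 70)},
}

FEATURE_COLUMNS: tuple[str, ...] = MF_NAMES + AF_NAMES

#: Canonical cohort CSV column order.
COHORT_COLUMNS: tuple[str, ...] = (
    ("lesion_id", "group", "diameter_mm") + FEATURE_COLUMNS + ("agent",)
)


@dataclass(frozen=True)
class PrevalenceSpec:
    """Marginal structure of a two-group lesion cohort.

    Parameters
    ----------
    prevalence
        ``feature -> (p_in_HCC, p_in_nonHCC)`` for every major and ancillary
        feature, probabilities in [0, 1].
    diameter_bins
        ``group -> (f_lt10, f_10_19, f_ge20)``, per-group bin frequencies
        summing to 1.
    group_sizes
        ``group -> n`` positive lesion counts.
    agent_hba
        ``group -> fraction`` of observations scanned with a hepatobiliary
        agent (baseline rate; see :func:`sample_cohort` for how phase-defined
        features interact with it).
    """

    prevalence: dict[str, tuple[float, float]]
    diameter_bins: dict[str, tuple[float, float, float]]
    group_sizes: dict[str, int]
    agent_hba: dict[str, float] = field(
        default_factory=lambda: dict(AGENT_HBA_FRACTION)
    )

    def __post_init__(self) -> None:
        for name, probs in self.prevalence.items():
            if name not in FEATURE_COLUMNS:
                raise ValueError(f"unknown feature in spec: {name!r}")
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence of {name!r} outside [0,1]: {p}")
        missing = set(FEATURE_COLUMNS) - set(self.prevalence)
        if missing:
            raise ValueError(f"spec missing features: {sorted(missing)}")
        for group in GROUPS:
            freqs = self.diameter_bins[group]
            if len(freqs) != 3 or any(f < 0 for f in freqs):
                raise ValueError("diameter-bin frequencies must be 3 non-negatives")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError(
                    f"diameter-bin frequencies for {group} sum to {sum(freqs)}, not 1"
                )
            n = self.group_sizes[group]
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ValueError(f"group size for {group} must be a positive integer")
            if not 0.0 <= self.agent_hba[group] <= 1.0:
                raise ValueError("agent fraction outside [0,1]")
        # exclusive pairs must admit a zero-joint distribution
        for gi in (0, 1):
            for a, b in EXCLUSIVE_PAIRS:
                if self.prevalence[a][gi] + self.prevalence[b][gi] > 1.0 + 1e-12:
                    raise ValueError(
                        f"prevalences of exclusive pair ({a}, {b}) exceed 1 "
                        f"in group {GROUPS[gi]}"
                    )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "prevalence": {k: list(v) for k, v in self.prevalence.items()},
            "diameter_bins": {k: list(v) for k, v in self.diameter_bins.items()},
            "group_sizes": dict(self.group_sizes),
            "agent_hba": dict(self.agent_hba),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PrevalenceSpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            prevalence={k: tuple(v) for k, v in payload["prevalence"].items()},
            diameter_bins={k: tuple(v) for k, v in payload["diameter_bins"].items()},
            group_sizes={k: int(v) for k, v in payload["group_sizes"].items()},
            agent_hba={k: float(v) for k, v in payload["agent_hba"].items()},
        )


@dataclass
class CohortTable:
    """An ordered lesion table plus a provenance tag.

    ``data`` holds one row per lesion with the canonical cohort columns
    (`lesion_id`, `group`, `diameter_mm`, the three MF flags, the 16 AF
    flags as booleans, `agent`). Downstream stages may append derived
    columns (`lr_initial`, `outcome`, ...).
    """

    data: pd.DataFrame
    provenance: str

    def __post_init__(self) -> None:
        validate_cohort(self.data)

    def __len__(self) -> int:
        return len(self.data)


def validate_cohort(df: pd.DataFrame) -> None:
    """Check the structural invariants of a cohort table.

    Raises ``ValueError`` naming the first violated constraint: missing
    columns, duplicate lesion ids, non-positive diameters, unknown group or
    agent labels, phase-defined AFs recorded under an extracellular agent,
    or a violated mutual-exclusivity pair.
    """
    if len(df) == 0:
        raise ValueError("cohort is empty")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort missing column(s): {missing}")
    if df["lesion_id"].duplicated().any():
        dup = df.loc[df["lesion_id"].duplicated(), "lesion_id"].iloc[0]
        raise ValueError(f"duplicate lesion_id: {dup!r}")
    if (df["diameter_mm"] <= 0).any():
        raise ValueError("diameter_mm must be positive")
    if not set(df["group"]).issubset(GROUPS):
        raise ValueError(f"group labels must be in {GROUPS}")
    if not set(df["agent"]).issubset(AGENTS):
        raise ValueError(f"agent labels must be in {AGENTS}")
    extracellular = df["agent"] == "extracellular"
    for name in HEPATOBILIARY_ONLY:
        if df.loc[extracellular, name].astype(bool).any():
            raise ValueError(
                f"{name} recorded under extracellular agent (phase does not exist)"
            )
    for a, b in EXCLUSIVE_PAIRS:
        if (df[a].astype(bool) & df[b].astype(bool)).any():
            raise ValueError(f"exclusive features both present: {a}, {b}")


def published_prevalence_spec() -> PrevalenceSpec:
    """The default spec: published feature prevalences and group sizes."""
    sizes = dict(PUBLISHED_GROUP_SIZES)
    prevalence = {
        name: (k_hcc / sizes["HCC"], k_non / sizes["nonHCC"])
        for name, (k_hcc, k_non) in PUBLISHED_FEATURE_COUNTS.items()
    }
    diameter_bins = {
        g: tuple(k / sizes[g] for k in PUBLISHED_DIAMETER_COUNTS[g]) for g in GROUPS
    }
    return PrevalenceSpec(
        prevalence=prevalence,
        diameter_bins=diameter_bins,
        group_sizes=sizes,
    )


def _lesion_ids(group: str, n: int) -> list[str]:
    return [f"{group}-{i + 1:04d}" for i in range(n)]


def sample_cohort(
    spec: PrevalenceSpec,
    seed: int,
    latent_loading: float = 0.0,
) -> CohortTable:
    """Draw a seeded synthetic cohort with the spec's marginal structure.

    Each lesion draws a diameter bin from its group's bin frequencies and a
    diameter uniformly inside the bin (the open >=20 mm bin is capped at
    80 mm). Features are Bernoulli at the group prevalence; the two mutually
    exclusive pairs are drawn as a single three-way categorical
    (neither / first / second) so exclusivity holds exactly while each
    member keeps its marginal prevalence. The contrast agent is forced to
    hepatobiliary whenever a phase-defined AF was drawn (those phases exist
    only then) and is otherwise Bernoulli at the spec's baseline fraction.

    ``latent_loading`` in [0, 1) switches on a Gaussian-copula variant in
    which all features of a lesion share a single latent severity factor
    with that loading; 0 (default) gives fully independent features.
    """
    if not 0.0 <= latent_loading < 1.0:
        raise ValueError("latent_loading must be in [0, 1)")
    rng = np.random.default_rng(seed)
    exclusive_members = {name for pair in EXCLUSIVE_PAIRS for name in pair}
    frames = []
    for gi, group in enumerate(GROUPS):
        n = spec.group_sizes[group]
        bins = rng.choice(3, size=n, p=np.asarray(spec.diameter_bins[group]))
        lows = np.array([r[0] for r in _BIN_RANGES])[bins]
        highs = np.array([r[1] for r in _BIN_RANGES])[bins]
        diam = rng.uniform(lows, highs)

        if latent_loading > 0.0:
            z = rng.standard_normal(n)

        def _uniforms() -> np.ndarray:
            # copula: shared latent factor z pushes all features together
            if latent_loading == 0.0:
                return rng.uniform(size=n)
            eps = rng.standard_normal(n)
            from scipy.stats import norm

            return norm.cdf(
                latent_loading * z + np.sqrt(1 - latent_loading**2) * eps
            )

        cols: dict[str, np.ndarray] = {}
        for name in FEATURE_COLUMNS:
            if name in exclusive_members:
                continue
            cols[name] = _uniforms() < spec.prevalence[name][gi]
        for a, b in EXCLUSIVE_PAIRS:
            u = _uniforms()
            pa = spec.prevalence[a][gi]
            pb = spec.prevalence[b][gi]
            cols[a] = u < pa
            cols[b] = u >= 1.0 - pb  # disjoint since pa + pb <= 1

        any_phase = np.zeros(n, dtype=bool)
        for name in HEPATOBILIARY_ONLY:
            any_phase |= cols[name]
        hba = any_phase | (rng.uniform(size=n) < spec.agent_hba[group])

        frame = pd.DataFrame(
            {
                "lesion_id": _lesion_ids(group, n),
                "group": group,
                "diameter_mm": np.round(diam, 2),
                **{name: cols[name] for name in FEATURE_COLUMNS},
                "agent": np.where(hba, "hepatobiliary", "extracellular"),
            }
        )
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)[list(COHORT_COLUMNS)]
    return CohortTable(data=data, provenance=f"synthetic-seed-{seed}")


def marginal_fixture(spec: PrevalenceSpec | None = None) -> CohortTable:
    """Deterministic cohort reproducing every per-feature count exactly.

    Requires a spec whose prevalences are exact count fractions (the default
    spec is). Each feature is set on the first ``k`` lesions of its group,
    except the second member of each exclusivity pair, which is set on the
    *last* ``k`` so the pair never overlaps. The joint structure is therefore
    an arbitrary deterministic artifact: only the marginal counts are
    meaningful. All lesions are tagged hepatobiliary so phase-defined AFs are
    representable.
    """
    spec = spec if spec is not None else published_prevalence_spec()
    tail_features = {pair[1] for pair in EXCLUSIVE_PAIRS}
    frames = []
    for gi, group in enumerate(GROUPS):
        n = spec.group_sizes[group]

        def _count(p: float, what: str) -> int:
            k = p * n
            if abs(k - round(k)) > 1e-6:
                raise ValueError(
                    f"{what} prevalence {p} does not give an integer count at n={n}"
                )
            return int(round(k))

        bin_counts = [_count(f, "diameter bin") for f in spec.diameter_bins[group]]
        if sum(bin_counts) != n:
            raise ValueError("diameter-bin counts do not sum to group size")
        mids = [6.0, 15.0, 30.0]
        diam = np.repeat(mids, bin_counts)

        cols: dict[str, np.ndarray] = {}
        for name in FEATURE_COLUMNS:
            k = _count(spec.prevalence[name][gi], name)
            flags = np.zeros(n, dtype=bool)
            if name in tail_features:
                flags[n - k :] = k > 0
            else:
                flags[:k] = True
            cols[name] = flags
        for a, b in EXCLUSIVE_PAIRS:
            if (cols[a] & cols[b]).any():
                raise ValueError(
                    f"cannot place exclusive pair ({a}, {b}) disjointly at these counts"
                )
        frames.append(
            pd.DataFrame(
                {
                    "lesion_id": _lesion_ids(group, n),
                    "group": group,
                    "diameter_mm": diam,
                    **cols,
                    "agent": "hepatobiliary",
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)[list(COHORT_COLUMNS)]
    return CohortTable(data=data, provenance="marginal-fixture")


def published_outcome_fixture(method: str) -> dict[str, list[str]]:
    """Per-group outcome-label lists matching the published distribution.

    ``method`` is ``"AF-HCC"`` or ``"AF-LR"``. Returns
    ``{"HCC": [...], "nonHCC": [...]}`` of ``degrade`` / ``retain`` /
    ``upgrade`` labels whose counts equal the published LR-3/4 outcome
    distribution for that adjustment method.
    """
    if method not in PUBLISHED_OUTCOME_COUNTS:
        raise ValueError(
            f"unknown method {method!r}; expected one of "
            f"{sorted(PUBLISHED_OUTCOME_COUNTS)}"
        )
    out: dict[str, list[str]] = {}
    for group, (n_deg, n_ret, n_up) in PUBLISHED_OUTCOME_COUNTS[method].items():
        out[group] = (
            ["degrade"] * n_deg + ["retain"] * n_ret + ["upgrade"] * n_up
        )
    return out
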