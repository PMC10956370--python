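"""Diagnostic performance of ancillary-feature adjustment on LR-3/4 lesions.

Sensitivity is the fraction of HCC-group LR-3/4 lesions whose adjustment
outcome is *upgrade*; specificity is the fraction of non-HCC-group LR-3/4
lesions whose outcome is anything but upgrade (the principled complement —
the published specificity column follows a different, unstated bookkeeping
and is not used as an oracle here). Two adjustment methods are compared by
Cohen's kappa on the three-level outcome labels and by McNemar's test on
paired correct/incorrect indicators, with a Bonferroni factor of 2 across
the sensitivity/specificity pair.

Model validation follows the published scheme: a stratified 7:3 split,
training-set and validation-set ROC AUC (Mann-Whitney estimator with
Hanley-McNeil CI), decision-curve net benefit, and calibration bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .engine import AfPanel, adjust_lesion
from .screening import Z975, fit_logistic

OUTCOMES = ("degrade", "retain", "upgrade")


@dataclass
class PerformanceReport:
    outcome_counts: dict[str, dict[str, int]]  # group -> outcome -> count
    sensitivity: float
    specificity: float
    n_hcc: int
    n_nonhcc: int

    def as_dict(self) -> dict:
        return {
            "outcome_counts": self.outcome_counts,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_hcc": self.n_hcc,
            "n_nonhcc": self.n_nonhcc,
        }


@dataclass
class ComparisonResult:
    kappa: float
    mcnemar_sensitivity: tuple[float | None, float]  # (statistic, p) pre-correction
    mcnemar_specificity: tuple[float | None, float]
    p_sensitivity_bonferroni: float
    p_specificity_bonferroni: float
    report_a: PerformanceReport
    report_b: PerformanceReport


@dataclass
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float


@dataclass
class ValidationResult:
    train_fraction: float
    seed: int
    train_auc: AucResult
    validation_auc: AucResult
    calibration: pd.DataFrame
    net_benefit: pd.DataFrame


# ---------------------------------------------------------------------------
# adjustment performance


def performance_from_outcomes(
    outcomes_by_group: dict[str, list[str]]
) -> PerformanceReport:
    """Performance metrics from per-group outcome-label lists."""
    counts = {
        group: {o: labels.count(o) for o in OUTCOMES}
        for group, labels in outcomes_by_group.items()
    }
    n_hcc = len(outcomes_by_group.get("HCC", []))
    n_non = len(outcomes_by_group.get("nonHCC", []))
    if n_hcc == 0 or n_non == 0:
        raise ValueError("both groups must contain LR-3/4 lesions")
    sens = counts["HCC"]["upgrade"] / n_hcc
    spec = (n_non - counts["nonHCC"]["upgrade"]) / n_non
    return PerformanceReport(
        outcome_counts=counts,
        sensitivity=sens,
        specificity=spec,
        n_hcc=n_hcc,
        n_nonhcc=n_non,
    )


def adjustment_outcomes(
    cohort: CohortTable, panel: AfPanel
) -> dict[str, list[str]]:
    """Outcome labels (degrade/retain/upgrade) for the LR-3/4 sub-cohort."""
    df = cohort.data
    if "lr_initial" not in df.columns:
        raise ValueError("cohort not categorized: run categorize_cohort first")
    df = df[df["lr_initial"].isin((3, 4))]
    out: dict[str, list[str]] = {"HCC": [], "nonHCC": []}
    for _, row in df.iterrows():
        out[row["group"]].append(adjust_lesion(row, panel).outcome)
    return out


def evaluate_adjustment(cohort: CohortTable, panel: AfPanel) -> PerformanceReport:
    """Apply a panel to the LR-3/4 lesions and report performance."""
    return performance_from_outcomes(adjustment_outcomes(cohort, panel))


# ---------------------------------------------------------------------------
# agreement and paired comparison


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two categorical labelings."""
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label sequences must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 paired labels")
    vocab = sorted(set(a) | set(b))
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum((a.count(v) / n) * (b.count(v) / n) for v in vocab)
    if p_e >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: both sequences constant and equal")
    return (p_o - p_e) / (1.0 - p_e)


def mcnemar_from_counts(b: int, c: int) -> tuple[float | None, float, str]:
    """McNemar test from discordant-pair counts.

    Exact two-sided binomial when ``b + c < 25``, else the chi-square
    statistic ``(b-c)^2/(b+c)`` without continuity correction. Returns
    ``(statistic, p, method)``; the statistic is None for the exact test.
    ``b + c == 0`` gives p = 1 (degenerate).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    m = b + c
    if m == 0:
        return None, 1.0, "degenerate"
    if m < 25:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), m, 0.5))
        return None, float(p), "exact_binomial"
    statistic = (b - c) ** 2 / m
    return float(statistic), float(stats.chi2.sf(statistic, df=1)), "chi2"


def mcnemar_test(correct_a, correct_b) -> tuple[float | None, float, str]:
    """McNemar test on paired correct/incorrect indicators of two methods."""
    ca = np.asarray(correct_a, dtype=bool)
    cb = np.asarray(correct_b, dtype=bool)
    if ca.shape != cb.shape:
        raise ValueError("paired indicator arrays must have equal length")
    b = int(np.sum(ca & ~cb))
    c = int(np.sum(~ca & cb))
    return mcnemar_from_counts(b, c)


def compare_methods(
    cohort: CohortTable, panel_a: AfPanel, panel_b: AfPanel
) -> ComparisonResult:
    """Compare two adjustment panels on the same LR-3/4 lesions.

    Kappa is computed over the pooled three-level outcome labels; McNemar
    over the paired correct-classification indicators for sensitivity (HCC
    group: correct = upgrade) and specificity (non-HCC group: correct = not
    upgrade), each Bonferroni-corrected by a factor of 2.
    """
    out_a = adjustment_outcomes(cohort, panel_a)
    out_b = adjustment_outcomes(cohort, panel_b)
    labels_a = out_a["HCC"] + out_a["nonHCC"]
    labels_b = out_b["HCC"] + out_b["nonHCC"]
    kappa = cohens_kappa(labels_a, labels_b)

    sens_a = [o == "upgrade" for o in out_a["HCC"]]
    sens_b = [o == "upgrade" for o in out_b["HCC"]]
    spec_a = [o != "upgrade" for o in out_a["nonHCC"]]
    spec_b = [o != "upgrade" for o in out_b["nonHCC"]]
    stat_s, p_s, _ = mcnemar_test(sens_a, sens_b)
    stat_p, p_p, _ = mcnemar_test(spec_a, spec_b)
    return ComparisonResult(
        kappa=kappa,
        mcnemar_sensitivity=(stat_s, p_s),
        mcnemar_specificity=(stat_p, p_p),
        p_sensitivity_bonferroni=min(1.0, 2 * p_s),
        p_specificity_bonferroni=min(1.0, 2 * p_p),
        report_a=performance_from_outcomes(out_a),
        report_b=performance_from_outcomes(out_b),
    )


# ---------------------------------------------------------------------------
# internal validation


def stratified_split(
    labels, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified index split; returns (train_idx, validation_idx).

    Per-class train counts start at ``floor(n_class * f)``; leftover slots
    (to reach ``round(n_total * f)``) go to classes by descending fractional
    part. Every class needs at least 2 members and both splits are non-empty.
    """
    y = np.asarray(labels)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be strictly between 0 and 1")
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2]
        raise ValueError(f"class with fewer than 2 members: {small.tolist()}")
    raw = counts * train_fraction
    base = np.floor(raw).astype(int)
    total_train = int(round(len(y) * train_fraction))
    leftover = total_train - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(max(0, leftover)):
        base[order[i % len(classes)]] += 1
    base = np.minimum(base, counts - 1)  # keep validation non-empty per class
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    for cls, k in zip(classes, base):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        train_parts.append(perm[:k])
        val_parts.append(perm[k:])
    train = np.sort(np.concatenate(train_parts))
    val = np.sort(np.concatenate(val_parts))
    return train, val


def roc_auc(scores, labels, bootstrap: int = 0, seed: int = 0) -> AucResult:
    """AUC by the rank (Mann-Whitney) estimator with tie correction.

    The 95% CI uses the Hanley-McNeil standard error by default; with
    ``bootstrap > 0`` a seeded percentile bootstrap is used instead.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for ROC analysis")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(bootstrap):
            idx = rng.integers(0, len(y), len(y))
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            rb = stats.rankdata(s[idx])
            m1 = int(np.sum(yb == 1))
            m0 = len(yb) - m1
            reps.append((rb[yb == 1].sum() - m1 * (m1 + 1) / 2) / (m1 * m0))
        lo, hi = np.percentile(reps, [2.5, 97.5])
        return AucResult(float(auc), float(lo), float(hi), float(np.std(reps)))
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n1 - 1) * (q1 - auc**2)
        + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    return AucResult(
        float(auc),
        float(max(0.0, auc - Z975 * se)),
        float(min(1.0, auc + Z975 * se)),
        se,
    )


def net_benefit(probabilities, labels, thresholds) -> pd.DataFrame:
    """Decision-curve net benefit: NB(t) = TP/n - FP/n * t/(1-t).

    Classification is positive when probability >= t. Also returns the
    treat-all (``nb_all``) and treat-none (``nb_none``) reference curves.
    Thresholds must lie in (0, 1).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    t = np.asarray(thresholds, dtype=float)
    if ((t <= 0) | (t >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for ti in t:
        pos = p >= ti
        tp = np.sum(pos & (y == 1)) / n
        fp = np.sum(pos & (y == 0)) / n
        w = ti / (1 - ti)
        rows.append((ti, tp - fp * w, prev - (1 - prev) * w, 0.0))
    return pd.DataFrame(rows, columns=["threshold", "net_benefit", "nb_all", "nb_none"])


def calibration_bins(probabilities, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width calibration bins: mean predicted vs observed event rate."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(p) == 0:
        raise ValueError("empty input")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append((b, float(p[mask].mean()), float(y[mask].mean()), int(mask.sum())))
    return pd.DataFrame(rows, columns=["bin", "mean_pred", "obs_rate", "n"])


def validate_model(
    features: pd.DataFrame,
    y,
    train_fraction: float = 0.7,
    seed: int = 0,
    n_bins: int = 10,
    thresholds: np.ndarray | None = None,
) -> ValidationResult:
    """Stratified split, refit on train, score both splits.

    Fits the logistic model on the training split only, then reports
    train/validation AUC (Hanley-McNeil CIs), validation calibration bins
    and the validation decision curve.
    """
    y = np.asarray(y, dtype=float)
    train_idx, val_idx = stratified_split(y, train_fraction, seed)
    X = features.to_numpy(dtype=float)
    fit = fit_logistic(X[train_idx], y[train_idx])
    def _scores(idx):
        eta = np.column_stack([np.ones(len(idx)), X[idx]]) @ fit.coefficients
        return 1.0 / (1.0 + np.exp(-eta))
    p_train = _scores(train_idx)
    p_val = _scores(val_idx)
    if thresholds is None:
        thresholds = np.linspace(0.05, 0.95, 19)
    return ValidationResult(
        train_fraction=train_fraction,
        seed=seed,
        train_auc=roc_auc(p_train, y[train_idx]),
        validation_auc=roc_auc(p_val, y[val_idx]),
        calibration=calibration_bins(p_val, y[val_idx], n_bins=n_bins),
        net_benefit=net_benefit(p_val, y[val_idx], thresholds),
    )
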