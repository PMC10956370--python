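"""Ancillary-feature screening: frequency tests, odds ratios, logistic models.

The screening pipeline mirrors the published analysis: per-feature 2x2
frequency comparison (chi-square or Fisher's exact, chosen by the expected
cell counts), univariable odds ratios with Woolf (log-OR) confidence
intervals, univariable logistic filtering at p < 0.10, and forward stepwise
multivariable selection by likelihood-ratio entry tests. Two contrasts are
supported: HCC vs non-HCC on all lesions (panel "AF-HCC") and restricted to
MF-categorized LR-3/4 lesions (panel "AF-LR"); selected features are split
into malignant vs benign sets by their prevalence direction.

The logistic fitter is a plain Newton-Raphson/IRLS maximizer of the
Bernoulli log-likelihood that reports convergence by gradient norm and flags
(quasi-)complete separation instead of raising, so that separated features
(e.g. an AF absent from one group) flow through the univariable filter the
same way they do in standard software output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .engine import AfPanel, LiradsCategory
from .features import AF_NAMES

#: Exact 97.5% normal quantile used for all Wald-type 95% intervals.
Z975: float = float(stats.norm.ppf(0.975))

#: |beta| beyond which a binary-predictor fit is treated as separated.
SEPARATION_BETA: float = 15.0


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = groups, columns = (feature present, absent)."""

    a: int  # present in group1
    b: int  # absent in group1
    c: int  # present in group2
    d: int  # absent in group2
    group1: str = "HCC"
    group2: str = "nonHCC"
    feature: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class OrEstimate:
    """Odds ratio with Woolf 95% CI and a Wald test on the log scale."""

    or_value: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    p: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int
    separation: bool = False
    names: tuple[str, ...] = ()


@dataclass
class StepwiseResult:
    selected: list[str]
    trace: list[tuple[str, float, str]]  # (candidate, p, action)


@dataclass
class ScreenPanel:
    """Screening output: the AF panel, its fitted model and the paper trail."""

    panel: AfPanel
    fit: LogisticFit | None
    contrast: str
    univariable: pd.DataFrame
    stepwise: StepwiseResult


# ---------------------------------------------------------------------------
# contingency statistics


def feature_contingency(
    cohort: CohortTable,
    feature: str,
    contrast: str | tuple[int, int] = "all",
) -> ContingencyTable:
    """2x2 table of a feature across a contrast.

    ``contrast``:
      * ``"all"`` — HCC vs non-HCC over all lesions;
      * ``"lr34"`` — HCC vs non-HCC restricted to MF-category LR-3/4
        (requires an ``lr_initial`` column);
      * ``(cat1, cat2)`` — two LR categories against each other, e.g.
        ``(3, 4)`` (pairwise category comparison, all lesions pooled).
    """
    df = cohort.data
    if feature not in df.columns:
        raise ValueError(f"unknown feature: {feature!r}")
    if isinstance(contrast, tuple):
        if "lr_initial" not in df.columns:
            raise ValueError("pairwise LR contrast requires lr_initial column")
        cat1, cat2 = (int(c) for c in contrast)
        g1 = df[df["lr_initial"] == cat1]
        g2 = df[df["lr_initial"] == cat2]
        names = (str(LiradsCategory(cat1)), str(LiradsCategory(cat2)))
    else:
        if contrast == "lr34":
            if "lr_initial" not in df.columns:
                raise ValueError("lr34 contrast requires lr_initial column")
            df = df[df["lr_initial"].isin((3, 4))]
        elif contrast != "all":
            raise ValueError(f"unknown contrast: {contrast!r}")
        g1 = df[df["group"] == "HCC"]
        g2 = df[df["group"] == "nonHCC"]
        names = ("HCC", "nonHCC")
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError(f"empty group after restriction for contrast {contrast!r}")
    a = int(g1[feature].astype(bool).sum())
    c = int(g2[feature].astype(bool).sum())
    return ContingencyTable(
        a=a, b=len(g1) - a, c=c, d=len(g2) - c,
        group1=names[0], group2=names[1], feature=feature,
    )


def choose_group_test(table: ContingencyTable) -> tuple[str, float]:
    """Pick and run the frequency test: Fisher exact if any expected < 5.

    Returns ``(test_name, p)``; Pearson chi-square is computed without
    continuity correction. A table with a zero margin has no defined test.
    """
    arr = table.as_array()
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero-margin table: association test undefined")
    expected = np.outer(rows, cols) / table.n
    if (expected < 5).any():
        _, p = stats.fisher_exact(arr, alternative="two-sided")
        return "fisher_exact", float(p)
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return "pearson_chi2", float(p)


def woolf_or(table: ContingencyTable, zero_cell: str = "haldane") -> OrEstimate:
    """Odds ratio of feature presence in group2 relative to group1.

    ``OR = (c*b) / (a*d)`` with Woolf standard error
    ``sqrt(1/a + 1/b + 1/c + 1/d)`` and a 95% CI on the log scale. Under this
    orientation an OR > 1 means the feature is more frequent in the second
    group (non-HCC), i.e. favors benignity.

    Zero cells: with ``zero_cell="haldane"`` 0.5 is added to all four cells
    (only when a zero is present) and the estimate is flagged ``corrected``;
    ``zero_cell="error"`` raises instead.
    """
    cells = [table.a, table.b, table.c, table.d]
    corrected = False
    if 0 in cells:
        if zero_cell == "error":
            raise ValueError(
                "zero cell in 2x2 table; pass zero_cell='haldane' to apply the "
                "Haldane-Anscombe 0.5 correction"
            )
        if zero_cell != "haldane":
            raise ValueError(f"unknown zero_cell policy: {zero_cell!r}")
        cells = [x + 0.5 for x in cells]
        corrected = True
    a, b, c, d = cells
    or_value = (c * b) / (a * d)
    beta = float(np.log(or_value))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = beta / se
    return OrEstimate(
        or_value=float(or_value),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        beta=beta,
        se=se,
        p=float(2 * stats.norm.sf(abs(z))),
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# logistic regression


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    add_intercept: bool = True,
    names: tuple[str, ...] = (),
) -> LogisticFit:
    """Newton-Raphson/IRLS fit of a binary logistic model.

    Converges when the gradient max-norm drops below ``tol``. If any
    coefficient runs past ``SEPARATION_BETA`` the fit is flagged as
    (quasi-)separated and returned non-converged with the current estimates —
    matching how standard software prints huge betas with p ~ 1 rather than
    failing.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ("intercept",) + tuple(names) if names else ()
        p += 1
    if n <= p:
        raise ValueError(f"need more observations than parameters (n={n}, p={p})")
    const_cols = np.ptp(X[:, 1:], axis=0) == 0 if add_intercept else np.ptp(X, axis=0) == 0
    if const_cols.any():
        raise ValueError("constant predictor column")

    beta = np.zeros(p)
    separation = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        W = mu * (1.0 - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(beta)) > SEPARATION_BETA:
            separation = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    ll = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    W = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = (X * W[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        wald_z=z,
        p_values=pvals,
        log_likelihood=ll,
        converged=converged and not separation,
        n_iterations=it,
        separation=separation,
        names=names,
    )


def univariable_screen(
    features: pd.DataFrame, y: np.ndarray
) -> pd.DataFrame:
    """Single-predictor logistic fit per feature.

    Returns a frame indexed by feature with ``beta``, ``se``, ``p``,
    ``separation`` and the feature's prevalence in each outcome class.
    Zero-variance features get p = NaN (never pass any filter).
    """
    y = np.asarray(y, dtype=float)
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        prev1 = float(x[y == 0].mean()) if (y == 0).any() else np.nan
        prev2 = float(x[y == 1].mean()) if (y == 1).any() else np.nan
        if np.ptp(x) == 0:
            rows.append((name, np.nan, np.nan, np.nan, False, prev1, prev2))
            continue
        fit = fit_logistic(x, y, names=(name,))
        rows.append(
            (
                name,
                float(fit.coefficients[1]),
                float(fit.standard_errors[1]),
                float(fit.p_values[1]),
                fit.separation,
                prev1,
                prev2,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["feature", "beta", "se", "p", "separation", "prev_y0", "prev_y1"],
    ).set_index("feature")


def forward_stepwise(
    features: pd.DataFrame,
    y: np.ndarray,
    p_enter: float = 0.10,
    candidates: list[str] | None = None,
) -> StepwiseResult:
    """Forward stepwise selection by likelihood-ratio entry tests.

    At each step the candidate whose addition gives the smallest LR-test
    p-value is entered if that p-value is below ``p_enter``; ties break by
    the canonical feature order. Candidates defaults to all columns.
    """
    y = np.asarray(y, dtype=float)
    order = {name: i for i, name in enumerate(AF_NAMES)}
    pool = list(candidates) if candidates is not None else list(features.columns)
    pool = sorted(pool, key=lambda s: (order.get(s, len(order)), s))
    selected: list[str] = []
    trace: list[tuple[str, float, str]] = []

    def _ll(cols: list[str]) -> float:
        if not cols:
            p1 = y.mean()
            p1 = min(max(p1, 1e-12), 1 - 1e-12)
            return float(
                np.sum(y * np.log(p1) + (1 - y) * np.log(1 - p1))
            )
        return fit_logistic(features[cols].to_numpy(), y).log_likelihood

    ll_current = _ll([])
    while pool:
        best: tuple[float, str, float] | None = None
        for name in pool:
            x = features[name].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                continue
            ll_new = _ll(selected + [name])
            lr = max(0.0, 2.0 * (ll_new - ll_current))
            p = float(stats.chi2.sf(lr, df=1))
            if best is None or p < best[0]:
                best = (p, name, ll_new)
        if best is None or best[0] >= p_enter:
            if best is not None:
                trace.append((best[1], best[0], "stop"))
            break
        p, name, ll_new = best
        selected.append(name)
        pool.remove(name)
        ll_current = ll_new
        trace.append((name, p, "enter"))
    return StepwiseResult(selected=selected, trace=trace)


def screen_panel(
    cohort: CohortTable,
    contrast: str = "all",
    p_enter: float = 0.10,
    bypass_univariable_filter: bool = False,
) -> ScreenPanel:
    """Full screening pass on one contrast -> an :class:`AfPanel`.

    ``contrast="all"`` screens HCC vs non-HCC over every lesion (AF-HCC
    style); ``contrast="lr34"`` restricts to MF-category LR-3/4 lesions
    (AF-LR style; requires ``lr_initial``). The outcome is membership of the
    non-HCC group. Features passing the univariable p < ``p_enter`` filter
    (or all features, with the bypass) enter forward stepwise selection;
    selected features are assigned to the malignant set when more prevalent
    in HCC, to the benign set otherwise.
    """
    df = cohort.data
    if contrast == "lr34":
        if "lr_initial" not in df.columns:
            raise ValueError("lr34 contrast requires lr_initial column")
        df = df[df["lr_initial"].isin((3, 4))]
        label = "AF-LR"
    elif contrast == "all":
        label = "AF-HCC"
    else:
        raise ValueError(f"unknown contrast: {contrast!r}")
    if df["group"].nunique() < 2:
        raise ValueError("both groups required for screening")
    features = df[list(AF_NAMES)].astype(float)
    y = (df["group"] == "nonHCC").to_numpy(dtype=float)

    uni = univariable_screen(features, y)
    if bypass_univariable_filter:
        candidates = [n for n in AF_NAMES if np.ptp(features[n].to_numpy()) > 0]
    else:
        candidates = [n for n in AF_NAMES if uni.loc[n, "p"] < p_enter]
    step = forward_stepwise(features, y, p_enter=p_enter, candidates=candidates)

    malignant, benign = [], []
    for name in step.selected:
        prev_hcc = float(features.loc[df["group"].to_numpy() == "HCC", name].mean())
        prev_non = float(features.loc[df["group"].to_numpy() == "nonHCC", name].mean())
        (malignant if prev_hcc > prev_non else benign).append(name)
    fit = (
        fit_logistic(
            features[step.selected].to_numpy(), y, names=tuple(step.selected)
        )
        if step.selected
        else None
    )
    return ScreenPanel(
        panel=AfPanel.from_sets(malignant, benign, label=label),
        fit=fit,
        contrast=contrast,
        univariable=uni,
        stepwise=step,
    )


def screening_report(cohort: CohortTable, result: ScreenPanel) -> pd.DataFrame:
    """Per-feature screening summary frame (CSV-ready).

    Columns: feature, contrast, a, b, c, d, test, p, or, ci_low, ci_high,
    selected, direction.
    """
    contrast = result.contrast
    rows = []
    for name in AF_NAMES:
        table = feature_contingency(cohort, name, contrast=contrast)
        try:
            test, p = choose_group_test(table)
        except ValueError:
            test, p = "undefined", np.nan
        est = woolf_or(table)
        selected = name in result.stepwise.selected
        if name in result.panel.malignant_afs:
            direction = "malignant"
        elif name in result.panel.benign_afs:
            direction = "benign"
        else:
            direction = ""
        rows.append(
            (
                name, contrast, table.a, table.b, table.c, table.d,
                test, p, est.or_value, est.ci_low, est.ci_high,
                selected, direction,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature", "contrast", "a", "b", "c", "d", "test", "p",
            "or", "ci_low", "ci_high", "selected", "direction",
        ],
    )
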