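"""Contingency statistics, Woolf odds ratios, IRLS logistic, stepwise."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from liradsaf import (
    ContingencyTable,
    PrevalenceSpec,
    choose_group_test,
    feature_contingency,
    fit_logistic,
    forward_stepwise,
    sample_cohort,
    screen_panel,
    screening_report,
    published_prevalence_spec,
    univariable_screen,
    woolf_or,
)
from liradsaf.engine import categorize_cohort
from liradsaf.features import AF_NAMES, MF_NAMES

# Published univariable rows whose OR equals the marginal cross-product
# (orientation: odds of the feature in non-HCC over HCC).
PUBLISHED_ORS = {
    "marked_T2": (28.29, 8.55, 93.66),
    "hbp_isointensity": (12.24, 4.61, 32.47),
    "parallel_blood_pool": (10.48, 2.99, 36.75),
    "undistorted_vessels": (0.17, 0.02, 1.32),
    "iron_sparing": (0.12, 0.02, 0.94),
}


def _fisher_two_sided_brute(a, b, c, d):
    """Sum of hypergeometric point probabilities <= that of the observed table."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFeatureContingency:
    @pytest.mark.parametrize(
        "feature, expected",
        [("marked_T2", (3, 308, 35, 127)), ("hbp_isointensity", (5, 306, 27, 135))],
    )
    def test_fixture_tables(self, fixture_cohort, feature, expected):
        t = feature_contingency(fixture_cohort, feature)
        assert (t.a, t.b, t.c, t.d) == expected

    def test_absent_feature_gives_zero_presence(self, spec):
        prev = {k: (0.0, 0.0) for k in MF_NAMES + AF_NAMES}
        zero = PrevalenceSpec(
            prevalence=prev,
            diameter_bins=spec.diameter_bins,
            group_sizes={"HCC": 30, "nonHCC": 20},
        )
        t = feature_contingency(sample_cohort(zero, seed=0), "mosaic")
        assert (t.a, t.c) == (0, 0)
        assert (t.b, t.d) == (30, 20)

    def test_lr34_restriction_and_pairwise(self, categorized_cohort):
        t_all = feature_contingency(categorized_cohort, "restricted_diffusion", "all")
        t_lr34 = feature_contingency(
            categorized_cohort, "restricted_diffusion", "lr34"
        )
        assert t_lr34.n < t_all.n
        t_pair = feature_contingency(
            categorized_cohort, "restricted_diffusion", (3, 4)
        )
        assert t_pair.group1 == "LR-3" and t_pair.group2 == "LR-4"

    def test_unknown_feature_rejected(self, fixture_cohort):
        with pytest.raises(ValueError, match="unknown feature"):
            feature_contingency(fixture_cohort, "sparkles")


class TestChooseGroupTest:
    def test_large_expected_uses_chi2(self):
        name, _ = choose_group_test(ContingencyTable(3, 308, 35, 127))
        assert name == "pearson_chi2"

    def test_small_expected_uses_fisher(self):
        name, _ = choose_group_test(ContingencyTable(0, 311, 1, 161))
        assert name == "fisher_exact"

    def test_symmetric_table_p_one(self):
        name, p = choose_group_test(ContingencyTable(1, 1, 1, 1))
        assert name == "fisher_exact"
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero-margin"):
            choose_group_test(ContingencyTable(0, 5, 0, 7))

    @pytest.mark.parametrize(
        "cells", [(2, 8, 7, 3), (0, 5, 4, 6), (3, 2, 2, 5), (1, 9, 5, 5)]
    )
    def test_fisher_matches_hypergeometric_enumeration(self, cells):
        name, p = choose_group_test(ContingencyTable(*cells))
        assert name == "fisher_exact"
        assert p == pytest.approx(_fisher_two_sided_brute(*cells), rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.integers(10, 60),
        b=st.integers(10, 60),
        c=st.integers(10, 60),
        d=st.integers(10, 60),
    )
    def test_chi2_matches_squared_score_identity(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        name, p = choose_group_test(t)
        if name != "pearson_chi2":
            return
        n = t.n
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert p == pytest.approx(float(stats.chi2.sf(chi2, 1)), rel=1e-9)


class TestWoolfOr:
    @pytest.mark.parametrize("feature, expected", PUBLISHED_ORS.items())
    def test_published_rows_to_printed_precision(
        self, fixture_cohort, feature, expected
    ):
        est = woolf_or(feature_contingency(fixture_cohort, feature))
        assert (
            round(est.or_value, 2),
            round(est.ci_low, 2),
            round(est.ci_high, 2),
        ) == expected

    def test_equal_odds_gives_or_one(self):
        est = woolf_or(ContingencyTable(10, 90, 10, 90))
        assert est.or_value == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_zero_cell_haldane_correction(self):
        est = woolf_or(ContingencyTable(0, 10, 5, 5))
        assert est.corrected
        assert np.isfinite(est.or_value)
        expected = (5.5 * 10.5) / (0.5 * 5.5)
        assert est.or_value == pytest.approx(expected)

    def test_zero_cell_error_policy(self):
        with pytest.raises(ValueError, match="Haldane"):
            woolf_or(ContingencyTable(0, 10, 5, 5), zero_cell="error")

    def test_ci_brackets_estimate(self, fixture_cohort):
        est = woolf_or(feature_contingency(fixture_cohort, "fat_in_mass"))
        assert est.ci_low <= est.or_value <= est.ci_high
        assert est.or_value == pytest.approx(np.exp(est.beta))


class TestFitLogistic:
    def test_single_predictor_beta_equals_log_cross_product(self, fixture_cohort):
        df = fixture_cohort.data
        y = (df.group == "nonHCC").to_numpy(float)
        x = df["marked_T2"].to_numpy(float)
        fit = fit_logistic(x, y)
        assert fit.converged
        assert fit.coefficients[1] == pytest.approx(np.log(28.2939632546), rel=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(12)
        X = rng.integers(0, 2, size=(400, 3)).astype(float)
        eta = -0.5 + X @ np.array([0.8, -0.4, 0.2])
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.coefficients, ref.params, rtol=1e-6)
        np.testing.assert_allclose(ours.standard_errors, ref.bse, rtol=1e-5)

    def test_null_type_i_error_calibrated(self):
        # independent binary x and y: Wald p uniform, beta centred on zero
        betas, rejections = [], 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = (rng.uniform(size=2000) < 0.5).astype(float)
            y = (rng.uniform(size=2000) < 0.5).astype(float)
            fit = fit_logistic(x, y)
            betas.append(fit.coefficients[1])
            rejections += fit.p_values[1] < 0.05
        assert abs(np.mean(betas)) < 0.05
        # Bin(40, 0.05): >7 rejections has probability < 1e-3
        assert rejections <= 7

    def test_perfect_separation_flagged(self):
        y = np.array([0.0] * 20 + [1.0] * 20)
        fit = fit_logistic(y.copy(), y)
        assert fit.separation
        assert not fit.converged

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.ones(50), np.r_[np.zeros(25), np.ones(25)])


def _design_cohort(seed, gap):
    """n=500/group; 2 designed features at the given prevalence gap, 8 noise."""
    base = published_prevalence_spec()
    designed = ["restricted_diffusion", "fat_in_mass"]
    noise = [
        "fat_sparing", "iron_sparing", "corona_enhancement", "nodule_in_nodule",
        "mosaic", "blood_products", "nonenhancing_capsule", "undistorted_vessels",
    ]
    prev = {name: (0.0, 0.0) for name in MF_NAMES + AF_NAMES}
    for name in MF_NAMES:
        prev[name] = (0.5, 0.5)
    for name in designed:
        prev[name] = (0.1 + gap, 0.1)
    for name in noise:
        prev[name] = (0.3, 0.3)
    spec = PrevalenceSpec(
        prevalence=prev,
        diameter_bins=base.diameter_bins,
        group_sizes={"HCC": 500, "nonHCC": 500},
    )
    df = sample_cohort(spec, seed=seed).data
    y = (df.group == "nonHCC").to_numpy(float)
    return df[designed + noise].astype(float), y, designed, noise


class TestForwardStepwise:
    def test_recovers_designed_features(self):
        hits = 0
        for seed in range(10):
            feats, y, designed, noise = _design_cohort(seed, gap=0.4)
            uni = univariable_screen(feats, y)
            cands = [n for n in feats.columns if uni.loc[n, "p"] < 0.10]
            res = forward_stepwise(feats, y, candidates=cands)
            hits += set(designed) <= set(res.selected)
        assert hits >= 9

    def test_null_design_selects_little(self):
        sizes = []
        for seed in range(10):
            feats, y, _, _ = _design_cohort(100 + seed, gap=0.0)
            uni = univariable_screen(feats, y)
            cands = [n for n in feats.columns if uni.loc[n, "p"] < 0.10]
            sizes.append(len(forward_stepwise(feats, y, candidates=cands).selected))
        # 10 null candidates at p_enter 0.10: expect ~1 entry per seed
        assert np.mean(sizes) <= 2.0

    def test_single_overwhelming_candidate_selected(self):
        y = np.r_[np.zeros(100), np.ones(100)]
        x = np.r_[np.zeros(95), np.ones(5), np.ones(80), np.zeros(20)]
        feats = pd.DataFrame({"mosaic": x})
        res = forward_stepwise(feats, y)
        assert res.selected == ["mosaic"]
        assert res.trace[0][2] == "enter"

    def test_empty_candidate_set_is_valid_empty_result(self):
        feats = pd.DataFrame({"mosaic": np.r_[np.zeros(10), np.ones(10)]})
        y = np.r_[np.zeros(10), np.ones(10)]
        res = forward_stepwise(feats, y, candidates=[])
        assert res.selected == []

    def test_row_order_invariance(self):
        feats, y, _, _ = _design_cohort(7, gap=0.4)
        res1 = forward_stepwise(feats, y)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        res2 = forward_stepwise(feats.iloc[perm].reset_index(drop=True), y[perm])
        assert res1.selected == res2.selected


class TestScreenPanel:
    def test_recovers_published_benign_afs_on_scaled_cohort(self, spec):
        big = PrevalenceSpec(
            prevalence=spec.prevalence,
            diameter_bins=spec.diameter_bins,
            group_sizes={"HCC": 311 * 4, "nonHCC": 162 * 4},
        )
        cohort = categorize_cohort(sample_cohort(big, seed=0))
        result = screen_panel(cohort, contrast="all")
        assert {"marked_T2", "hbp_isointensity"} <= set(result.panel.benign_afs)

    def test_identical_groups_give_empty_panel(self, spec):
        # non-HCC rows are exact copies of the HCC rows: every univariable
        # p-value is 1, so nothing can enter
        prev = {name: (0.3, 0.3) for name in MF_NAMES + AF_NAMES}
        flat = PrevalenceSpec(
            prevalence=prev,
            diameter_bins=spec.diameter_bins,
            group_sizes={"HCC": 200, "nonHCC": 200},
        )
        cohort = sample_cohort(flat, seed=42)
        df = cohort.data
        hcc = df[df.group == "HCC"].copy()
        mirror = hcc.copy()
        mirror["group"] = "nonHCC"
        mirror["lesion_id"] = ["N-" + i for i in hcc["lesion_id"]]
        cohort.data = pd.concat([hcc, mirror], ignore_index=True)
        result = screen_panel(cohort, contrast="all")
        assert result.panel.malignant_afs == frozenset()
        assert result.panel.benign_afs == frozenset()

    def test_direction_rule(self, sampled_cohort):
        # restricted diffusion is far commoner in HCC -> malignant side
        result = screen_panel(sampled_cohort, contrast="all")
        if "restricted_diffusion" in result.stepwise.selected:
            assert "restricted_diffusion" in result.panel.malignant_afs
        if "marked_T2" in result.stepwise.selected:
            assert "marked_T2" in result.panel.benign_afs

    def test_report_schema(self, categorized_cohort):
        result = screen_panel(categorized_cohort, contrast="lr34")
        report = screening_report(categorized_cohort, result)
        assert list(report.columns) == [
            "feature", "contrast", "a", "b", "c", "d", "test", "p",
            "or", "ci_low", "ci_high", "selected", "direction",
        ]
        assert len(report) == len(AF_NAMES)
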