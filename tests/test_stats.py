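import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import safbdg as sb
from safbdg.stats import (
    clogit_from_differences,
    confounder_screen,
    fit_category_contrasts,
    fit_clogit_1to1,
    fit_logit,
    interaction_test,
    paired_descriptives,
    trend_test,
)

# ---------------------------------------------------------------------------
# independent oracles


def conditional_loglik(beta, x_case, x_ctrl):
    """The matched-pair conditional likelihood, written out directly."""
    beta = np.atleast_1d(beta)
    ll = 0.0
    for xc, x0 in zip(x_case, x_ctrl):
        a = math.exp(float(beta @ xc))
        b = math.exp(float(beta @ x0))
        ll += math.log(a / (a + b))
    return ll


def grid_maximize(f, p, span=8.0, rounds=12, pts=21):
    """Brute-force iterated grid search, independent of any gradient."""
    center = np.zeros(p)
    width = span
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, pts) for c in center]
        if p == 1:
            grid = axes[0][:, None]
        else:
            mesh = np.meshgrid(*axes, indexing="ij")
            grid = np.column_stack([m.ravel() for m in mesh])
        vals = [f(b) for b in grid]
        center = grid[int(np.argmax(vals))]
        width = 2.0 * (2.0 * width / (pts - 1))
    return center


def _random_pairs(seed, n_pairs=8, p=2):
    rng = np.random.default_rng(seed)
    x_case = rng.normal(0.3, 1.0, size=(n_pairs, p))
    x_ctrl = rng.normal(0.0, 1.0, size=(n_pairs, p))
    return x_case, x_ctrl


def _pairs_frame(x_case, x_ctrl):
    n, p = x_case.shape
    cols = [f"x{i}" for i in range(p)]
    rows = []
    for j in range(n):
        rows.append({"pair_id": f"P{j}", "status": "case",
                     **dict(zip(cols, x_case[j]))})
        rows.append({"pair_id": f"P{j}", "status": "control",
                     **dict(zip(cols, x_ctrl[j]))})
    return pd.DataFrame(rows), cols


# ---------------------------------------------------------------------------
# conditional logistic regression


class TestClogit:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_grid_search_oracle(self, seed):
        x_case, x_ctrl = _random_pairs(seed)
        data, cols = _pairs_frame(x_case, x_ctrl)
        fit = fit_clogit_1to1(data, cols)
        oracle = grid_maximize(
            lambda b: conditional_loglik(b, x_case, x_ctrl), p=2)
        np.testing.assert_allclose(
            fit.summary["beta"].to_numpy(), oracle, atol=1e-6)

    def test_three_handbuilt_pairs_single_binary_exposure(self):
        # two case-exposed discordant pairs, one control-exposed
        x_case = np.array([[1.0], [1.0], [0.0]])
        x_ctrl = np.array([[0.0], [0.0], [1.0]])
        data, cols = _pairs_frame(x_case, x_ctrl)
        fit = fit_clogit_1to1(data, cols)
        oracle = grid_maximize(
            lambda b: conditional_loglik(b, x_case, x_ctrl), p=1)
        assert fit.beta("x0") == pytest.approx(float(oracle[0]), abs=1e-6)
        # closed form for 1 binary exposure: log(case-exposed/control-exposed)
        assert fit.beta("x0") == pytest.approx(math.log(2.0), abs=1e-6)
        assert fit.n_informative_pairs == 3

    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_difference_logistic_equivalence(self, seed):
        """clogit == no-intercept logistic on within-pair differences."""
        import statsmodels.api as sm

        x_case, x_ctrl = _random_pairs(seed, n_pairs=40)
        data, cols = _pairs_frame(x_case, x_ctrl)
        fit = fit_clogit_1to1(data, cols)
        diffs = x_case - x_ctrl
        ref = sm.Logit(np.ones(len(diffs)), diffs).fit(
            disp=0, method="newton", tol=1e-12, maxiter=500)
        np.testing.assert_allclose(
            fit.summary["beta"].to_numpy(), ref.params, atol=1e-8)

    def test_label_swap_flips_sign_exactly(self):
        x_case, x_ctrl = _random_pairs(6, n_pairs=20)
        data, cols = _pairs_frame(x_case, x_ctrl)
        swapped = data.copy()
        swapped["status"] = swapped["status"].map(
            {"case": "control", "control": "case"})
        fit = fit_clogit_1to1(data, cols)
        fit_swapped = fit_clogit_1to1(swapped, cols)
        np.testing.assert_allclose(
            fit_swapped.summary["beta"].to_numpy(),
            -fit.summary["beta"].to_numpy(), atol=1e-10)

    def test_exposure_constant_within_pairs_not_identifiable(self):
        x = np.random.default_rng(0).normal(size=(5, 1))
        data, cols = _pairs_frame(x, x)
        with pytest.raises(sb.ConvergenceError):
            fit_clogit_1to1(data, cols)

    def test_separation_detected_with_term_name(self):
        x_case = np.ones((6, 1))
        x_ctrl = np.zeros((6, 1))
        data, cols = _pairs_frame(x_case, x_ctrl)
        with pytest.raises(sb.SeparationError, match="x0"):
            fit_clogit_1to1(data, cols)

    def test_noninformative_pairs_counted(self):
        diffs = np.array([[0.0], [0.0], [1.0], [-1.0], [1.0]])
        fit = clogit_from_differences(diffs, names=["x"])
        assert fit.n_informative_pairs == 3
        assert fit.n == 5


class TestClogitSamplingProperties:
    def test_parameter_recovery_at_known_ors(self):
        """Mean MLE over replicates recovers log(theta) for several theta."""
        rng = np.random.default_rng(101)
        for theta in (0.5, 1.0, 2.0):
            betas = []
            for _ in range(300):
                pairs = sb.simulate_exposure_pairs(396, theta, rng)
                fit = fit_category_contrasts(pairs, "category")
                betas.append(fit.beta("high_vs_low"))
            betas = np.asarray(betas)
            sem = betas.std(ddof=1) / math.sqrt(len(betas))
            assert abs(betas.mean() - math.log(theta)) < 4 * sem + 0.01

    def test_wald_ci_coverage_near_95pct(self):
        rng = np.random.default_rng(202)
        theta = 0.56
        covered = 0
        n_rep = 1000
        for _ in range(n_rep):
            pairs = sb.simulate_exposure_pairs(396, theta, rng)
            fit = fit_category_contrasts(pairs, "category")
            lo, hi = fit.ci95("high_vs_low")
            covered += lo <= theta <= hi
        coverage = covered / n_rep
        assert abs(coverage - 0.95) < 3 * math.sqrt(0.95 * 0.05 / n_rep)


# ---------------------------------------------------------------------------
# unconditional logistic regression


class TestLogit:
    @staticmethod
    def _two_by_two(a, b, c, d):
        # a: exposed cases, b: exposed controls, c: unexposed cases,
        # d: unexposed controls
        rows = (
            [{"status": "case", "exposure": 1.0}] * a
            + [{"status": "control", "exposure": 1.0}] * b
            + [{"status": "case", "exposure": 0.0}] * c
            + [{"status": "control", "exposure": 0.0}] * d
        )
        return pd.DataFrame(rows)

    def test_two_by_two_closed_form(self):
        # OR = ad/bc = (10*10)/(20*20) = 0.25
        fit = fit_logit(self._two_by_two(10, 20, 20, 10), ["exposure"])
        assert fit.or_("exposure") == pytest.approx(0.25, rel=1e-5)

    def test_independence_gives_unit_or(self):
        fit = fit_logit(self._two_by_two(15, 15, 15, 15), ["exposure"])
        assert fit.or_("exposure") == pytest.approx(1.0, abs=1e-6)

    def test_matches_clogit_direction_when_matching_ignorable(self):
        """Unmatched fit agrees in direction with the conditional fit on
        exchangeable pairs (matching carries no information here)."""
        pairs = sb.simulate_exposure_pairs(2000, 0.5, seed=7)
        cond = fit_category_contrasts(pairs, "category", conditional=True)
        uncond = fit_category_contrasts(pairs, "category", conditional=False)
        assert cond.beta("high_vs_low") < 0
        assert uncond.beta("high_vs_low") < 0
        assert abs(uncond.beta("high_vs_low")
                   - cond.beta("high_vs_low")) < 0.25

    def test_single_outcome_class_rejected(self):
        df = self._two_by_two(5, 0, 5, 0)
        with pytest.raises(sb.DomainError):
            fit_logit(df, ["exposure"])


# ---------------------------------------------------------------------------
# trend and interaction tests


class TestTrend:
    def test_strong_monotone_effect_gives_small_p(self):
        pairs = sb.simulate_exposure_pairs(396, 0.3, seed=31)
        res = trend_test(pairs, "category")
        assert res.p_trend < 0.01
        assert res.slope < 0

    def test_reversed_categories_flip_slope_same_p(self):
        pairs = sb.simulate_exposure_pairs(200, 0.5, seed=33)
        rev = pairs.copy()
        rev["category"] = 2.0 - rev["category"]
        a = trend_test(pairs, "category")
        b = trend_test(rev, "category")
        assert b.slope == pytest.approx(-a.slope, abs=1e-8)
        assert b.p_trend == pytest.approx(a.p_trend, abs=1e-10)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(44)
        pvals = []
        for _ in range(300):
            pairs = sb.simulate_exposure_pairs(300, 1.0, rng)
            pvals.append(trend_test(pairs, "category").p_trend)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestInteraction:
    @staticmethod
    def _stratified_pairs(n_pairs, theta0, theta1, seed):
        rng = np.random.default_rng(seed)
        a = sb.simulate_exposure_pairs(n_pairs // 2, theta0, rng)
        b = sb.simulate_exposure_pairs(n_pairs // 2, theta1, rng)
        b["pair_id"] = "B" + b["pair_id"]
        a["stratum"], b["stratum"] = 0.0, 1.0
        return pd.concat([a, b], ignore_index=True)

    def test_injected_interaction_detected(self):
        # OR-ratio 3 across strata at n = 2000 pairs
        data = self._stratified_pairs(2000, 2.0 / 3.0, 2.0, seed=51)
        p, fit = interaction_test(data, "category", "stratum")
        assert p < 0.05
        assert fit.p("_product") == p

    def test_null_interaction_calibrated(self):
        rng = np.random.default_rng(52)
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            data = self._stratified_pairs(400, 0.7, 0.7,
                                          seed=rng.integers(2**31))
            p, _ = interaction_test(data, "category", "stratum")
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.12

    def test_duplicated_strata_give_p_one(self):
        """Identical data in both strata: interaction estimate exactly 0."""
        base = sb.simulate_exposure_pairs(300, 0.6, seed=53)
        other = base.copy()
        other["pair_id"] = "B" + other["pair_id"]
        base["stratum"], other["stratum"] = 0.0, 1.0
        p, fit = interaction_test(
            pd.concat([base, other], ignore_index=True),
            "category", "stratum")
        assert fit.beta("_product") == pytest.approx(0.0, abs=1e-7)
        assert p == pytest.approx(1.0, abs=1e-5)

    def test_nonbinary_stratifier_rejected(self):
        pairs = sb.simulate_exposure_pairs(50, 1.0, seed=54)
        pairs["stratum"] = np.arange(len(pairs), dtype=float)
        with pytest.raises(sb.DomainError):
            interaction_test(pairs, "category", "stratum")


# ---------------------------------------------------------------------------
# confounder screen


class TestConfounderScreen:
    @staticmethod
    def _confounded(n=2000, seed=61):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=n)                       # true confounder
        noise = rng.normal(size=n)                   # independent noise
        x = (z + rng.normal(size=n) > 0).astype(float)
        logit = -0.3 + 1.2 * z                       # outcome driven by z
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        return pd.DataFrame({
            "status": np.where(y, "case", "control"),
            "exposure": x, "confounder": z, "noise": noise,
        })

    def test_selects_true_confounder_rejects_noise(self):
        data = self._confounded()
        res = confounder_screen(data, "exposure", ["confounder", "noise"],
                                conditional=False)
        assert res.selected == ["confounder"]
        assert bool(res.table.loc["confounder", "selected"])
        assert not bool(res.table.loc["noise", "selected"])
        assert res.table.loc["confounder", "relative_change"] > 0.10

    def test_collinear_candidate_flagged_not_selected(self):
        data = self._confounded()
        data["copy_of_exposure"] = data["exposure"]
        with pytest.warns(UserWarning, match="collinear"):
            res = confounder_screen(data, "exposure", ["copy_of_exposure"],
                                    conditional=False)
        assert res.selected == []
        assert "collinear" in res.table.loc["copy_of_exposure", "note"]


# ---------------------------------------------------------------------------
# paired descriptive tests


class TestPairedDescriptives:
    def test_identical_values_paired_t(self):
        res = paired_descriptives([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "normal")
        assert res.statistic == 0.0 and res.p == 1.0

    def test_five_pair_t_matches_textbook_arithmetic(self):
        case = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        control = np.array([4.0, 6.0, 6.0, 9.0, 7.0])
        d = case - control
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_hand = 2 * sps.t.sf(abs(t_hand), len(d) - 1)
        res = paired_descriptives(case, control, "normal")
        assert res.statistic == pytest.approx(t_hand)
        assert res.p == pytest.approx(p_hand)
        assert res.summary["cases_mean"] == pytest.approx(7.0)

    def test_wilcoxon_undefined_on_zero_differences(self):
        res = paired_descriptives([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], "skewed")
        assert math.isnan(res.p)
        assert "zero" in res.note

    def test_wilcoxon_runs_on_skewed_data(self):
        rng = np.random.default_rng(71)
        case = rng.lognormal(1.0, 1.0, 30)
        control = rng.lognormal(0.8, 1.0, 30)
        res = paired_descriptives(case, control, "skewed")
        assert res.test == "wilcoxon"
        assert 0 <= res.p <= 1

    def test_mcnemar_balanced_discordance_is_zero(self):
        case = [1] * 5 + [0] * 5 + [1] * 3 + [0] * 3
        control = [0] * 5 + [1] * 5 + [1] * 3 + [0] * 3
        res = paired_descriptives(case, control, "categorical")
        assert res.test == "mcnemar"
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(sb.DomainError):
            paired_descriptives([1], [1], "fancy")
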