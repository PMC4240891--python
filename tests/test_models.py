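"""Logistic regression, LRT, stratified/stepwise analyses, chi-square, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from immunomet.models import (ModelError, adjusted_response_table, build_design,
                              chisq_independence, fit_logistic, lrt_pvalue,
                              spearman_matrix, stepwise_select,
                              stratified_analysis, univariate_response_table)


def _fit_xy(x, y):
    design = pd.DataFrame({"x": np.asarray(x, dtype=float)})
    return fit_logistic(design, pd.Series(y, index=design.index))


def _two_by_two(n_exp, k_exp, n_unexp, k_unexp):
    x = np.r_[np.ones(n_exp), np.zeros(n_unexp)]
    y = np.r_[np.ones(k_exp), np.zeros(n_exp - k_exp),
              np.ones(k_unexp), np.zeros(n_unexp - k_unexp)]
    return x, y


class TestFitLogistic:
    def test_two_by_two_matches_cross_product_or_and_wald_se(self):
        # exposed 20/100 responders, unexposed 10/100: OR = (20*90)/(80*10)
        x, y = _two_by_two(100, 20, 100, 10)
        fit = _fit_xy(x, y)
        assert fit.odds_ratios.loc["x", "odds_ratio"] == pytest.approx(2.25, abs=1e-6)
        se_closed = np.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90)
        assert fit.terms.loc["x", "se"] == pytest.approx(se_closed, abs=1e-6)
        z = stats.norm.ppf(0.975)
        lo, hi = np.exp(np.log(2.25) + np.array([-z, z]) * se_closed)
        assert fit.odds_ratios.loc["x", "ci_low"] == pytest.approx(lo, rel=1e-6)
        assert fit.odds_ratios.loc["x", "ci_high"] == pytest.approx(hi, rel=1e-6)

    def test_no_association_gives_unit_or(self):
        x, y = _two_by_two(100, 15, 100, 15)
        fit = _fit_xy(x, y)
        assert fit.odds_ratios.loc["x", "odds_ratio"] == pytest.approx(1.0, abs=1e-8)

    def test_loglik_matches_grid_search_oracle(self, rng):
        x = rng.normal(size=30)
        y = (rng.random(30) < expit(0.5 + 0.8 * x)).astype(float)
        fit = _fit_xy(x, y)

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        coarse = np.arange(-4, 4.001, 0.05)
        best = max(((loglik(a, b), a, b) for a in coarse for b in coarse))
        fine_a = np.arange(best[1] - 0.06, best[1] + 0.061, 0.001)
        fine_b = np.arange(best[2] - 0.06, best[2] + 0.061, 0.001)
        grid_max = max(loglik(a, b) for a in fine_a for b in fine_b)
        assert fit.loglik >= grid_max - 1e-9
        assert fit.loglik - grid_max <= 1e-6
        assert fit.loglik <= 0  # Bernoulli log-likelihood

    def test_incomplete_cases_dropped_and_counted(self, rng):
        design = pd.DataFrame({"x": [1.0, 2.0, np.nan, 4.0] * 5})
        y = pd.Series([0, 1, 1, 0] * 5, dtype=float)
        fit = fit_logistic(design, y)
        assert fit.n_used == 15 and fit.n_dropped == 5

    def test_perfect_separation_flagged_not_raised(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20), np.ones(20)]
        fit = _fit_xy(x, y)
        assert not fit.converged

    def test_singular_design_names_collinear_column(self, rng):
        x = rng.normal(size=50)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        y = pd.Series((rng.random(50) < 0.4).astype(float))
        with pytest.raises(ModelError, match="b"):
            fit_logistic(design, y)


class TestLrt:
    def test_identical_models_give_p_one(self, rng):
        x = rng.normal(size=60)
        y = (rng.random(60) < 0.35).astype(float)
        fit = _fit_xy(x, y)
        assert lrt_pvalue(fit, fit) == 1.0

    def test_p_consistent_with_deviance_difference(self, rng):
        x = rng.normal(size=(150, 2))
        y = pd.Series((rng.random(150) < expit(-0.5 + 0.6 * x[:, 0])).astype(float))
        full = fit_logistic(pd.DataFrame({"a": x[:, 0], "b": x[:, 1]}), y)
        reduced = fit_logistic(full._X.drop(columns=["b"]), full._y)
        stat = 2 * (full.loglik - reduced.loglik)
        assert stat >= -1e-9
        assert lrt_pvalue(full, reduced) == pytest.approx(
            stats.chi2.sf(max(stat, 0.0), 1))

    def test_non_nested_models_rejected(self, rng):
        x = rng.normal(size=(60, 2))
        y = pd.Series((rng.random(60) < 0.4).astype(float))
        fit_a = fit_logistic(pd.DataFrame({"a": x[:, 0]}), y)
        fit_b = fit_logistic(pd.DataFrame({"b": x[:, 1]}), y)
        with pytest.raises(ModelError):
            lrt_pvalue(fit_a, fit_b)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(400):
            x = rng.normal(size=200)
            y = pd.Series((rng.random(200) < 0.3).astype(float))
            full = fit_logistic(pd.DataFrame({"x": x}), y)
            reduced = fit_logistic(full._X.drop(columns=["x"]), full._y)
            pvals.append(lrt_pvalue(full, reduced))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTables:
    def test_univariate_reports_all_variables_with_valid_pvalues(self, rng):
        n = 300
        scores = pd.DataFrame(rng.normal(size=(n, 4)),
                              columns=["B/P", "T/NK", "M/D", "P"])
        subtype = pd.Series(rng.choice(["Basal", "LumA", "Normal-like"], n))
        y = pd.Series((rng.random(n) < expit(-1 + scores["P"])).astype(float))
        table = univariate_response_table(scores, subtype, y)
        assert set(scores.columns) <= set(table["variable"])
        assert table["p_value"].between(0, 1).all()
        p_row = table.loc[table["variable"] == "P"].iloc[0]
        assert p_row["ci_low"] < p_row["odds_ratio"] < p_row["ci_high"]
        assert p_row["p_value"] < 0.001

    def test_adjustment_removes_confounded_association(self):
        # immune is a noisy proxy of P and has no effect of its own
        rng = np.random.default_rng(17)
        reps, n = 200, 600
        adj_cover, unadj_cover = 0, 0
        for _ in range(reps):
            p = rng.normal(size=n)
            immune = 0.7 * p + np.sqrt(1 - 0.49) * rng.normal(size=n)
            y = pd.Series((rng.random(n) < expit(-1 + 0.93 * p)).astype(float))
            scores = pd.DataFrame({"B/P": immune, "P": p})
            subtype = pd.Series(rng.choice(["Basal", "Normal-like"], n))
            adj = adjusted_response_table(scores, subtype, y).iloc[0]
            una = univariate_response_table(scores[["B/P"]], None, y).iloc[0]
            adj_cover += adj["ci_low"] <= 1.0 <= adj["ci_high"]
            unadj_cover += una["ci_low"] <= 1.0 <= una["ci_high"]
        assert adj_cover / reps >= 0.90
        assert unadj_cover / reps <= 0.30

    def test_orthogonal_covariates_leave_or_unchanged(self):
        # modest effects: the non-collapsibility gap is negligible
        rng = np.random.default_rng(29)
        deltas = []
        for _ in range(50):
            n = 800
            immune = rng.normal(size=n)
            p = rng.normal(size=n)
            y = pd.Series((rng.random(n)
                           < expit(-1 + 0.3 * immune + 0.3 * p)).astype(float))
            scores = pd.DataFrame({"B/P": immune, "P": p})
            subtype = pd.Series(rng.choice(["Basal", "Normal-like"], n))
            adj = adjusted_response_table(scores, subtype, y).iloc[0]
            una = univariate_response_table(scores[["B/P"]], None, y).iloc[0]
            deltas.append(np.log(adj["odds_ratio"]) - np.log(una["odds_ratio"]))
        mc_se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < max(2 * mc_se, 0.02)


class TestStratified:
    def test_effect_detected_only_in_affected_stratum(self):
        rng = np.random.default_rng(41)
        n = 900
        strata = pd.Series(np.repeat(["low", "intermediate", "high"], n // 3))
        x = rng.normal(size=n)
        eta = np.where(strata == "high", -1 + 1.0 * x, -1.0)
        y = pd.Series((rng.random(n) < expit(eta)).astype(float))
        scores = pd.DataFrame({"B/P": x, "T/NK": x, "M/D": x})
        table = stratified_analysis(scores, strata, y)
        high = table[(table["stratum"] == "high") & (table["variable"] == "B/P")].iloc[0]
        low = table[(table["stratum"] == "low") & (table["variable"] == "B/P")].iloc[0]
        assert high["ci_low"] > 1.0
        assert low["ci_low"] <= 1.0 <= low["ci_high"]

    def test_stratum_headers_partition_annotated_samples(self, rng):
        n = 300
        strata = pd.Series(rng.choice(["a", "b", "c"], n))
        scores = pd.DataFrame({"B/P": rng.normal(size=n),
                               "T/NK": rng.normal(size=n),
                               "M/D": rng.normal(size=n)})
        y = pd.Series((rng.random(n) < 0.3).astype(float))
        y.iloc[:20] = np.nan
        table = stratified_analysis(scores, strata, y)
        per_stratum = table.groupby("stratum")["n"].first()
        assert per_stratum.sum() == int(y.notna().sum())
        headers = table.groupby("stratum")[["n", "pr", "nr"]].first()
        assert (headers["pr"] + headers["nr"] == headers["n"]).all()

    def test_small_stratum_skipped_with_counts(self, rng):
        n = 105
        strata = pd.Series(["big"] * 100 + ["tiny"] * 5)
        scores = pd.DataFrame({"B/P": rng.normal(size=n),
                               "T/NK": rng.normal(size=n),
                               "M/D": rng.normal(size=n)})
        y = pd.Series((rng.random(n) < 0.3).astype(float))
        table = stratified_analysis(scores, strata, y)
        tiny = table[table["stratum"] == "tiny"]
        assert len(tiny) == 1 and bool(tiny.iloc[0]["skipped"])
        assert tiny.iloc[0]["n"] == 5


class TestStepwise:
    @staticmethod
    def _design(x):
        cols = {f"x{j}": x[:, j] for j in range(x.shape[1])}
        design = pd.DataFrame(cols)
        return design, {c: [c] for c in design.columns}

    def test_true_predictor_found_noise_rare(self):
        rng = np.random.default_rng(3)
        reps = 200
        found_true, noise_hits = 0, np.zeros(5)
        for _ in range(reps):
            x = rng.normal(size=(400, 6))
            y = pd.Series((rng.random(400) < expit(-1 + 0.8 * x[:, 0])).astype(float))
            design, tmap = self._design(x)
            result = stepwise_select(design, tmap, y)
            found_true += "x0" in result.selected
            for j in range(1, 6):
                noise_hits[j - 1] += f"x{j}" in result.selected
        assert found_true / reps >= 0.95
        # per-term inclusion expected at the 5% per-step level
        assert (noise_hits / reps <= 0.10).all()

    def test_collinear_pair_yields_single_selection(self):
        # outcome acts through x0; x1 is an r=0.8 sibling with no
        # conditional effect of its own
        rng = np.random.default_rng(13)
        reps, exactly_one = 200, 0
        for _ in range(reps):
            x0 = rng.normal(size=400)
            x1 = 0.8 * x0 + 0.6 * rng.normal(size=400)
            y = pd.Series((rng.random(400) < expit(-1 + 0.8 * x0)).astype(float))
            design, tmap = self._design(np.column_stack([x0, x1]))
            result = stepwise_select(design, tmap, y)
            exactly_one += len(result.selected) == 1
        assert exactly_one / reps >= 0.90

    def test_all_noise_usually_selects_nothing(self):
        rng = np.random.default_rng(23)
        reps = 200
        empty_one, empty_five = 0, 0
        for _ in range(reps):
            x = rng.normal(size=(200, 5))
            y = pd.Series((rng.random(200) < 0.3).astype(float))
            d1, t1 = self._design(x[:, :1])
            empty_one += len(stepwise_select(d1, t1, y).selected) == 0
            d5, t5 = self._design(x)
            empty_five += len(stepwise_select(d5, t5, y).selected) == 0
        # single candidate enters ~5% of the time; with five candidates
        # the chance any enters is ~1-0.95^5
        assert 0.90 <= empty_one / reps <= 0.99
        assert empty_five / reps >= 0.70

    def test_deterministic_and_stay_criterion_holds(self, rng):
        x = rng.normal(size=(500, 4))
        y = pd.Series((rng.random(500)
                       < expit(-1 + 0.7 * x[:, 0] + 0.5 * x[:, 2])).astype(float))
        design, tmap = self._design(x)
        a = stepwise_select(design, tmap, y)
        b = stepwise_select(design, tmap, y)
        assert a.selected == b.selected
        # every retained term stays significant in the final model
        for term in a.selected:
            reduced = fit_logistic(
                a.final._X.drop(columns=tmap[term]), a.final._y)
            assert lrt_pvalue(a.final, reduced) < 0.05


class TestChisq:
    def test_hand_oracle_2x2(self):
        table = pd.DataFrame([[10, 20], [20, 10]])
        stat, df, p = chisq_independence(table)
        # sum over cells of (O-E)^2/E with all E = 15
        assert stat == pytest.approx(20 / 3, abs=1e-9)
        assert df == 1

    def test_proportional_rows_give_zero(self):
        table = pd.DataFrame([[10, 20], [20, 40], [5, 10]])
        stat, df, p = chisq_independence(table)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_by_two_df(self, rng):
        table = pd.DataFrame(rng.integers(5, 40, size=(4, 2)))
        _, df, _ = chisq_independence(table)
        assert df == 3

    def test_zero_marginal_rejected(self):
        with pytest.raises(ModelError):
            chisq_independence(pd.DataFrame([[0, 0], [5, 5]]))


class TestSpearman:
    def test_monotone_transform_perfectly_correlated(self, rng):
        s = pd.Series(rng.normal(size=50))
        scores = pd.DataFrame({"B/P": s, "T/NK": np.exp(s)})
        rho = spearman_matrix(scores)
        assert rho.loc["B/P", "T/NK"] == pytest.approx(1.0)

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(31)
        scores = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        assert abs(spearman_matrix(scores).loc["a", "b"]) < 0.08

    def test_matches_rank_then_pearson_oracle(self, rng):
        a = pd.Series(rng.normal(size=15))
        b = pd.Series(rng.normal(size=15))
        rho = spearman_matrix(pd.DataFrame({"a": a, "b": b})).loc["a", "b"]
        oracle = np.corrcoef(a.rank(), b.rank())[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        scores = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("wxyz"))
        rho = spearman_matrix(scores)
        assert np.allclose(rho, rho.T)
        assert np.allclose(np.diag(rho), 1.0)
        assert (rho.abs() <= 1.0 + 1e-12).all().all()

    def test_constant_column_undefined(self, rng):
        scores = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        rho = spearman_matrix(scores)
        assert np.isnan(rho.loc["a", "b"])
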