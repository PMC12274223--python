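"""Assumption checks, GLM fitting, FDR control and %SS correlations."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from atas import CohortSpec, adjust_fdr, correlate_with_ss, make_synthetic_cohort
from atas.simulate import zero_effect_spec
from atas.stats import (
    GAMMA,
    GAUSSIAN,
    NEGATIVE_BINOMIAL,
    ModelPlan,
    PlanEntry,
    assess_distributions,
    build_model_plan,
    check_heteroscedasticity,
    check_multicollinearity,
    check_overdispersion,
    fit_group_models,
)

warnings.filterwarnings("ignore", category=RuntimeWarning)


def _cohort(seed=0):
    return make_synthetic_cohort(CohortSpec(seed=seed))


# ---------------------------------------------------------------------------
# multicollinearity
# ---------------------------------------------------------------------------

class TestVIF:
    def _table(self, X):
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        return df

    def test_orthogonal_predictors(self):
        n = 40
        t = self._table(np.stack([np.tile([1.0, -1.0], n // 2),
                                  np.repeat([1.0, -1.0], n // 2)], axis=1))
        out = check_multicollinearity(t, predictors=("x0", "x1"))
        assert np.allclose(out["vif"], 1.0)
        assert not out["flagged"].any()

    def test_duplicated_predictor_infinite(self):
        x = np.arange(20, dtype=float)
        t = self._table(np.stack([x, x], axis=1))
        out = check_multicollinearity(t, predictors=("x0", "x1"))
        assert np.all(np.isinf(out["vif"]))
        assert out["flagged"].all()

    def test_known_r2(self, rng):
        # x1 = x0 + noise scaled so that R^2(x1 ~ x0) = 0.75 -> VIF = 4
        n = 200_0
        x0 = rng.normal(size=n)
        noise = rng.normal(size=n)
        x0 = (x0 - x0.mean()) / x0.std()
        noise = (noise - noise.mean()) / noise.std()
        noise -= x0 * (noise @ x0) / n  # exact orthogonalization
        noise /= noise.std()
        x1 = np.sqrt(0.75) * x0 + np.sqrt(0.25) * noise
        out = check_multicollinearity(self._table(np.stack([x0, x1], axis=1)),
                                      predictors=("x0", "x1"))
        assert out["vif"].iloc[0] == pytest.approx(4.0, rel=1e-6)

    def test_cohort_predictors_not_flagged(self):
        out = check_multicollinearity(_cohort())
        assert not out["flagged"].any()
        assert (out["vif"] >= 1.0).all()


# ---------------------------------------------------------------------------
# normality / heteroscedasticity / overdispersion
# ---------------------------------------------------------------------------

class TestAssessDistributions:
    def test_lognormal_gets_transform_recommended(self, rng):
        hits = 0
        for i in range(50):
            t = pd.DataFrame({"m": rng.lognormal(0.0, 1.0, 35)})
            out = assess_distributions(t, metrics=["m"])
            hits += bool(out.loc[0, "log_transform"])
        assert hits > 40  # power > 80%

    def test_lognormal_fixed_by_log(self, rng):
        t = pd.DataFrame({"m": rng.lognormal(0.0, 1.0, 200)})
        out = assess_distributions(t, metrics=["m"])
        assert bool(out.loc[0, "log_fixed"])

    def test_constant_column_missing(self):
        out = assess_distributions(pd.DataFrame({"m": [1.0] * 10}), metrics=["m"])
        assert np.isnan(out.loc[0, "shapiro_p"])

    def test_nonpositive_values_withhold_transform(self, rng):
        x = np.concatenate([rng.lognormal(0, 1, 34), [-1.0]])
        with pytest.warns(UserWarning):
            out = assess_distributions(pd.DataFrame({"m": x}), metrics=["m"])
        assert not bool(out.loc[0, "log_transform"])


class TestBreuschPagan:
    def _table(self, y, rng):
        n = len(y)
        return pd.DataFrame({
            "group": rng.choice(["AWS", "AWNS"], n),
            "sex": rng.choice(["male", "female"], n),
            "age": rng.uniform(20, 60, n), "m": y})

    def test_power_grows_with_sample_size(self, rng):
        """Error SD rising with age is detected; power climbs with n.

        The LM statistic is ~ n * R^2 of the squared-residual regression, and
        that R^2 is bounded near 1/3 for Gaussian errors, so at n = 35 the
        test has only moderate power against even a strong alternative; by
        n = 200 detection is near-certain.
        """
        power = {}
        for n in (35, 200):
            hits = 0
            for _ in range(50):
                age = rng.uniform(20, 60, n)
                y = 1.0 + 0.1 * age + rng.normal(0, 1, n) * np.exp(0.05 * age)
                t = self._table(y, rng)
                t["age"] = age
                hits += check_heteroscedasticity(t, "m")["weighted"]
            power[n] = hits / 50
        assert power[35] > 0.3
        assert power[200] > 0.8

    def test_degenerate_constant_response_missing(self, rng):
        t = self._table(np.ones(35), rng)
        out = check_heteroscedasticity(t, "m")
        assert not out["weighted"]
        assert np.isnan(out["bp_p"])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.diagnostic import het_breuschpagan
        age = rng.uniform(20, 60, 35)
        y = age * rng.normal(1, 0.5, 35)
        t = self._table(y, rng)
        t["age"] = age
        out = check_heteroscedasticity(t, "m")
        from atas.stats import encode_predictors
        X = sm.add_constant(encode_predictors(t).to_numpy())
        resid = sm.OLS(y, X).fit().resid
        lm, lm_p, _, _ = het_breuschpagan(resid, X)
        assert out["bp_lm"] == pytest.approx(lm)
        assert out["bp_p"] == pytest.approx(lm_p)


class TestOverdispersion:
    def test_negbin_counts_flagged(self, rng):
        hits = 0
        for _ in range(50):
            r = 1 / 0.15
            mu = 60.0
            y = rng.negative_binomial(r, r / (r + mu), 35)
            hits += check_overdispersion(pd.DataFrame({"c": y}), "c")["negbin"]
        assert hits >= 45

    def test_constant_counts_not_flagged(self):
        out = check_overdispersion(pd.DataFrame({"c": [7] * 20}), "c")
        assert not out["negbin"]

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            check_overdispersion(pd.DataFrame({"c": [1.5] * 20}), "c")

    def test_all_zero_missing(self):
        out = check_overdispersion(pd.DataFrame({"c": [0] * 20}), "c")
        assert np.isnan(out["dispersion"])


# ---------------------------------------------------------------------------
# model plan
# ---------------------------------------------------------------------------

class TestBuildModelPlan:
    def _narrative_inputs(self):
        """Assumption-check outcomes matching the published narrative."""
        norm = pd.DataFrame([
            # non-normal: pause time (log not fixed), mean pause (log fixed),
            # long pause CV (log not fixed); everything else normal
            {"metric": m,
             "shapiro_p": 0.01 if m in ("total_pause_time_s", "mean_pause_ms",
                                        "long_pause_cv") else 0.5,
             "log_transform": m in ("total_pause_time_s", "mean_pause_ms",
                                    "long_pause_cv"),
             "shapiro_p_log": 0.3 if m == "mean_pause_ms" else 0.01,
             "log_fixed": m == "mean_pause_ms"}
            for m in ["speech_rate_wpm", "total_pause_time_s", "mean_pause_ms",
                      "mean_vocal_ms", "pause_cv", "vocal_cv",
                      "mean_long_pause_ms", "mean_short_pause_ms",
                      "long_pause_cv", "short_pause_cv"]])
        het = {m: {"weighted": m in ("speech_rate_wpm", "total_pause_time_s",
                                     "long_pause_cv")}
               for m in norm["metric"]}
        over = {m: {"negbin": True}
                for m in ("pause_count", "long_pause_count", "short_pause_count")}
        return norm, het, over

    def test_reproduces_published_assignment(self):
        plan = build_model_plan(*self._narrative_inputs())
        e = plan.entries
        assert (e["speech_rate_wpm"].family, e["speech_rate_wpm"].weighted) == \
            (GAUSSIAN, True)
        assert (e["total_pause_time_s"].family, e["total_pause_time_s"].weighted) == \
            (GAMMA, True)
        assert (e["long_pause_cv"].family, e["long_pause_cv"].weighted) == \
            (GAMMA, True)
        assert e["mean_pause_ms"].family == GAUSSIAN
        assert e["mean_pause_ms"].log_transform
        for m in ("pause_count", "long_pause_count", "short_pause_count"):
            assert e[m].family == NEGATIVE_BINOMIAL
        for m in ("mean_vocal_ms", "pause_cv", "vocal_cv", "mean_long_pause_ms",
                  "mean_short_pause_ms", "short_pause_cv"):
            assert e[m].family == GAUSSIAN and not e[m].log_transform

    def test_all_clean_gives_all_gaussian(self):
        norm, het, over = self._narrative_inputs()
        norm["log_transform"] = False
        het = {m: {"weighted": False} for m in het}
        over = {m: {"negbin": False} for m in over}
        plan = build_model_plan(norm, het, over)
        assert all(v.family == GAUSSIAN for v in plan.entries.values())


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------

class TestFitGroupModels:
    def test_gaussian_identity_equals_ols(self):
        table = _cohort(seed=4)
        plan = ModelPlan(entries={"speech_rate_wpm": PlanEntry()})
        res = fit_group_models(table, plan)[0]
        from atas.stats import encode_predictors
        X = sm.add_constant(encode_predictors(table).to_numpy())
        y = table["speech_rate_wpm"].to_numpy()
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res.table["B"].to_numpy(), ols.params, atol=1e-8)

    def test_group_recovery_speech_rate(self, rng):
        """Generating shift -35.52 wpm recovered across replicates."""
        bs = []
        for i in range(60):
            table = _cohort(seed=1000 + i)
            plan = ModelPlan(entries={"speech_rate_wpm": PlanEntry()})
            bs.append(fit_group_models(table, plan)[0].b_for("Group"))
        se = np.std(bs, ddof=1) / np.sqrt(len(bs))
        assert abs(np.mean(bs) - (-35.52)) < 3 * se + 0.5

    def test_negbin_alpha_recovered(self, rng):
        alphas = []
        for i in range(30):
            table = _cohort(seed=2000 + i)
            plan = ModelPlan(entries={
                "long_pause_count": PlanEntry(family=NEGATIVE_BINOMIAL)})
            res = fit_group_models(table, plan)[0]
            assert res.alpha is not None and res.alpha > 0
            alphas.append(res.alpha)
        se = np.std(alphas, ddof=1) / np.sqrt(len(alphas))
        assert abs(np.mean(alphas) - 0.18) < 3 * se + 0.05

    def test_negbin_approaches_poisson_at_tiny_alpha(self, rng):
        n = 500
        age = rng.uniform(20, 60, n)
        group = rng.integers(0, 2, n)
        mu = np.exp(3.0 + 0.4 * group + 0.002 * age)
        y = rng.poisson(mu)  # alpha -> 0 limit
        table = pd.DataFrame({
            "group": np.where(group == 1, "AWS", "AWNS"),
            "sex": rng.choice(["male", "female"], n), "age": age, "c": y})
        plan = ModelPlan(entries={"c": PlanEntry(family=NEGATIVE_BINOMIAL)})
        res = fit_group_models(table, plan)[0]
        from atas.stats import encode_predictors
        X = sm.add_constant(encode_predictors(table).to_numpy())
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(res.table["B"].to_numpy(), pois.params, atol=1e-2)

    def test_group_relabeling_flips_sign(self):
        table = _cohort(seed=6)
        plan = ModelPlan(entries={"speech_rate_wpm": PlanEntry()})
        res = fit_group_models(table, plan)[0]
        flipped = table.copy()
        flipped["group"] = np.where(flipped["group"] == "AWS", "AWNS", "AWS")
        res2 = fit_group_models(flipped, plan)[0]
        assert res2.b_for("Group") == pytest.approx(-res.b_for("Group"))
        assert res2.b_for("Age") == pytest.approx(res.b_for("Age"))

    def test_gamma_with_nonpositive_falls_back(self):
        table = _cohort(seed=7).copy()
        table.loc[table.index[0], "total_pause_time_s"] = -1.0
        plan = ModelPlan(entries={"total_pause_time_s": PlanEntry(family=GAMMA)})
        with pytest.warns(UserWarning):
            res = fit_group_models(table, plan)[0]
        assert res.converged


# ---------------------------------------------------------------------------
# FDR and correlations
# ---------------------------------------------------------------------------

def brute_force_bh(p, q):
    """Step-up BH straight from the definition."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    adj = np.empty(m)
    for idx in range(m):
        rank = np.flatnonzero(order == idx)[0] + 1
        candidates = [m * p[order[j - 1]] / j for j in range(rank, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return reject, adj


class TestAdjustFdr:
    def test_worked_examples(self):
        reject, _ = adjust_fdr([0.01, 0.02, 0.03, 0.04], q=0.1)
        assert reject.all()
        reject, _ = adjust_fdr([1.0, 1.0, 1.0], q=0.1)
        assert not reject.any()
        reject, _ = adjust_fdr([0.05], q=0.1)
        assert reject.all()

    def test_empty(self):
        reject, adj = adjust_fdr([], q=0.1)
        assert reject.size == 0 and adj.size == 0

    def test_matches_brute_force_exhaustively(self):
        grid = [0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 1.0]
        for m in range(1, 6):
            for combo in itertools.product(grid, repeat=m):
                p = np.array(combo)
                r1, a1 = adjust_fdr(p, q=0.1)
                r2, a2 = brute_force_bh(p, 0.1)
                np.testing.assert_array_equal(r1, r2)
                np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_matches_brute_force_random_m10(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, 10)
            r1, a1 = adjust_fdr(p, q=0.1)
            r2, a2 = brute_force_bh(p, 0.1)
            np.testing.assert_array_equal(r1, r2)
            np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(0, 1, 13)
        r1, a1 = adjust_fdr(p, q=0.1)
        r2, a2, _, _ = multipletests(p, alpha=0.1, method="fdr_bh")
        np.testing.assert_array_equal(r1, r2)
        np.testing.assert_allclose(a1, a2)


class TestCorrelateWithSS:
    def _table(self, x, ss, group="AWS"):
        n = len(x)
        t = pd.DataFrame({c: np.nan for c in
                          ["speech_rate_wpm"]}, index=range(n))
        t["speech_rate_wpm"] = x
        t["group"] = group
        t["percent_ss"] = ss
        return t

    def test_perfect_negative(self):
        x = np.arange(10.0)
        out = correlate_with_ss(self._table(x, 50 - x),
                                metrics=["speech_rate_wpm"])
        row = out[out.subset == "aws"].iloc[0]
        assert row["r"] == pytest.approx(-1.0)

    def test_null_mean_near_zero(self, rng):
        rs = []
        for _ in range(100):
            out = correlate_with_ss(
                self._table(rng.normal(size=35), rng.uniform(0, 10, 35)),
                metrics=["speech_rate_wpm"])
            rs.append(out[out.subset == "all"].iloc[0]["r"])
        assert abs(np.mean(rs)) < 0.06

    def test_recovery_rho_086(self, rng):
        rho, n = 0.86, 35
        rs = []
        for _ in range(100):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
            out = correlate_with_ss(self._table(z[:, 0], 5 + z[:, 1]),
                                    metrics=["speech_rate_wpm"])
            rs.append(out[out.subset == "all"].iloc[0]["r"])
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs) - rho) < 3 * se + 0.01

    def test_constant_column_missing(self):
        out = correlate_with_ss(self._table(np.ones(10), np.arange(10.0)),
                                metrics=["speech_rate_wpm"])
        assert out["r"].isna().all()
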