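"""Group-comparison statistics for cohort metric tables.

The procedure mirrors standard GLM practice for small two-group cohorts:

* assumption checks — multicollinearity (VIF), normality (Shapiro-Wilk, with
  a log-transform retest for positive non-normal metrics), homoscedasticity
  (Breusch-Pagan) and count overdispersion (Pearson dispersion plus the
  Cameron-Trivedi auxiliary regression) — drive a per-metric model plan;
* each metric is then fit with intercept + group + sex + age, using a
  Gaussian GLM (optionally weighted and/or on the log scale), a weighted
  gamma GLM with log link, or an NB2 negative binomial whose dispersion
  alpha is estimated alongside the coefficients;
* p-values for the group effect are corrected with the Benjamini-Hochberg
  step-up procedure at FDR q = 0.1;
* every metric is correlated (Pearson) with percent syllables stuttered.

Reference levels: group AWNS, sex female — the group coefficient is the
AWS-minus-AWNS difference.

"Weighted" fits use inverse-fitted-variance weights from a one-pass auxiliary
log-linear regression of squared OLS residuals on the predictors; this is the
textbook remedy matching a Breusch-Pagan diagnosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .metrics import METRIC_COLUMNS

COUNT_METRICS = ["pause_count", "long_pause_count", "short_pause_count"]
CONTINUOUS_METRICS = [m for m in METRIC_COLUMNS if m not in COUNT_METRICS]

GAUSSIAN = "gaussian"
GAMMA = "gamma"
NEGATIVE_BINOMIAL = "negative_binomial"

DEFAULT_PREDICTORS = ("group", "sex", "age")

_MIN_VALID = 8  # fewer complete rows than this and a GLM fit is meaningless


def encode_predictors(table: pd.DataFrame,
                      predictors=DEFAULT_PREDICTORS) -> pd.DataFrame:
    """Numeric design columns: group AWS=1/AWNS=0, sex male=1/female=0, age as-is."""
    out = pd.DataFrame(index=table.index)
    for p in predictors:
        if p == "group":
            out[p] = (table["group"].astype(str) == "AWS").astype(float)
        elif p == "sex":
            out[p] = (table["sex"].astype(str) == "male").astype(float)
        else:
            out[p] = pd.to_numeric(table[p], errors="coerce")
    return out


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def check_multicollinearity(table: pd.DataFrame,
                            predictors=DEFAULT_PREDICTORS,
                            vif_threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factor per predictor: VIF_j = 1 / (1 - R^2_j)."""
    X = encode_predictors(table, predictors).dropna()
    if len(X) < len(predictors) + 2:
        raise ValueError("too few complete rows for a VIF check")
    rows = []
    for j, p in enumerate(predictors):
        others = [q for q in predictors if q != p]
        design = sm.add_constant(X[others].to_numpy()) if others else np.ones((len(X), 1))
        r2 = sm.OLS(X[p].to_numpy(), design).fit().rsquared
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"predictor": p, "vif": vif, "flagged": bool(vif >= vif_threshold)})
    return pd.DataFrame(rows)


def assess_distributions(table: pd.DataFrame, metrics=None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk normality per metric, with a log-transform recommendation.

    A log transform is recommended when normality is rejected and all values
    are positive; the transformed values are re-tested and both p-values are
    reported. ``log_fixed`` records whether the transform restored normality.
    """
    metrics = list(metrics) if metrics is not None else CONTINUOUS_METRICS
    rows = []
    for m in metrics:
        x = pd.to_numeric(table[m], errors="coerce").dropna().to_numpy()
        rec = {"metric": m, "shapiro_p": np.nan, "log_transform": False,
               "shapiro_p_log": np.nan, "log_fixed": False}
        if x.size >= 3 and np.ptp(x) > 0:
            rec["shapiro_p"] = sps.shapiro(x).pvalue
            if rec["shapiro_p"] < alpha:
                if np.all(x > 0):
                    rec["log_transform"] = True
                    rec["shapiro_p_log"] = sps.shapiro(np.log(x)).pvalue
                    rec["log_fixed"] = bool(rec["shapiro_p_log"] >= alpha)
                else:
                    warnings.warn(
                        f"{m}: log transform withheld (non-positive values)")
        rows.append(rec)
    return pd.DataFrame(rows)


def check_heteroscedasticity(table: pd.DataFrame, metric: str,
                             predictors=DEFAULT_PREDICTORS,
                             alpha: float = 0.05) -> dict:
    """Breusch-Pagan LM test on the OLS residuals of ``metric ~ predictors``.

    The LM statistic is n * R^2 of the auxiliary regression of squared
    residuals on the predictors, referred to chi-square with p degrees of
    freedom. A significant result flags the metric for weighted fitting.
    """
    X = encode_predictors(table, predictors)
    y = pd.to_numeric(table[metric], errors="coerce")
    ok = X.notna().all(axis=1) & y.notna()
    X, y = X[ok].to_numpy(), y[ok].to_numpy()
    out = {"metric": metric, "bp_lm": np.nan, "bp_p": np.nan, "weighted": False}
    if len(y) < len(DEFAULT_PREDICTORS) + 3 or np.ptp(y) == 0:
        return out
    design = sm.add_constant(X)
    resid = sm.OLS(y, design).fit().resid
    aux = sm.OLS(resid**2, design).fit()
    lm = len(y) * aux.rsquared
    p = sps.chi2.sf(lm, X.shape[1])
    out.update(bp_lm=float(lm), bp_p=float(p), weighted=bool(p < alpha))
    return out


def check_overdispersion(table: pd.DataFrame, count_metric: str,
                         alpha: float = 0.05) -> dict:
    """Overdispersion check for a count metric.

    Fits a Poisson GLM (intercept only is enough for the marginal check used
    here: intercept + group + sex + age when available), computes the Pearson
    dispersion (chi-square / df), and runs the Cameron-Trivedi auxiliary
    regression of ((y - mu)^2 - y) / mu on mu without intercept; a one-sided
    significant positive slope plus dispersion > 1 flags the negative
    binomial family. The slope is itself a method-of-moments estimate of the
    NB2 dispersion alpha.
    """
    y = pd.to_numeric(table[count_metric], errors="coerce").dropna()
    out = {"metric": count_metric, "dispersion": np.nan, "aux_p": np.nan,
           "alpha_mom": np.nan, "negbin": False}
    yv = y.to_numpy(dtype=float)
    if yv.size < 5 or np.all(yv == 0):
        return out
    if np.any(yv < 0) or np.any(yv != np.round(yv)):
        raise ValueError(f"{count_metric} is not a nonnegative integer metric")
    cols = [c for c in DEFAULT_PREDICTORS if c in table.columns]
    X = encode_predictors(table.loc[y.index], cols) if cols else None
    design = sm.add_constant(X.to_numpy()) if X is not None and X.notna().all().all() \
        else np.ones((yv.size, 1))
    try:
        fit = sm.GLM(yv, design, family=sm.families.Poisson()).fit()
    except Exception:
        return out
    mu = fit.fittedvalues
    dispersion = float(fit.pearson_chi2 / fit.df_resid)
    z = ((yv - mu) ** 2 - yv) / mu
    aux = sm.OLS(z, mu).fit()
    slope, t = float(aux.params[0]), float(aux.tvalues[0])
    p_one_sided = float(sps.t.sf(t, df=yv.size - 1))
    out.update(dispersion=dispersion, aux_p=p_one_sided, alpha_mom=slope,
               negbin=bool(dispersion > 1.0 and p_one_sided < alpha))
    return out


# ---------------------------------------------------------------------------
# model plan and fitting
# ---------------------------------------------------------------------------

@dataclass
class PlanEntry:
    family: str = GAUSSIAN
    weighted: bool = False
    log_transform: bool = False
    link: str = "identity"


@dataclass
class ModelPlan:
    entries: dict[str, PlanEntry] = field(default_factory=dict)

    def label(self, metric: str) -> str:
        e = self.entries[metric]
        if e.family == NEGATIVE_BINOMIAL:
            return "Negative binomial"
        name = "gamma GLM" if e.family == GAMMA else "GLM Gaussian"
        if e.weighted:
            name = "Weighted " + name
        if e.log_transform:
            name += " (log scale)"
        return name


def build_model_plan(normality: pd.DataFrame,
                     heteroscedasticity: dict[str, dict],
                     overdispersion: dict[str, dict]) -> ModelPlan:
    """Turn assumption-check results into a per-metric model family plan.

    Continuous metrics default to a Gaussian GLM; heteroscedasticity adds
    weights; a metric that is non-normal but fixed by the log transform is
    modeled as Gaussian on the log scale; non-normal, positive and *not*
    fixed by the log transform selects the gamma family with log link.
    Count metrics get the negative binomial (log link) when overdispersed,
    otherwise Gaussian.
    """
    plan = ModelPlan()
    norm = normality.set_index("metric")
    for m in CONTINUOUS_METRICS:
        entry = PlanEntry()
        het = heteroscedasticity.get(m, {})
        entry.weighted = bool(het.get("weighted", False))
        if m in norm.index and bool(norm.loc[m, "log_transform"]):
            if bool(norm.loc[m, "log_fixed"]):
                entry.log_transform = True
            else:
                entry.family = GAMMA
                entry.link = "log"
        plan.entries[m] = entry
    for m in COUNT_METRICS:
        od = overdispersion.get(m, {})
        if bool(od.get("negbin", False)):
            plan.entries[m] = PlanEntry(family=NEGATIVE_BINOMIAL, link="log")
        else:
            plan.entries[m] = PlanEntry(family=GAUSSIAN)
    return plan


@dataclass
class ModelResult:
    metric: str
    model: str
    table: pd.DataFrame  # rows: predictor, B, SE, z, p
    alpha: float | None = None
    alpha_se: float | None = None
    converged: bool = True
    error: str | None = None

    def p_for(self, predictor: str) -> float:
        row = self.table[self.table["predictor"] == predictor]
        return float(row["p"].iloc[0]) if len(row) else float("nan")

    def b_for(self, predictor: str) -> float:
        row = self.table[self.table["predictor"] == predictor]
        return float(row["B"].iloc[0]) if len(row) else float("nan")


def _hetero_weights(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Inverse-fitted-variance weights from a log-linear aux regression."""
    resid = sm.OLS(y, design).fit().resid
    log_r2 = np.log(resid**2 + 1e-12)
    fitted = sm.OLS(log_r2, design).fit().fittedvalues
    w = 1.0 / np.exp(fitted)
    return w / w.mean()


def fit_group_models(table: pd.DataFrame, plan: ModelPlan,
                     predictors=DEFAULT_PREDICTORS) -> list[ModelResult]:
    """Fit the planned GLM for every metric in the plan.

    Rows with a missing metric value are dropped listwise per metric.
    Non-convergence or degenerate data is recorded on the result, not fatal.
    """
    results = []
    names = ["Intercept", *[p.capitalize() for p in predictors]]
    for metric, entry in plan.entries.items():
        y = pd.to_numeric(table[metric], errors="coerce")
        X = encode_predictors(table, predictors)
        ok = y.notna() & X.notna().all(axis=1)
        yv, Xv = y[ok].to_numpy(dtype=float), X[ok].to_numpy()
        label = plan.label(metric)
        if len(yv) < _MIN_VALID:
            results.append(ModelResult(metric, label, pd.DataFrame(
                columns=["predictor", "B", "SE", "z", "p"]),
                converged=False, error="too few complete rows"))
            continue
        design = sm.add_constant(Xv)
        try:
            res = _fit_one(yv, design, entry)
        except Exception as exc:
            results.append(ModelResult(metric, label, pd.DataFrame(
                columns=["predictor", "B", "SE", "z", "p"]),
                converged=False, error=str(exc)))
            continue
        k = len(names)
        tab = pd.DataFrame({
            "predictor": names,
            "B": np.asarray(res.params)[:k],
            "SE": np.asarray(res.bse)[:k],
            "z": np.asarray(res.tvalues)[:k],
            "p": np.asarray(res.pvalues)[:k],
        })
        alpha = alpha_se = None
        if entry.family == NEGATIVE_BINOMIAL:
            alpha = float(np.asarray(res.params)[-1])
            alpha_se = float(np.asarray(res.bse)[-1])
        results.append(ModelResult(metric, label, tab, alpha=alpha,
                                   alpha_se=alpha_se,
                                   converged=bool(getattr(res, "converged", True))))
    return results


def _fit_one(y: np.ndarray, design: np.ndarray, entry: PlanEntry):
    if entry.family == NEGATIVE_BINOMIAL:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.NegativeBinomial(y, design).fit(disp=False, maxiter=200)
    if entry.family == GAMMA:
        if np.any(y <= 0):  # domain violation: fall back per plan contract
            warnings.warn("gamma family with non-positive values; using Gaussian")
            entry = PlanEntry(family=GAUSSIAN, weighted=entry.weighted)
        else:
            w = _hetero_weights(np.log(y), design) if entry.weighted else None
            fam = sm.families.Gamma(link=sm.families.links.Log())
            kw = {"var_weights": w} if w is not None else {}
            return sm.GLM(y, design, family=fam, **kw).fit()
    yv = np.log(y) if entry.log_transform else y
    w = _hetero_weights(yv, design) if entry.weighted else None
    kw = {"var_weights": w} if w is not None else {}
    return sm.GLM(yv, design, family=sm.families.Gaussian(), **kw).fit()


# ---------------------------------------------------------------------------
# multiple testing and correlations
# ---------------------------------------------------------------------------

def adjust_fdr(p_values, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values). Adjusted p-values are
    min_{j >= i} m * p_(j) / j, capped at 1 and monotone.
    """
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    reject_sorted = np.zeros(m, dtype=bool)
    below = np.flatnonzero(ranked <= np.arange(1, m + 1) * q / m)
    if below.size:
        reject_sorted[: below[-1] + 1] = True
    reject = np.empty(m, dtype=bool)
    p_adj = np.empty(m)
    reject[order] = reject_sorted
    p_adj[order] = adj
    return reject, p_adj


def correlate_with_ss(table: pd.DataFrame, metrics=None,
                      subsets=("all", "aws")) -> pd.DataFrame:
    """Pearson correlation of every metric with percent syllables stuttered.

    Computed over all rows with %SS defined and, separately, over AWS rows
    only — which rows enter the published battery is ambiguous, so both
    variants are reported and labeled.
    """
    metrics = list(metrics) if metrics is not None else METRIC_COLUMNS
    rows = []
    for subset in subsets:
        sub = table if subset == "all" else table[table["group"] == "AWS"]
        ss = pd.to_numeric(sub["percent_ss"], errors="coerce")
        for m in metrics:
            x = pd.to_numeric(sub[m], errors="coerce")
            ok = ss.notna() & x.notna()
            rec = {"subset": subset, "metric": m, "n": int(ok.sum()),
                   "r": np.nan, "p": np.nan}
            if ok.sum() >= 3 and np.ptp(x[ok]) > 0 and np.ptp(ss[ok]) > 0:
                r, pv = sps.pearsonr(x[ok], ss[ok])
                rec.update(r=float(r), p=float(pv))
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

def compare_groups(table: pd.DataFrame, q: float = 0.1,
                   predictors=DEFAULT_PREDICTORS) -> dict:
    """Full statistical battery on a cohort table.

    Returns a dict with ``vif``, ``normality``, ``heteroscedasticity``,
    ``overdispersion``, ``plan``, ``models`` (list of ModelResult),
    ``results`` (tidy per-predictor table with BH-adjusted group p-values)
    and ``correlations``.
    """
    vif = check_multicollinearity(table, predictors)
    norm = assess_distributions(table)
    het = {m: check_heteroscedasticity(table, m, predictors)
           for m in CONTINUOUS_METRICS}
    over = {m: check_overdispersion(table, m) for m in COUNT_METRICS}
    plan = build_model_plan(norm, het, over)
    models = fit_group_models(table, plan, predictors)

    tidy = []
    for res in models:
        for _, row in res.table.iterrows():
            tidy.append({"metric": res.metric, "model": res.model, **row})
        if res.alpha is not None:
            z = res.alpha / res.alpha_se if res.alpha_se else np.nan
            tidy.append({"metric": res.metric, "model": res.model,
                         "predictor": "Dispersion (alpha)", "B": res.alpha,
                         "SE": res.alpha_se, "z": z,
                         "p": 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan})
    tidy = pd.DataFrame(tidy)

    group_rows = tidy["predictor"] == "Group"
    gp = tidy.loc[group_rows, "p"].to_numpy()
    valid = np.isfinite(gp)
    reject = np.zeros(gp.size, dtype=bool)
    p_adj = np.full(gp.size, np.nan)
    if valid.any():
        reject[valid], p_adj[valid] = adjust_fdr(gp[valid], q=q)
    tidy.loc[group_rows, "p_adjusted"] = p_adj
    tidy.loc[group_rows, "significant"] = reject

    corr = correlate_with_ss(table) if "percent_ss" in table.columns else pd.DataFrame()
    return {"vif": vif, "normality": norm, "heteroscedasticity": het,
            "overdispersion": over, "plan": plan, "models": models,
            "results": tidy, "correlations": corr}
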