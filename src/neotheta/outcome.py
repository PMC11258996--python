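"""Longitudinal prediction analysis: path models, diagnostics, outliers.

The "path analysis" is the set of separate OLS regressions relating the
neural discrimination measure at birth to receptive (words understood)
and expressive (words produced) vocabulary at 12 and 18 months, plus
the 12→18-month vocabulary models:

    1: comp12 ~ discrimination     4: prod18 ~ discrimination
    2: prod12 ~ discrimination     5: comp18 ~ comp12 + prod12
    3: comp18 ~ discrimination     6: prod18 ~ comp12 + prod12

Each model is fitted on its own listwise-complete subsample (attrition
differs by age, so n varies per model).  Significance is judged against
a Bonferroni-adjusted alpha (two comparisons per hypothesis).  Residuals
are screened with White and Breusch–Pagan heteroskedasticity tests;
influential cases are flagged by leverage greater than twice the
average, removed, and the 18-month models refitted (3', 4'); models 5'
and 6' drop the predictors that did not survive the adjusted alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

logger = logging.getLogger(__name__)

VOCAB_COLUMNS = ("comp12", "prod12", "comp18", "prod18")

MODEL_SPECS = {
    "1": ("comp12", ("discrimination_0m",)),
    "2": ("prod12", ("discrimination_0m",)),
    "3": ("comp18", ("discrimination_0m",)),
    "4": ("prod18", ("discrimination_0m",)),
    "5": ("comp18", ("comp12", "prod12")),
    "6": ("prod18", ("comp12", "prod12")),
}

P_FLOOR = 1e-300  # sentinel for p-values that underflow (e.g. y == x)


@dataclass
class RegressionReport:
    """Fitted-model summary mirroring a regression table row.

    ``beta`` holds standardized coefficients (predictor and outcome
    z-scored), so in a single-predictor model |beta| equals the
    multiple correlation R.  Diagnostics are attached lazily by the
    dedicated functions.
    """

    model_id: str
    dependent: str
    independents: tuple
    n: int
    beta: dict
    coef: dict
    R: float
    r_square: float
    df_model: int
    df_resid: int
    F: float
    p_model: float
    p_coef: dict
    diagnostics: dict = field(default_factory=dict)
    _results: object = field(default=None, repr=False)
    _data: pd.DataFrame = field(default=None, repr=False)

    def row(self):
        return {
            "model": self.model_id, "dependent": self.dependent,
            "R": self.R, "r_square": self.r_square, "df": self.df_model,
            "F": self.F, "p": self.p_model,
            "independents": "; ".join(self.independents),
            "beta": "; ".join(f"{self.beta[x]:.3f}" for x in self.independents),
            "p_coef": "; ".join(f"{self.p_coef[x]:.3f}"
                                for x in self.independents),
            "n": self.n,
        }


def remove_vocab_outliers(tbl: pd.DataFrame, column="prod12", z=3.0):
    """Drop cases whose ``column`` value lies above mean + z·SD.

    One-sided by design (the screened direction is implausibly *large*
    expressive vocabulary); the group statistics include the candidate
    case, and the bound is strict (a value exactly at mean + z·SD is
    kept).  With small n a gross outlier inflates the SD enough to mask
    itself — that masking is the documented behaviour of the rule, not
    a defect.  Returns ``(screened_table, removed_ids)``.
    """
    vals = tbl[column].dropna()
    if len(vals) < 3:
        raise ValueError("need at least 3 non-missing values to screen")
    bound = vals.mean() + z * vals.std(ddof=1)
    bad = tbl.index[tbl[column] > bound]
    if len(bad):
        logger.info("outlier screen on %s: removed %s (bound %.2f)",
                    column, list(tbl.loc[bad, "participant_id"]), bound)
    return tbl.drop(index=bad), list(tbl.loc[bad, "participant_id"])


def fit_linear_model(tbl: pd.DataFrame, dependent, independents,
                     model_id=None) -> RegressionReport:
    """OLS with intercept on the listwise-complete subsample.

    Reports standardized betas (b·sd(x)/sd(y)), multiple correlation R,
    R², the model F test and per-predictor two-tailed t p-values.
    Rank-deficient designs raise with the offending columns named.
    """
    independents = tuple(independents)
    cols = [dependent, *independents]
    sub = tbl.loc[:, cols].dropna()
    n, k = len(sub), len(independents)
    if n <= k + 1:
        raise ValueError(f"model {model_id}: n={n} too small for "
                         f"{k} predictor(s)")
    X = sm.add_constant(sub[list(independents)].astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"model {model_id}: collinear design columns "
                         f"{list(independents)}")
    res = sm.OLS(sub[dependent].astype(float), X).fit()
    sd_y = sub[dependent].std(ddof=1)
    beta = {x: float(res.params[x] * sub[x].std(ddof=1) / sd_y)
            for x in independents}
    r2 = float(res.rsquared)
    report = RegressionReport(
        model_id=model_id or "", dependent=dependent,
        independents=independents, n=n, beta=beta,
        coef={x: float(res.params[x]) for x in independents},
        R=float(np.sqrt(max(r2, 0.0))), r_square=r2,
        df_model=int(res.df_model), df_resid=int(res.df_resid),
        F=float(res.fvalue), p_model=float(max(res.f_pvalue, P_FLOOR)),
        p_coef={x: float(max(res.pvalues[x], P_FLOOR)) for x in independents},
        _results=res, _data=sub,
    )
    return report


def f_from_r(r, n, k=1):
    """Model F statistic implied by a (printed) multiple correlation R."""
    r2 = r * r
    df2 = n - k - 1
    return (r2 / k) / ((1.0 - r2) / df2)


def p_from_f(F, k, df2):
    """Right-tail p of the model F test on (k, df2) degrees of freedom."""
    return float(stats.f.sf(F, k, df2))


def p_from_r(r, n):
    """Two-tailed p of a Pearson correlation via t = r·√((n−2)/(1−r²))."""
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def bonferroni(alpha=0.05, m=2):
    """Bonferroni-adjusted alpha: α/m (0.05 over 2 comparisons → 0.025)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _lm_het_test(resid, aux, variant="lm"):
    """Lagrange-multiplier heteroskedasticity test on squared residuals.

    ``variant="lm"`` is the n·R² statistic from the auxiliary regression
    of e² on the given regressors; ``variant="ess"`` is the
    normality-assuming ESS/2 form on e²/mean(e²).  Degenerate (constant)
    residuals give (0, 1).
    """
    resid = np.asarray(resid, dtype=float)
    e2 = resid ** 2
    n = len(e2)
    df = aux.shape[1]
    if np.allclose(e2, e2[0]):
        return 0.0, 1.0
    Xa = sm.add_constant(np.asarray(aux, dtype=float))
    if variant == "lm":
        fit = sm.OLS(e2, Xa).fit()
        stat = n * fit.rsquared
    elif variant == "ess":
        g = e2 / e2.mean()
        fit = sm.OLS(g, Xa).fit()
        stat = fit.ess / 2.0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(stat), float(stats.chi2.sf(stat, df))


def breusch_pagan(report: RegressionReport, variant="lm"):
    """Breusch–Pagan test: auxiliary regressors = the model's predictors.

    Default statistic is n·R² of the auxiliary fit, referred to χ² with
    one degree of freedom per predictor; ``variant="ess"`` switches to
    the classical normality-based ESS/2 form.
    """
    aux = report._data[list(report.independents)].to_numpy(dtype=float)
    return _lm_het_test(report._results.resid, aux, variant=variant)


def white_test(report: RegressionReport):
    """White test: predictors plus their squares and pairwise products.

    For a single-predictor model the auxiliary set is {x, x²} (df = 2);
    restricted to {x} alone it reduces to the Breusch–Pagan test.
    """
    X = report._data[list(report.independents)].to_numpy(dtype=float)
    cols = [X]
    cols.append(X ** 2)
    k = X.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            cols.append((X[:, i] * X[:, j])[:, None])
    aux = np.column_stack(cols)
    # drop duplicate columns (e.g. an indicator equal to its square)
    _, keep = np.unique(np.round(aux, 12), axis=1, return_index=True)
    aux = aux[:, np.sort(keep)]
    return _lm_het_test(report._results.resid, aux)


def influence_diagnostics(report: RegressionReport, leverage_factor=2.0):
    """Leverage (hat diagonal) and Cook's distance, with influential ids.

    Influential iff leverage strictly exceeds ``leverage_factor`` times
    the average leverage (k+1)/n — the operative removal rule.  Cook's
    distance is reported for every case but not used for removal.
    """
    infl = OLSInfluence(report._results)
    lev = np.asarray(infl.hat_matrix_diag, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cooks = np.asarray(infl.cooks_distance[0], dtype=float)
    if np.any(lev >= 1.0 - 1e-12):
        logger.warning("leverage of 1 encountered; Cook's distance undefined")
        cooks = np.where(lev >= 1.0 - 1e-12, np.nan, cooks)
    mean_lev = (report.df_model + 1) / report.n
    flag = lev > leverage_factor * mean_lev
    ids = list(report._data.index[flag])
    diag = {
        "leverage": lev, "cooks_d": cooks, "mean_leverage": mean_lev,
        "influential_index": ids,
    }
    report.diagnostics["influence"] = diag
    return diag


def refit_without_influential(tbl: pd.DataFrame, dependent, independents,
                              drop_index, model_id=None) -> RegressionReport:
    """Refit a model on the sample with the influential cases removed."""
    reduced = tbl.drop(index=[i for i in drop_index if i in tbl.index])
    report = fit_linear_model(reduced, dependent, independents,
                              model_id=model_id)
    return report


def pearson_correlation(x, y):
    """Pearson r with two-tailed p on pairwise-complete observations.

    Returns ``(r, p, n)``; zero variance in either variable yields a
    NaN sentinel with a warning.
    """
    x = pd.Series(x).astype(float)
    y = pd.Series(y).astype(float)
    ok = x.notna() & y.notna()
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    xs, ys = x[ok], y[ok]
    if xs.std(ddof=1) == 0 or ys.std(ddof=1) == 0:
        logger.warning("zero variance in correlation input")
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


@dataclass
class PathAnalysisReport:
    """Machine-readable mirror of the regression tables and path diagram."""

    alpha: float
    adjusted_alpha: float
    models: dict
    posthoc: dict
    influential_ids: list
    removed_outliers: list
    correlations: dict

    def all_models(self):
        return {**self.models, **self.posthoc}

    def table(self):
        rows = [m.row() for m in self.models.values()]
        rows += [m.row() for m in self.posthoc.values()]
        return pd.DataFrame(rows)

    def edges(self):
        """Path-diagram edge list with significance at the adjusted alpha."""
        out = []
        for m in self.all_models().values():
            for x in m.independents:
                out.append({
                    "model": m.model_id, "from": x, "to": m.dependent,
                    "beta": m.beta[x], "p": m.p_coef[x],
                    "significant": m.p_coef[x] <= self.adjusted_alpha,
                })
        for name, (r, p, n) in self.correlations.items():
            a, b = name.split("~")
            out.append({"model": name, "from": a, "to": b, "beta": r,
                        "p": p, "significant": (p == p) and
                        p <= self.adjusted_alpha})
        return out


def run_path_analysis(tbl: pd.DataFrame, alpha=0.05, m_comparisons=2,
                      outlier_column="prod12", outlier_z=3.0,
                      leverage_factor=2.0, screen_outliers=True
                      ) -> PathAnalysisReport:
    """Fit models 1–6 with diagnostics and the post-hoc 3'–6' refits.

    Listwise deletion is per model, never global, so the per-model n
    follows the attrition pattern of the cohort.  Influential cases are
    identified on models 3 and 4 (leverage > 2 × average), removed once,
    and those models refitted (3', 4'); refits never re-trigger further
    removals.  Models 5' and 6' drop the predictors whose coefficient p
    exceeded the adjusted alpha in 5 and 6.
    """
    tbl = tbl.copy()
    if "participant_id" not in tbl.columns:
        tbl["participant_id"] = [f"P{i:02d}" for i in range(len(tbl))]
    tbl = tbl.set_index("participant_id", drop=False)

    removed = []
    if screen_outliers:
        tbl, removed = remove_vocab_outliers(tbl, outlier_column, outlier_z)

    adjusted = bonferroni(alpha, m_comparisons)
    models, skipped = {}, []
    for mid, (dep, ind) in MODEL_SPECS.items():
        try:
            rep = fit_linear_model(tbl, dep, ind, model_id=mid)
        except ValueError as err:
            logger.warning("model %s skipped: %s", mid, err)
            skipped.append(mid)
            continue
        rep.diagnostics["white"] = white_test(rep)
        rep.diagnostics["breusch_pagan"] = breusch_pagan(rep)
        influence_diagnostics(rep, leverage_factor)
        models[mid] = rep

    influential = []
    for mid in ("3", "4"):
        if mid in models:
            influential.extend(models[mid].diagnostics["influence"]
                               ["influential_index"])
    influential = sorted(set(influential))

    posthoc = {}
    if influential:
        for mid in ("3", "4"):
            if mid not in models:
                continue
            dep, ind = MODEL_SPECS[mid]
            try:
                posthoc[mid + "'"] = refit_without_influential(
                    tbl, dep, ind, influential, model_id=mid + "'")
            except ValueError as err:
                logger.warning("model %s' skipped: %s", mid, err)

    for mid in ("5", "6"):
        if mid not in models:
            continue
        rep = models[mid]
        keep = [x for x in rep.independents if rep.p_coef[x] <= adjusted]
        if keep and len(keep) < len(rep.independents):
            posthoc[mid + "'"] = fit_linear_model(tbl, rep.dependent, keep,
                                                  model_id=mid + "'")

    correlations = {}
    for name, (a, b) in {"comp12~prod12": ("comp12", "prod12"),
                         "comp18~prod18": ("comp18", "prod18")}.items():
        try:
            correlations[name] = pearson_correlation(tbl[a], tbl[b])
        except ValueError as err:
            logger.warning("correlation %s skipped: %s", name, err)

    return PathAnalysisReport(alpha=alpha, adjusted_alpha=adjusted,
                              models=models, posthoc=posthoc,
                              influential_ids=influential,
                              removed_outliers=removed,
                              correlations=correlations)
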