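"""Logistic-regression machinery for tumor-response association analysis.

Associations between metagene scores, intrinsic subtype and the binary
chemotherapy-response outcome are quantified with maximum-likelihood
logistic regression: odds ratios with Wald 95% confidence intervals,
likelihood-ratio test (LRT) p-values, covariate-adjusted and stratified
models, forward-stepwise selection with a stay criterion, a chi-square
test of treatment-by-response independence, and Spearman correlation of
the metagene scores.

Continuous metagene scores enter per one log2-intensity unit of the raw
(uncentered) score; categorical covariates are expanded to indicators
against a declared reference level. All models are complete-case.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "LogisticFit",
    "StepwiseResult",
    "build_design",
    "fit_logistic",
    "lrt_pvalue",
    "univariate_response_table",
    "adjusted_response_table",
    "stratified_analysis",
    "stepwise_select",
    "chisq_independence",
    "spearman_matrix",
]

log = logging.getLogger(__name__)

IMMUNE_METAGENES = ("B/P", "T/NK", "M/D")

#: |log-odds| beyond which a coefficient is treated as diverging
#: (symptomatic of perfect separation).
_DIVERGENCE_BOUND = 15.0


class ModelError(ValueError):
    pass


@dataclass
class LogisticFit:
    """Fitted logistic model: coefficients, Wald CIs, log-likelihood."""

    terms: pd.DataFrame            # index: column name; columns coef, se
    odds_ratios: pd.DataFrame      # columns odds_ratio, ci_low, ci_high
    loglik: float
    n_used: int
    n_dropped: int
    converged: bool
    _X: pd.DataFrame = field(repr=False)
    _y: pd.Series = field(repr=False)

    def coef(self, name: str) -> float:
        return float(self.terms.loc[name, "coef"])


@dataclass
class StepwiseResult:
    selected: list[str]
    steps: pd.DataFrame            # step, action, term, p_value
    final: LogisticFit


def build_design(data: pd.DataFrame, continuous: tuple[str, ...] = (),
                 categorical: dict[str, str] | None = None
                 ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Build a numeric design matrix and a term -> columns map.

    ``categorical`` maps a column name to its reference level; each
    remaining level becomes an indicator column ``col[level]`` and the
    whole block counts as one term (entered/dropped together, as in the
    categorical-subtype models).
    """
    cols: dict[str, pd.Series] = {}
    term_map: dict[str, list[str]] = {}
    for name in continuous:
        cols[name] = pd.to_numeric(data[name], errors="coerce")
        term_map[name] = [name]
    for name, ref in (categorical or {}).items():
        values = data[name].astype("object")
        levels = [lv for lv in pd.unique(values.dropna()) if lv != ref]
        levels.sort()
        block = []
        for lv in levels:
            cname = f"{name}[{lv}]"
            ind = values.map(lambda v: np.nan if pd.isna(v) else float(v == lv))
            cols[cname] = ind
            block.append(cname)
        term_map[name] = block
    return pd.DataFrame(cols, index=data.index), term_map


def fit_logistic(design: pd.DataFrame, y: pd.Series) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald 95% CIs.

    Rows with any missing covariate or outcome are dropped (logged).
    Perfect separation is flagged as non-converged rather than raised;
    a rank-deficient design is an error naming the collinear columns.
    """
    y = pd.to_numeric(pd.Series(y, index=design.index), errors="coerce")
    frame = design.copy()
    frame["__y__"] = y
    complete = frame.dropna()
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        log.info("fit_logistic: dropped %d incomplete case(s)", n_dropped)
    yv = complete.pop("__y__")
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ModelError("outcome must be binary 0/1")
    X = sm.add_constant(complete, has_constant="add")
    if len(X) <= X.shape[1]:
        raise ModelError(f"too few complete cases (n={len(X)}) for {X.shape[1]} terms")

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise ModelError(f"singular design; collinear column(s): {bad}")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yv, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            res = sm.Logit(yv, X).fit(method="bfgs", maxiter=200, disp=0)
            converged = False
    coefs = res.params
    if np.any(np.abs(coefs.drop("const")) > _DIVERGENCE_BOUND):
        converged = False

    # numerically safe Bernoulli log-likelihood (finite even when a
    # separated fit pushed the linear predictor to extremes)
    eta = np.clip(X.to_numpy() @ coefs.to_numpy(), -500.0, 500.0)
    loglik = float(np.sum(yv.to_numpy() * eta - np.logaddexp(0.0, eta)))

    terms = pd.DataFrame({"coef": res.params, "se": res.bse})
    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        ors = pd.DataFrame({
            "odds_ratio": np.exp(terms["coef"]),
            "ci_low": np.exp(terms["coef"] - z * terms["se"]),
            "ci_high": np.exp(terms["coef"] + z * terms["se"]),
        }).drop(index="const")
    return LogisticFit(terms=terms, odds_ratios=ors, loglik=loglik,
                       n_used=int(len(X)), n_dropped=int(n_dropped),
                       converged=converged, _X=complete, _y=yv)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    keep: list[str] = []
    bad: list[str] = []
    arr = X.to_numpy()
    for j, name in enumerate(X.columns):
        trial = keep + [j]
        if np.linalg.matrix_rank(arr[:, trial]) < len(trial):
            bad.append(str(name))
        else:
            keep.append(j)
    return bad


def lrt_pvalue(full: LogisticFit, reduced: LogisticFit) -> float:
    """Likelihood-ratio p-value for nested logistic models.

    2*(llf_full - llf_reduced) referred to chi-square with df equal to
    the difference in term counts; models must be fit on the same
    samples with nested term sets.
    """
    full_terms = set(full.terms.index)
    red_terms = set(reduced.terms.index)
    if not red_terms <= full_terms:
        raise ModelError("models are not nested (reduced terms not a subset)")
    if full.n_used != reduced.n_used or not full._y.index.equals(reduced._y.index):
        raise ModelError("nested models must be fit on the same samples")
    df = len(full_terms) - len(red_terms)
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-9:
        if not (full.converged and reduced.converged):
            log.warning("LRT undefined: non-converged fit with negative "
                        "statistic (%.3g); reporting NaN", stat)
            return float("nan")
        raise ModelError(f"negative LRT statistic ({stat:.3g}); fits did not converge")
    stat = max(stat, 0.0)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))


def _term_fit_and_p(design: pd.DataFrame, y: pd.Series, drop_cols: list[str]
                    ) -> tuple[LogisticFit, float]:
    """Fit the full design and LRT-test the block ``drop_cols``."""
    full = fit_logistic(design, y)
    reduced = fit_logistic(full._X.drop(columns=drop_cols), full._y)
    return full, lrt_pvalue(full, reduced)


def _or_row(fit: LogisticFit, col: str) -> dict:
    r = fit.odds_ratios.loc[col]
    return {"odds_ratio": float(r["odds_ratio"]), "ci_low": float(r["ci_low"]),
            "ci_high": float(r["ci_high"])}


def univariate_response_table(scores: pd.DataFrame, subtype: pd.Series,
                              y: pd.Series, reference: str = "Normal-like"
                              ) -> pd.DataFrame:
    """Simple (single-covariate) response models per metagene and subtype.

    One logistic model per metagene score (continuous) and one with
    subtype as a categorical covariate against the reference level;
    reports OR, Wald 95% CI and LRT p-value per variable.
    """
    rows = []
    for m in scores.columns:
        design = scores[[m]]
        try:
            fit, p = _term_fit_and_p(design, y, [m])
        except ModelError as err:
            log.warning("univariate %s: %s", m, err)
            continue
        rows.append({"variable": m, **_or_row(fit, m), "p_value": p,
                     "n": fit.n_used, "converged": fit.converged})
    if subtype is not None:
        data = pd.DataFrame({"subtype": subtype})
        design, term_map = build_design(data, categorical={"subtype": reference})
        fit, p = _term_fit_and_p(design, y, term_map["subtype"])
        rows.append({"variable": "subtype", "odds_ratio": np.nan, "ci_low": np.nan,
                     "ci_high": np.nan, "p_value": p, "n": fit.n_used,
                     "converged": fit.converged})
        for col in term_map["subtype"]:
            level = col[col.index("[") + 1:-1]
            full = fit
            red = fit_logistic(full._X.drop(columns=[col]), full._y)
            rows.append({"variable": f"subtype:{level} vs {reference}",
                         **_or_row(full, col), "p_value": lrt_pvalue(full, red),
                         "n": full.n_used, "converged": full.converged})
    return pd.DataFrame(rows)


def adjusted_response_table(scores: pd.DataFrame, subtype: pd.Series,
                            y: pd.Series, reference: str = "Normal-like",
                            proliferation: str = "P") -> pd.DataFrame:
    """Immune-metagene response models adjusted for proliferation and subtype.

    For each immune metagene fits immune + P + subtype and reports the
    immune term's adjusted OR, CI and LRT p-value (model with vs without
    the immune term).
    """
    rows = []
    immune = [m for m in scores.columns if m in IMMUNE_METAGENES]
    for m in immune:
        data = scores[[m, proliferation]].copy()
        data["subtype"] = subtype
        design, term_map = build_design(
            data, continuous=(m, proliferation), categorical={"subtype": reference})
        fit, p = _term_fit_and_p(design, y, [m])
        rows.append({"variable": m, **_or_row(fit, m), "p_value": p,
                     "n": fit.n_used, "converged": fit.converged})
    return pd.DataFrame(rows)


def stratified_analysis(scores: pd.DataFrame, strata: pd.Series, y: pd.Series,
                        metagenes: tuple[str, ...] = IMMUNE_METAGENES,
                        min_cases: int = 10) -> pd.DataFrame:
    """Per-stratum simple response models for the immune metagenes.

    ``strata`` (tertile or subtype labels) must be computed on the full
    scored cohort; within each stratum the models use the
    outcome-annotated subset. A stratum with fewer than ``min_cases``
    annotated cases is reported with its counts but its models are
    skipped (noted in the ``skipped`` column).
    """
    y = pd.to_numeric(pd.Series(y, index=scores.index), errors="coerce")
    rows = []
    for stratum in pd.unique(strata.dropna()):
        members = strata.index[strata == stratum]
        ys = y.loc[members].dropna()
        n, pr = int(len(ys)), int((ys == 1).sum())
        nr = n - pr
        if n < min_cases:
            log.warning("stratum %s: only %d annotated case(s); models skipped", stratum, n)
            rows.append({"stratum": stratum, "n": n, "pr": pr, "nr": nr,
                         "variable": None, "odds_ratio": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan, "converged": False,
                         "skipped": True})
            continue
        for m in metagenes:
            fit, p = _term_fit_and_p(scores.loc[members, [m]], y.loc[members], [m])
            rows.append({"stratum": stratum, "n": n, "pr": pr, "nr": nr,
                         "variable": m, **_or_row(fit, m), "p_value": p,
                         "converged": fit.converged, "skipped": False})
    return pd.DataFrame(rows)


def stepwise_select(design: pd.DataFrame, term_map: dict[str, list[str]],
                    y: pd.Series, alpha_enter: float = 0.05,
                    alpha_stay: float = 0.05) -> StepwiseResult:
    """Forward-stepwise logistic selection with a stay criterion.

    At each step the candidate term with the smallest LRT p-value below
    ``alpha_enter`` joins the model (ties broken lexicographically by
    term name); any included term whose LRT p-value then exceeds
    ``alpha_stay`` is removed. Complete cases over all candidate columns
    are used throughout so every nested comparison shares one sample set.
    Terminates (a term removed immediately after entering stops the
    loop); an empty selection is a valid result.
    """
    frame = design.copy()
    frame["__y__"] = pd.to_numeric(pd.Series(y, index=design.index), errors="coerce")
    complete = frame.dropna()
    yv = complete.pop("__y__")

    selected: list[str] = []
    steps = []
    step_no = 0

    def model_fit(terms: list[str]) -> LogisticFit:
        cols = [c for t in terms for c in term_map[t]]
        return fit_logistic(complete[cols], yv)

    while True:
        step_no += 1
        current = model_fit(selected)
        candidates = sorted(t for t in term_map if t not in selected)
        best_term, best_p = None, None
        for t in candidates:
            try:
                trial = model_fit(selected + [t])
                p = lrt_pvalue(trial, current)
            except ModelError:
                continue
            if not np.isfinite(p):
                continue
            if best_p is None or p < best_p:
                best_term, best_p = t, p
        if best_term is None or best_p >= alpha_enter:
            break
        selected.append(best_term)
        steps.append({"step": step_no, "action": "enter", "term": best_term,
                      "p_value": best_p})

        # removal pass
        removed_entering = False
        while len(selected) > 1:
            current = model_fit(selected)
            worst_term, worst_p = None, None
            for t in selected:
                reduced = model_fit([s for s in selected if s != t])
                p = lrt_pvalue(current, reduced)
                if not np.isfinite(p):
                    continue
                if worst_p is None or p > worst_p:
                    worst_term, worst_p = t, p
            if worst_p is None or worst_p <= alpha_stay:
                break
            selected.remove(worst_term)
            steps.append({"step": step_no, "action": "remove", "term": worst_term,
                          "p_value": worst_p})
            if worst_term == best_term:
                removed_entering = True
                break
        if removed_entering:
            break

    final = model_fit(selected)
    return StepwiseResult(selected=selected,
                          steps=pd.DataFrame(steps, columns=["step", "action",
                                                             "term", "p_value"]),
                          final=final)


def chisq_independence(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table."""
    counts = table.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ModelError("contingency counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ModelError("contingency table has a zero marginal")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def spearman_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations among metagene scores.

    Computed on samples with complete scores; a constant score column is
    flagged and its correlations are undefined (NaN).
    """
    complete = scores.dropna()
    if len(complete) < 3:
        raise ModelError("need at least 3 samples with complete scores")
    constant = [c for c in complete.columns if complete[c].nunique() == 1]
    if constant:
        log.warning("spearman_matrix: constant score column(s) %s undefined", constant)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return complete.corr(method="spearman")
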