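"""Matched case-control inference.

The centrepiece is a 1:1 conditional logistic regression fitted directly
from its conditional likelihood

    L(beta) = prod_j exp(beta' x_case_j) /
                     (exp(beta' x_case_j) + exp(beta' x_control_j)),

which reduces to an intercept-free Bernoulli likelihood on within-pair
covariate differences d_j = x_case_j - x_control_j:
log L = sum_j log sigma(beta' d_j). It is maximised by Newton-Raphson with
the analytic gradient and Hessian. Around it sit an unconditional logistic
fit (delegated to statsmodels) for strata that break the matching, Wald
trend and interaction tests, the 10 % change-in-estimate confounder screen,
and paired descriptive tests (paired t, Wilcoxon signed-rank, McNemar-type
symmetry test).

Categorical covariates are one-hot coded against the alphabetically first
level; the ``"unknown"`` level and NaN count as missing, and every model is
fitted complete-case (pairs with any missing design value are dropped and
counted).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, log_expit
import statsmodels.api as sm
from statsmodels.stats.contingency_tables import SquareTable, mcnemar

from .exceptions import ConvergenceError, DomainError, SeparationError

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95 % normal quantile
_DIVERGENCE_BETA = 30.0


@dataclass
class RegressionResult:
    """One fitted model: per-term estimates plus fit diagnostics.

    ``summary`` is indexed by term with columns ``beta``, ``se``, ``or_``,
    ``ci_low``, ``ci_high``, ``p``.
    """

    method: str
    summary: pd.DataFrame
    n: int
    converged: bool
    iterations: int
    loglik: float
    n_informative_pairs: int | None = None
    n_dropped: int = 0

    def beta(self, term: str) -> float:
        return float(self.summary.loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.summary.loc[term, "se"])

    def or_(self, term: str) -> float:
        return float(self.summary.loc[term, "or_"])

    def ci95(self, term: str) -> tuple[float, float]:
        row = self.summary.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])


def _summary_frame(names, beta, se) -> pd.DataFrame:
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "or_": np.exp(beta),
            "ci_low": np.exp(beta - Z95 * se),
            "ci_high": np.exp(beta + Z95 * se),
            "p": 2 * sps.norm.sf(np.abs(z)),
        },
        index=pd.Index(names, name="term"),
    )


def design_matrix(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Numeric design: categoricals one-hot against the first sorted level.

    ``"unknown"`` and NaN become missing across the term's dummy block.
    """
    cols = {}
    for term in terms:
        col = data[term]
        if pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col):
            cols[term] = col.astype(float)
            continue
        vals = col.astype(object).where(col.notna(), np.nan)
        vals = vals.where(vals != "unknown", np.nan)
        levels = sorted({v for v in vals.dropna().unique()})
        if len(levels) < 2:
            raise DomainError(
                f"categorical term {term!r} has fewer than two levels"
            )
        missing = vals.isna()
        for level in levels[1:]:
            dummy = (vals == level).astype(float)
            dummy[missing] = np.nan
            cols[f"{term}[{level}]"] = dummy
    return pd.DataFrame(cols, index=data.index)


def pair_differences(
    data: pd.DataFrame,
    terms,
    pair_col: str = "pair_id",
    status_col: str = "status",
) -> tuple[pd.DataFrame, int]:
    """Within-pair (case minus control) differences of the design columns.

    Pairs with any missing design value are dropped (complete-case);
    returns ``(differences, n_pairs_dropped)``.
    """
    X = design_matrix(data, terms)
    X[pair_col] = data[pair_col].to_numpy()
    X["_is_case"] = (data[status_col] == "case").to_numpy()
    cases = X[X["_is_case"]].set_index(pair_col).drop(columns="_is_case")
    controls = X[~X["_is_case"]].set_index(pair_col).drop(columns="_is_case")
    common = cases.index.intersection(controls.index)
    diffs = cases.loc[common] - controls.loc[common]
    complete = diffs.dropna()
    return complete, len(diffs) - len(complete)


def clogit_from_differences(
    diffs,
    names=None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> RegressionResult:
    """Newton-Raphson MLE of the 1:1 conditional likelihood.

    ``diffs`` holds one row per pair of case-minus-control covariate
    differences. Convergence is declared at ``max|step| < tol``; a
    diverging coefficient with a non-vanishing gradient raises
    :class:`SeparationError` naming the offending term.
    """
    if isinstance(diffs, pd.DataFrame):
        names = list(diffs.columns) if names is None else list(names)
        D = diffs.to_numpy(dtype=float)
    else:
        D = np.asarray(diffs, dtype=float)
        if D.ndim == 1:
            D = D[:, None]
        names = [f"x{i}" for i in range(D.shape[1])] \
            if names is None else list(names)

    informative = np.any(D != 0, axis=1)
    n_informative = int(informative.sum())
    if n_informative < 1:
        raise ConvergenceError("no informative pairs (all differences zero)")
    dead = np.all(D == 0, axis=0)
    if dead.any():
        bad = [names[i] for i in np.flatnonzero(dead)]
        raise ConvergenceError(
            "term(s) constant within every pair (non-identifiable): "
            + ", ".join(bad)
        )

    beta = np.zeros(D.shape[1])
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = D @ beta
        mu = expit(eta)
        grad = D.T @ (1.0 - mu)
        w = mu * (1.0 - mu)
        hess = (D * w[:, None]).T @ D
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as err:
            raise SeparationError(
                "singular Hessian (collinear or separated terms): "
                + ", ".join(names)
            ) from err
        beta = beta + step
        if np.abs(beta).max() > _DIVERGENCE_BETA \
                and np.abs(grad).max() > 1e-4:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"no finite MLE: coefficient for {worst!r} diverges "
                "(separated data)"
            )
        if np.abs(step).max() < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations"
        )

    eta = D @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    hess = (D * w[:, None]).T @ D
    se = np.sqrt(np.diag(np.linalg.inv(hess)))
    return RegressionResult(
        method="clogit_1to1",
        summary=_summary_frame(names, beta, se),
        n=D.shape[0],
        n_informative_pairs=n_informative,
        converged=converged,
        iterations=iterations,
        loglik=float(log_expit(eta).sum()),
    )


def fit_clogit_1to1(
    data: pd.DataFrame,
    terms,
    pair_col: str = "pair_id",
    status_col: str = "status",
    drop_constant: bool = False,
    **kwargs,
) -> RegressionResult:
    """Conditional logistic regression on subject-level data.

    ``terms`` are exposure/covariate columns (numeric or categorical).
    ``drop_constant`` silently removes terms that are constant within every
    pair (useful for interaction models where a pair-level stratifier's
    main effect cancels by design).
    """
    diffs, n_dropped = pair_differences(data, terms, pair_col, status_col)
    if drop_constant:
        dead = [c for c in diffs.columns if (diffs[c] == 0).all()]
        if dead:
            logger.info("dropping pair-constant term(s): %s", dead)
            diffs = diffs.drop(columns=dead)
    result = clogit_from_differences(diffs, **kwargs)
    result.n_dropped = n_dropped
    return result


def fit_logit(
    data: pd.DataFrame,
    terms,
    status_col: str = "status",
) -> RegressionResult:
    """Unconditional ML logistic regression (statsmodels) with intercept."""
    X = design_matrix(data, terms)
    y = (data[status_col] == "case").astype(float) \
        if data[status_col].dtype == object \
        else data[status_col].astype(float)
    keep = X.notna().all(axis=1)
    X, y = X[keep], y[keep]
    if y.nunique() < 2:
        raise DomainError("both outcome classes must be present")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as err:  # includes PerfectSeparationError
        raise SeparationError(f"logistic fit failed: {err}") from err
    if not fit.mle_retvals.get("converged", False) \
            or np.abs(fit.params.to_numpy()).max() > _DIVERGENCE_BETA:
        raise SeparationError(
            "logistic fit did not converge (possible separation)"
        )
    return RegressionResult(
        method="logit",
        summary=_summary_frame(list(Xc.columns), fit.params.to_numpy(),
                               fit.bse.to_numpy()),
        n=int(len(y)),
        converged=True,
        iterations=int(fit.mle_retvals.get("iterations", 0)),
        loglik=float(fit.llf),
        n_dropped=int((~keep).sum()),
    )


@dataclass
class TrendTestResult:
    """Ordinal-slope and highest-vs-lowest contrasts for a 3-level exposure."""

    p_trend: float
    slope: float
    slope_se: float
    p_high_vs_low: float
    or_high_vs_low: float
    fit_ordinal: RegressionResult
    fit_contrasts: RegressionResult


def _category_codes(values: pd.Series) -> pd.Series:
    """Map low/mid/high (or already-numeric 0/1/2) onto ordinal codes."""
    if pd.api.types.is_numeric_dtype(values):
        return values.astype(float)
    order = {"low": 0.0, "mid": 1.0, "high": 2.0}
    bad = set(values.dropna().unique()) - set(order)
    if bad:
        raise DomainError(f"unknown category labels: {sorted(bad)}")
    return values.map(order)


def fit_category_contrasts(
    data: pd.DataFrame,
    category_col: str,
    covariates=(),
    conditional: bool = True,
    **cols,
) -> RegressionResult:
    """Dummy-coded mid/high-vs-low fit; terms ``mid_vs_low``/``high_vs_low``."""
    codes = _category_codes(data[category_col])
    work = data.copy()
    work["mid_vs_low"] = (codes == 1).astype(float)
    work["high_vs_low"] = (codes == 2).astype(float)
    terms = ["mid_vs_low", "high_vs_low", *covariates]
    if conditional:
        return fit_clogit_1to1(work, terms, **cols)
    return fit_logit(work, terms, **cols)


def trend_test(
    data: pd.DataFrame,
    category_col: str,
    covariates=(),
    conditional: bool = True,
    **cols,
) -> TrendTestResult:
    """Wald trend test on the ordinal (0/1/2) exposure slope.

    Also reports the highest-vs-lowest dummy contrast, since "trend across
    tertiles" is sometimes read as that single comparison; both are
    labelled in the result.
    """
    work = data.copy()
    work["_ordinal"] = _category_codes(data[category_col])
    terms = ["_ordinal", *covariates]
    if conditional:
        fit_ord = fit_clogit_1to1(work, terms, **cols)
    else:
        fit_ord = fit_logit(work, terms, **cols)
    fit_dum = fit_category_contrasts(
        data, category_col, covariates, conditional, **cols
    )
    return TrendTestResult(
        p_trend=fit_ord.p("_ordinal"),
        slope=fit_ord.beta("_ordinal"),
        slope_se=fit_ord.se("_ordinal"),
        p_high_vs_low=fit_dum.p("high_vs_low"),
        or_high_vs_low=fit_dum.or_("high_vs_low"),
        fit_ordinal=fit_ord,
        fit_contrasts=fit_dum,
    )


def interaction_test(
    data: pd.DataFrame,
    exposure_col: str,
    stratifier_col: str,
    covariates=(),
    conditional: bool = True,
    **cols,
) -> tuple[float, RegressionResult]:
    """Wald test on the exposure x stratifier product term.

    The stratifier must be binary (bool or 0/1). Under the conditional
    model a pair-constant stratifier main effect cancels and is dropped
    automatically; the product term remains identified.
    """
    strat = data[stratifier_col]
    vals = set(pd.unique(strat.dropna()))
    if not vals <= {0, 1, 0.0, 1.0, True, False}:
        raise DomainError("stratifier must be binary (0/1 or bool)")
    work = data.copy()
    work["_strat"] = strat.astype(float)
    work["_product"] = work["_strat"] * design_matrix(
        data, [exposure_col]).iloc[:, 0]
    terms = [exposure_col, "_strat", "_product", *covariates]
    if conditional:
        fit = fit_clogit_1to1(work, terms, drop_constant=True, **cols)
    else:
        fit = fit_logit(work, terms, **cols)
    return fit.p("_product"), fit


@dataclass
class ScreenResult:
    """Outcome of the change-in-estimate confounder screen."""

    selected: list[str]
    table: pd.DataFrame
    or_crude: float
    threshold: float = 0.10


def confounder_screen(
    data: pd.DataFrame,
    exposure_col: str,
    candidates,
    conditional: bool = True,
    threshold: float = 0.10,
    **cols,
) -> ScreenResult:
    """Select covariates that shift the crude exposure OR by > ``threshold``.

    Candidates are evaluated one at a time against the crude (exposure-only)
    model; a candidate is retained when
    ``|OR_adjusted - OR_crude| / OR_crude > threshold``. Candidates whose
    adjusted model fails to converge, or that are collinear with the
    exposure, are flagged and excluded with a warning.
    """
    fitter = fit_clogit_1to1 if conditional else fit_logit
    crude = fitter(data, [exposure_col], **cols)
    exposure_term = crude.summary.index[
        crude.summary.index.str.startswith(exposure_col)][0] \
        if exposure_col not in crude.summary.index else exposure_col
    or_crude = crude.or_(exposure_term)

    exp_vals = design_matrix(data, [exposure_col]).iloc[:, 0]
    rows, selected = [], []
    for cand in candidates:
        note = ""
        or_adj = np.nan
        rel = np.nan
        cand_design = design_matrix(data, [cand])
        collinear = any(
            np.nanstd(col) > 0 and abs(
                pd.Series(col).corr(exp_vals)) > 0.9999
            for _, col in cand_design.items()
        ) or any(
            np.allclose(col.fillna(-1), exp_vals.fillna(-1))
            for _, col in cand_design.items()
        )
        if collinear:
            note = "collinear with exposure; excluded"
            warnings.warn(f"candidate {cand!r} {note}", stacklevel=2)
        else:
            try:
                adjusted = fitter(data, [exposure_col, cand], **cols)
                or_adj = adjusted.or_(exposure_term)
                rel = abs(or_adj - or_crude) / or_crude
                if rel > threshold:
                    selected.append(cand)
            except ConvergenceError as err:
                note = f"adjusted model failed: {err}"
                warnings.warn(f"candidate {cand!r} {note}", stacklevel=2)
        rows.append({
            "candidate": cand,
            "or_crude": or_crude,
            "or_adjusted": or_adj,
            "relative_change": rel,
            "selected": cand in selected,
            "note": note,
        })
    return ScreenResult(
        selected=selected,
        table=pd.DataFrame(rows).set_index("candidate"),
        or_crude=or_crude,
        threshold=threshold,
    )


@dataclass
class PairedTestResult:
    """Paired case-control comparison of one variable."""

    test: str
    statistic: float
    p: float
    summary: dict = field(default_factory=dict)
    note: str = ""


def paired_descriptives(case_values, control_values,
                        kind: str = "normal") -> PairedTestResult:
    """Paired descriptive test, dispatched by declared variable type.

    ``kind='normal'``: paired t-test (mean +/- sd per arm).
    ``kind='skewed'``: Wilcoxon signed-rank (median and quartiles per arm);
    undefined when every within-pair difference is zero.
    ``kind='categorical'``: McNemar test for binary variables, Bowker
    symmetry test for more levels (percentages per arm).
    """
    case = np.asarray(case_values)
    control = np.asarray(control_values)
    if case.shape != control.shape:
        raise DomainError("paired arrays must have equal length")

    if kind == "normal":
        case = case.astype(float)
        control = control.astype(float)
        diffs = case - control
        summary = {
            "cases_mean": float(case.mean()), "cases_sd": float(case.std(ddof=1)),
            "controls_mean": float(control.mean()),
            "controls_sd": float(control.std(ddof=1)),
        }
        if np.allclose(diffs, 0):
            return PairedTestResult("paired_t", 0.0, 1.0, summary,
                                    note="all differences zero")
        stat, p = sps.ttest_rel(case, control)
        return PairedTestResult("paired_t", float(stat), float(p), summary)

    if kind == "skewed":
        case = case.astype(float)
        control = control.astype(float)
        summary = {
            "cases_median": float(np.median(case)),
            "cases_q25": float(np.quantile(case, 0.25)),
            "cases_q75": float(np.quantile(case, 0.75)),
            "controls_median": float(np.median(control)),
            "controls_q25": float(np.quantile(control, 0.25)),
            "controls_q75": float(np.quantile(control, 0.75)),
        }
        if np.allclose(case - control, 0):
            return PairedTestResult(
                "wilcoxon", np.nan, np.nan, summary,
                note="undefined: all within-pair differences are zero",
            )
        stat, p = sps.wilcoxon(case, control)
        return PairedTestResult("wilcoxon", float(stat), float(p), summary)

    if kind == "categorical":
        levels = sorted(set(case.tolist()) | set(control.tolist()))
        k = len(levels)
        idx = {lev: i for i, lev in enumerate(levels)}
        table = np.zeros((k, k))
        for a, b in zip(case, control):
            table[idx[a], idx[b]] += 1
        summary = {
            f"cases_pct_{lev}": 100.0 * float((case == lev).mean())
            for lev in levels
        } | {
            f"controls_pct_{lev}": 100.0 * float((control == lev).mean())
            for lev in levels
        }
        if k == 1:
            return PairedTestResult("mcnemar", 0.0, 1.0, summary,
                                    note="single category")
        if k == 2:
            discordant = table[0, 1] + table[1, 0]
            if discordant == 0:
                return PairedTestResult("mcnemar", 0.0, 1.0, summary,
                                        note="no discordant pairs")
            res = mcnemar(table, exact=False, correction=False)
            return PairedTestResult("mcnemar", float(res.statistic),
                                    float(res.pvalue), summary)
        res = SquareTable(table, shift_zeros=False).symmetry()
        return PairedTestResult("bowker_symmetry", float(res.statistic),
                                float(res.pvalue), summary)

    raise DomainError(f"unknown variable kind: {kind!r}")
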