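"""Covariate-adjusted logistic models for joint and stratified odds ratios.

The central object is the *joint cell model*: a single maximum-likelihood
logistic regression with a 7-level dummy encoding of the non-reference
(PRS quartile x exposure) cells, the (Q1, unexposed) cell as referent,
adjusted for age, BMI, study (unordered dummies) and the first three
principal components.  Because the cell encoding is saturated in the two
factors, every stratified presentation — exposure ORs within quartiles,
quartile ORs within exposure strata — is an exact function of the joint
cells and their covariance (Delta method on the log scale).

Also provided: the ordinal trend test (quartile entered as a numeric
covariate, Wald test) and Cochran's Q for between-study heterogeneity of
study-specific estimates (fixed-effect inverse-variance pooling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

EXPOSURE_COLUMNS = {"any": "mht_any", "eonly": "mht_eonly", "ep": "mht_ep"}
ADJUSTMENT_COVARIATES = ("age", "bmi", "pc1", "pc2", "pc3")

CONVERGENCE_TOL = 1e-8
MAX_ITER = 100


class ModelFitError(RuntimeError):
    """Logistic fit failed (separation, non-convergence, or empty cell)."""


@dataclass
class LogisticFit:
    """A fitted logistic model: coefficients, covariance, likelihood."""

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    nobs: int
    terms: list[str]
    converged: bool
    cell_terms: list[str] | None = None
    exposure: str | None = None

    def __post_init__(self) -> None:
        if list(self.params.index) != list(self.cov.index):
            raise ValueError("params and covariance dimensions disagree")

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov.loc[term, term]))


@dataclass
class JointORTable:
    """The 4x2 cross-classified OR grid with its log-scale covariance.

    ``grid`` has one row per (quartile, exposed) cell with the log-OR, SE,
    OR and Wald 95% CI relative to the (Q1, unexposed) reference cell;
    ``cov`` is the covariance of the 7 non-reference cell log-ORs.
    """

    grid: pd.DataFrame
    cov: pd.DataFrame
    exposure: str


def cell_term(quartile: int, exposed: int) -> str:
    return f"cell_q{quartile}_e{exposed}"


def exposure_column(exposure: str) -> str:
    try:
        return EXPOSURE_COLUMNS[exposure]
    except KeyError:
        raise ValueError(
            f"unknown exposure {exposure!r}; use one of {sorted(EXPOSURE_COLUMNS)}"
        ) from None


def complete_cases(data: pd.DataFrame, exposure: str) -> pd.DataFrame:
    """Subset with a non-missing value of the requested exposure variable."""
    col = exposure_column(exposure)
    if col not in data.columns:
        raise ValueError(f"phenotype table lacks column {col!r}")
    sub = data.loc[data[col].notna()].copy()
    if sub.empty:
        raise ValueError(f"no subjects with non-missing {col}")
    return sub


def _covariate_design(data: pd.DataFrame) -> pd.DataFrame:
    X = data.loc[:, list(ADJUSTMENT_COVARIATES)].astype(float)
    study = pd.get_dummies(data["study"], prefix="study", dtype=float)
    # first study level is the reference
    X = pd.concat([X, study.iloc[:, 1:]], axis=1)
    return X


def _fit_logit(y: pd.Series, X: pd.DataFrame, context: str) -> sm.discrete.discrete_model.BinaryResultsWrapper:
    X = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y.astype(float), X.astype(float))
    try:
        with np.errstate(all="ignore"):
            res = model.fit(method="newton", maxiter=MAX_ITER, tol=CONVERGENCE_TOL, disp=False)
    except Exception as exc:  # statsmodels raises several separation/LinAlg errors
        raise ModelFitError(f"logistic fit failed for {context}: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ModelFitError(f"logistic fit did not converge for {context}")
    if not np.all(np.isfinite(res.bse)):
        bad = list(res.bse.index[~np.isfinite(res.bse)])
        raise ModelFitError(f"infinite standard errors (separation?) for {context}: {bad}")
    return res


def _wrap(res, cell_terms=None, exposure=None) -> LogisticFit:
    return LogisticFit(
        params=res.params,
        cov=res.cov_params(),
        llf=float(res.llf),
        nobs=int(res.nobs),
        terms=list(res.params.index),
        converged=True,
        cell_terms=cell_terms,
        exposure=exposure,
    )


def _check_cells(sub: pd.DataFrame, col: str) -> None:
    counts = sub.groupby(["prs_q", col], observed=False).size()
    empty = [(k, e) for k in (1, 2, 3, 4) for e in (0, 1) if counts.get((k, e), 0) == 0]
    if empty:
        names = [cell_term(k, int(e)) for k, e in empty]
        raise ModelFitError(f"empty quartile x exposure cells: {names}")
    per_study = sub.groupby("study")["case_status"].agg(["sum", "count"])
    bad = per_study.index[(per_study["sum"] == 0) | (per_study["sum"] == per_study["count"])]
    if len(bad):
        raise ModelFitError(f"studies without both cases and controls: {list(bad)}")


def cell_design(data: pd.DataFrame, exposure: str) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Complete-case outcome/design for the joint cell model."""
    col = exposure_column(exposure)
    sub = complete_cases(data, exposure)
    if "prs_q" not in sub.columns:
        raise ValueError("data must carry a prs_q quartile column")
    _check_cells(sub, col)
    cells = {}
    for k in (1, 2, 3, 4):
        for e in (0, 1):
            if (k, e) == (1, 0):
                continue
            cells[cell_term(k, e)] = (
                (sub["prs_q"] == k) & (sub[col] == e)
            ).astype(float)
    X = pd.concat([pd.DataFrame(cells, index=sub.index), _covariate_design(sub)], axis=1)
    return sub, X, list(cells)


def fit_cell_model(data: pd.DataFrame, exposure: str = "any") -> LogisticFit:
    """Fit the joint (quartile x exposure) cell logistic model.

    ``data`` must carry ``case_status``, ``prs_q``, the exposure columns and
    the adjustment covariates.  Complete-case on the requested exposure.
    """
    sub, X, cell_terms = cell_design(data, exposure)
    res = _fit_logit(sub["case_status"], X, f"cell model ({exposure})")
    return _wrap(res, cell_terms=cell_terms, exposure=exposure)


def joint_or_table(fit: LogisticFit) -> JointORTable:
    """Tabulate cell ORs with Wald 95% CIs; reference cell fixed at 1."""
    if not fit.cell_terms:
        raise ValueError("fit does not come from fit_cell_model")
    rows = [{"quartile": 1, "exposed": 0, "log_or": 0.0, "se": 0.0,
             "or": 1.0, "ci_low": 1.0, "ci_high": 1.0}]
    for k in (1, 2, 3, 4):
        for e in (0, 1):
            if (k, e) == (1, 0):
                continue
            term = cell_term(k, e)
            b = float(fit.params[term])
            se = fit.se(term)
            rows.append({
                "quartile": k, "exposed": e, "log_or": b, "se": se,
                "or": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.96 * se)),
                "ci_high": float(np.exp(b + 1.96 * se)),
            })
    grid = pd.DataFrame(rows).sort_values(["quartile", "exposed"]).reset_index(drop=True)
    cov = fit.cov.loc[fit.cell_terms, fit.cell_terms]
    return JointORTable(grid=grid, cov=cov, exposure=fit.exposure or "any")


def _padded_cov(table: JointORTable) -> tuple[pd.DataFrame, dict[tuple[int, int], str]]:
    """Cell covariance including the reference cell as an exact zero."""
    ref = cell_term(1, 0)
    names = [ref] + list(table.cov.index)
    cov = pd.DataFrame(0.0, index=names, columns=names)
    cov.loc[table.cov.index, table.cov.columns] = table.cov
    mapping = {(k, e): cell_term(k, e) for k in (1, 2, 3, 4) for e in (0, 1)}
    return cov, mapping


def _log_grid(table: JointORTable) -> dict[tuple[int, int], float]:
    return {(int(r.quartile), int(r.exposed)): float(r.log_or)
            for r in table.grid.itertuples()}


def stratified_or(table: JointORTable) -> dict[str, pd.DataFrame]:
    """Stratified ORs as exact ratios of joint cells.

    Returns ``exposure_within_quartile`` (the exposed/unexposed OR in each
    quartile) and ``quartile_within_stratum`` (Q2-Q4 vs Q1 within each
    exposure stratum), each with Delta-method log-scale SEs from the cell
    covariance.
    """
    cov, names = _padded_cov(table)
    logs = _log_grid(table)

    def contrast(num: tuple[int, int], den: tuple[int, int]) -> tuple[float, float]:
        b = logs[num] - logs[den]
        v = (cov.loc[names[num], names[num]] + cov.loc[names[den], names[den]]
             - 2.0 * cov.loc[names[num], names[den]])
        return b, float(np.sqrt(max(v, 0.0)))

    rows = []
    for k in (1, 2, 3, 4):
        b, se = contrast((k, 1), (k, 0))
        rows.append({"quartile": k, "or": np.exp(b),
                     "ci_low": np.exp(b - 1.96 * se), "ci_high": np.exp(b + 1.96 * se),
                     "log_or": b, "se": se})
    within_q = pd.DataFrame(rows)

    rows = []
    for e in (0, 1):
        for k in (2, 3, 4):
            b, se = contrast((k, e), (1, e))
            rows.append({"exposed": e, "quartile": k, "or": np.exp(b),
                         "ci_low": np.exp(b - 1.96 * se), "ci_high": np.exp(b + 1.96 * se),
                         "log_or": b, "se": se})
    within_e = pd.DataFrame(rows)
    return {"exposure_within_quartile": within_q, "quartile_within_stratum": within_e}


@dataclass
class TrendResult:
    coef: float
    se: float
    z: float
    p: float
    nobs: int


def trend_test(data: pd.DataFrame, exposure: str = "any", stratum: int = 0) -> TrendResult:
    """Wald trend test across quartiles within one exposure stratum.

    Fits the adjusted logistic model on the stratum subset with ``prs_q``
    entered as a single numeric covariate (values 1-4).
    """
    col = exposure_column(exposure)
    sub = complete_cases(data, exposure)
    sub = sub.loc[sub[col] == stratum]
    present = sorted(sub["prs_q"].unique())
    if present != [1, 2, 3, 4]:
        raise ValueError(f"stratum lacks quartiles: has {present}")
    X = pd.concat([sub[["prs_q"]].astype(float), _covariate_design(sub)], axis=1)
    res = _fit_logit(sub["case_status"], X, f"trend ({exposure}={stratum})")
    coef = float(res.params["prs_q"])
    se = float(res.bse["prs_q"])
    z = coef / se if se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return TrendResult(coef=coef, se=se, z=z, p=p, nobs=int(res.nobs))


@dataclass
class CochranQResult:
    q: float
    df: int
    p: float
    pooled: float
    pooled_se: float


def cochran_q(estimates, ses) -> CochranQResult:
    """Cochran's Q heterogeneity test over study-specific estimates.

    Fixed-effect inverse-variance pooling: weights ``w = 1/SE^2``, pooled
    estimate ``sum(w b)/sum(w)``, ``Q = sum w (b - pooled)^2`` on a
    chi-square with (number of studies - 1) degrees of freedom.
    """
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("estimates and ses must be matching 1-d arrays")
    if len(b) < 2:
        raise ValueError("Cochran's Q needs at least 2 studies")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("standard errors must be finite and positive")
    w = 1.0 / s**2
    pooled = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(b) - 1
    return CochranQResult(q=q, df=df, p=float(stats.chi2.sf(q, df)),
                          pooled=pooled, pooled_se=float(np.sqrt(1.0 / np.sum(w))))


def per_study_exposure_logor(data: pd.DataFrame, exposure: str = "any") -> pd.DataFrame:
    """Study-specific adjusted exposure log-ORs, for heterogeneity tests."""
    col = exposure_column(exposure)
    sub = complete_cases(data, exposure)
    rows = []
    for study, grp in sub.groupby("study"):
        X = grp[[col] + list(ADJUSTMENT_COVARIATES)].astype(float)
        res = _fit_logit(grp["case_status"], X, f"study {study} ({exposure})")
        rows.append({"study": study, "log_or": float(res.params[col]),
                     "se": float(res.bse[col]), "n": int(res.nobs)})
    return pd.DataFrame(rows)
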