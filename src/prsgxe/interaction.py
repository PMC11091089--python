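"""Interaction of PRS quartiles and exposure on two scales.

Multiplicative scale: a likelihood-ratio test comparing the adjusted
logistic model with main effects (three quartile dummies + exposure) to
the model adding the three quartile x exposure product terms; under the
null of multiplicativity the statistic is chi-square with 3 df.

Additive scale: the relative excess risk due to interaction,

    RERI_k = OR_k1 - OR_k0 - OR_01 + 1,

for quartile k with the (Q1, unexposed) cell as the doubly-unexposed
referent.  RERI is zero when the joint excess risk equals the sum of the
two marginal excess risks; odds ratios stand in for risk ratios under the
rare-disease approximation.  Its variance comes from the Delta method on
the three cell coefficients: with gradient
``g = (e^{b_k1}, -e^{b_k0}, -e^{b_01})``, ``var = g' S g`` where ``S`` is
the coefficient covariance block, giving a Wald 95% CI and a two-sided
normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    LogisticFit,
    ModelFitError,
    _covariate_design,
    _fit_logit,
    _wrap,
    cell_term,
    complete_cases,
    exposure_column,
)

_NEG_SLACK = -1e-8


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float


@dataclass
class RERIResult:
    quartile: int
    reri: float
    variance: float
    se: float
    ci95: tuple[float, float]
    p: float


def fit_interaction_models(data: pd.DataFrame, exposure: str = "any") -> tuple[LogisticFit, LogisticFit]:
    """Fit the product-term (full) and main-effects (reduced) models.

    Both models share the quartile dummies, the exposure indicator and the
    standard adjustment covariates on the identical complete-case subset;
    the full model adds the three quartile x exposure products.  The full
    model is a reparameterization of the joint cell model (same fitted
    cells, same likelihood).
    """
    col = exposure_column(exposure)
    sub = complete_cases(data, exposure)
    main = {f"prsq{k}": (sub["prs_q"] == k).astype(float) for k in (2, 3, 4)}
    main["exposed"] = sub[col].astype(float)
    base = pd.concat([pd.DataFrame(main, index=sub.index), _covariate_design(sub)], axis=1)
    prod = {f"prsq{k}_x_exposed": main[f"prsq{k}"] * main["exposed"] for k in (2, 3, 4)}
    full_X = pd.concat([base, pd.DataFrame(prod, index=sub.index)], axis=1)
    y = sub["case_status"]
    reduced = _wrap(_fit_logit(y, base, f"main-effects model ({exposure})"), exposure=exposure)
    full = _wrap(_fit_logit(y, full_X, f"product-term model ({exposure})"), exposure=exposure)
    return full, reduced


def multiplicative_lrt(full: LogisticFit, reduced: LogisticFit) -> LRTResult:
    """Likelihood-ratio test of the product terms.

    ``statistic = 2 (llf_full - llf_reduced)`` on chi-square with df equal
    to the number of extra terms; both fits must use the same subjects and
    the reduced terms must nest in the full terms.
    """
    if full.nobs != reduced.nobs:
        raise ValueError(f"fits use different n: {full.nobs} vs {reduced.nobs}")
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("reduced model is not nested in the full model")
    extra = set(full.terms) - set(reduced.terms)
    stat = 2.0 * (full.llf - reduced.llf)
    if stat < _NEG_SLACK:
        raise ModelFitError(f"negative LRT statistic {stat}; fits inconsistent")
    stat = max(stat, 0.0)
    df = len(extra)
    if df == 0:
        # identical term sets: degenerate comparison
        return LRTResult(statistic=float(stat), df=0, p=1.0)
    return LRTResult(statistic=float(stat), df=df, p=float(stats.chi2.sf(stat, df)))


def reri_point(or11: float, or10: float, or01: float) -> float:
    """RERI from three odds ratios: ``OR11 - OR10 - OR01 + 1``.

    ``or11`` is the doubly-exposed cell, ``or10`` and ``or01`` the two
    singly-exposed cells, all relative to the doubly-unexposed referent.
    """
    for name, v in (("or11", or11), ("or10", or10), ("or01", or01)):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be a positive finite odds ratio, got {v}")
    return float(or11 - or10 - or01 + 1.0)


def reri_inference(fit: LogisticFit, quartiles: tuple[int, ...] = (2, 3, 4)) -> list[RERIResult]:
    """Delta-method RERI inference from the joint cell model.

    For quartile k the three coefficients are the (Qk, exposed),
    (Qk, unexposed) and (Q1, exposed) cell log-ORs; their covariance block
    propagates to ``var(RERI)`` through the gradient of the RERI formula.
    """
    if not fit.cell_terms:
        raise ValueError("fit does not come from fit_cell_model")
    out = []
    for k in quartiles:
        if k == 1:
            raise ValueError("RERI is defined for quartiles 2-4 (Q1 is the referent)")
        names = [cell_term(k, 1), cell_term(k, 0), cell_term(1, 1)]
        missing = [t for t in names if t not in fit.params.index]
        if missing:
            raise ValueError(f"fit lacks cell coefficients {missing}")
        b = fit.params[names].to_numpy(dtype=float)
        try:
            S = fit.cov.loc[names, names].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValueError(f"fit lacks covariance block for {names}") from exc
        reri = reri_point(np.exp(b[0]), np.exp(b[1]), np.exp(b[2]))
        g = np.array([np.exp(b[0]), -np.exp(b[1]), -np.exp(b[2])])
        var = float(g @ S @ g)
        if var < 0:
            raise ValueError(f"negative Delta-method variance {var}")
        se = float(np.sqrt(var))
        ci = (reri - 1.96 * se, reri + 1.96 * se)
        p = float(2.0 * stats.norm.sf(abs(reri) / se)) if se > 0 else (1.0 if reri == 0 else 0.0)
        out.append(RERIResult(quartile=k, reri=reri, variance=var, se=se, ci95=ci, p=p))
    return out
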