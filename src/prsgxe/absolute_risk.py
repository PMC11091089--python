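"""30-year absolute risk projection with competing mortality.

The projection converts the case-control relative risks into cumulative
incidence for a 50-year-old woman of a given risk profile (PRS quartile x
exposure cell):

1.  Age-group relative risks.  The joint cell logistic model is re-fitted
    within three age subgroups (<=60, 61-70, >70); cell ORs approximate
    the profile relative risks RR_g(profile) under the rare-disease
    assumption.
2.  Attributable proportion.  Within each age group the case-distribution
    estimator ``AP_g = 1 - mean over cases of 1/RR(profile of case)``
    converts the composite (population-average) incidence I(a) into the
    baseline hazard of the referent profile,
    ``lambda0(a) = I(a) (1 - AP_g(a))``.
3.  Cumulative risk.  Annual piecewise-constant hazards with the
    cause-specific competing-risk decomposition:

        h_crc(a) = RR_g(a) * lambda0(a),   h(a) = h_crc(a) + m(a)
        risk     = sum_a S(a) (1 - e^{-h(a)}) h_crc(a)/h(a),
        S(a+1)   = S(a) e^{-h(a)},  S(50) = 1,

    with m(a) the competing non-disease mortality hazard, reported in
    percent over ages 50-80.
4.  Uncertainty.  Subjects are resampled with replacement within
    case/control strata; relative risks and attributable proportions are
    re-estimated per replicate and the risks recomputed, giving normal
    (point +- 1.96 SD; default) or percentile bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import ModelFitError, exposure_column, fit_cell_model, joint_or_table
from .simulate import substream

AGE_GROUPS = ((50, 60), (60, 70), (70, 80))   # (lo, hi]: <=60, 61-70, >70
PROFILES = [(k, e) for k in (1, 2, 3, 4) for e in (0, 1)]


def age_group_of(age: float) -> int:
    if age <= 60:
        return 0
    if age <= 70:
        return 1
    return 2


def validate_rate_table(table: pd.DataFrame, lo: int = 50, hi: int = 80) -> pd.DataFrame:
    """Check contiguity, non-overlap, coverage of [lo, hi) and rates >= 0."""
    need = {"age_start", "age_end", "rate_per_100k"}
    if not need <= set(table.columns):
        raise ValueError(f"rate table needs columns {sorted(need)}")
    t = table.sort_values("age_start").reset_index(drop=True)
    if (t["rate_per_100k"] < 0).any():
        raise ValueError("negative rates in rate table")
    if (t["age_end"] <= t["age_start"]).any():
        raise ValueError("age bands must have age_end > age_start")
    if not (t["age_start"].iloc[1:].to_numpy() == t["age_end"].iloc[:-1].to_numpy()).all():
        raise ValueError("age bands must be contiguous and non-overlapping")
    if t["age_start"].iloc[0] > lo or t["age_end"].iloc[-1] < hi:
        raise ValueError(f"rate table must cover ages {lo}-{hi}")
    return t


def annual_rates(table: pd.DataFrame, age_start: int = 50, age_end: int = 80) -> np.ndarray:
    """Expand an age-banded table to per-year hazards (per person-year)."""
    t = validate_rate_table(table, age_start, age_end)
    out = np.empty(age_end - age_start)
    for row in t.itertuples():
        for a in range(int(max(row.age_start, age_start)), int(min(row.age_end, age_end))):
            out[a - age_start] = row.rate_per_100k / 1e5
    return out


@dataclass
class AgeGroupRR:
    """Relative risks per profile and attributable proportion per age group.

    ``rr[g]`` maps (quartile, exposed) -> RR in age group g (referent
    profile fixed at 1); ``ap[g]`` is the attributable proportion in [0, 1).
    """

    rr: list[dict[tuple[int, int], float]]
    ap: np.ndarray

    def __post_init__(self) -> None:
        for g, rrg in enumerate(self.rr):
            if not np.isclose(rrg[(1, 0)], 1.0):
                raise ValueError(f"referent-profile RR must be 1 in age group {g}")
        if np.any(self.ap >= 1.0) or np.any(~np.isfinite(self.ap)):
            raise ValueError("attributable proportions must be finite and < 1")


def attributable_proportion(case_profiles, rr: dict[tuple[int, int], float]) -> float:
    """Case-distribution attributable proportion ``1 - mean(1/RR(case))``."""
    profiles = list(case_profiles)
    if not profiles:
        raise ValueError("attributable proportion needs at least one case")
    inv = np.array([1.0 / rr[p] for p in profiles])
    if np.any(~np.isfinite(inv)) or np.any(inv < 0):
        raise ValueError("relative risks must be positive and finite")
    return float(1.0 - inv.mean())


def estimate_age_group_rr(data: pd.DataFrame, exposure: str = "any") -> AgeGroupRR:
    """Fit the cell model within each age subgroup; derive RRs and APs."""
    col = exposure_column(exposure)
    rr_list, ap_list = [], []
    for lo, hi in AGE_GROUPS:
        grp = data.loc[(data["age"] > lo) & (data["age"] <= hi)] if lo > 50 else \
            data.loc[data["age"] <= hi]
        if grp.empty:
            raise ModelFitError(f"no subjects in age group ({lo}, {hi}]")
        fit = fit_cell_model(grp, exposure)
        table = joint_or_table(fit)
        rr = {(int(row["quartile"]), int(row["exposed"])): float(row["or"])
              for _, row in table.grid.iterrows()}
        cases = grp.loc[(grp["case_status"] == 1) & grp[col].notna()]
        profiles = list(zip(cases["prs_q"].astype(int), cases[col].astype(int)))
        ap = attributable_proportion(profiles, rr)
        rr_list.append(rr)
        ap_list.append(ap)
    return AgeGroupRR(rr=rr_list, ap=np.asarray(ap_list))


def baseline_hazard(
    incidence: pd.DataFrame,
    agerr: AgeGroupRR,
    age_start: int = 50,
    age_end: int = 80,
) -> np.ndarray:
    """Referent-profile hazard ``lambda0(a) = I(a) (1 - AP_g(a))`` per year."""
    comp = annual_rates(incidence, age_start, age_end)
    groups = np.array([age_group_of(a + 1) for a in range(age_start, age_end)])
    return comp * (1.0 - agerr.ap[groups])


def cumulative_risk(
    rr_by_group,
    lambda0: np.ndarray,
    mortality: pd.DataFrame,
    age_start: int = 50,
    age_end: int = 80,
) -> float:
    """Cumulative disease risk (%) over [age_start, age_end) for one profile.

    ``rr_by_group`` gives the profile's relative risk in each of the three
    age groups; hazards are annual and piecewise constant, with competing
    mortality removing subjects via the cause-specific decomposition.
    """
    rr_by_group = np.asarray(rr_by_group, dtype=float)
    mort = annual_rates(mortality, age_start, age_end)
    if lambda0.shape != mort.shape:
        raise ValueError("lambda0 and mortality cover different age ranges")
    if np.any(lambda0 < 0) or np.any(mort < 0) or np.any(rr_by_group < 0):
        raise ValueError("hazards and relative risks must be non-negative")
    surv = 1.0
    risk = 0.0
    for i, a in enumerate(range(age_start, age_end)):
        g = age_group_of(a + 1)     # age attained during year [a, a+1)
        h_crc = rr_by_group[g] * lambda0[i]
        h = h_crc + mort[i]
        if h > 0:
            risk += surv * (1.0 - np.exp(-h)) * h_crc / h
        surv *= np.exp(-h)
    return 100.0 * risk


def project_risks(
    data: pd.DataFrame,
    incidence: pd.DataFrame,
    mortality: pd.DataFrame,
    exposure: str = "any",
    age_start: int = 50,
    age_end: int = 80,
) -> pd.DataFrame:
    """Point 30-year risks (%) for all 8 (quartile x exposure) profiles."""
    agerr = estimate_age_group_rr(data, exposure)
    lam0 = baseline_hazard(incidence, agerr, age_start, age_end)
    rows = []
    for k, e in PROFILES:
        rr = [agerr.rr[g][(k, e)] for g in range(len(AGE_GROUPS))]
        rows.append({"quartile": k, "exposed": e,
                     "risk": cumulative_risk(rr, lam0, mortality, age_start, age_end)})
    return pd.DataFrame(rows)


@dataclass
class AbsoluteRiskResult:
    """Bootstrap-quantified 30-year risks per profile.

    ``table`` holds point risk, CI bounds and bootstrap SE per profile in
    percent; ``replicates`` is the (B_kept x 8) matrix of replicate risks;
    ``n_dropped`` counts resamples discarded for unfittable cells.
    """

    table: pd.DataFrame
    replicates: np.ndarray
    b_requested: int
    n_dropped: int
    ci_method: str
    seed: int


def bootstrap_risks(
    data: pd.DataFrame,
    incidence: pd.DataFrame,
    mortality: pd.DataFrame,
    exposure: str = "any",
    b: int = 100,
    seed: int = 0,
    ci_method: str = "normal",
    age_start: int = 50,
    age_end: int = 80,
) -> AbsoluteRiskResult:
    """Bootstrap CIs for the projected risks.

    Resamples subjects with replacement within case/control strata,
    re-estimates age-group RRs and APs per replicate, and recomputes the
    risks.  ``ci_method`` is ``"normal"`` (point +- 1.96 SD of replicates,
    clipped to [0, 100]) or ``"percentile"``.  Replicates whose cell model
    cannot be fitted (empty cell) are dropped; more than 20% dropped is an
    error.
    """
    if b < 2:
        raise ValueError("bootstrap needs B >= 2")
    if ci_method not in ("normal", "percentile"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    point = project_risks(data, incidence, mortality, exposure, age_start, age_end)
    rng = substream(seed, "bootstrap")
    cases = data.index[data["case_status"] == 1]
    controls = data.index[data["case_status"] == 0]
    reps, dropped = [], 0
    for _ in range(b):
        idx = np.concatenate([
            rng.choice(cases, size=len(cases), replace=True),
            rng.choice(controls, size=len(controls), replace=True),
        ])
        boot = data.loc[idx]
        try:
            r = project_risks(boot, incidence, mortality, exposure, age_start, age_end)
        except ModelFitError:
            dropped += 1
            continue
        reps.append(r["risk"].to_numpy())
    if dropped > 0.2 * b:
        raise ModelFitError(f"{dropped}/{b} bootstrap replicates failed to fit")
    reps = np.asarray(reps)
    sd = reps.std(axis=0, ddof=1)
    out = point.copy()
    out["se_boot"] = sd
    if ci_method == "normal":
        out["ci_low"] = np.clip(out["risk"] - 1.96 * sd, 0.0, 100.0)
        out["ci_high"] = np.clip(out["risk"] + 1.96 * sd, 0.0, 100.0)
    else:
        out["ci_low"] = np.percentile(reps, 2.5, axis=0)
        out["ci_high"] = np.percentile(reps, 97.5, axis=0)
    return AbsoluteRiskResult(table=out, replicates=reps, b_requested=b,
                              n_dropped=dropped, ci_method=ci_method, seed=seed)


@dataclass
class RiskDifference:
    difference: float
    se: float
    z: float
    p: float
    degenerate: bool


def risk_difference(
    risk_unexposed: float,
    risk_exposed: float,
    reps_unexposed: np.ndarray,
    reps_exposed: np.ndarray,
) -> RiskDifference:
    """Difference of absolute risks (non-users minus users) with a
    bootstrap z-test.

    Replicate pairs must come from the same resamples so their correlation
    is retained in the SE of the difference.  A zero bootstrap SE is
    flagged as degenerate (p undefined -> NaN).
    """
    ru = np.asarray(reps_unexposed, dtype=float)
    re = np.asarray(reps_exposed, dtype=float)
    if ru.shape != re.shape:
        raise ValueError("replicate streams have different lengths")
    diff = float(risk_unexposed - risk_exposed)
    se = float((ru - re).std(ddof=1))
    if se == 0.0:
        return RiskDifference(difference=diff, se=0.0, z=np.nan, p=np.nan, degenerate=True)
    z = diff / se
    return RiskDifference(difference=diff, se=se, z=float(z),
                          p=float(2.0 * stats.norm.sf(abs(z))), degenerate=False)
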