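"""Synthetic case-control data with known gene-environment structure.

Generates cohorts that mirror the statistical structure of a pooled
consortium case-control study of postmenopausal women: biallelic SNP
dosages under Hardy-Weinberg equilibrium, a weighted PRS whose quartiles
carry known disease log-odds, a binary hormone-therapy exposure (with
mutually exclusive estrogen-only / estrogen-progestogen subtypes, type
information missing for a configurable fraction), multi-study intercepts,
and adjustment covariates (age, BMI, three principal-component scores).

Disease status is Bernoulli with
``logit p = anchor + study offset + covariate effects + cell effect``,
where the cell effect is the true log-OR of the subject's
(PRS quartile x any-MHT) cell recorded in the :class:`TruthRecord`.
Exposure is assigned independently of genotype (gene-environment
independence, the standard case-control assumption); an optional
correlation knob shifts exposure probability with the PRS for robustness
experiments.  Retrospective case-control sampling preserves all odds
ratios, so the population prevalence anchor is a computational device,
not an estimand.

All randomness flows from one master seed through named sub-streams, so
individual stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prs import assign_quartiles, compute_prs

# Table-like default truths: quartile log-ORs among non-users, the exposure
# log-OR in the lowest quartile, and sub-multiplicative product-term
# increments chosen so the exposed-cell ORs are 1.09 / 1.40 / 1.83.
_DEFAULT_QUARTILE_OR = (1.42, 1.94, 2.82)
_DEFAULT_MHT_OR = 0.75
_DEFAULT_EXPOSED_CELL_OR = (1.09, 1.40, 1.83)

_STREAMS = {
    "maf": 0,
    "weights": 1,
    "genotypes": 2,
    "covariates": 3,
    "study": 4,
    "exposure": 5,
    "disease": 6,
    "sampling": 7,
    "bootstrap": 8,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child generator of the master seed (independent per stage)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


def _default_interaction() -> tuple[float, float, float]:
    out = []
    for q_or, cell_or in zip(_DEFAULT_QUARTILE_OR, _DEFAULT_EXPOSED_CELL_OR):
        out.append(float(np.log(cell_or) - np.log(q_or) - np.log(_DEFAULT_MHT_OR)))
    return tuple(out)


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    Defaults emulate the pooled study the analysis targets: 141 risk
    variants with MAF >= 0.01, 11,519 cases / 16,967 controls, any-MHT
    prevalence 35.2%, and Table-like joint cell odds ratios with a
    protective exposure (OR 0.75 in the lowest quartile) and
    sub-multiplicative interaction.  Set ``true_interaction=(0, 0, 0)``
    for exact multiplicativity.
    """

    n_variants: int = 141
    maf_range: tuple[float, float] = (0.01, 0.5)
    weight_mean: float = 0.08
    weight_sd: float = 0.04
    n_studies: int = 5
    study_intercepts: tuple[float, ...] | None = None
    mht_prevalence: float = 0.352
    # P(E-only & type known), P(E+P & type known) among any-MHT users; plus
    # the fraction of non-users carrying type information.  Defaults
    # reproduce the reported type-information subset sizes and exposure
    # prevalences (28.2% E-only, 21.9% E+P within their subsets).
    mht_type_split: tuple[float, float] = (0.215, 0.150)
    nonuser_type_info: float = 0.297
    age_mean: float = 62.0
    age_sd: float = 8.0
    bmi_mean: float = 27.0
    bmi_sd: float = 5.0
    pc_sd: float = 1.0
    age_logor: float = 0.02
    bmi_logor: float = 0.01
    pc_logors: tuple[float, float, float] = (0.0, 0.0, 0.0)
    quartile_logors: tuple[float, float, float] = tuple(np.log(_DEFAULT_QUARTILE_OR))
    true_mht_logor: float = float(np.log(_DEFAULT_MHT_OR))
    true_interaction: tuple[float, float, float] = field(default_factory=_default_interaction)
    prs_exposure_corr: float = 0.0
    baseline_prevalence: float = 0.25
    n_population: int = 80_000
    n_cases: int = 11_519
    n_controls: int = 16_967
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within [0.01, 0.5], got {self.maf_range}")
        for name in ("mht_prevalence", "baseline_prevalence", "nonuser_type_info"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0) and not (name == "nonuser_type_info" and p == 0.0):
                raise ValueError(f"{name} must be in (0,1), got {p}")
        if sum(self.mht_type_split) > 1.0:
            raise ValueError("mht_type_split probabilities exceed 1")
        if self.n_cases + self.n_controls > self.n_population:
            raise ValueError(
                f"n_cases + n_controls = {self.n_cases + self.n_controls} exceeds "
                f"n_population = {self.n_population}"
            )
        if self.study_intercepts is not None and len(self.study_intercepts) != self.n_studies:
            raise ValueError("study_intercepts length must equal n_studies")


@dataclass
class TruthRecord:
    """Ground truth of a simulated population, for recovery tests.

    ``cell_logor[k, e]`` is the true log-OR of quartile ``k+1`` with
    exposure ``e`` relative to the (Q1, unexposed) cell.  ``true_reri`` is
    the additive-scale interaction on the OR scale,
    ``exp(b_k1) - exp(b_k0) - exp(b_01) + 1`` per quartile; it is zero only
    under exp-scale additivity (RR11 = RR10 + RR01 - 1), while
    ``interaction_logor`` being all-zero means exact multiplicativity
    (additivity of log-odds) — the two scales are recorded separately.
    """

    weights: np.ndarray
    mafs: np.ndarray
    cell_logor: np.ndarray            # 4 quartiles x 2 exposure levels
    true_reri: dict[int, float]       # OR scale, quartiles 2..4
    interaction_logor: tuple[float, float, float]   # log scale (0 = multiplicative)
    covariate_logors: dict[str, float]
    quartile_cutpoints: np.ndarray


def _cell_logor_grid(config: SimConfig) -> np.ndarray:
    grid = np.zeros((4, 2))
    q = (0.0,) + tuple(config.quartile_logors)
    for k in range(4):
        grid[k, 0] = q[k]
        grid[k, 1] = q[k] + config.true_mht_logor
        if k >= 1:
            grid[k, 1] += config.true_interaction[k - 1]
    return grid


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate a source population with known joint cell effects.

    Returns ``(genotypes, phenotypes, truth)``: a subjects x variants dosage
    frame, a phenotype frame (case_status, age, bmi, study, pc1-3,
    mht_any / mht_eonly / mht_ep with NaN for type-unknown, and the true
    quartile ``prs_q_true``), and the :class:`TruthRecord`.
    """
    n = config.n_population
    mafs = substream(config.seed, "maf").uniform(*config.maf_range, size=config.n_variants)
    weights = substream(config.seed, "weights").normal(
        config.weight_mean, config.weight_sd, size=config.n_variants
    )
    geno = substream(config.seed, "genotypes").binomial(
        2, mafs, size=(n, config.n_variants)
    ).astype(float)
    variant_ids = [f"rs{i + 1:05d}" for i in range(config.n_variants)]
    subject_ids = [f"S{i + 1:06d}" for i in range(n)]
    genotypes = pd.DataFrame(geno, index=pd.Index(subject_ids, name="subject_id"),
                             columns=variant_ids)

    prs = compute_prs(genotypes,
                      pd.DataFrame({"variant_id": variant_ids, "weight": weights}))
    cuts = np.quantile(prs.to_numpy(), [0.25, 0.5, 0.75], method="linear")
    quart = np.searchsorted(cuts, prs.to_numpy(), side="left") + 1

    rng_cov = substream(config.seed, "covariates")
    age = rng_cov.normal(config.age_mean, config.age_sd, size=n)
    bmi = rng_cov.normal(config.bmi_mean, config.bmi_sd, size=n)
    pcs = rng_cov.normal(0.0, config.pc_sd, size=(n, 3))
    study = substream(config.seed, "study").integers(config.n_studies, size=n)
    intercepts = (np.asarray(config.study_intercepts) if config.study_intercepts is not None
                  else np.linspace(-0.3, 0.3, config.n_studies))

    rng_exp = substream(config.seed, "exposure")
    p_mht = np.full(n, config.mht_prevalence)
    if config.prs_exposure_corr:
        z = (prs.to_numpy() - prs.mean()) / prs.std()
        logit = np.log(p_mht / (1 - p_mht)) + config.prs_exposure_corr * z
        p_mht = 1.0 / (1.0 + np.exp(-logit))
    mht_any = (rng_exp.random(n) < p_mht).astype(int)

    # mutually exclusive subtype labels among users; NaN = type unknown
    p_e, p_p = config.mht_type_split
    u = rng_exp.random(n)
    mht_eonly = np.full(n, np.nan)
    mht_ep = np.full(n, np.nan)
    users = mht_any == 1
    eonly_known = users & (u < p_e)
    ep_known = users & (u >= p_e) & (u < p_e + p_p)
    nonuser_known = (~users) & (rng_exp.random(n) < config.nonuser_type_info)
    mht_eonly[eonly_known] = 1.0
    mht_eonly[ep_known | nonuser_known] = 0.0
    mht_ep[ep_known] = 1.0
    mht_ep[eonly_known | nonuser_known] = 0.0

    grid = _cell_logor_grid(config)
    cell_effect = grid[quart - 1, mht_any]
    logit = (np.log(config.baseline_prevalence / (1 - config.baseline_prevalence))
             + intercepts[study]
             + config.age_logor * (age - config.age_mean)
             + config.bmi_logor * (bmi - config.bmi_mean)
             + pcs @ np.asarray(config.pc_logors)
             + cell_effect)
    p_disease = 1.0 / (1.0 + np.exp(-logit))
    case_status = (substream(config.seed, "disease").random(n) < p_disease).astype(int)

    phenotypes = pd.DataFrame({
        "case_status": case_status,
        "age": age,
        "bmi": bmi,
        "study": [f"study{s + 1}" for s in study],
        "pc1": pcs[:, 0], "pc2": pcs[:, 1], "pc3": pcs[:, 2],
        "mht_any": mht_any.astype(float),
        "mht_eonly": mht_eonly,
        "mht_ep": mht_ep,
        "prs_q_true": quart,
    }, index=genotypes.index)

    true_reri = {}
    for k in range(1, 4):
        true_reri[k + 1] = float(
            np.exp(grid[k, 1]) - np.exp(grid[k, 0]) - np.exp(grid[0, 1]) + 1.0
        )
    truth = TruthRecord(
        weights=weights, mafs=mafs, cell_logor=grid, true_reri=true_reri,
        interaction_logor=tuple(config.true_interaction),
        covariate_logors={"age": config.age_logor, "bmi": config.bmi_logor,
                          "pc1": config.pc_logors[0], "pc2": config.pc_logors[1],
                          "pc3": config.pc_logors[2]},
        quartile_cutpoints=cuts,
    )
    return genotypes, phenotypes, truth


def weight_table_from_truth(truth: TruthRecord, variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Export the simulated weights as a standard weight table (effect
    allele is the counted ALT allele ``A``)."""
    n = len(truth.weights)
    if variant_ids is None:
        variant_ids = [f"rs{i + 1:05d}" for i in range(n)]
    return pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": "1",
        "pos": np.arange(1, n + 1) * 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "weight": truth.weights,
    })


def sample_case_control(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple random sample without replacement within outcome strata.

    Retrospective sampling conditions on case status, which only shifts the
    logistic intercept, so every odds ratio of the source population is
    preserved in expectation.
    """
    rng = substream(seed, "sampling")
    cases = phenotypes.index[phenotypes["case_status"] == 1]
    controls = phenotypes.index[phenotypes["case_status"] == 0]
    if n_cases > len(cases):
        raise ValueError(f"requested {n_cases} cases but population has {len(cases)}")
    if n_controls > len(controls):
        raise ValueError(f"requested {n_controls} controls but population has {len(controls)}")
    keep = np.concatenate([
        rng.choice(cases, size=n_cases, replace=False),
        rng.choice(controls, size=n_controls, replace=False),
    ])
    keep = pd.Index(keep, name=phenotypes.index.name)
    return genotypes.loc[keep], phenotypes.loc[keep]


# Synthetic registry-style rate tables: 5-year bands with rates per
# 100,000 person-years, shaped like U.S. female colorectal-cancer incidence
# and all-cause-minus-CRC mortality at ages 50-84.
_DEFAULT_BANDS = [(50, 55), (55, 60), (60, 65), (65, 70), (70, 75), (75, 80), (80, 85)]
_DEFAULT_INCIDENCE = [60.0, 90.0, 130.0, 180.0, 240.0, 300.0, 380.0]
_DEFAULT_MORTALITY = [300.0, 500.0, 800.0, 1300.0, 2100.0, 3400.0, 5600.0]


def simulate_rate_tables(
    bands: list[tuple[int, int]] | None = None,
    incidence: list[float] | None = None,
    mortality: list[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Age-banded annual incidence and competing-mortality rate tables.

    Returns two frames with columns ``age_start, age_end, rate_per_100k``
    (closed-open bands).  Defaults are synthetic registry-like values
    rising with age and covering ages 50-85.
    """
    bands = bands if bands is not None else list(_DEFAULT_BANDS)
    incidence = incidence if incidence is not None else list(_DEFAULT_INCIDENCE)
    mortality = mortality if mortality is not None else list(_DEFAULT_MORTALITY)
    if not (len(bands) == len(incidence) == len(mortality)):
        raise ValueError("bands, incidence and mortality must have equal length")
    if min(incidence) < 0 or min(mortality) < 0:
        raise ValueError("rates must be non-negative")
    starts, ends = zip(*bands)
    if min(starts) > 50 or max(ends) < 80:
        raise ValueError("rate tables must cover ages 50-80")
    inc = pd.DataFrame({"age_start": starts, "age_end": ends, "rate_per_100k": incidence})
    mort = pd.DataFrame({"age_start": starts, "age_end": ends, "rate_per_100k": mortality})
    return inc, mort
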