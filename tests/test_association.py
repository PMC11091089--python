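import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prsgxe.association import (
    ModelFitError,
    cochran_q,
    fit_cell_model,
    joint_or_table,
    stratified_or,
    trend_test,
)
from prsgxe.interaction import fit_interaction_models
from prsgxe.simulate import SimConfig

from conftest import analysis_frame


@pytest.fixture(scope="module")
def cell_fit(medium_cc):
    data, _ = medium_cc
    return data, fit_cell_model(data, "any")


class TestJointORTable:
    def test_reference_cell_fixed_at_one(self, cell_fit):
        _, fit = cell_fit
        grid = joint_or_table(fit).grid
        ref = grid.query("quartile == 1 and exposed == 0").iloc[0]
        assert ref["or"] == 1.0 and ref["ci_low"] == 1.0 and ref["ci_high"] == 1.0

    def test_ci_bounds_reproduce_wald_formula(self, cell_fit):
        _, fit = cell_fit
        grid = joint_or_table(fit).grid
        for _, row in grid.iloc[1:].iterrows():
            assert row["ci_low"] == pytest.approx(np.exp(row["log_or"] - 1.96 * row["se"]))
            assert row["ci_high"] == pytest.approx(np.exp(row["log_or"] + 1.96 * row["se"]))
            assert row["ci_low"] <= row["or"] <= row["ci_high"]

    def test_recovers_simulated_cell_truths(self, medium_cc):
        data, truth = medium_cc
        grid = joint_or_table(fit_cell_model(data, "any")).grid
        for _, row in grid.iloc[1:].iterrows():
            b_true = truth.cell_logor[int(row["quartile"]) - 1, int(row["exposed"])]
            assert abs(row["log_or"] - b_true) < 3.5 * row["se"]

    def test_empty_cell_is_error_naming_cell(self, medium_cc):
        data, _ = medium_cc
        broken = data.copy()
        broken = broken.loc[~((broken["prs_q"] == 4) & (broken["mht_any"] == 1))]
        with pytest.raises(ModelFitError, match="cell_q4_e1"):
            fit_cell_model(broken, "any")

    def test_irrelevant_covariates_leave_cell_logors_unchanged(self):
        # covariate-free simulation: adding the (inert) covariates to the
        # model must not move the cell estimates materially (the two fits
        # coincide in the population; at n ~ 12,000 the perturbation is
        # an order of magnitude below the estimates' standard errors)
        from prsgxe.association import _fit_logit, cell_design

        config = SimConfig(n_population=15_000, n_cases=3_000, n_controls=4_000,
                           n_variants=40, seed=17, age_logor=0.0, bmi_logor=0.0,
                           study_intercepts=(0.0,) * 5)
        data, _ = analysis_frame(config, 3_000, 4_000)
        adjusted = joint_or_table(fit_cell_model(data, "any")).grid
        sub, X, cells = cell_design(data, "any")
        crude = _fit_logit(sub["case_status"], X[cells], "cells only")
        diff = adjusted["log_or"].iloc[1:].to_numpy() - crude.params[cells].to_numpy()
        assert np.abs(diff).max() < 0.01


class TestStratifiedOR:
    def test_saturated_identity_exact_on_coefficients(self, cell_fit):
        _, fit = cell_fit
        table = joint_or_table(fit)
        strat = stratified_or(table)
        logs = {(int(r["quartile"]), int(r["exposed"])): r["log_or"]
                for _, r in table.grid.iterrows()}
        for _, row in strat["exposure_within_quartile"].iterrows():
            k = int(row["quartile"])
            assert row["log_or"] == pytest.approx(logs[(k, 1)] - logs[(k, 0)], abs=1e-12)
        for _, row in strat["quartile_within_stratum"].iterrows():
            k, e = int(row["quartile"]), int(row["exposed"])
            assert row["log_or"] == pytest.approx(logs[(k, e)] - logs[(1, e)], abs=1e-12)

    def test_identical_cells_give_or_one(self, cell_fit):
        _, fit = cell_fit
        strat = stratified_or(joint_or_table(fit))
        # Q1 exposure contrast vs reference is the (1,1) cell itself
        row = strat["exposure_within_quartile"].query("quartile == 1").iloc[0]
        cell = joint_or_table(fit).grid.query("quartile == 1 and exposed == 1").iloc[0]
        assert row["or"] == pytest.approx(cell["or"], rel=1e-12)

    def test_reparameterization_invariance(self, cell_fit):
        # the cell model and the main-effects + product-terms model are the
        # same model in different coordinates: identical likelihood and
        # identical fitted cell log-ORs
        data, fit = cell_fit
        full, _ = fit_interaction_models(data, "any")
        assert full.llf == pytest.approx(fit.llf, abs=1e-5)
        b = full.params
        cell_q4_e1 = b["prsq4"] + b["exposed"] + b["prsq4_x_exposed"]
        assert cell_q4_e1 == pytest.approx(fit.params["cell_q4_e1"], abs=1e-5)


class TestTrend:
    def test_detects_log_linear_quartile_effect(self):
        # power: with a 0.35-per-quartile log-linear effect the trend test
        # rejects in every replicate, and the mean slope recovers the truth
        coefs, pvals = [], []
        for seed in range(8):
            config = SimConfig(n_population=20_000, n_cases=4_000, n_controls=5_000,
                               n_variants=40, seed=seed,
                               quartile_logors=(0.35, 0.70, 1.05),
                               true_interaction=(0.0, 0.0, 0.0))
            data, _ = analysis_frame(config, 4_000, 5_000)
            res = trend_test(data, "any", stratum=0)
            coefs.append(res.coef)
            pvals.append(res.p)
        assert max(pvals) < 0.05
        assert np.mean(coefs) == pytest.approx(0.35, abs=0.05)

    def test_null_calibration_under_permutation(self, medium_cc, rng):
        data, _ = medium_cc
        sub = data.sample(n=2_000, random_state=3).copy()
        pvals = []
        for _ in range(40):
            sub["case_status"] = rng.permutation(sub["case_status"].to_numpy())
            pvals.append(trend_test(sub, "any", stratum=0).p)
        # permutation kills the trend: p-values roughly uniform
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_missing_quartile_is_error(self, medium_cc):
        data, _ = medium_cc
        broken = data.loc[data["prs_q"] != 4]
        with pytest.raises(ValueError, match="quartile"):
            trend_test(broken, "any", stratum=0)


class TestCochranQ:
    def test_identical_estimates_give_zero_q(self):
        res = cochran_q([0.3, 0.3, 0.3], [0.1, 0.2, 0.15])
        assert res.q == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_study_analytic_case(self):
        res = cochran_q([0.0, 1.0], [1.0, 1.0])
        assert res.pooled == pytest.approx(0.5)
        assert res.q == pytest.approx(0.5)
        assert res.df == 1

    def test_matches_explicit_summation_oracle(self, rng):
        b = rng.normal(size=5)
        s = rng.uniform(0.05, 0.5, size=5)
        res = cochran_q(b, s)
        w = 1 / s**2
        pooled = np.sum(w * b) / np.sum(w)
        q = float(np.sum(w * (b - pooled) ** 2))
        assert res.q == pytest.approx(q, abs=1e-12)
        assert res.p == pytest.approx(stats.chi2.sf(q, 4), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cochran_q([0.1, 0.2], [0.0, 0.1])
        with pytest.raises(ValueError, match="2 studies"):
            cochran_q([0.1], [0.1])
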