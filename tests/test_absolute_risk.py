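import numpy as np
import pandas as pd
import pytest

from prsgxe.absolute_risk import (
    AGE_GROUPS,
    PROFILES,
    age_group_of,
    annual_rates,
    attributable_proportion,
    baseline_hazard,
    bootstrap_risks,
    cumulative_risk,
    estimate_age_group_rr,
    project_risks,
    risk_difference,
    validate_rate_table,
)
from prsgxe.simulate import simulate_rate_tables


def rate_table(rate, lo=50, hi=85):
    return pd.DataFrame({"age_start": [lo], "age_end": [hi], "rate_per_100k": [rate]})


def microsimulate(rr_by_group, lambda0, mort, n, seed):
    """Individual-level annual competing-risk simulation (oracle)."""
    rng = np.random.default_rng(seed)
    alive = np.ones(n, dtype=bool)
    got_crc = np.zeros(n, dtype=bool)
    for i, a in enumerate(range(50, 80)):
        g = age_group_of(a + 1)
        h_crc = rr_by_group[g] * lambda0[i]
        h = h_crc + mort[i]
        if h == 0:
            continue
        p_event = 1.0 - np.exp(-h)
        u = rng.random(n)
        crc = alive & (u < p_event * h_crc / h)
        dead = alive & ~crc & (u < p_event)
        got_crc |= crc
        alive &= ~(crc | dead)
    return 100.0 * got_crc.mean()


class TestAttributableProportion:
    def test_all_rr_one_gives_zero(self):
        rr = {(k, e): 1.0 for k, e in PROFILES}
        assert attributable_proportion([(1, 0)] * 10, rr) == 0.0

    def test_all_cases_at_rr_two_gives_half(self):
        rr = {(4, 1): 2.0}
        assert attributable_proportion([(4, 1)] * 7, rr) == pytest.approx(0.5)

    def test_matches_explicit_loop_oracle(self, rng):
        rr = {p: float(r) for p, r in zip(PROFILES, rng.uniform(0.5, 4.0, len(PROFILES)))}
        cases = [PROFILES[i] for i in rng.integers(0, len(PROFILES), size=200)]
        expected = 1.0 - sum(1.0 / rr[c] for c in cases) / len(cases)
        assert attributable_proportion(cases, rr) == pytest.approx(expected, abs=1e-12)

    def test_empty_case_set_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            attributable_proportion([], {})


class TestRateTables:
    def test_gap_between_bands_rejected(self):
        t = pd.DataFrame({"age_start": [50, 62], "age_end": [60, 85],
                          "rate_per_100k": [10.0, 10.0]})
        with pytest.raises(ValueError, match="contiguous"):
            validate_rate_table(t)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            validate_rate_table(rate_table(-5.0))

    def test_partial_coverage_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            validate_rate_table(rate_table(10.0, lo=55))

    def test_annual_expansion_is_piecewise_constant(self):
        inc, _ = simulate_rate_tables()
        annual = annual_rates(inc)
        assert annual.shape == (30,)
        assert annual[0] == pytest.approx(60.0 / 1e5)
        assert annual[14] == pytest.approx(130.0 / 1e5)   # age 64 in the 60-65 band


class TestBaselineHazard:
    def _agerr(self, ap):
        from prsgxe.absolute_risk import AgeGroupRR
        rr = [{(k, e): 1.0 for k, e in PROFILES} for _ in AGE_GROUPS]
        return AgeGroupRR(rr=rr, ap=np.asarray(ap))

    def test_zero_ap_returns_composite_incidence(self):
        inc, _ = simulate_rate_tables()
        lam0 = baseline_hazard(inc, self._agerr([0.0, 0.0, 0.0]))
        assert np.allclose(lam0, annual_rates(inc))

    def test_half_ap_halves_rate(self):
        lam0 = baseline_hazard(rate_table(100.0), self._agerr([0.5, 0.5, 0.5]))
        assert np.allclose(lam0, 0.0005)

    def test_composite_incidence_reconstructed_exactly(self):
        # population profile counts and RRs; cases distributed
        # proportionally to count x RR; then lambda0 * E_pop[RR] must give
        # back the composite incidence (consistency of the AP estimator)
        rr = {(1, 0): 1.0, (2, 0): 2.0, (3, 0): 0.5, (4, 0): 4.0}
        pop = {(1, 0): 10, (2, 0): 20, (3, 0): 30, (4, 0): 40}
        cases = []
        for p in rr:
            cases += [p] * int(pop[p] * rr[p] * 2)   # integer counts
        ap = attributable_proportion(cases, rr)
        mean_rr = sum(pop[p] * rr[p] for p in rr) / sum(pop.values())
        incidence = 123.0 / 1e5
        lam0 = incidence * (1.0 - ap)
        assert lam0 * mean_rr == pytest.approx(incidence, abs=1e-10)


class TestCumulativeRisk:
    def test_zero_incidence_gives_zero(self):
        lam0 = np.zeros(30)
        assert cumulative_risk([1, 1, 1], lam0, rate_table(100.0)) == 0.0

    def test_constant_hazard_closed_form(self):
        lam0 = np.full(30, 0.001)
        risk = cumulative_risk([1, 1, 1], lam0, rate_table(0.0))
        assert risk == pytest.approx(100 * (1 - np.exp(-0.03)), abs=1e-9)

    def test_monotone_in_horizon(self):
        inc, mort = simulate_rate_tables()
        lam0 = annual_rates(inc)
        risks = [cumulative_risk([1, 1, 1], lam0[: end - 50], mort, 50, end)
                 for end in (60, 70, 80)]
        assert risks[0] < risks[1] < risks[2]

    def test_decreasing_in_competing_mortality(self):
        lam0 = np.full(30, 0.002)
        low = cumulative_risk([1, 1, 1], lam0, rate_table(100.0))
        high = cumulative_risk([1, 1, 1], lam0, rate_table(20_000.0))
        assert high < low

    def test_age_increasing_incidence_beats_constant_age50_rate(self):
        rising = pd.DataFrame({"age_start": [50, 60, 70], "age_end": [60, 70, 85],
                               "rate_per_100k": [100.0, 200.0, 400.0]})
        flat = rate_table(100.0)
        mort = rate_table(0.0)
        r_rising = cumulative_risk([1, 1, 1], annual_rates(rising), mort)
        r_flat = cumulative_risk([1, 1, 1], annual_rates(flat), mort)
        assert r_rising > r_flat

    def test_matches_microsimulation_oracle(self):
        inc, mort = simulate_rate_tables()
        lam0 = annual_rates(inc) * 0.7
        rr = [1.4, 2.1, 2.9]
        analytic = cumulative_risk(rr, lam0, mort)
        n = 300_000
        sim = microsimulate(rr, lam0, annual_rates(mort), n, seed=8)
        se = 100 * np.sqrt((analytic / 100) * (1 - analytic / 100) / n)
        assert abs(analytic - sim) < 2 * se

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            cumulative_risk([1, 1, 1], np.full(30, -0.001), rate_table(0.0))


@pytest.fixture(scope="module")
def risks(medium_cc):
    data, _ = medium_cc
    inc, mort = simulate_rate_tables()
    return project_risks(data, inc, mort), data, inc, mort


class TestProjectionAndBootstrap:
    def test_all_risks_within_bounds(self, risks):
        table, *_ = risks
        assert table["risk"].between(0, 100).all()

    def test_referent_profile_between_extremes(self, risks):
        table, *_ = risks
        ref = table.query("quartile == 1 and exposed == 0")["risk"].iloc[0]
        assert table["risk"].min() <= ref <= table["risk"].max()

    def test_age_group_rr_structure(self, medium_cc):
        data, _ = medium_cc
        agerr = estimate_age_group_rr(data, "any")
        for g in range(3):
            assert agerr.rr[g][(1, 0)] == 1.0
        assert np.all(agerr.ap < 1.0)

    def test_bootstrap_deterministic_given_seed(self, risks):
        _, data, inc, mort = risks
        b1 = bootstrap_risks(data, inc, mort, b=8, seed=5)
        b2 = bootstrap_risks(data, inc, mort, b=8, seed=5)
        assert np.array_equal(b1.replicates, b2.replicates)
        pd.testing.assert_frame_equal(b1.table, b2.table)

    def test_normal_ci_arithmetic(self, risks):
        _, data, inc, mort = risks
        boot = bootstrap_risks(data, inc, mort, b=8, seed=5)
        t = boot.table
        assert np.allclose(t["ci_low"], np.clip(t["risk"] - 1.96 * t["se_boot"], 0, 100))
        assert np.allclose(t["ci_high"], np.clip(t["risk"] + 1.96 * t["se_boot"], 0, 100))

    def test_percentile_ci_option(self, risks):
        _, data, inc, mort = risks
        boot = bootstrap_risks(data, inc, mort, b=8, seed=5, ci_method="percentile")
        assert (boot.table["ci_low"] <= boot.table["ci_high"]).all()

    def test_b_below_two_rejected(self, risks):
        _, data, inc, mort = risks
        with pytest.raises(ValueError, match="B >= 2"):
            bootstrap_risks(data, inc, mort, b=1, seed=0)


class TestRiskDifference:
    def test_difference_of_points(self, rng):
        reps0 = rng.normal(6.0, 0.3, size=100)
        reps1 = rng.normal(3.7, 0.3, size=100)
        res = risk_difference(6.1, 3.7, reps0, reps1)
        assert res.difference == pytest.approx(2.4)
        assert res.p < 1e-6 and not res.degenerate

    def test_identical_replicate_streams_flagged_degenerate(self):
        reps = np.linspace(1, 2, 50)
        res = risk_difference(1.5, 1.5, reps, reps)
        assert res.degenerate and res.se == 0.0
        assert np.isnan(res.p)

    def test_mismatched_replicates_rejected(self):
        with pytest.raises(ValueError, match="length"):
            risk_difference(1.0, 2.0, np.zeros(10), np.zeros(9))
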