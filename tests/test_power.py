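"""Closed-form power engine: published values, oracles, and invariants."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmrct import (
    DesignParams,
    InvalidDesignError,
    InvalidPoolError,
    PoolSpec,
    analytic_power,
    cmrct_sample_size,
    design_report,
    detectable_effect,
    effect_rescale,
    min_consent_rate,
    min_eligible_pool,
    prct_sample_size,
    round_half_up,
)

from conftest import mc_power_oracle

P = DesignParams()  # alpha .05, power .80, d .25, a .25, rho .5


class TestAnalyticPower:
    def test_null_effect_gives_half_alpha(self):
        assert analytic_power(0.0, 100, 100, P) == pytest.approx(0.025, abs=1e-6)

    def test_published_balanced_cell(self):
        # 653 vs 653 detects 0.155 at ~80% power
        assert analytic_power(0.155, 653, 653, P) == pytest.approx(0.80, abs=0.005)

    def test_agrees_with_simulation_oracle(self):
        # Independent ANCOVA Monte-Carlo at the conventional per-arm size
        analytic = analytic_power(0.25, 252, 252, P)
        assert round(analytic, 3) == 0.801
        oracle = mc_power_oracle(0.25, 252, 252, R=20_000)
        assert abs(analytic - oracle) < 3 * math.sqrt(0.8 * 0.2 / 20_000) + 0.003

    def test_symmetric_in_arms(self):
        assert analytic_power(0.2, 504, 802, P) == pytest.approx(
            analytic_power(0.2, 802, 504, P), abs=1e-15)

    def test_monotone_in_effect_and_arms(self):
        base = analytic_power(0.2, 300, 500, P)
        assert analytic_power(0.25, 300, 500, P) > base
        assert analytic_power(0.2, 400, 500, P) > base
        assert analytic_power(0.2, 300, 600, P) > base

    def test_rejects_degenerate_arms(self):
        with pytest.raises(InvalidDesignError):
            analytic_power(0.2, 1, 100, P)
        with pytest.raises(InvalidDesignError):
            analytic_power(-0.1, 100, 100, P)


class TestDetectableEffect:
    def test_published_balanced_value(self):
        assert round_half_up(detectable_effect(653, 653, P), 3) == 0.155

    def test_unbalanced_realized_design(self):
        # 504 offered vs 802 controls, solved by numeric root of the power curve
        d = detectable_effect(504, 802, P)
        assert d == pytest.approx(0.1592, abs=5e-4)
        assert analytic_power(d, 504, 802, P) == pytest.approx(0.80, abs=1e-10)

    def test_symmetry(self):
        assert detectable_effect(802, 504, P) == detectable_effect(504, 802, P)

    @pytest.mark.parametrize("E", [10, 100, 1306])
    def test_minimized_at_balanced_split(self, E):
        n1 = np.arange(2, E - 1)
        d = np.array([detectable_effect(int(k), E - int(k), P) for k in n1])
        assert n1[np.argmin(d)] == E // 2

    @given(st.integers(10, 2000), st.integers(10, 2000),
           st.floats(0.01, 0.2), st.floats(0.5, 0.95))
    def test_inverse_of_power(self, n1, n2, alpha, target):
        params = dataclasses.replace(P, alpha=alpha, power_target=target)
        d = detectable_effect(n1, n2, params)
        assert analytic_power(d, n1, n2, params) == pytest.approx(
            target, abs=1e-10)

    def test_adjustment_attrition_cancellation(self):
        # (1 - rho^2)/(1 - a) = 1 at the defaults, so baseline-adjusted
        # results equal the unadjusted, no-attrition ones exactly.
        bare = dataclasses.replace(P, attrition=0.0, analysis_mode="unadjusted")
        for n1, n2 in [(653, 653), (504, 802), (139, 1167)]:
            assert detectable_effect(n1, n2, P) == pytest.approx(
                detectable_effect(n1, n2, bare), abs=1e-12)


class TestEffectRescale:
    @pytest.mark.parametrize("d,c,expected,dp", [
        (0.5, 0.41, 0.21, 2),   # worked mixture example: 0.5*0.41 + 0*0.59
        (0.25, 0.62, 0.155, 3),
    ])
    def test_dilution_examples(self, d, c, expected, dp):
        assert round_half_up(effect_rescale(d, c, "dilute"), dp) == expected

    @given(st.floats(0.01, 2.0), st.floats(0.01, 1.0))
    def test_roundtrip_identity(self, d, c):
        assert effect_rescale(effect_rescale(d, c, "dilute"), c,
                              "undilute") == pytest.approx(d, rel=1e-12)

    def test_full_consent_identity(self):
        assert effect_rescale(0.37, 1.0, "dilute") == 0.37

    def test_invalid_consent(self):
        with pytest.raises(InvalidDesignError):
            effect_rescale(0.2, 0.0, "dilute")


class TestCmrctSampleSize:
    def test_62pct_row_feasible_with_published_effect(self, motivating_pool):
        params = dataclasses.replace(P, consent_rate=0.62)
        plan = cmrct_sample_size(motivating_pool, params)
        assert plan.feasible
        assert round_half_up(plan.detectable_offer_effect, 3) <= 0.155
        assert plan.n_offered + plan.n_control == 1306
        # The balanced split itself passes the printed-precision check
        assert round_half_up(detectable_effect(653, 653, params), 3) == 0.155

    def test_60pct_consent_infeasible(self, motivating_pool):
        params = dataclasses.replace(P, consent_rate=0.60)
        plan = cmrct_sample_size(motivating_pool, params)
        assert not plan.feasible
        assert plan.n_offered == 653  # balanced fallback
        assert plan.achieved_power < 0.80

    def test_full_consent_near_published_count(self, motivating_pool):
        params = dataclasses.replace(P, consent_rate=1.0)
        plan = cmrct_sample_size(motivating_pool, params)
        # Exhaustive-scan strict search lands within +4 of the published 139
        assert 139 <= plan.n_offered <= 143
        assert plan.achieved_power == pytest.approx(0.80, abs=0.005)

    def test_consent_effect_relation(self, motivating_pool):
        params = dataclasses.replace(P, consent_rate=0.7)
        plan = cmrct_sample_size(motivating_pool, params)
        assert plan.detectable_consent_effect == pytest.approx(
            plan.detectable_offer_effect / 0.7, rel=1e-12)
        assert plan.expected_consenters == round(0.7 * plan.n_offered)

    def test_large_pool_limit_halves_prct_arm(self):
        # With effectively unlimited controls the comparison variance is
        # sigma^2/n1 instead of 2 sigma^2/n, so the required treated arm
        # converges to half the balanced per-arm size.
        params = dataclasses.replace(P, consent_rate=1.0)
        big = PoolSpec(cohort_size=10 ** 6, eligible_count=10 ** 6)
        plan = cmrct_sample_size(big, params)
        per_arm = prct_sample_size(params).per_arm
        assert abs(plan.n_offered - math.ceil(per_arm / 2)) <= 1

    def test_tiny_pool_rejected(self):
        with pytest.raises(InvalidPoolError):
            cmrct_sample_size(PoolSpec(cohort_size=10, eligible_count=3), P)


class TestMinConsentRate:
    def test_published_threshold(self, motivating_pool):
        assert min_consent_rate(motivating_pool, P) == 62

    def test_below_threshold_is_infeasible(self, motivating_pool):
        params = dataclasses.replace(P, consent_rate=0.61)
        assert not cmrct_sample_size(motivating_pool, params).feasible

    def test_larger_effect_halves_threshold(self, motivating_pool):
        params = dataclasses.replace(P, d_consent=0.5)
        assert min_consent_rate(motivating_pool, params) == 31

    def test_vanishes_for_huge_pools(self):
        huge = PoolSpec(cohort_size=10 ** 7, eligible_count=10 ** 7)
        assert min_consent_rate(huge, P) <= 1


class TestPrctSampleSize:
    def test_published_plan(self):
        plan = prct_sample_size(dataclasses.replace(P, consent_rate=1.0))
        assert (plan.per_arm, plan.n_consented, plan.n_invited) == (252, 504, 504)

    @pytest.mark.parametrize("c,invited", [
        (0.9, 560), (0.8, 630), (0.7, 720), (0.62, 813),
        (0.6, 840), (0.5, 1008), (0.4, 1260),
    ])
    def test_published_invited_column(self, c, invited):
        plan = prct_sample_size(dataclasses.replace(P, consent_rate=c))
        assert plan.n_invited == invited
        assert plan.n_consented == 504  # independent of consent rate
        assert plan.n_invited >= plan.n_consented


class TestMinEligiblePool:
    def test_scan_oracle_balanced_full_consent(self):
        params = dataclasses.replace(P, consent_rate=1.0)
        assert min_eligible_pool(params, 0.5) == 503

    def test_matches_brute_force_scan(self):
        # Independent oracle: scan E directly with the power function in
        # cohort-requirement mode (no attrition, unadjusted variance).
        params = dataclasses.replace(P, consent_rate=0.8, d_consent=0.3)
        f = 0.3
        mode = dataclasses.replace(params, attrition=0.0,
                                   analysis_mode="unadjusted")
        target = 0.8 * 0.3
        expected = next(
            E for E in range(4, 10 ** 5)
            if analytic_power(
                target,
                min(max(int(np.rint(f * E)), 2), E - 2),
                E - min(max(int(np.rint(f * E)), 2), E - 2),
                mode) >= 0.80 - 1e-12)
        assert min_eligible_pool(params, f) == expected

    def test_inverse_square_effect_scaling(self):
        big = min_eligible_pool(dataclasses.replace(P, consent_rate=1.0,
                                                    d_consent=0.25), 0.5)
        small = min_eligible_pool(dataclasses.replace(P, consent_rate=1.0,
                                                      d_consent=0.5), 0.5)
        assert big / small == pytest.approx(4.0, rel=0.05)

    def test_consent_dilution_scaling(self):
        # halving consent squares into the 1/d^2 scaling: ~4x larger pool
        # (up to the integer rounding of the offered count)
        full = min_eligible_pool(dataclasses.replace(P, consent_rate=1.0), 0.25)
        half = min_eligible_pool(dataclasses.replace(P, consent_rate=0.5), 0.25)
        assert half / full == pytest.approx(4.0, rel=0.01)

    def test_monotone_and_minimized_at_balance(self):
        pools = [min_eligible_pool(dataclasses.replace(P, consent_rate=c), 0.5)
                 for c in (0.4, 0.6, 0.8, 1.0)]
        assert pools == sorted(pools, reverse=True)
        by_f = [min_eligible_pool(dataclasses.replace(P, consent_rate=0.8), f)
                for f in (0.1, 0.25, 0.4, 0.5)]
        assert by_f == sorted(by_f, reverse=True)

    def test_rejects_oversized_fraction(self):
        with pytest.raises(InvalidDesignError):
            min_eligible_pool(P, 0.7)


class TestDesignReport:
    def test_published_table_structure(self, motivating_pool):
        grid = [1.0, 0.9, 0.8, 0.7, 0.62, 0.6, 0.5, 0.4]
        df = design_report(motivating_pool, P, grid)
        assert len(df) == 8
        row62 = df[df.consent_pct == 62].iloc[0]
        assert row62.cmrct_effect == 0.155
        assert row62.cmrct_feasible
        assert (df.prct_consented == 504).all()
        infeasible = df[df.consent_pct.isin([60, 50, 40])]
        assert (~infeasible.cmrct_feasible).all()
        assert infeasible.cmrct_selected.isna().all()
        feasible = df[df.cmrct_feasible]
        assert (feasible.cmrct_treatment_arm
                + feasible.cmrct_control_arm == 1306).all()

    def test_empty_grid_rejected(self, motivating_pool):
        with pytest.raises(InvalidDesignError):
            design_report(motivating_pool, P, [])


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        {"alpha": 0.0}, {"power_target": 1.0}, {"consent_rate": 1.5},
        {"attrition": 1.0}, {"rho": -0.1}, {"d_consent": 0.0},
        {"analysis_mode": "anova"},
    ])
    def test_out_of_range_rejected(self, kw):
        with pytest.raises(InvalidDesignError) as exc:
            DesignParams(**kw)
        assert list(kw)[0] in str(exc.value)

    def test_pool_consistency(self):
        with pytest.raises(InvalidPoolError):
            PoolSpec(cohort_size=100, eligible_count=200)
        assert PoolSpec(cohort_size=4377, eligible_count=None,
                        eligibility_rate=0.2984).n_eligible == 1306
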