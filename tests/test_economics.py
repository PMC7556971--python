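"""Discounting, adverse-event burdens, accumulation, incremental results."""

import math

import numpy as np
import pytest

from fruqcea import (
    ArmResult,
    CostSchedule,
    StateTrace,
    accumulate,
    ae_burden,
    compute_icer,
    discount_factor,
    evaluate,
    net_monetary_benefit,
)

CYCLE_YEARS = 28.0 / 365.25


class TestDiscountFactor:
    def test_cycle_zero_undiscounted(self):
        assert discount_factor(0, 0.03) == 1.0

    def test_zero_rate_undiscounted(self):
        assert discount_factor(57, 0.0) == 1.0

    def test_one_year_at_three_percent(self):
        assert discount_factor(13, 0.03) == pytest.approx(1.03 ** (-364 / 365.25), rel=1e-12)
        assert discount_factor(13, 0.03) == pytest.approx(0.9709, abs=2e-4)

    def test_monotone_decreasing_in_time_and_rate(self):
        f = discount_factor(np.arange(50), 0.03)
        assert np.all(np.diff(f) < 0)
        assert discount_factor(10, 0.05) < discount_factor(10, 0.03)


class TestAEBurden:
    def test_treated_arm_burden_matches_direct_sum(self, params):
        cost, qaly_loss = ae_burden(params.ae_profiles("fruquintinib"))
        expected_cost = 0.212 * 59.1 + 0.108 * 134.4 + 0.029 * 844.3 + 0.025 * 3551.7
        expected_loss = (0.108 * 0.116 * 14 + 0.029 * 0.103 * 5) / 365.25
        assert cost == pytest.approx(expected_cost, rel=1e-12)
        assert cost == pytest.approx(140.3, abs=0.05)
        assert qaly_loss == pytest.approx(expected_loss, rel=1e-12)
        assert qaly_loss == pytest.approx(5.2e-4, abs=1e-5)

    def test_comparator_arm_burden_is_hypertension_only(self, params):
        cost, qaly_loss = ae_burden(params.ae_profiles("placebo"))
        assert cost == pytest.approx(0.022 * 59.1, rel=1e-12)
        assert qaly_loss == 0.0

    def test_values_override_point_estimates(self, params):
        cost0, _ = ae_burden(params.ae_profiles("placebo"))
        cost1, _ = ae_burden(params.ae_profiles("placebo"), {"cost_hypertension": 118.2})
        assert cost1 == pytest.approx(2 * cost0)

    def test_invalid_probability_rejected(self, params):
        with pytest.raises(ValueError, match=r"outside \[0,1\]"):
            ae_burden(params.ae_profiles("placebo"), {"prob_hypertension_bsc": 1.5})


def one_cycle_bsc_trace():
    return StateTrace("placebo", 28.0, on_treatment=[0.0, 0.0], bsc=[1.0, 1.0], dead=[0.0, 0.0])


class TestAccumulate:
    def test_zero_costs_and_utility_give_zero(self):
        trace = one_cycle_bsc_trace()
        res = accumulate(trace, CostSchedule.bsc_only(0.0, 0.0), 0.0, 0.03)
        assert res == ArmResult(0.0, 0.0)

    def test_single_cycle_closed_form(self):
        trace = one_cycle_bsc_trace()
        res = accumulate(trace, CostSchedule.bsc_only(1415.4, 0.0), 0.66, 0.0)
        assert res.cost == pytest.approx(1415.4, rel=1e-12)
        assert res.qaly == pytest.approx(0.66 * CYCLE_YEARS, rel=1e-12)
        assert res.qaly == pytest.approx(0.0506, abs=1e-4)

    def test_arm_mismatch_rejected(self):
        trace = one_cycle_bsc_trace()
        sched = CostSchedule.post_negotiation(1128.8, 1415.4, 0.0, 0.0)
        with pytest.raises(ValueError, match="arm"):
            accumulate(trace, sched, 0.66, 0.03)

    def test_pre_negotiation_charges_only_donation_cycles(self):
        # 7 rows, cohort stays fully on treatment, r=0: drug charged in cycles 1,2,5
        trace = StateTrace("fruquintinib", 28.0, on_treatment=np.ones(7),
                           bsc=np.zeros(7), dead=np.zeros(7))
        sched = CostSchedule.pre_negotiation(3408.5, 0.0, 0.0, 0.0)
        res = accumulate(trace, sched, 0.0, 0.0)
        assert res.cost == pytest.approx(3 * 3408.5, rel=1e-12)

    def test_qaly_bounded_by_utility_times_discounted_life_years(self, params, traces):
        from fruqcea.model import build_schedule

        for arm in ("fruquintinib", "placebo"):
            sched = build_schedule(params, arm)
            res = accumulate(traces[arm], sched, 0.66, 0.03)
            ly = accumulate(traces[arm], CostSchedule(arm=arm), 1.0, 0.03).qaly
            assert res.qaly <= 0.66 * ly + 1e-12

    def test_removing_ae_burden_increases_qaly_and_decreases_cost(self, params):
        base = evaluate(params)
        zeroed = {n: 0.0 for n in params.parameters if n.startswith("prob_")}
        no_ae = evaluate(params, values=zeroed)
        assert no_ae.intervention.qaly > base.intervention.qaly
        # placebo's only adverse event (hypertension) carries zero disutility,
        # so its QALYs are unchanged while costs still drop
        assert no_ae.comparator.qaly == base.comparator.qaly
        assert no_ae.intervention.cost < base.intervention.cost
        assert no_ae.comparator.cost < base.comparator.cost

    def test_higher_discount_rate_shrinks_both_outputs(self, params):
        lo = evaluate(params, values={"discount_rate_annual": 0.0})
        hi = evaluate(params, values={"discount_rate_annual": 0.05})
        for arm in ("intervention", "comparator"):
            assert getattr(hi, arm).cost < getattr(lo, arm).cost
            assert getattr(hi, arm).qaly < getattr(lo, arm).qaly


class TestIncrementalResults:
    def test_published_post_negotiation_arithmetic(self):
        ce = compute_icer(ArmResult(20750.9, 0.6404), ArmResult(12042.2, 0.4776))
        assert ce.incremental_cost == pytest.approx(8708.7, abs=1e-9)
        assert ce.incremental_effect == pytest.approx(0.1628, abs=1e-12)
        assert ce.icer == pytest.approx(5.35e4, rel=2e-3)
        assert ce.quadrant == "tradeoff"

    def test_published_pre_negotiation_arithmetic(self):
        ce = compute_icer(ArmResult(23590.0, 0.6404), ArmResult(12042.2, 0.4776))
        assert ce.incremental_cost == pytest.approx(11547.8, abs=1e-9)
        assert ce.icer == pytest.approx(7.10e4, rel=2e-3)

    def test_identical_arms_are_indifferent(self):
        ce = compute_icer(ArmResult(100.0, 0.5), ArmResult(100.0, 0.5))
        assert ce.incremental_cost == 0.0 and ce.incremental_effect == 0.0
        assert math.isnan(ce.icer)
        assert ce.quadrant == "indifferent"

    def test_dominance_labels(self):
        assert compute_icer(ArmResult(50.0, 0.6), ArmResult(100.0, 0.5)).quadrant == "dominant"
        assert compute_icer(ArmResult(150.0, 0.4), ArmResult(100.0, 0.5)).quadrant == "dominated"

    def test_antisymmetric_under_arm_swap(self):
        a, b = ArmResult(20750.9, 0.6404), ArmResult(12042.2, 0.4776)
        fwd, rev = compute_icer(a, b), compute_icer(b, a)
        assert rev.incremental_cost == -fwd.incremental_cost
        assert rev.incremental_effect == -fwd.incremental_effect
        assert rev.icer == pytest.approx(fwd.icer, rel=1e-12)

    def test_net_monetary_benefit_properties(self):
        ce = compute_icer(ArmResult(20750.9, 0.6404), ArmResult(12042.2, 0.4776))
        assert net_monetary_benefit(ce, 0.0) == -ce.incremental_cost
        assert net_monetary_benefit(ce, ce.icer) == pytest.approx(0.0, abs=1e-8)
        # not cost-effective at three-times-GDP threshold
        assert net_monetary_benefit(ce, 27130.0) < 0
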