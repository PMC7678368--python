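"""Cost and QALY accrual, discounting, dosing bands and comparisons."""

import numpy as np
import pytest

from cavte.economics import (
    ArmResult,
    UncoveredWeightBandError,
    compare,
    dalteparin_band,
    discount_factor,
    drug_cost_for_cycle,
    evaluate_arm,
    qalys_to_days,
    weight_from_bmi,
)
from cavte.markov_engine import run_cohort
from cavte.parameters import MortalityTable, rate_key
from cavte.synthetic_data import base_config


class TestDiscounting:
    def test_cycle_zero_undiscounted(self, cfg):
        assert discount_factor(0.04, 0, cfg) == 1.0

    def test_one_year_at_four_percent(self, cfg):
        assert discount_factor(0.04, 12, cfg) == pytest.approx(1 / 1.04)

    def test_zero_rate_never_discounts(self, cfg):
        assert all(discount_factor(0.0, c, cfg) == 1.0 for c in range(60))

    def test_negative_rate_rejected(self, cfg):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 5, cfg)

    def test_discounted_totals_bounded_by_undiscounted(self, fixture_ps, cfg):
        cfg0 = cfg.model_copy(
            update={"discount_rate_costs_annual": 0.0, "discount_rate_qalys_annual": 0.0}
        )
        disc = evaluate_arm(fixture_ps, cfg, "rivaroxaban")
        undisc = evaluate_arm(fixture_ps, cfg0, "rivaroxaban")
        assert disc.total_cost <= undisc.total_cost
        assert disc.total_qalys <= undisc.total_qalys


class TestWeightAndDosing:
    def test_cohort_average_weight_selects_middle_band(self):
        weight = weight_from_bmi(25.6, 1.72)
        assert 69 <= weight <= 82
        assert dalteparin_band(weight) == ("69-82", 15000, 12500)

    def test_unit_height_identity(self):
        assert weight_from_bmi(25.6, 1.0) == 25.6

    def test_low_and_high_bands(self):
        assert dalteparin_band(60) == ("57-68", 12500, 10000)
        assert dalteparin_band(90) == ("83-98", 18000, 15000)
        assert dalteparin_band(weight_from_bmi(25.6, 1.50))[0] == "57-68"

    def test_uncovered_weight_rejected(self):
        with pytest.raises(UncoveredWeightBandError):
            dalteparin_band(56)
        with pytest.raises(UncoveredWeightBandError):
            dalteparin_band(120)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            weight_from_bmi(0, 1.72)


class TestDrugCosts:
    def test_outside_treatment_window_costs_nothing(self, fixture_ps, cfg):
        sched = fixture_ps.drug_schedules["rivaroxaban"]
        assert drug_cost_for_cycle("rivaroxaban", 6, sched, cfg).total == 0.0
        assert drug_cost_for_cycle("rivaroxaban", -1, sched, cfg).total == 0.0

    def test_loading_dose_calendar_arithmetic(self, fixture_ps, cfg):
        sched = fixture_ps.drug_schedules["rivaroxaban"]
        cost = drug_cost_for_cycle("rivaroxaban", 0, sched, cfg)
        units = 21 * 2 + (cfg.days_per_month - 21) * 1
        assert cost.drug == pytest.approx(units * sched.unit_price)

    def test_maintenance_month(self, fixture_ps, cfg):
        sched = fixture_ps.drug_schedules["rivaroxaban"]
        cost = drug_cost_for_cycle("rivaroxaban", 3, sched, cfg)
        assert cost.drug == pytest.approx(cfg.days_per_month * sched.unit_price)

    def test_dalteparin_daily_injection_months_2_to_6(self, fixture_ps, cfg):
        sched = fixture_ps.drug_schedules["dalteparin"]
        cost = drug_cost_for_cycle("dalteparin", 2, sched, cfg)
        assert cost.drug == pytest.approx(cfg.days_per_month * 9.93)
        assert cost.instruction == 0.0

    def test_instruction_charged_at_treatment_start_only(self, fixture_ps, cfg):
        sched = fixture_ps.drug_schedules["dalteparin"]
        assert drug_cost_for_cycle("dalteparin", 0, sched, cfg).instruction > 0
        assert drug_cost_for_cycle("dalteparin", 1, sched, cfg).instruction == 0

    def test_monitoring_amortised_vs_lump(self, fixture_ps, cfg):
        sched = fixture_ps.drug_schedules["rivaroxaban"]
        amortised = sum(
            drug_cost_for_cycle("rivaroxaban", j, sched, cfg).monitoring for j in range(6)
        )
        cfg_lump = cfg.model_copy(update={"renal_monitoring_lump": True})
        lump = sum(
            drug_cost_for_cycle("rivaroxaban", j, sched, cfg_lump).monitoring for j in range(6)
        )
        assert amortised == pytest.approx(sched.monitoring_cost_annual / 2)
        assert lump == pytest.approx(sched.monitoring_cost_annual)


class TestAccrual:
    def test_zero_event_trace_has_treatment_costs_only(self, stress_variants, cfg):
        res = evaluate_arm(stress_variants[0], cfg, "rivaroxaban")
        assert res.cost_breakdown["event"] == pytest.approx(0.0)
        assert res.cost_breakdown["treatment"] > 0
        assert sum(res.event_counts.values()) == 0

    def test_breakdown_partitions_total(self, fixture_ps, cfg):
        res = evaluate_arm(fixture_ps, cfg, "dalteparin")
        assert res.total_cost == pytest.approx(sum(res.cost_breakdown.values()), abs=1e-6)
        assert res.total_cost == pytest.approx(res.cost_cycle_category.sum(), abs=1e-6)

    def test_perspective_switch_removes_exactly_indirect(self, fixture_ps, cfg):
        societal = evaluate_arm(fixture_ps, cfg, "dalteparin")
        payer_cfg = cfg.model_copy(update={"perspective": "healthcare_payer"})
        payer = evaluate_arm(fixture_ps, payer_cfg, "dalteparin")
        assert societal.total_cost - payer.total_cost == pytest.approx(
            societal.cost_breakdown["indirect"], abs=1e-9
        )
        assert societal.total_qalys == payer.total_qalys

    def test_dvt_event_line_hand_arithmetic(self, stress_variants):
        toy = stress_variants[0].model_copy(deep=True)
        for arm in ("rivaroxaban", "dalteparin"):
            for phase in ("on_treatment", "off_treatment"):
                spec = toy.rates[rate_key("vte", arm, phase)]
                spec.form = "monthly_probability"
                spec.horizon_months = None
                spec.value = 0.01
        toy.type_distributions["vte_pooled"].counts = [0.0, 0.0, 1.0, 0.0]  # all DVT
        toy.informal_care.tariff_per_hour = 0.0
        c = toy.costs["dvt_event"].value
        v = toy.costs["travel_per_visit"].value
        cfg1 = base_config().model_copy(
            update={
                "horizon_cycles": 1,
                "treatment_duration_cycles": {"rivaroxaban": 1, "dalteparin": 1},
                "discount_rate_costs_annual": 0.0,
            }
        )
        res = evaluate_arm(toy, cfg1, "dalteparin")
        assert res.event_counts["recurrent_dvt"] == pytest.approx(10.0)
        assert res.cost_by_event_type["recurrent_dvt"] == pytest.approx(10 * c)
        assert res.cost_breakdown["indirect"] == pytest.approx(10 * v)

    def test_fatal_event_cost_equalities(self, fixture_ps, cfg):
        res = evaluate_arm(fixture_ps, cfg, "rivaroxaban")
        sym_per_event = res.cost_by_event_type["recurrent_symptomatic_pe"] / _disc_events(
            res, "recurrent_symptomatic_pe", fixture_ps, cfg
        )
        fatal_per_event = res.cost_by_event_type["fatal_recurrent_vte"] / _disc_events(
            res, "fatal_recurrent_vte", fixture_ps, cfg
        )
        assert sym_per_event == pytest.approx(fatal_per_event)

    def test_incidental_pe_carries_no_event_cost(self, fixture_ps, cfg):
        res = evaluate_arm(fixture_ps, cfg, "rivaroxaban")
        assert res.event_counts["recurrent_incidental_pe"] > 0
        assert res.cost_by_event_type["recurrent_incidental_pe"] == 0.0


def _disc_events(res: ArmResult, event: str, ps, cfg):
    trace = run_cohort(ps, cfg, res.arm)
    return sum(
        trace.events[event][c] * discount_factor(cfg.discount_rate_costs_annual, c, cfg)
        for c in range(cfg.horizon_cycles)
    )


class TestQalys:
    def test_full_health_no_discounting(self, stress_variants):
        toy = stress_variants[0].model_copy(deep=True)
        toy.utilities["baseline"].ci_low = toy.utilities["baseline"].ci_high = None
        toy.utilities["baseline"].value = 1.0
        cfg0 = base_config().model_copy(update={"discount_rate_qalys_annual": 0.0})
        res = evaluate_arm(toy, cfg0, "rivaroxaban")
        assert res.total_qalys / 1000 == pytest.approx(5.0)

    def test_everyone_dead_accrues_zero(self, stress_variants, cfg):
        res = evaluate_arm(stress_variants[1], cfg, "rivaroxaban")
        # only the first cycle (before absorption) contributes
        assert res.qaly_cycle[1:].sum() == pytest.approx(0.0)

    def test_flat_utility_discounted_sum(self, stress_variants):
        toy = stress_variants[0].model_copy(deep=True)
        toy.utilities["baseline"].ci_low = toy.utilities["baseline"].ci_high = None
        toy.utilities["baseline"].value = 0.8
        cfg12 = base_config().model_copy(update={"horizon_cycles": 12, "treatment_duration_cycles": {"rivaroxaban": 6, "dalteparin": 6}})
        res = evaluate_arm(toy, cfg12, "rivaroxaban")
        expect = 0.8 * sum(1.015 ** (-m / 12) for m in range(12)) / 12
        assert res.total_qalys / 1000 == pytest.approx(expect, rel=1e-12)


class TestComparison:
    def _result(self, cost, qalys):
        return ArmResult(
            arm="x", horizon_cycles=60, perspective="societal", total_cost=cost,
            cost_breakdown={}, cost_by_event_type={}, treatment_components={},
            total_qalys=qalys, event_counts={}, cost_cycle_category=np.zeros((60, 3)),
            qaly_cycle=np.zeros(60),
        )

    def test_cheaper_and_better_is_dominant(self):
        comp = compare(self._result(3139, 2.459), self._result(4615, 2.448))
        assert comp.verdict == "dominant_A"
        assert comp.icer is None
        assert comp.delta_cost == pytest.approx(-1476)
        assert comp.delta_qalys == pytest.approx(0.011, abs=0.001)

    def test_identical_arms_equivalent(self):
        comp = compare(self._result(100, 1.0), self._result(100, 1.0))
        assert comp.verdict == "equivalent" and comp.icer is None

    def test_icer_arithmetic(self):
        comp = compare(self._result(1100, 1.1), self._result(100, 1.0))
        assert comp.verdict == "icer_value"
        assert comp.icer == pytest.approx(10000)

    def test_mismatched_horizons_rejected(self):
        a = self._result(1, 1)
        b = self._result(1, 1)
        b.horizon_cycles = 6
        with pytest.raises(ValueError):
            compare(a, b)

    def test_raising_dalteparin_price_increases_savings(self, ps, cfg):
        base = compare(
            evaluate_arm(ps, cfg, "rivaroxaban"), evaluate_arm(ps, cfg, "dalteparin")
        )
        ps.drug_schedules["dalteparin"].unit_price *= 1.5
        dearer = compare(
            evaluate_arm(ps, cfg, "rivaroxaban"), evaluate_arm(ps, cfg, "dalteparin")
        )
        assert dearer.delta_cost < base.delta_cost


class TestQalyDays:
    def test_conversion_examples(self):
        assert qalys_to_days(0.0) == 0.0
        assert qalys_to_days(0.012) == 4.4
        assert qalys_to_days(1.0) == 365.3
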