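"""Discounted cost and QALY accrual over a cohort trace, and deterministic
cost-effectiveness comparison.

Costs fall into three categories mirroring the reporting layout:

* ``event`` — acute care charged in the cycle an event occurs, plus chronic
  monthly care for post-ICH, CTEPH and severe PTS until death.  Incidental
  PE carries no event cost (found on routine imaging, no physician visit);
  fatal recurrent VTE is costed like non-fatal symptomatic PE and fatal
  major bleeding like non-fatal non-ICH major bleeding.
* ``treatment`` — drug dispensing per the phase schedules, renal-function
  monitoring (rivaroxaban), injection instruction and paid administration
  (dalteparin).
* ``indirect`` — informal care after burdensome acute events (restricted to
  the early/locally-advanced cancer subgroup) and travel for renal
  monitoring visits, DVT and CRNMB episodes.  The healthcare-payer
  perspective drops this category; the societal perspective keeps it.

Costs discount at 4%/year and QALYs at 1.5%/year by default (set in
``ModelConfig``).  Utilities are annual weights accrued at 1/12 per cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from cavte.markov_engine import CohortTrace, count_events, run_cohort
from cavte.parameters import DrugSchedule, ModelConfig, ParameterSet

CATEGORIES = ("event", "treatment", "indirect")

#: acute events after which an informal-care package is costed
INFORMAL_CARE_EVENTS = (
    "recurrent_symptomatic_pe",
    "recurrent_dvt",
    "non_ich_mb",
    "ich",
)

#: dalteparin dose bands by body weight: label, lo kg, hi kg, month-1 IU/day,
#: months-2-6 IU/day (as printed in the dosing table)
DALTEPARIN_BANDS = (
    ("57-68", 57.0, 68.0, 12500, 10000),
    ("69-82", 69.0, 82.0, 15000, 12500),
    ("83-98", 83.0, 98.0, 18000, 15000),
)


class UncoveredWeightBandError(ValueError):
    """Weight outside the covered dalteparin dose bands (57-98 kg)."""


@dataclass
class TreatmentCycleCost:
    """Per-patient treatment cost components for one cycle within treatment."""

    drug: float = 0.0
    monitoring: float = 0.0
    instruction: float = 0.0
    administration: float = 0.0

    @property
    def total(self) -> float:
        return self.drug + self.monitoring + self.instruction + self.administration


@dataclass
class ArmResult:
    """Discounted costs (by category and event type), QALYs and event counts."""

    arm: str
    horizon_cycles: int
    perspective: str
    total_cost: float
    cost_breakdown: dict[str, float]
    cost_by_event_type: dict[str, float]
    treatment_components: dict[str, float]
    total_qalys: float
    event_counts: dict[str, float]
    cost_cycle_category: np.ndarray = field(repr=False)  # (H, 3) discounted euros
    qaly_cycle: np.ndarray = field(repr=False)  # (H,) discounted QALYs


@dataclass
class Comparison:
    """Incremental result of arm A versus arm B."""

    delta_cost: float
    delta_qalys: float
    verdict: str  # dominant_A | dominant_B | icer_value | equivalent
    icer: Optional[float] = None


def discount_factor(annual_rate: float, cycle: int, cfg: ModelConfig) -> float:
    """Discount factor at the start of ``cycle``: (1+r)^(-cycle*months/12)."""
    if annual_rate < 0:
        raise ValueError(f"negative discount rate {annual_rate}")
    years = cycle * cfg.cycle_length_months / 12.0
    return (1.0 + annual_rate) ** (-years)


def weight_from_bmi(bmi: float, height: float) -> float:
    """Body weight in kg from BMI (kg/m^2) and height (m)."""
    if bmi <= 0 or height <= 0:
        raise ValueError("BMI and height must be positive")
    return bmi * height**2


def dalteparin_band(weight: float) -> tuple[str, int, int]:
    """(band label, month-1 IU/day, months-2-6 IU/day) for a body weight.

    Raises :class:`UncoveredWeightBandError` outside 57-98 kg rather than
    extrapolating the dosing table.
    """
    for label, lo, hi, m1, m26 in DALTEPARIN_BANDS:
        if lo <= weight < hi + 1.0:  # bands are contiguous in whole kg
            return label, m1, m26
    raise UncoveredWeightBandError(f"weight {weight:.1f} kg outside covered bands 57-98 kg")


def drug_cost_for_cycle(
    arm: str,
    cycle_within_treatment: int,
    schedule: DrugSchedule,
    cfg: ModelConfig,
) -> TreatmentCycleCost:
    """Per-patient treatment cost components in one cycle of the treatment window.

    Drug units follow the phase schedule over the calendar days of the cycle
    (``days_per_month`` from the config).  Renal monitoring is amortised at
    1/12 of the annual cost per on-treatment cycle (or lumped at treatment
    start when ``cfg.renal_monitoring_lump``); the injection instruction is
    charged once at treatment start; paid administration accrues per cycle
    scaled by the applicable cohort fraction.
    """
    j = cycle_within_treatment
    dur = cfg.treatment_duration_cycles[arm]
    if j < 0 or j >= dur:
        return TreatmentCycleCost()
    dpm = cfg.days_per_month
    start, end = j * dpm, (j + 1) * dpm
    treatment_end = dur * dpm

    units = 0.0
    phase_start = 0.0
    for phase in schedule.phase_doses:
        phase_end = treatment_end if phase.duration_days is None else phase_start + phase.duration_days
        overlap = max(0.0, min(end, phase_end, treatment_end) - max(start, phase_start))
        units += overlap * phase.units_per_day
        phase_start = phase_end
        if phase_start >= treatment_end:
            break

    cost = TreatmentCycleCost(drug=units * schedule.unit_price)
    if schedule.monitoring_cost_annual:
        if cfg.renal_monitoring_lump:
            cost.monitoring = schedule.monitoring_cost_annual if j == 0 else 0.0
        else:
            cost.monitoring = schedule.monitoring_cost_annual / 12.0
    if schedule.instruction_cost_one_time and j == 0:
        cost.instruction = schedule.instruction_cost_one_time
    if schedule.administration_cost_per_cycle:
        cost.administration = (
            schedule.administration_cost_per_cycle * schedule.administration_applicable_fraction
        )
    return cost


def accrue_costs(
    trace: CohortTrace,
    ps: ParameterSet,
    cfg: ModelConfig,
    perspective: str | None = None,
) -> tuple[dict[str, float], dict[str, float], dict[str, float], np.ndarray]:
    """Discounted cost accrual over a trace.

    Returns (category totals, per-event-type event costs, treatment
    components, per-cycle-per-category matrix).  All categories are always
    computed; the caller applies the perspective when totalling.
    """
    H = trace.horizon_cycles
    arm = trace.arm
    schedule = ps.drug_schedules[arm]
    dur = cfg.treatment_duration_cycles[arm]
    costs = ps.costs
    travel = costs["travel_per_visit"].value
    early_fraction = ps.cohort.cancer_stage_fractions["early_locally_advanced"]
    informal_per_event = ps.informal_care.cost_per_event() * early_fraction

    per_k = [drug_cost_for_cycle(arm, k, schedule, cfg) for k in range(dur)]
    df_cost = np.array(
        [discount_factor(cfg.discount_rate_costs_annual, c, cfg) for c in range(H)]
    )

    cycle_cat = np.zeros((H, 3))
    by_type: dict[str, float] = {}
    components = {"drug": 0.0, "monitoring": 0.0, "instruction": 0.0, "administration": 0.0}

    ev = trace.events
    ich_spec = costs["ich"]
    cteph_spec = costs["cteph"]

    for c in range(H):
        df = df_cost[c]
        # --- event category
        type_costs = {
            "recurrent_symptomatic_pe": ev["recurrent_symptomatic_pe"][c]
            * costs["symptomatic_pe_event"].value,
            "recurrent_incidental_pe": 0.0,
            "recurrent_dvt": ev["recurrent_dvt"][c] * costs["dvt_event"].value,
            "fatal_recurrent_vte": ev["fatal_recurrent_vte"][c]
            * costs["symptomatic_pe_event"].value,
            "ich": ev["ich"][c] * ich_spec.acute_value
            + trace.cells["post_ich"][c] * ich_spec.value,
            "non_ich_mb": ev["non_ich_mb"][c] * costs["non_ich_mb_event"].value,
            "fatal_mb": ev["fatal_mb"][c] * costs["non_ich_mb_event"].value,
            "crnmb": ev["crnmb"][c] * costs["crnmb_event"].value,
            "pts_severe": trace.chronic_prevalence["pts_severe"][c]
            * costs["pts_monthly"].value,
            "cteph": ev["cteph"][c] * cteph_spec.acute_value
            + trace.chronic_prevalence["cteph"][c] * cteph_spec.value,
        }
        for t, euros in type_costs.items():
            disc = euros * df
            by_type[t] = by_type.get(t, 0.0) + disc
            cycle_cat[c, 0] += disc

        # --- treatment category (at-risk tunnel cells within the treatment window)
        occ_on = trace.cells["index_vte"][c, :dur]
        for comp in components:
            euros = float(sum(occ_on[k] * getattr(per_k[k], comp) for k in range(dur)))
            components[comp] += euros * df
            cycle_cat[c, 1] += euros * df

        # --- indirect category: travel + informal care
        on_total = float(occ_on.sum())
        indirect = (ev["recurrent_dvt"][c] + ev["crnmb"][c]) * travel
        if schedule.monitoring_cost_annual:
            indirect += on_total * travel / 12.0  # renal monitoring visit travel
        indirect += (
            sum(ev[t][c] for t in INFORMAL_CARE_EVENTS) * informal_per_event
        )
        cycle_cat[c, 2] += indirect * df

    totals = {cat: float(cycle_cat[:, i].sum()) for i, cat in enumerate(CATEGORIES)}
    return totals, by_type, components, cycle_cat


_EVENT_DECREMENT = {
    "recurrent_incidental_pe": "dec_incidental_pe",
    "recurrent_symptomatic_pe": "dec_symptomatic_pe",
    "recurrent_dvt": "dec_dvt",
    "non_ich_mb": "dec_non_ich_mb",
    "ich": "dec_ich_acute",
    "crnmb": "dec_crnmb",
}


def accrue_qalys(trace: CohortTrace, ps: ParameterSet, cfg: ModelConfig) -> tuple[float, np.ndarray]:
    """Discounted QALY accrual: occupancy x annual utility / 12 per cycle.

    Event months carry the baseline utility minus the event decrement
    (floored at 0); the post-ICH state has its own utility; background PTS
    and CTEPH decrements apply to their prevalent fractions; dead states
    contribute exactly 0.
    """
    H = trace.horizon_cycles
    u = ps.utilities
    base = u["baseline"].value
    per_cycle = np.zeros(H)
    for c in range(H):
        q = float(trace.cells["index_vte"][c].sum()) * base
        for name, dec_label in _EVENT_DECREMENT.items():
            occ = float(trace.cells[name][c].sum())
            q += occ * max(base - u[dec_label].value, 0.0)
        q += float(trace.cells["post_ich"][c]) * u["post_ich"].value
        q -= float(trace.chronic_prevalence["pts_severe"][c]) * u["dec_pts"].value
        q -= float(trace.chronic_prevalence["cteph"][c]) * u["dec_cteph"].value
        q = max(q, 0.0)
        per_cycle[c] = q / 12.0 * discount_factor(cfg.discount_rate_qalys_annual, c, cfg)
    return float(per_cycle.sum()), per_cycle


def evaluate_arm(
    ps: ParameterSet, cfg: ModelConfig, arm: str, trace: CohortTrace | None = None
) -> ArmResult:
    """Run (or reuse) a cohort trace and accrue discounted costs and QALYs."""
    if trace is None:
        trace = run_cohort(ps, cfg, arm)
    totals, by_type, components, cycle_cat = accrue_costs(trace, ps, cfg)
    qalys, qaly_cycle = accrue_qalys(trace, ps, cfg)
    included = CATEGORIES if cfg.perspective == "societal" else ("event", "treatment")
    total_cost = sum(totals[c] for c in included)
    return ArmResult(
        arm=arm,
        horizon_cycles=cfg.horizon_cycles,
        perspective=cfg.perspective,
        total_cost=total_cost,
        cost_breakdown=totals,
        cost_by_event_type=by_type,
        treatment_components=components,
        total_qalys=qalys,
        event_counts=count_events(trace),
        cost_cycle_category=cycle_cat,
        qaly_cycle=qaly_cycle,
    )


def compare(a: ArmResult, b: ArmResult) -> Comparison:
    """Incremental comparison of arm A (intervention) versus arm B (comparator).

    When A is cheaper and more effective (or the reverse) the strategy is
    dominant and no numeric ICER is reported.
    """
    if a.horizon_cycles != b.horizon_cycles:
        raise ValueError("cannot compare results with different horizons")
    if a.perspective != b.perspective:
        raise ValueError("cannot compare results with different perspectives")
    dc = a.total_cost - b.total_cost
    dq = a.total_qalys - b.total_qalys
    if dc == 0 and dq == 0:
        return Comparison(dc, dq, "equivalent")
    if dc < 0 and dq > 0:
        return Comparison(dc, dq, "dominant_A")
    if dc > 0 and dq < 0:
        return Comparison(dc, dq, "dominant_B")
    icer = dc / dq if dq != 0 else float("inf") * (1 if dc > 0 else -1)
    return Comparison(dc, dq, "icer_value", icer=icer)


def qalys_to_days(q: float) -> float:
    """QALYs expressed as quality-adjusted life-days (365.25 days/year).

    Reported to one decimal, rounding half away from zero.
    """
    days = q * 365.25
    return math.copysign(math.floor(abs(days) * 10 + 0.5) / 10, days)
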