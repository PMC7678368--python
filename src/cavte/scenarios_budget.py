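"""Base case, predefined scenario analyses and the budget-impact analysis.

Scenarios (identified 0-6):

0. base case — 5-year horizon, societal perspective
1. 6-month horizon, societal perspective
2. base case from the healthcare payer's perspective (indirect costs dropped)
3. base case with the 57-68 kg dalteparin dose band (12 500 / 10 000 IU)
4. base case with the 83-98 kg dalteparin dose band (18 000 / 15 000 IU)
5. scenario 1 with observed real-world treatment durations
   (3 months rivaroxaban, 1 month dalteparin)
6. base case with arm-specific (instead of pooled) event-type distributions

The budget impact scales the per-patient cost difference at a 1-year
cut-off to the annual number of cancer patients with VTE nationwide
(full-replacement maximum, no market-share phase-in).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from cavte.economics import (
    ArmResult,
    Comparison,
    DALTEPARIN_BANDS,
    compare,
    evaluate_arm,
)
from cavte.parameters import ModelConfig, ParameterSet, PhaseDose
from cavte.uncertainty import PSAResult

#: national inputs for the budget impact (cancer registry count for 2017 and
#: the VTE incidence among cancer patients, per 1000 person-years)
DUTCH_CANCER_PATIENTS_2017 = 579_781
VTE_INCIDENCE_PER_1000_PY = 13.9


@dataclass
class ScenarioSpec:
    """A named override bundle applied on top of the base inputs."""

    id: int
    description: str
    apply: Callable[[ParameterSet, ModelConfig], tuple[ParameterSet, ModelConfig]]


@dataclass
class ScenarioResult:
    scenario_id: int
    description: str
    rivaroxaban: ArmResult
    dalteparin: ArmResult
    comparison: Comparison


@dataclass
class BudgetImpactResult:
    """Annual national cost change of replacing dalteparin with rivaroxaban."""

    n_patients: float
    per_patient_delta: dict[str, float]  # euros per patient by category
    totals: dict[str, float]  # euros by category
    total: float
    ci_bounds: Optional[dict[str, tuple[float, float]]] = None


def dalteparin_schedule_for_band(ps: ParameterSet, band_label: str):
    """Rebuild the dalteparin schedule for a dose band, with its band price."""
    bands = {label: (m1, m26) for label, _lo, _hi, m1, m26 in DALTEPARIN_BANDS}
    if band_label not in bands:
        raise ValueError(f"unknown dalteparin band {band_label!r}")
    if band_label not in ps.dalteparin_band_prices:
        raise ValueError(f"no price recorded for dalteparin band {band_label!r}")
    m1, m26 = bands[band_label]
    schedule = ps.drug_schedules["dalteparin"].model_copy(deep=True)
    month1_days = schedule.phase_doses[0].duration_days
    schedule.phase_doses = [
        PhaseDose(
            duration_days=month1_days,
            dose_description=f"{m1} IU daily (band {band_label} kg)",
            units_per_day=1,
        ),
        PhaseDose(
            duration_days=None,
            dose_description=f"{m26} IU daily (band {band_label} kg)",
            units_per_day=1,
        ),
    ]
    schedule.unit_price = ps.dalteparin_band_prices[band_label]
    return schedule


def _identity(ps, cfg):
    return ps, cfg


def _horizon(cycles: int):
    def apply(ps, cfg):
        return ps, cfg.model_copy(update={"horizon_cycles": cycles})

    return apply


def _payer(ps, cfg):
    return ps, cfg.model_copy(update={"perspective": "healthcare_payer"})


def _band(label: str):
    def apply(ps, cfg):
        ps2 = ps.model_copy(deep=True)
        ps2.drug_schedules["dalteparin"] = dalteparin_schedule_for_band(ps, label)
        return ps2, cfg

    return apply


def _realworld_durations(ps, cfg):
    cfg2 = cfg.model_copy(
        update={
            "horizon_cycles": 6,
            "treatment_duration_cycles": {"rivaroxaban": 3, "dalteparin": 1},
        }
    )
    return ps, cfg2


def _arm_specific(ps, cfg):
    return ps, cfg.model_copy(update={"type_distribution_mode": "arm_specific"})


SCENARIOS: dict[int, ScenarioSpec] = {
    0: ScenarioSpec(0, "base case: 5-year horizon, societal perspective", _identity),
    1: ScenarioSpec(1, "6-month horizon, societal perspective", _horizon(6)),
    2: ScenarioSpec(2, "base case, healthcare payer's perspective", _payer),
    3: ScenarioSpec(3, "dalteparin band 57-68 kg (12 500 / 10 000 IU)", _band("57-68")),
    4: ScenarioSpec(4, "dalteparin band 83-98 kg (18 000 / 15 000 IU)", _band("83-98")),
    5: ScenarioSpec(5, "6-month horizon, 3-month rivaroxaban vs 1-month dalteparin", _realworld_durations),
    6: ScenarioSpec(6, "arm-specific event-type distributions", _arm_specific),
}


def run_scenario(scenario_id: int, ps: ParameterSet, cfg: ModelConfig) -> ScenarioResult:
    """Apply a scenario's overrides and run both arms deterministically."""
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario id {scenario_id}; valid ids are 0-6")
    spec = SCENARIOS[scenario_id]
    ps2, cfg2 = spec.apply(ps, cfg)
    a = evaluate_arm(ps2, cfg2, "rivaroxaban")
    b = evaluate_arm(ps2, cfg2, "dalteparin")
    return ScenarioResult(spec.id, spec.description, a, b, compare(a, b))


def annual_patient_population(
    n_cancer_patients: float = DUTCH_CANCER_PATIENTS_2017,
    incidence_per_1000_py: float = VTE_INCIDENCE_PER_1000_PY,
) -> tuple[float, int]:
    """Annual cancer patients with VTE: exact value and nearest-thousand round."""
    if n_cancer_patients < 0 or incidence_per_1000_py < 0:
        raise ValueError("inputs must be nonnegative")
    exact = n_cancer_patients * incidence_per_1000_py / 1000.0
    return exact, int(round(exact / 1000.0) * 1000)


def budget_impact(
    ps: ParameterSet,
    cfg: ModelConfig,
    n_patients: float,
    psa: PSAResult | None = None,
    cutoff_cycles: int = 12,
) -> BudgetImpactResult:
    """Annual budget impact of full replacement of dalteparin by rivaroxaban.

    Per-patient per-category cost deltas at the 1-year cut-off are scaled by
    the annual patient population.  When a PSA result is supplied, 95%
    percentile intervals of each line are derived from its iterations.
    """
    if cfg.horizon_cycles < cutoff_cycles:
        raise ValueError(
            f"budget impact needs a horizon of at least {cutoff_cycles} cycles"
        )
    a = evaluate_arm(ps, cfg, "rivaroxaban")
    b = evaluate_arm(ps, cfg, "dalteparin")
    cohort_n = ps.cohort.n_patients
    delta = (
        a.cost_cycle_category[:cutoff_cycles].sum(axis=0)
        - b.cost_cycle_category[:cutoff_cycles].sum(axis=0)
    ) / cohort_n
    categories = ("event", "treatment", "indirect")
    per_patient = dict(zip(categories, (float(x) for x in delta)))
    totals = {cat: per_patient[cat] * n_patients for cat in categories}
    total = float(sum(totals.values()))

    ci = None
    if psa is not None:
        if psa.category_deltas_1y is None:
            raise ValueError("PSA result lacks 1-year category deltas")
        scaled = psa.category_deltas_1y / cohort_n * n_patients
        ci = {
            cat: (
                float(np.percentile(scaled[:, i], 2.5)),
                float(np.percentile(scaled[:, i], 97.5)),
            )
            for i, cat in enumerate(categories)
        }
        row_totals = scaled.sum(axis=1)
        ci["total"] = (
            float(np.percentile(row_totals, 2.5)),
            float(np.percentile(row_totals, 97.5)),
        )
    return BudgetImpactResult(
        n_patients=n_patients,
        per_patient_delta=per_patient,
        totals=totals,
        total=total,
        ci_bounds=ci,
    )
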