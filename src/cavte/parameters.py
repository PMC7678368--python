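"""Input data model for the cost-effectiveness pipeline.

Every number the model consumes — event rates, event-type distributions,
unit costs, utilities, drug schedules, the cohort profile and the run
configuration — lives in a validated :class:`ParameterSet`.  Each spec
carries a ``provenance`` flag distinguishing values printed in the source
clinical literature (``paper_main_text``) from generated stand-ins
(``synthetic_placeholder``), so fixture placeholders can never be mistaken
for evidence-based inputs.

Parameter sets serialise to a single JSON document with deterministic key
ordering; bulk rate/cost tables can additionally be imported from CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

ARMS = ("rivaroxaban", "dalteparin")
EVENTS = ("vte", "mb", "crnmb")
PHASES = ("on_treatment", "off_treatment")

Provenance = Literal["paper_main_text", "synthetic_placeholder"]


class ValidationProblem(ValueError):
    """A parameter file violates the schema or an invariant."""


class CompletenessError(ValidationProblem):
    """A required (event, arm, phase) slot or labelled spec is missing."""


class _Model(BaseModel):
    # validation happens at construction and load; in-memory mutation (PSA
    # sampling, scenario overrides, tests) stays cheap and unchecked
    model_config = ConfigDict(extra="forbid")


class RateSpec(_Model):
    """An event rate or cumulative risk with optional uncertainty.

    ``form`` declares the scale of ``value``: a cumulative risk over
    ``horizon_months``, a per-month exponential rate, or a per-month
    probability.  CI bounds, when given, are on the same scale.
    """

    label: str
    value: float = Field(ge=0)
    form: Literal["cumulative_risk", "monthly_rate", "monthly_probability"]
    horizon_months: Optional[float] = Field(default=None, gt=0)
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    distribution: Literal["beta", "none"] = "beta"
    provenance: Provenance = "synthetic_placeholder"

    @model_validator(mode="after")
    def _check(self) -> "RateSpec":
        if self.form in ("cumulative_risk", "monthly_probability") and self.value > 1:
            raise ValueError(f"{self.label}: probability-scale value {self.value} > 1")
        if self.form == "cumulative_risk" and self.horizon_months is None:
            raise ValueError(f"{self.label}: cumulative_risk needs horizon_months")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError(f"{self.label}: CI bounds must be given together")
        if self.ci_low is not None:
            if not (self.ci_low <= self.value <= self.ci_high):
                raise ValueError(f"{self.label}: CI must bracket the value")
            if self.ci_low < 0:
                raise ValueError(f"{self.label}: negative ci_low")
        return self


class TypeDistribution(_Model):
    """Split of a total event probability across event subtypes.

    Fractions are proportional to observed event counts; ``pooled`` marks a
    distribution computed from both treatment arms together (the base-case
    treatment-independence assumption).
    """

    labels: list[str]
    counts: list[float]
    pooled: bool = True
    distribution: Literal["dirichlet", "none"] = "dirichlet"

    @model_validator(mode="after")
    def _check(self) -> "TypeDistribution":
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts must align")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative event count")
        if sum(self.counts) <= 0:
            raise ValueError("counts must sum to a positive number")
        return self

    def fractions(self) -> dict[str, float]:
        total = float(sum(self.counts))
        return {lab: c / total for lab, c in zip(self.labels, self.counts)}


class CostSpec(_Model):
    """A unit cost in 2019 euros.

    ``recurrence`` distinguishes one-off event costs, per-cycle recurring
    costs, and acute-then-chronic costs (``acute_value`` in the diagnosis
    month, ``value`` per month thereafter until death).
    """

    label: str
    value: float = Field(ge=0)
    recurrence: Literal["one_time", "per_cycle", "acute_then_chronic"] = "one_time"
    acute_value: Optional[float] = Field(default=None, ge=0)
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    distribution: Literal["gamma", "none"] = "gamma"
    category: Literal["event", "treatment", "indirect"]
    provenance: Provenance = "synthetic_placeholder"

    @model_validator(mode="after")
    def _check(self) -> "CostSpec":
        if self.recurrence == "acute_then_chronic" and self.acute_value is None:
            raise ValueError(f"{self.label}: acute_then_chronic needs acute_value")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError(f"{self.label}: CI bounds must be given together")
        if self.ci_low is not None and not (0 <= self.ci_low <= self.value <= self.ci_high):
            raise ValueError(f"{self.label}: CI must be ordered around the value")
        return self


class UtilitySpec(_Model):
    """A health-state utility weight or a utility decrement (annual scale)."""

    label: str
    value: float = Field(ge=0)
    kind: Literal["state_utility", "decrement"]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    distribution: Literal["beta", "none"] = "beta"
    provenance: Provenance = "synthetic_placeholder"

    @model_validator(mode="after")
    def _check(self) -> "UtilitySpec":
        if self.kind == "state_utility" and self.value > 1:
            raise ValueError(f"{self.label}: state utility {self.value} > 1")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError(f"{self.label}: CI bounds must be given together")
        if self.ci_low is not None and not (0 <= self.ci_low <= self.value <= self.ci_high):
            raise ValueError(f"{self.label}: CI must be ordered around the value")
        return self


class PhaseDose(_Model):
    """One dosing phase of a drug schedule.

    ``duration_days`` of ``None`` means the phase runs to the end of the
    treatment period (used for maintenance dosing).
    """

    duration_days: Optional[float] = Field(default=None, gt=0)
    dose_description: str
    units_per_day: float = Field(ge=0)


class DrugSchedule(_Model):
    """Dosing, pricing and ancillary treatment-cost structure for one arm."""

    drug: Literal["rivaroxaban", "dalteparin"]
    phase_doses: list[PhaseDose]
    unit_price: float = Field(ge=0)
    monitoring_cost_annual: float = Field(default=0.0, ge=0)
    instruction_cost_one_time: float = Field(default=0.0, ge=0)
    administration_cost_per_cycle: float = Field(default=0.0, ge=0)
    administration_applicable_fraction: float = Field(default=0.0, ge=0, le=1)
    provenance: Provenance = "synthetic_placeholder"

    @model_validator(mode="after")
    def _check(self) -> "DrugSchedule":
        if not self.phase_doses:
            raise ValueError(f"{self.drug}: schedule needs at least one phase")
        open_ended = [p for p in self.phase_doses if p.duration_days is None]
        if len(open_ended) > 1 or (open_ended and self.phase_doses[-1].duration_days is not None):
            raise ValueError(f"{self.drug}: only the last phase may be open-ended")
        return self


class InformalCareSpec(_Model):
    """Informal (unpaid) care package accrued after burdensome acute events.

    The weekly hour load mixes intensive and non-intensive care; the package
    is costed as hours/week x tariff x duration and applied only to the
    early/locally-advanced cancer subgroup (patients with metastatic or
    haematologic disease are assumed to already have care in place).
    """

    intensive_hours_per_week: float = Field(ge=0)
    nonintensive_hours_per_week: float = Field(ge=0)
    tariff_per_hour: float = Field(ge=0)
    duration_weeks: float = Field(ge=0)
    intensive_fraction: float = Field(ge=0, le=1)
    provenance: Provenance = "synthetic_placeholder"

    def cost_per_event(self) -> float:
        hours = (
            self.intensive_fraction * self.intensive_hours_per_week
            + (1 - self.intensive_fraction) * self.nonintensive_hours_per_week
        )
        return hours * self.tariff_per_hour * self.duration_weeks


class CohortProfile(_Model):
    """Baseline characteristics of the modelled cohort."""

    n_patients: int = Field(gt=0)
    age_years: float = Field(gt=0)
    male_fraction: float = Field(ge=0, le=1)
    bmi_kg_m2: float = Field(gt=0)
    height_m: float = Field(gt=0)
    cancer_stage_fractions: dict[str, float]
    index_vte_fractions: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "CohortProfile":
        stage = sum(self.cancer_stage_fractions.values())
        # the printed stage split sums to 0.99; allow that rounding slack
        if abs(stage - 1.0) > 0.02:
            raise ValueError(f"cancer stage fractions sum to {stage:.3f}, not ~1")
        index = sum(self.index_vte_fractions.values())
        if abs(index - 1.0) > 1e-9:
            raise ValueError(f"index VTE fractions sum to {index:.3f}, not 1")
        required = {"early_locally_advanced", "metastatic", "haematologic"}
        if not required <= set(self.cancer_stage_fractions):
            raise CompletenessError("missing cancer stage fraction keys")
        return self


class MortalityTable(_Model):
    """All-cause monthly death probabilities indexed by months since entry.

    Cycles beyond the table length reuse the last entry.
    """

    monthly_probability: list[float]
    provenance: Provenance = "synthetic_placeholder"

    @model_validator(mode="after")
    def _check(self) -> "MortalityTable":
        if not self.monthly_probability:
            raise ValueError("mortality table is empty")
        if any(not 0 <= p <= 1 for p in self.monthly_probability):
            raise ValueError("mortality probabilities must lie in [0, 1]")
        return self

    def at(self, cycle: int) -> float:
        idx = min(cycle, len(self.monthly_probability) - 1)
        return self.monthly_probability[idx]


class PiecewiseHazard(_Model):
    """Piecewise-constant monthly onset rate for a background chronic process.

    ``start_months[i]`` is the first month at which ``monthly_rates[i]``
    applies; segments must start at 0 and be strictly increasing.
    """

    condition: Literal["pts_severe", "cteph"]
    start_months: list[int]
    monthly_rates: list[float]
    distribution: Literal["beta", "none"] = "none"
    provenance: Provenance = "synthetic_placeholder"

    @model_validator(mode="after")
    def _check(self) -> "PiecewiseHazard":
        if len(self.start_months) != len(self.monthly_rates) or not self.start_months:
            raise ValueError("start_months and monthly_rates must align and be non-empty")
        if self.start_months[0] != 0:
            raise ValueError("first hazard segment must start at month 0")
        if any(a >= b for a, b in zip(self.start_months, self.start_months[1:])):
            raise ValueError("hazard segment starts must be strictly increasing")
        if any(r < 0 for r in self.monthly_rates):
            raise ValueError("negative hazard rate")
        return self

    def rate_at(self, month: int) -> float:
        rate = self.monthly_rates[0]
        for start, r in zip(self.start_months, self.monthly_rates):
            if month >= start:
                rate = r
        return rate


class ModelConfig(_Model):
    """Run configuration: horizon, cycle length, discounting and perspective."""

    cycle_length_months: float = Field(default=1.0, gt=0)
    horizon_cycles: int = Field(default=60, gt=0)
    treatment_duration_cycles: dict[str, int] = Field(
        default_factory=lambda: {"rivaroxaban": 6, "dalteparin": 6}
    )
    discount_rate_costs_annual: float = Field(default=0.04, ge=0)
    discount_rate_qalys_annual: float = Field(default=0.015, ge=0)
    perspective: Literal["societal", "healthcare_payer"] = "societal"
    days_per_month: float = Field(default=30.4375, gt=0)
    type_distribution_mode: Literal["pooled", "arm_specific"] = "pooled"
    renal_monitoring_lump: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        for arm in ARMS:
            if arm not in self.treatment_duration_cycles:
                raise CompletenessError(f"treatment duration missing for {arm}")
            if self.treatment_duration_cycles[arm] > self.horizon_cycles:
                raise ValueError("treatment duration exceeds horizon")
            if self.treatment_duration_cycles[arm] < 0:
                raise ValueError("negative treatment duration")
        return self


class ParameterSet(_Model):
    """Every model input, with uncertainty and provenance metadata.

    ``rates`` is keyed ``"<event>:<arm>:<phase>"`` with events ``vte``,
    ``mb``, ``crnmb``; arms ``rivaroxaban``, ``dalteparin``; phases
    ``on_treatment``, ``off_treatment``.
    """

    rates: dict[str, RateSpec]
    type_distributions: dict[str, TypeDistribution]
    costs: dict[str, CostSpec]
    utilities: dict[str, UtilitySpec]
    drug_schedules: dict[str, DrugSchedule]
    dalteparin_band_prices: dict[str, float] = Field(default_factory=dict)
    informal_care: InformalCareSpec
    cohort: CohortProfile
    mortality: MortalityTable
    chronic_hazards: dict[str, PiecewiseHazard]

    REQUIRED_TYPE_DISTS: tuple[str, ...] = ("vte_pooled", "mb_pooled")
    REQUIRED_COSTS: tuple[str, ...] = (
        "symptomatic_pe_event",
        "dvt_event",
        "non_ich_mb_event",
        "crnmb_event",
        "ich",
        "cteph",
        "pts_monthly",
        "travel_per_visit",
    )
    REQUIRED_UTILITIES: tuple[str, ...] = (
        "baseline",
        "post_ich",
        "dec_symptomatic_pe",
        "dec_incidental_pe",
        "dec_dvt",
        "dec_non_ich_mb",
        "dec_ich_acute",
        "dec_crnmb",
        "dec_pts",
        "dec_cteph",
    )

    @model_validator(mode="after")
    def _check(self) -> "ParameterSet":
        if not self.rates:
            raise ValidationProblem("rates collection is empty")
        for event in EVENTS:
            for arm in ARMS:
                for phase in PHASES:
                    key = rate_key(event, arm, phase)
                    if key not in self.rates:
                        raise CompletenessError(f"missing rate slot {key!r}")
        for name in self.REQUIRED_TYPE_DISTS:
            if name not in self.type_distributions:
                raise CompletenessError(f"missing type distribution {name!r}")
        for label in self.REQUIRED_COSTS:
            if label not in self.costs:
                raise CompletenessError(f"missing cost spec {label!r}")
        for label in self.REQUIRED_UTILITIES:
            if label not in self.utilities:
                raise CompletenessError(f"missing utility spec {label!r}")
        for arm in ARMS:
            if arm not in self.drug_schedules:
                raise CompletenessError(f"missing drug schedule for {arm}")
        for cond in ("pts_severe", "cteph"):
            if cond not in self.chronic_hazards:
                raise CompletenessError(f"missing chronic hazard for {cond}")
        return self

    def rate(self, event: str, arm: str, phase: str) -> RateSpec:
        return self.rates[rate_key(event, arm, phase)]

    def type_distribution(self, event: str, arm: str, mode: str = "pooled") -> TypeDistribution:
        """Pooled split in the base case; arm-specific in scenario analyses."""
        if mode == "pooled":
            return self.type_distributions[f"{event}_pooled"]
        name = f"{event}_{arm}"
        if name not in self.type_distributions:
            raise CompletenessError(f"no arm-specific type distribution {name!r}")
        return self.type_distributions[name]


def rate_key(event: str, arm: str, phase: str) -> str:
    if event not in EVENTS or arm not in ARMS or phase not in PHASES:
        raise ValidationProblem(f"invalid rate key components ({event}, {arm}, {phase})")
    return f"{event}:{arm}:{phase}"


# ---------------------------------------------------------------------------
# Serialisation


def write_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    """Write ``ps`` as a JSON document with stable key ordering."""
    payload = ps.model_dump(mode="json")
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load and validate a JSON parameter document."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationProblem(f"{path}: not valid JSON ({exc})") from exc
    return ParameterSet.model_validate(payload)


def costs_from_csv(path: str | Path, default_recurrence: str = "one_time") -> dict[str, CostSpec]:
    """Bulk-import cost specs from a CSV table.

    Expected columns: label,value,ci_low,ci_high,distribution,category,provenance.
    """
    df = pd.read_csv(path)
    out: dict[str, CostSpec] = {}
    for row in df.to_dict(orient="records"):
        kwargs = dict(
            label=row["label"],
            value=float(row["value"]),
            distribution=row.get("distribution", "gamma"),
            category=row["category"],
            provenance=row.get("provenance", "synthetic_placeholder"),
            recurrence=row.get("recurrence", default_recurrence),
        )
        if pd.notna(row.get("ci_low")) and pd.notna(row.get("ci_high")):
            kwargs["ci_low"] = float(row["ci_low"])
            kwargs["ci_high"] = float(row["ci_high"])
        out[kwargs["label"]] = CostSpec(**kwargs)
    return out


def rates_from_csv(path: str | Path) -> dict[str, RateSpec]:
    """Bulk-import rate specs from a CSV table.

    Expected columns: label,value,form,horizon_months,ci_low,ci_high,
    distribution,provenance.  The label doubles as the rates-dict key and
    should follow the ``event:arm:phase`` convention.
    """
    df = pd.read_csv(path)
    out: dict[str, RateSpec] = {}
    for row in df.to_dict(orient="records"):
        kwargs = dict(
            label=row["label"],
            value=float(row["value"]),
            form=row["form"],
            distribution=row.get("distribution", "beta"),
            provenance=row.get("provenance", "synthetic_placeholder"),
        )
        if pd.notna(row.get("horizon_months")):
            kwargs["horizon_months"] = float(row["horizon_months"])
        if pd.notna(row.get("ci_low")) and pd.notna(row.get("ci_high")):
            kwargs["ci_low"] = float(row["ci_low"])
            kwargs["ci_high"] = float(row["ci_high"])
        out[kwargs["label"]] = RateSpec(**kwargs)
    return out
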