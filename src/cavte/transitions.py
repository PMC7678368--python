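"""Rate conversions and per-cycle transition structure of the state graph.

The model states are: the at-risk tunnel (``index_vte`` at tunnel index *k*,
meaning *k* months since the last index or recurrent VTE), six transient
one-cycle event states (recurrent incidental/symptomatic PE, recurrent DVT,
ICH, non-ICH major bleed, CRNMB), the permanent ``post_ich`` state, and
three absorbing dead states (fatal recurrent VTE, fatal major bleed, death
by any cause).

Transition intensities enter as rates or cumulative risks and are converted
to per-cycle probabilities with the exponential formula
``P = 1 - exp(-r * t)``.  The tunnel index carries the time dependency:
patients are on anticoagulation while their tunnel index is below the arm's
treatment duration, a non-fatal recurrent VTE resets the tunnel (and hence
restarts treatment), and bleeding events let the tunnel clock continue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from cavte.parameters import (
    ModelConfig,
    ParameterSet,
    PiecewiseHazard,
    RateSpec,
)

STATE_NAMES = (
    "index_vte",
    "recurrent_incidental_pe",
    "recurrent_symptomatic_pe",
    "recurrent_dvt",
    "ich",
    "non_ich_mb",
    "crnmb",
    "post_ich",
    "fatal_recurrent_vte",
    "fatal_mb",
    "death_any_cause",
)

#: transient states that return the patient to the at-risk tunnel after one cycle
TRANSIENT_VTE = ("recurrent_incidental_pe", "recurrent_symptomatic_pe", "recurrent_dvt")
TRANSIENT_BLEED = ("non_ich_mb", "crnmb")
DEAD_STATES = ("fatal_recurrent_vte", "fatal_mb", "death_any_cause")

VTE_TYPES = ("incidental_pe", "symptomatic_pe", "dvt", "fatal_pe")
MB_TYPES = ("ich", "non_ich", "fatal")

_VTE_TARGET = {
    "incidental_pe": "recurrent_incidental_pe",
    "symptomatic_pe": "recurrent_symptomatic_pe",
    "dvt": "recurrent_dvt",
    "fatal_pe": "fatal_recurrent_vte",
}
_MB_TARGET = {"ich": "ich", "non_ich": "non_ich_mb", "fatal": "fatal_mb"}


class InfeasibleParametersError(ValueError):
    """Event plus death probability mass exceeds 1 for some state and cycle."""


@dataclass(frozen=True)
class StateId:
    """A (state name, tunnel index) cell of the state space."""

    name: str
    tunnel_index: int = 0

    def __post_init__(self) -> None:
        if self.name not in STATE_NAMES:
            raise ValueError(f"unknown state {self.name!r}")
        if self.tunnel_index < 0:
            raise ValueError("negative tunnel index")


@dataclass
class TransitionRow:
    """Outgoing per-cycle transition probabilities of one state cell."""

    source: StateId
    targets: dict[StateId, float]

    def __post_init__(self) -> None:
        total = sum(self.targets.values())
        if any(p < -1e-15 or p > 1 + 1e-12 for p in self.targets.values()):
            raise ValueError(f"{self.source}: probability outside [0, 1]")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.source}: row sums to {total}, not 1")


def rate_to_probability(rate: float, t: float = 1.0) -> float:
    """Convert a per-month event rate to a probability over ``t`` months.

    Uses the exponential relation ``P = 1 - exp(-r t)``.
    """
    if rate < 0:
        raise ValueError(f"negative rate {rate}")
    if t <= 0:
        raise ValueError(f"non-positive cycle length {t}")
    return -math.expm1(-rate * t)


def cumulative_risk_to_rate(risk: float, horizon: float) -> float:
    """Invert a cumulative risk over ``horizon`` months to a per-month rate.

    ``rate_to_probability(cumulative_risk_to_rate(p, h), h) == p``.
    """
    if not 0 <= risk < 1:
        raise ValueError(f"cumulative risk {risk} outside [0, 1)")
    if horizon <= 0:
        raise ValueError(f"non-positive horizon {horizon}")
    return -math.log1p(-risk) / horizon


def probability_to_rate(p: float, t: float = 1.0) -> float:
    """Inverse of :func:`rate_to_probability`."""
    return cumulative_risk_to_rate(p, t)


def monthly_probability(spec: RateSpec, cycle_length_months: float = 1.0) -> float:
    """Per-cycle event probability implied by a rate spec, on any input scale."""
    if spec.form == "monthly_rate":
        return rate_to_probability(spec.value, cycle_length_months)
    if spec.form == "monthly_probability":
        rate = probability_to_rate(spec.value, 1.0)
        return rate_to_probability(rate, cycle_length_months)
    rate = cumulative_risk_to_rate(spec.value, spec.horizon_months)
    return rate_to_probability(rate, cycle_length_months)


def split_probability(total: float, dist) -> dict[str, float]:
    """Split a total event probability across subtypes in proportion to counts."""
    if not 0 <= total <= 1:
        raise ValueError(f"total probability {total} outside [0, 1]")
    if sum(dist.counts) <= 0:
        raise ValueError("degenerate type distribution: all counts zero")
    return {lab: total * frac for lab, frac in dist.fractions().items()}


def chronic_hazard(condition: str, tunnel_index: int, ps: ParameterSet,
                   cycle_length_months: float = 1.0) -> float:
    """Per-cycle onset probability of a background chronic condition.

    ``pts_severe`` and ``cteph`` run in the background of the state graph:
    onset can happen at any time, and once present the condition persists
    until death.  Hazards are piecewise-constant in months since model entry.
    """
    if condition not in ps.chronic_hazards:
        raise ValueError(f"unknown chronic condition {condition!r}")
    if tunnel_index < 0:
        raise ValueError("negative tunnel index")
    haz: PiecewiseHazard = ps.chronic_hazards[condition]
    return rate_to_probability(haz.rate_at(tunnel_index), cycle_length_months)


@dataclass
class ArmDynamics:
    """Precomputed per-cycle probabilities for one treatment arm.

    Shared between the vectorised cohort engine and the row-by-row
    :func:`build_transition_row` API so both describe the same process.
    """

    arm: str
    treatment_duration: int
    p_vte: dict[str, float]          # phase -> per-cycle probability
    p_mb: dict[str, float]
    p_crnmb: dict[str, float]
    vte_split: dict[str, float]      # fractions over VTE_TYPES
    mb_split: dict[str, float]       # fractions over MB_TYPES
    mortality: np.ndarray = field(repr=False)  # per-cycle death probability

    def phase(self, tunnel_index: int) -> str:
        return "on_treatment" if tunnel_index < self.treatment_duration else "off_treatment"


def compute_dynamics(ps: ParameterSet, cfg: ModelConfig, arm: str) -> ArmDynamics:
    """Resolve rate specs and type distributions into per-cycle probabilities."""
    t = cfg.cycle_length_months
    mode = cfg.type_distribution_mode
    p = {
        ev: {ph: monthly_probability(ps.rate(ev, arm, ph), t) for ph in ("on_treatment", "off_treatment")}
        for ev in ("vte", "mb", "crnmb")
    }
    vte_split = ps.type_distribution("vte", arm, mode).fractions()
    mb_split = ps.type_distribution("mb", arm, mode).fractions()
    missing = set(VTE_TYPES) - set(vte_split)
    if missing:
        raise ValueError(f"VTE type distribution missing {sorted(missing)}")
    missing = set(MB_TYPES) - set(mb_split)
    if missing:
        raise ValueError(f"MB type distribution missing {sorted(missing)}")
    mortality = np.array([ps.mortality.at(c) for c in range(cfg.horizon_cycles)])
    return ArmDynamics(
        arm=arm,
        treatment_duration=cfg.treatment_duration_cycles[arm],
        p_vte=p["vte"],
        p_mb=p["mb"],
        p_crnmb=p["crnmb"],
        vte_split=vte_split,
        mb_split=mb_split,
        mortality=mortality,
    )


def build_transition_row(
    state: StateId,
    cycle: int,
    arm: str,
    ps: ParameterSet,
    cfg: ModelConfig,
    dynamics: ArmDynamics | None = None,
) -> TransitionRow:
    """Outgoing transition probabilities of ``state`` at ``cycle`` for ``arm``.

    Encodes the full topology: at-risk tunnel cells face competing recurrent
    VTE, major-bleed, CRNMB and all-cause death probabilities with the
    residual advancing the tunnel; transient event cells last one cycle and
    return to the tunnel (VTE events reset it, bleeds continue it, ICH feeds
    the permanent post-ICH state); dead states absorb.
    """
    if cycle >= cfg.horizon_cycles:
        raise ValueError(f"cycle {cycle} outside horizon {cfg.horizon_cycles}")
    d = dynamics if dynamics is not None else compute_dynamics(ps, cfg, arm)
    cap = cfg.horizon_cycles
    k = state.tunnel_index
    p_death = float(d.mortality[cycle])
    nxt = min(k + 1, cap)

    if state.name in DEAD_STATES:
        return TransitionRow(state, {state: 1.0})

    if state.name == "post_ich":
        return TransitionRow(
            state,
            {StateId("death_any_cause"): p_death, StateId("post_ich"): 1.0 - p_death},
        )

    if state.name in TRANSIENT_VTE:
        return TransitionRow(
            state,
            {
                StateId("death_any_cause"): p_death,
                StateId("index_vte", 0): 1.0 - p_death,
            },
        )

    if state.name in TRANSIENT_BLEED:
        return TransitionRow(
            state,
            {
                StateId("death_any_cause"): p_death,
                StateId("index_vte", nxt): 1.0 - p_death,
            },
        )

    if state.name == "ich":
        return TransitionRow(
            state,
            {StateId("death_any_cause"): p_death, StateId("post_ich"): 1.0 - p_death},
        )

    # at-risk tunnel cell
    phase = d.phase(k)
    pv, pm, pc = d.p_vte[phase], d.p_mb[phase], d.p_crnmb[phase]
    targets: dict[StateId, float] = {}
    for typ, frac in split_probability(pv, _SplitView(d.vte_split)).items():
        target = _VTE_TARGET[typ]
        _add(targets, StateId(target, 0 if target in DEAD_STATES else k), frac)
    for typ, frac in split_probability(pm, _SplitView(d.mb_split)).items():
        target = _MB_TARGET[typ]
        _add(targets, StateId(target, 0 if target in DEAD_STATES else k), frac)
    _add(targets, StateId("crnmb", k), pc)
    _add(targets, StateId("death_any_cause"), p_death)
    residual = 1.0 - sum(targets.values())
    if residual < -1e-12:
        raise InfeasibleParametersError(
            f"arm={arm} cycle={cycle} state={state.name}@{k}: "
            f"event + death mass {1 - residual:.6f} exceeds 1"
        )
    _add(targets, StateId("index_vte", nxt), max(residual, 0.0))
    return TransitionRow(state, targets)


class _SplitView:
    """Adapter so split_probability accepts a plain fractions dict."""

    def __init__(self, fractions: dict[str, float]):
        self._fractions = fractions
        self.counts = list(fractions.values())

    def fractions(self) -> dict[str, float]:
        return dict(self._fractions)


def _add(targets: dict[StateId, float], sid: StateId, p: float) -> None:
    if p == 0:
        return
    targets[sid] = targets.get(sid, 0.0) + p
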