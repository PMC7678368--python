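"""Deterministic cohort propagation through the VTE state graph.

The engine advances expected state occupancy (persons, fractional) cycle by
cycle with vectorised updates over the tunnel dimension.  The per-cycle
probabilities come from :func:`cavte.transitions.compute_dynamics`, the same
object that backs :func:`cavte.transitions.build_transition_row`, so the
fast path and the row-by-row description are two views of one process.

Background chronic complications (severe post-thrombotic syndrome and
CTEPH) are tracked as marginal prevalence alongside the state occupancy:
onset applies to the alive, not-yet-affected fraction each cycle and the
affected pool shrinks with all-cause survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cavte.parameters import ModelConfig, ParameterSet
from cavte.transitions import (
    ArmDynamics,
    InfeasibleParametersError,
    TRANSIENT_BLEED,
    TRANSIENT_VTE,
    chronic_hazard,
    compute_dynamics,
)

TUNNEL_STATES = ("index_vte",) + TRANSIENT_VTE + ("ich",) + TRANSIENT_BLEED
SCALAR_STATES = ("post_ich", "fatal_recurrent_vte", "fatal_mb", "death_any_cause")
EVENT_TYPES = (
    "recurrent_incidental_pe",
    "recurrent_symptomatic_pe",
    "recurrent_dvt",
    "fatal_recurrent_vte",
    "ich",
    "non_ich_mb",
    "fatal_mb",
    "crnmb",
    "pts_severe",
    "cteph",
)
CHRONIC_CONDITIONS = ("pts_severe", "cteph")


@dataclass
class CohortTrace:
    """Per-cycle occupancy, events and background chronic prevalence.

    ``cells`` maps tunnel-carrying state names to ``(horizon+1, horizon+1)``
    arrays indexed ``[cycle, tunnel_index]`` and scalar states to
    ``(horizon+1,)`` arrays.  ``events`` holds expected event counts per
    cycle (the cycle during which the event occurs).
    """

    arm: str
    horizon_cycles: int
    n_patients: float
    cells: dict[str, np.ndarray] = field(repr=False)
    events: dict[str, np.ndarray] = field(repr=False)
    chronic_prevalence: dict[str, np.ndarray] = field(repr=False)
    chronic_onsets: dict[str, np.ndarray] = field(repr=False)

    def alive(self) -> np.ndarray:
        dead = sum(self.cells[s] for s in ("fatal_recurrent_vte", "fatal_mb", "death_any_cause"))
        return self.n_patients - dead

    def occupancy_matrix(self) -> np.ndarray:
        """Flat (cycle, state-cell) occupancy; column order per state_columns()."""
        cols = [self.cells[name] for name in TUNNEL_STATES]
        cols.append(np.column_stack([self.cells[name] for name in SCALAR_STATES]))
        return np.hstack(cols)

    def state_columns(self) -> list[tuple[str, int]]:
        cap = self.horizon_cycles
        cols = [(name, k) for name in TUNNEL_STATES for k in range(cap + 1)]
        cols += [(name, 0) for name in SCALAR_STATES]
        return cols

    def total_occupancy(self) -> np.ndarray:
        """Persons per cycle summed over every state cell (conservation check)."""
        return self.occupancy_matrix().sum(axis=1)


def run_cohort(ps: ParameterSet, cfg: ModelConfig, arm: str) -> CohortTrace:
    """Propagate the cohort over ``cfg.horizon_cycles`` monthly cycles.

    All patients enter the at-risk tunnel at index 0 (the index VTE).  The
    run is fully deterministic: occupancy is the expected number of persons
    in each state cell at the start of each cycle.
    """
    d = compute_dynamics(ps, cfg, arm)
    H = cfg.horizon_cycles
    cap = H  # tunnel indices 0..cap
    n = float(ps.cohort.n_patients)

    cells = {name: np.zeros((H + 1, cap + 1)) for name in TUNNEL_STATES}
    for name in SCALAR_STATES:
        cells[name] = np.zeros(H + 1)
    cells["index_vte"][0, 0] = n

    events = {t: np.zeros(H) for t in EVENT_TYPES}
    prevalence = {c: np.zeros(H + 1) for c in CHRONIC_CONDITIONS}
    onsets = {c: np.zeros(H) for c in CHRONIC_CONDITIONS}

    k = np.arange(cap + 1)
    on = k < d.treatment_duration
    pv = np.where(on, d.p_vte["on_treatment"], d.p_vte["off_treatment"])
    pm = np.where(on, d.p_mb["on_treatment"], d.p_mb["off_treatment"])
    pc = np.where(on, d.p_crnmb["on_treatment"], d.p_crnmb["off_treatment"])

    vte_frac = d.vte_split
    mb_frac = d.mb_split

    for c in range(H):
        p_death = float(d.mortality[c])
        if float((pv + pm + pc + p_death).max()) > 1 + 1e-12:
            raise InfeasibleParametersError(
                f"arm={arm} cycle={c}: event + death probability mass exceeds 1"
            )
        surv = 1.0 - p_death
        risk = cells["index_vte"][c]

        inflow = {
            "recurrent_incidental_pe": risk * pv * vte_frac["incidental_pe"],
            "recurrent_symptomatic_pe": risk * pv * vte_frac["symptomatic_pe"],
            "recurrent_dvt": risk * pv * vte_frac["dvt"],
            "ich": risk * pm * mb_frac["ich"],
            "non_ich_mb": risk * pm * mb_frac["non_ich"],
            "crnmb": risk * pc,
        }
        fatal_vte_in = float((risk * pv).sum()) * vte_frac["fatal_pe"]
        fatal_mb_in = float((risk * pm).sum()) * mb_frac["fatal"]

        residual = np.maximum(risk * (1.0 - pv - pm - pc - p_death), 0.0)
        new_risk = np.zeros(cap + 1)
        new_risk[1:] += residual[:-1]
        new_risk[-1] += residual[-1]

        # transient returns: VTE events reset the tunnel, bleeds continue it
        vte_return = sum(float(cells[name][c].sum()) for name in TRANSIENT_VTE)
        new_risk[0] += vte_return * surv
        for name in TRANSIENT_BLEED:
            occ = cells[name][c]
            new_risk[1:] += occ[:-1] * surv
            new_risk[-1] += occ[-1] * surv

        alive_cells = (
            float(risk.sum())
            + sum(float(cells[name][c].sum()) for name in TRANSIENT_VTE + ("ich",) + TRANSIENT_BLEED)
            + float(cells["post_ich"][c])
        )

        cells["index_vte"][c + 1] = new_risk
        for name, arr in inflow.items():
            cells[name][c + 1] = arr
        cells["post_ich"][c + 1] = (cells["post_ich"][c] + float(cells["ich"][c].sum())) * surv
        cells["fatal_recurrent_vte"][c + 1] = cells["fatal_recurrent_vte"][c] + fatal_vte_in
        cells["fatal_mb"][c + 1] = cells["fatal_mb"][c] + fatal_mb_in
        cells["death_any_cause"][c + 1] = cells["death_any_cause"][c] + p_death * alive_cells

        events["recurrent_incidental_pe"][c] = float(inflow["recurrent_incidental_pe"].sum())
        events["recurrent_symptomatic_pe"][c] = float(inflow["recurrent_symptomatic_pe"].sum())
        events["recurrent_dvt"][c] = float(inflow["recurrent_dvt"].sum())
        events["fatal_recurrent_vte"][c] = fatal_vte_in
        events["ich"][c] = float(inflow["ich"].sum())
        events["non_ich_mb"][c] = float(inflow["non_ich_mb"].sum())
        events["fatal_mb"][c] = fatal_mb_in
        events["crnmb"][c] = float(inflow["crnmb"].sum())

        # background chronic processes on the marginal alive cohort
        alive_prev = alive_cells
        alive_new = alive_prev - p_death * alive_cells - fatal_vte_in - fatal_mb_in
        for cond in CHRONIC_CONDITIONS:
            p_on = chronic_hazard(cond, c, ps, cfg.cycle_length_months)
            new_onsets, affected = background_chronic_update(
                alive_prev, alive_new, float(prevalence[cond][c]), p_on
            )
            onsets[cond][c] = new_onsets
            prevalence[cond][c + 1] = affected
        events["pts_severe"][c] = onsets["pts_severe"][c]
        events["cteph"][c] = onsets["cteph"][c]

    return CohortTrace(
        arm=arm,
        horizon_cycles=H,
        n_patients=n,
        cells=cells,
        events=events,
        chronic_prevalence=prevalence,
        chronic_onsets=onsets,
    )


def background_chronic_update(
    alive_prev: float, alive_new: float, affected_prev: float, onset_probability: float
) -> tuple[float, float]:
    """One-cycle update of a background chronic condition's prevalence.

    Onset applies to the alive, not-yet-affected pool; the affected pool is
    then scaled by the cohort's one-cycle survival ratio (affected persons
    face the same all-cause mortality as the rest of the cohort).
    Returns (new onsets this cycle, affected persons at next cycle start).
    """
    if not 0 <= onset_probability <= 1:
        raise ValueError(f"onset probability {onset_probability} outside [0, 1]")
    susceptible = max(alive_prev - affected_prev, 0.0)
    new_onsets = susceptible * onset_probability
    ratio = alive_new / alive_prev if alive_prev > 0 else 0.0
    affected = (affected_prev + new_onsets) * ratio
    return new_onsets, min(affected, alive_new)


def count_events(trace: CohortTrace, window_cycles: range | slice | None = None) -> dict[str, float]:
    """Expected event counts per type over a cycle window (default: all).

    Counts are cohort expectations (fractional); ``recurrent_vte`` aggregates
    the four VTE subtypes.
    """
    if window_cycles is None:
        window_cycles = range(trace.horizon_cycles)
    if isinstance(window_cycles, slice):
        window_cycles = range(*window_cycles.indices(trace.horizon_cycles))
    idx = list(window_cycles)
    if not idx:
        raise ValueError("empty event-count window")
    if idx[0] < 0 or idx[-1] >= trace.horizon_cycles:
        raise ValueError("event-count window outside horizon")
    counts = {t: float(trace.events[t][idx].sum()) for t in EVENT_TYPES}
    counts["recurrent_vte"] = (
        counts["recurrent_incidental_pe"]
        + counts["recurrent_symptomatic_pe"]
        + counts["recurrent_dvt"]
        + counts["fatal_recurrent_vte"]
    )
    return counts


def trace_to_frames(trace: CohortTrace) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy exports: (cycle,state,tunnel_index,persons) and per-cycle events."""
    occ = trace.occupancy_matrix()
    cols = trace.state_columns()
    records = []
    for c in range(trace.horizon_cycles + 1):
        row = occ[c]
        for (name, k), persons in zip(cols, row):
            if persons > 0:
                records.append((c, name, k, persons))
    occ_df = pd.DataFrame(records, columns=["cycle", "state", "tunnel_index", "persons"])
    ev_records = [
        (c, t, float(trace.events[t][c]))
        for t in EVENT_TYPES
        for c in range(trace.horizon_cycles)
    ]
    ev_df = pd.DataFrame(ev_records, columns=["cycle", "event_type", "expected_events"])
    return occ_df, ev_df
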