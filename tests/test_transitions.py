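"""Rate conversions, type splitting and transition-row structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cavte.parameters import TypeDistribution, rate_key
from cavte.transitions import (
    InfeasibleParametersError,
    StateId,
    build_transition_row,
    chronic_hazard,
    compute_dynamics,
    cumulative_risk_to_rate,
    rate_to_probability,
    split_probability,
)


class TestRateConversions:
    def test_zero_rate_gives_zero_probability(self):
        assert rate_to_probability(0.0, 1.0) == 0.0

    def test_large_rate_approaches_one(self):
        assert rate_to_probability(1e9, 1.0) == pytest.approx(1.0)
        assert rate_to_probability(1e9, 1.0) < 1.0 or rate_to_probability(1e9, 1.0) == 1.0

    def test_monthly_probability_from_rate(self):
        # independently: P(Exp(0.019422) < 1) = 0.0192346; Monte-Carlo check below
        assert rate_to_probability(0.019422, 1.0) == pytest.approx(0.0192346, abs=1e-7)
        rng = np.random.default_rng(12345)
        mc = float((rng.exponential(1 / 0.019422, size=10**6) < 1).mean())
        se = math.sqrt(0.0192346 * (1 - 0.0192346) / 10**6)
        assert abs(mc - rate_to_probability(0.019422, 1.0)) < 3 * se

    def test_six_month_recurrence_risk_inverts_to_monthly_rate(self):
        # root of 1 - (1 - p_month)^6 = 0.11 equals the closed form
        rate = cumulative_risk_to_rate(0.11, 6)
        assert rate == pytest.approx(0.0194223, abs=1e-7)
        p_month = rate_to_probability(rate, 1.0)
        assert 1 - (1 - p_month) ** 6 == pytest.approx(0.11, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.1, 1.0)

    def test_certain_risk_rejected(self):
        with pytest.raises(ValueError):
            cumulative_risk_to_rate(1.0, 6)

    @given(st.floats(0, 0.999), st.floats(0.1, 120))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_inverse(self, risk, horizon):
        rate = cumulative_risk_to_rate(risk, horizon)
        assert rate_to_probability(rate, horizon) == pytest.approx(risk, abs=1e-12)


class TestSplitProbability:
    def test_symmetric_split(self):
        td = TypeDistribution(labels=["a", "b"], counts=[1, 1])
        assert split_probability(0.1, td) == {"a": 0.05, "b": 0.05}

    def test_zero_total_gives_zeros(self):
        td = TypeDistribution(labels=["a", "b"], counts=[3, 7])
        assert all(v == 0 for v in split_probability(0.0, td).values())

    def test_bleed_type_split_preserves_total(self):
        td = TypeDistribution(labels=["ich", "non_ich", "fatal"], counts=[3, 14, 1])
        out = split_probability(0.06, td)
        assert out["ich"] == pytest.approx(0.01, abs=1e-15)
        assert out["non_ich"] == pytest.approx(0.06 * 14 / 18, abs=1e-15)
        assert out["fatal"] == pytest.approx(0.06 / 18, abs=1e-15)
        assert sum(out.values()) == pytest.approx(0.06, abs=1e-15)


class TestChronicHazard:
    def test_zero_hazard_everywhere(self, ps):
        for haz in ps.chronic_hazards.values():
            haz.monthly_rates = [0.0] * len(haz.monthly_rates)
        assert all(chronic_hazard("pts_severe", m, ps) == 0 for m in range(60))

    def test_constant_hazard_time_independent(self, ps):
        ps.chronic_hazards["cteph"].start_months = [0]
        ps.chronic_hazards["cteph"].monthly_rates = [0.002]
        probs = {chronic_hazard("cteph", m, ps) for m in range(60)}
        assert len(probs) == 1

    def test_piecewise_lookup_after_breakpoint(self, ps):
        ps.chronic_hazards["pts_severe"].start_months = [0, 6]
        ps.chronic_hazards["pts_severe"].monthly_rates = [0.004, 0.001]
        assert chronic_hazard("pts_severe", 7, ps) == rate_to_probability(0.001, 1.0)
        assert chronic_hazard("pts_severe", 5, ps) == rate_to_probability(0.004, 1.0)

    def test_unknown_condition_rejected(self, ps):
        with pytest.raises(ValueError):
            chronic_hazard("gout", 0, ps)


class TestTransitionRows:
    def test_absorbing_dead_state(self, ps, cfg):
        row = build_transition_row(StateId("fatal_mb"), 3, "rivaroxaban", ps, cfg)
        assert row.targets == {StateId("fatal_mb"): 1.0}

    def test_zero_rates_send_full_mass_down_tunnel(self, stress_variants, cfg):
        zero = stress_variants[0]
        row = build_transition_row(StateId("index_vte", 4), 2, "dalteparin", zero, cfg)
        assert row.targets[StateId("index_vte", 5)] == pytest.approx(1.0, abs=1e-15)

    def test_on_treatment_vte_mass_matches_hand_composition(self, ps, cfg):
        # recompose: 4%/6mo risk -> monthly probability, split by pooled counts
        row = build_transition_row(StateId("index_vte", 2), 2, "rivaroxaban", ps, cfg)
        p_vte = rate_to_probability(cumulative_risk_to_rate(0.04, 6), 1.0)
        frac = ps.type_distributions["vte_pooled"].fractions()
        got = row.targets[StateId("recurrent_dvt", 2)]
        assert got == pytest.approx(p_vte * frac["dvt"], abs=1e-15)
        fatal = row.targets[StateId("fatal_recurrent_vte")]
        assert fatal == pytest.approx(p_vte * frac["fatal_pe"], abs=1e-15)

    def test_off_treatment_rates_after_discontinuation(self, ps, cfg):
        d = compute_dynamics(ps, cfg, "rivaroxaban")
        assert d.phase(5) == "on_treatment" and d.phase(6) == "off_treatment"

    def test_retreatment_resets_tunnel(self, ps, cfg):
        row = build_transition_row(StateId("recurrent_dvt", 9), 4, "rivaroxaban", ps, cfg)
        surviving = 1 - ps.mortality.at(4)
        assert row.targets[StateId("index_vte", 0)] == pytest.approx(surviving)

    def test_bleed_continues_tunnel(self, ps, cfg):
        row = build_transition_row(StateId("crnmb", 9), 4, "rivaroxaban", ps, cfg)
        assert StateId("index_vte", 10) in row.targets
        assert StateId("index_vte", 0) not in row.targets

    def test_ich_feeds_post_ich(self, ps, cfg):
        row = build_transition_row(StateId("ich", 3), 1, "dalteparin", ps, cfg)
        assert StateId("post_ich") in row.targets

    def test_infeasible_mass_fails_loudly(self, ps, cfg):
        for arm in ("rivaroxaban", "dalteparin"):
            for phase in ("on_treatment", "off_treatment"):
                spec = ps.rate("vte", arm, phase)
                spec.ci_low = spec.ci_high = None
                spec.form = "monthly_probability"
                spec.value = 0.995
                spec.horizon_months = None
        with pytest.raises(InfeasibleParametersError, match="cycle"):
            build_transition_row(StateId("index_vte", 0), 0, "rivaroxaban", ps, cfg)

    @given(
        vte=st.floats(0, 0.5),
        mb=st.floats(0, 0.3),
        crnmb=st.floats(0, 0.3),
        mort=st.floats(0, 0.3),
        tunnel=st.integers(0, 60),
        cycle=st.integers(0, 59),
    )
    @settings(max_examples=60, deadline=None)
    def test_rows_normalise_for_random_parameters(
        self, fixture_ps, cfg, vte, mb, crnmb, mort, tunnel, cycle
    ):
        ps = fixture_ps.model_copy(deep=True)
        for event, risk in (("vte", vte), ("mb", mb), ("crnmb", crnmb)):
            for arm in ("rivaroxaban", "dalteparin"):
                for phase in ("on_treatment", "off_treatment"):
                    spec = ps.rates[rate_key(event, arm, phase)]
                    spec.ci_low = spec.ci_high = None
                    spec.value = risk
        ps.mortality.monthly_probability = [mort]
        for name in ("index_vte", "recurrent_dvt", "crnmb", "ich", "post_ich", "fatal_mb"):
            row = build_transition_row(StateId(name, tunnel), cycle, "dalteparin", ps, cfg)
            total = sum(row.targets.values())
            assert total == pytest.approx(1.0, abs=1e-12)
            assert all(0 <= p <= 1 for p in row.targets.values())

    def test_event_mass_monotone_in_rate(self, ps, cfg):
        def vte_mass(risk):
            p = ps.rate("vte", "rivaroxaban", "on_treatment")
            p.ci_low = p.ci_high = None
            p.value = risk
            row = build_transition_row(StateId("index_vte", 0), 0, "rivaroxaban", ps, cfg)
            return sum(
                v for s, v in row.targets.items()
                if s.name.startswith("recurrent") or s.name == "fatal_recurrent_vte"
            )

        masses = [vte_mass(r) for r in (0.01, 0.04, 0.2, 0.6)]
        assert masses == sorted(masses)

    def test_pooled_splits_identical_across_arms(self, ps, cfg):
        da = compute_dynamics(ps, cfg, "rivaroxaban")
        db = compute_dynamics(ps, cfg, "dalteparin")
        assert da.mb_split == db.mb_split and da.vte_split == db.vte_split
        cfg6 = cfg.model_copy(update={"type_distribution_mode": "arm_specific"})
        da6 = compute_dynamics(ps, cfg6, "rivaroxaban")
        db6 = compute_dynamics(ps, cfg6, "dalteparin")
        assert da6.mb_split != db6.mb_split
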