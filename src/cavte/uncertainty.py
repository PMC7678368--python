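"""Probabilistic and univariate sensitivity analysis.

Probabilities and utilities vary over beta distributions, costs over gamma
distributions and event-type splits over Dirichlet distributions, all fitted
by method of moments to the parameter's 95% CI (normal-approximation
SE = (hi - lo)/3.92).  Where no CI is available the SE falls back to 25% of
the mean.  Each PSA iteration draws one coherent parameter set, applies it
to both treatment arms (common random numbers) and re-runs the full
deterministic pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

from cavte.economics import CATEGORIES, compare, evaluate_arm
from cavte.parameters import ModelConfig, ParameterSet, TypeDistribution

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class DistributionSpec:
    """A fitted sampling distribution for one scalar parameter."""

    family: str  # beta | gamma | dirichlet | degenerate
    parameters: dict
    source: str  # fitted_from_ci | se_fallback | counts

    def sample(self, rng: np.random.Generator) -> float | np.ndarray:
        if self.family == "degenerate":
            return self.parameters["value"]
        if self.family == "beta":
            return float(rng.beta(self.parameters["alpha"], self.parameters["beta"]))
        if self.family == "gamma":
            return float(rng.gamma(self.parameters["shape"], self.parameters["scale"]))
        if self.family == "dirichlet":
            return rng.dirichlet(self.parameters["alpha"])
        raise ValueError(f"unknown family {self.family}")


@dataclass
class PSAResult:
    """Per-iteration incremental results with quadrant and CI summaries."""

    n_iterations: int
    seed: int
    delta_cost: np.ndarray = field(repr=False)
    delta_qalys: np.ndarray = field(repr=False)
    category_deltas: np.ndarray = field(repr=False)  # (n, 3) full horizon
    category_deltas_1y: Optional[np.ndarray] = field(default=None, repr=False)  # (n, 3)

    @property
    def iterations(self) -> list[tuple[float, float]]:
        return list(zip(self.delta_cost.tolist(), self.delta_qalys.tolist()))

    def quadrant_fractions(self) -> dict[str, float]:
        """Cost-effectiveness plane quadrant shares (boundaries to the
        cost-increasing / less-effective side)."""
        dc, dq = self.delta_cost, self.delta_qalys
        n = len(dc)
        return {
            "more_effective_cost_saving": float(((dq > 0) & (dc < 0)).sum()) / n,
            "more_effective_cost_increasing": float(((dq > 0) & (dc >= 0)).sum()) / n,
            "less_effective_cost_saving": float(((dq <= 0) & (dc < 0)).sum()) / n,
            "less_effective_cost_increasing": float(((dq <= 0) & (dc >= 0)).sum()) / n,
        }

    def ci_bounds(self, values: np.ndarray | None = None) -> tuple[float, float]:
        """2.5/97.5 percentile bounds (default: of the cost delta)."""
        v = self.delta_cost if values is None else values
        return float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))


@dataclass
class TornadoEntry:
    """Deterministic reruns of one parameter at its 95% CI bounds."""

    label: str
    delta_cost_low: float
    delta_cost_high: float
    delta_qalys_low: float
    delta_qalys_high: float

    @property
    def impact_range(self) -> float:
        return abs(self.delta_cost_high - self.delta_cost_low)

    @property
    def impact_range_qalys(self) -> float:
        return abs(self.delta_qalys_high - self.delta_qalys_low)


def se_fallback(mean: float) -> float:
    """Fallback standard error when no CI is available: 25% of the mean."""
    if mean < 0:
        raise ValueError("negative mean")
    return 0.25 * mean


def _se_from_ci(ci_low: float, ci_high: float) -> float:
    return (ci_high - ci_low) / (2 * Z95)


def fit_beta_from_ci(mean: float, ci_low: float, ci_high: float) -> DistributionSpec:
    """Method-of-moments beta matching ``mean`` and the CI-implied SE."""
    if not 0 <= ci_low <= mean <= ci_high <= 1:
        raise ValueError("require 0 <= ci_low <= mean <= ci_high <= 1")
    se = _se_from_ci(ci_low, ci_high)
    if se == 0:
        return DistributionSpec("degenerate", {"value": mean}, "fitted_from_ci")
    if mean in (0.0, 1.0):
        warnings.warn(f"beta fit degenerate at mean={mean} with nonzero spread")
        return DistributionSpec("degenerate", {"value": mean}, "fitted_from_ci")
    var = se**2
    cap = mean * (1 - mean)
    if var >= cap:
        warnings.warn("CI wider than a beta supports; shrinking variance")
        var = 0.95 * cap
    nu = cap / var - 1
    return DistributionSpec(
        "beta", {"alpha": mean * nu, "beta": (1 - mean) * nu}, "fitted_from_ci"
    )


def fit_gamma_from_ci(mean: float, ci_low: float, ci_high: float) -> DistributionSpec:
    """Method-of-moments gamma: shape = m^2/s^2, scale = s^2/m."""
    if not 0 <= ci_low <= mean <= ci_high:
        raise ValueError("require 0 <= ci_low <= mean <= ci_high")
    se = _se_from_ci(ci_low, ci_high)
    if se == 0 or mean == 0:
        return DistributionSpec("degenerate", {"value": mean}, "fitted_from_ci")
    var = se**2
    return DistributionSpec(
        "gamma", {"shape": mean**2 / var, "scale": var / mean}, "fitted_from_ci"
    )


def dirichlet_from_counts(dist: TypeDistribution) -> DistributionSpec:
    """Dirichlet with concentration equal to the raw event counts."""
    if any(c <= 0 for c in dist.counts):
        raise ValueError("Dirichlet requires strictly positive counts in every component")
    return DistributionSpec(
        "dirichlet", {"alpha": np.asarray(dist.counts, dtype=float), "labels": dist.labels}, "counts"
    )


def _spec_distribution(value: float, ci_low, ci_high, family: str) -> DistributionSpec:
    """CI-fitted distribution for a spec, with the 25%-SE fallback."""
    fit = fit_beta_from_ci if family == "beta" else fit_gamma_from_ci
    if ci_low is not None and ci_high is not None:
        return fit(value, ci_low, ci_high)
    se = se_fallback(value)
    if se == 0:
        return DistributionSpec("degenerate", {"value": value}, "se_fallback")
    lo = max(value - Z95 * se, 0.0)
    hi = value + Z95 * se
    if family == "beta":
        hi = min(hi, 1.0)
        lo, hi = value - min(value - lo, hi - value), value + min(value - lo, hi - value)
    d = fit(value, lo, hi)
    d.source = "se_fallback"
    return d


def _varied_scalars(ps: ParameterSet) -> Iterator[tuple[str, float, DistributionSpec, Callable]]:
    """Yield (label, point value, distribution, setter) for every varied scalar.

    Iteration order is deterministic (sorted keys) so draws are reproducible.
    """
    for key in sorted(ps.rates):
        spec = ps.rates[key]
        if spec.distribution == "none":
            continue
        family = "beta" if spec.form in ("cumulative_risk", "monthly_probability") else "gamma"
        dist = _spec_distribution(spec.value, spec.ci_low, spec.ci_high, family)

        def setter(new, ps=ps, key=key):
            ps.rates[key].value = new

        yield f"rate:{key}", spec.value, dist, setter
    for key in sorted(ps.costs):
        spec = ps.costs[key]
        if spec.distribution == "none":
            continue
        dist = _spec_distribution(spec.value, spec.ci_low, spec.ci_high, "gamma")

        def setter(new, ps=ps, key=key):
            c = ps.costs[key]
            if c.acute_value is not None and c.value > 0:
                c.acute_value = c.acute_value * new / c.value
            c.value = new

        yield f"cost:{key}", spec.value, dist, setter
    for key in sorted(ps.utilities):
        spec = ps.utilities[key]
        if spec.distribution == "none":
            continue
        dist = _spec_distribution(spec.value, spec.ci_low, spec.ci_high, "beta")

        def setter(new, ps=ps, key=key):
            ps.utilities[key].value = new

        yield f"utility:{key}", spec.value, dist, setter
    for key in sorted(ps.chronic_hazards):
        haz = ps.chronic_hazards[key]
        if haz.distribution == "none":
            continue
        for i, rate in enumerate(haz.monthly_rates):
            dist = _spec_distribution(rate, None, None, "gamma")

            def setter(new, ps=ps, key=key, i=i):
                rates = list(ps.chronic_hazards[key].monthly_rates)
                rates[i] = new
                ps.chronic_hazards[key].monthly_rates = rates

            yield f"chronic:{key}:{i}", rate, dist, setter


def sample_parameter_set(ps: ParameterSet, seed: int | np.random.Generator) -> ParameterSet:
    """One coherent random draw of every varied parameter.

    Returns a deep copy; the input is never mutated.  The same draw is meant
    to be applied to both arms within a PSA iteration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = ps.model_copy(deep=True)
    for _label, _value, dist, setter in _varied_scalars(out):
        setter(float(dist.sample(rng)))
    for name in sorted(out.type_distributions):
        td = out.type_distributions[name]
        if td.distribution == "dirichlet":
            draw = dirichlet_from_counts(td).sample(rng)
            td.counts = [float(x) for x in draw]
    return out


def run_psa(
    ps: ParameterSet,
    cfg: ModelConfig,
    n_iterations: int = 2000,
    seed: int = 0,
    budget_cutoff_cycles: int = 12,
) -> PSAResult:
    """Full-pipeline probabilistic sensitivity analysis.

    Each iteration samples a parameter set, runs both arms and records the
    incremental cost, incremental QALYs and per-category cost deltas (full
    horizon and, when the horizon allows, at the 1-year budget cut-off).
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    track_1y = cfg.horizon_cycles >= budget_cutoff_cycles
    dc = np.zeros(n_iterations)
    dq = np.zeros(n_iterations)
    cat = np.zeros((n_iterations, 3))
    cat_1y = np.zeros((n_iterations, 3)) if track_1y else None
    seeds = np.random.SeedSequence(seed).generate_state(n_iterations)
    for i in range(n_iterations):
        try:
            ps_i = sample_parameter_set(ps, int(seeds[i]))
            a = evaluate_arm(ps_i, cfg, "rivaroxaban")
            b = evaluate_arm(ps_i, cfg, "dalteparin")
        except Exception as exc:
            raise RuntimeError(f"PSA iteration {i} (seed {int(seeds[i])}) failed: {exc}") from exc
        comp = compare(a, b)
        dc[i], dq[i] = comp.delta_cost, comp.delta_qalys
        cat[i] = a.cost_cycle_category.sum(axis=0) - b.cost_cycle_category.sum(axis=0)
        if track_1y:
            cat_1y[i] = (
                a.cost_cycle_category[:budget_cutoff_cycles].sum(axis=0)
                - b.cost_cycle_category[:budget_cutoff_cycles].sum(axis=0)
            )
    return PSAResult(
        n_iterations=n_iterations,
        seed=seed,
        delta_cost=dc,
        delta_qalys=dq,
        category_deltas=cat,
        category_deltas_1y=cat_1y,
    )


def tornado(
    ps: ParameterSet,
    cfg: ModelConfig,
    param_labels: Sequence[str] | None = None,
    top: int = 10,
) -> list[TornadoEntry]:
    """Univariate sensitivity analysis.

    Re-runs the deterministic pipeline with each parameter at its 95% CI
    bounds (others at point values) and ranks entries by their range of
    impact on the incremental costs.  Parameters without usable bounds are
    skipped with a warning.
    """
    entries = []
    available = {label: (value, dist, setter) for label, value, dist, setter in _varied_scalars(ps)}
    labels = list(available) if param_labels is None else list(param_labels)
    for label in labels:
        if label not in available:
            warnings.warn(f"tornado: no varied parameter {label!r}; skipped")
            continue
        value, dist, _setter = available[label]
        lo, hi = _bounds_for(label, ps, value)
        if lo is None:
            warnings.warn(f"tornado: no CI bounds for {label!r}; skipped")
            continue
        results = []
        for bound in (lo, hi):
            ps_b = ps.model_copy(deep=True)
            bound_setters = dict(
                (lab, st) for lab, _v, _d, st in _varied_scalars(ps_b)
            )
            bound_setters[label](bound)
            comp = compare(
                evaluate_arm(ps_b, cfg, "rivaroxaban"), evaluate_arm(ps_b, cfg, "dalteparin")
            )
            results.append(comp)
        entries.append(
            TornadoEntry(
                label=label,
                delta_cost_low=results[0].delta_cost,
                delta_cost_high=results[1].delta_cost,
                delta_qalys_low=results[0].delta_qalys,
                delta_qalys_high=results[1].delta_qalys,
            )
        )
    entries.sort(key=lambda e: e.impact_range, reverse=True)
    return entries[:top]


def _bounds_for(label: str, ps: ParameterSet, value: float) -> tuple[float | None, float | None]:
    """95% CI bounds for a labelled parameter (stated CI or 25%-SE fallback)."""
    kind, _, key = label.partition(":")
    spec = None
    if kind == "rate":
        spec = ps.rates.get(key)
    elif kind == "cost":
        spec = ps.costs.get(key)
    elif kind == "utility":
        spec = ps.utilities.get(key)
    if spec is not None and spec.ci_low is not None:
        return spec.ci_low, spec.ci_high
    se = se_fallback(value)
    if se == 0:
        return value, value
    lo = max(value - Z95 * se, 0.0)
    hi = value + Z95 * se
    if kind == "utility" or (spec is not None and getattr(spec, "form", None) in (
        "cumulative_risk",
        "monthly_probability",
    )):
        hi = min(hi, 1.0)
    return lo, hi
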