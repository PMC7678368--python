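# cavte

Markov cohort cost-effectiveness and budget-impact modelling of
anticoagulation in **ca**ncer-associated **VTE** (venous thromboembolism).

Cancer patients who experience a VTE — deep vein thrombosis (DVT) or
pulmonary embolism (PE) — receive months of anticoagulation to prevent
recurrence. The guideline standard, daily subcutaneous low molecular weight
heparin (dalteparin), is burdensome and expensive; the oral factor-Xa
inhibitor rivaroxaban lowers VTE recurrence (6-month cumulative risk 4% vs
11%) at the price of more bleeding (major bleeding 6% vs 4%, clinically
relevant non-major bleeding 13% vs 4%). `cavte` is a reusable,
fully-tested implementation of the health-economic pipeline that turns
those trade-offs into decision numbers for the Dutch setting: the
incremental cost-effectiveness ratio (ICER), scenario analyses,
probabilistic and univariate sensitivity analyses, and a national annual
budget impact.

## The model

A deterministic Markov cohort model with 1-month cycles over a 5-year
horizon. 1000 patients enter in the *index VTE* state and face monthly
competing risks of recurrent VTE (incidental PE, symptomatic PE, DVT or
fatal PE), major bleeding (intracranial haemorrhage, non-ICH, fatal),
CRNMB, and all-cause death. Rates `r` become cycle probabilities via
`P = 1 − exp(−r·t)`. Tunnel states (1, 2, …, 60 months post-VTE) carry the
time dependency: patients are on treatment while fewer than 6 months
(base case) have passed since their last VTE, a non-fatal recurrence
resets the clock and restarts treatment, and event states last exactly one
cycle. Severe post-thrombotic syndrome and chronic thromboembolic
pulmonary hypertension run as background prevalence processes. Costs
(2019 euros, discounted 4%/year) accrue in event, treatment and indirect
categories; QALYs (discounted 1.5%/year) accrue as occupancy × utility/12.
The societal perspective includes indirect costs (informal care, travel);
the healthcare-payer perspective drops them.

The comparison reports ΔCosts, ΔQALYs and either an ICER
(Δcost/ΔQALY) or a dominance verdict when one arm is both cheaper and more
effective. The budget impact scales the per-patient cost difference at a
1-year cut-off to the annual number of Dutch cancer patients with VTE
(579 781 cancer patients × 13.9 VTE per 1000 person-years ≈ 8000/year).

Because the study's full input table (unit costs, utilities, off-treatment
rates) is a supplementary file not bundled here, `cavte.synthetic_data`
generates a complete stand-in parameter set: all headline published values
are encoded verbatim and everything else is a seeded placeholder flagged
`synthetic_placeholder`. Supplying a real parameter file via
`load_parameter_set` replaces the fixture wholesale.

## Worked example

```python
from cavte import compare, evaluate_arm, generate_fixture, qalys_to_days
from cavte.synthetic_data import base_config

ps, manifest = generate_fixture(seed=1)
cfg = base_config()

riv = evaluate_arm(ps, cfg, "rivaroxaban")
dal = evaluate_arm(ps, cfg, "dalteparin")
comp = compare(riv, dal)

n = ps.cohort.n_patients
print(f"rivaroxaban: EUR {riv.total_cost / n:.0f}, {riv.total_qalys / n:.3f} QALYs")
print(f"dalteparin:  EUR {dal.total_cost / n:.0f}, {dal.total_qalys / n:.3f} QALYs")
print(f"delta: EUR {comp.delta_cost / n:.0f}, {comp.delta_qalys / n:.4f} QALYs "
      f"({qalys_to_days(comp.delta_qalys / n)} days) -> {comp.verdict}")
```

prints (seed 1 fixture):

```
rivaroxaban: EUR 4435, 2.568 QALYs
dalteparin:  EUR 7049, 2.564 QALYs
delta: EUR -2613, 0.0044 QALYs (1.6 days) -> dominant_A
```

Per patient over five years, rivaroxaban costs €2613 less and yields
0.0044 more QALYs (1.6 quality-adjusted life-days) than dalteparin with
these fixture inputs, so it *dominates*: no ICER is reported because a
ratio of a saving to a health gain has no decision meaning. The
magnitudes of the deltas depend on the placeholder costs and utilities;
the structure (treatment-cost savings driving dominance) is the model's.

A command-line interface wraps the same pipeline:

```sh
cavte generate-fixtures --seed 1 --out params.json
cavte run --params params.json --scenario 2
cavte psa --params params.json --iterations 2000 --seed 1 --out psa.csv
cavte budget --params params.json --psa-iterations 2000
```

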