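# Methods

This note documents the model implemented in `cavte`: its structure,
assumptions, parameters, numerical conventions, and the limits of what the
synthetic fixture can and cannot show.

## State space and transitions

The cohort model tracks expected occupancy over cells `(state, tunnel)`.
The at-risk state `index_vte` carries a tunnel index `k` = months since the
last (index or recurrent) VTE, capped at the horizon. Six transient event
states (recurrent incidental PE, recurrent symptomatic PE, recurrent DVT,
ICH, non-ICH major bleed, CRNMB) are occupied for exactly one cycle;
three dead states (fatal recurrent VTE, fatal major bleed, death by any
cause) and the permanent `post_ich` state absorb. From an at-risk cell the
monthly competing outcomes are:

* recurrent VTE, split across subtypes in proportion to pooled event
  counts (arm-specific counts in the distribution-assumption scenario);
* major bleeding, split into ICH / non-ICH / fatal the same way;
* CRNMB (mutually exclusive with major bleeding within a cycle);
* all-cause death from a registry-style monthly probability table;
* residual mass advancing to tunnel `k+1`.

Rates and cumulative risks convert to cycle probabilities through
`P = 1 − exp(−r·t)`, with `r = −ln(1 − risk)/horizon` inverting a
cumulative risk; the two maps are exact inverses and tested to 1e−12.

Treatment status is a function of the tunnel: on-treatment while
`k < treatment_duration` (6 cycles per arm in the base case). A non-fatal
recurrent VTE returns the patient to tunnel 0, which restarts both the
event-rate clock and the treatment clock (re-treatment). Bleeding events do
not reset the tunnel; after the one-cycle bleed state the patient resumes
at `k+1`. The event month itself therefore advances the tunnel clock by
one cycle, the same amount as an uneventful month; the alternative
(crediting two months after a bleed) would let bleeding shorten the
treatment window, which we judged less defensible.

Event plus death probability mass exceeding 1 in any cell raises an
`InfeasibleParametersError` naming the arm, cycle and state rather than
renormalising silently. All-cause mortality and modelled fatal events are
additive: the registry input is treated as not already containing fatal
VTE/MB, matching a state list that separates "death by any cause" from the
fatal event states. If the registry input did include them, deaths would
be mildly double-counted; with monthly fatal-event probabilities of order
1e−3 the distortion is small, but it is an assumption, not a fact.

Severe post-thrombotic syndrome and CTEPH are background processes:
piecewise-constant monthly onset hazards (indexed by months since model
entry) applied to the alive, not-yet-affected fraction, with the affected
pool scaled by the cohort's one-cycle survival ratio. Tracking them as
marginal prevalence rather than crossing them into every state cell keeps
the state space small; their costs and utility decrements therefore apply
multiplicatively to the whole alive cohort, which slightly mis-attributes
them across health states but preserves totals. Because the model runs a
single cohort from entry, "months since entry" is the only time axis
available to the marginal background process; a tunnel-indexed background
hazard would require the crossed state space we deliberately avoided.

No half-cycle correction is applied; occupancy is counted at cycle start.
This is a deliberate, documented convention so results are reproducible
bit for bit.

## Costs

2019 euros, discounted at 4% per annum as `(1+r)^(−cycle/12)`, in three
categories:

* **Event costs.** One-off acute costs in the cycle of occurrence.
  Incidental PE costs nothing (found on routine tumour imaging); fatal
  recurrent VTE is costed like non-fatal symptomatic PE; fatal major
  bleeding like non-fatal non-ICH major bleeding. ICH and CTEPH have an
  acute first-month cost followed by monthly chronic care on the
  prevalent/post-ICH pool until death; severe PTS has monthly chronic care
  only.
* **Treatment costs.** Drug units dispensed per the phase schedules over
  `days_per_month` = 30.4375 calendar days (365.25/12 — the source never
  states its convention; drug-cost arithmetic needs one): rivaroxaban
  15 mg twice daily for 21 days then 20 mg once daily; dalteparin one
  injection daily, 200 IU/kg in month 1 then 150 IU/kg, priced per dose
  band. The cohort's band follows from weight = BMI × height² =
  25.6 × 1.72² ≈ 75.7 kg → band 69–82 kg (15 000/12 500 IU, €9.93 per
  injection). Rivaroxaban adds an annual renal check-up amortised at 1/12
  per on-treatment cycle (a lump-at-start switch exists; the source gives
  frequency, not timing). Dalteparin adds a one-time injection
  instruction at each treatment start — including re-treatment after a
  recurrence, read as a new treatment episode — and a per-cycle paid
  administration cost restricted to the 39% early/locally-advanced
  subgroup (metastatic and haematologic patients are assumed to already
  have home care).
* **Indirect costs.** Travel for renal-monitoring visits (amortised like
  the visit), DVT and CRNMB episodes; and an informal-care package per
  burdensome acute event (symptomatic PE, DVT, non-ICH MB, ICH) costed as
  a mix of intensive (26 h/week) and non-intensive (8 h/week) care ×
  tariff × duration, restricted to the same 39% subgroup and deliberately
  not applied to chronic complications (avoiding double counting). Tying
  informal care to events rather than to dalteparin treatment is a
  deliberate design choice: it is the only reading consistent with
  indirect costs being *higher* in the arm with more bleeding events.

The healthcare-payer perspective simply drops the indirect category;
QALYs are perspective-invariant.

## Utilities

Annual weights accrued at 1/12 per cycle, discounted at 1.5% per annum.
At-risk cells carry a baseline utility; event months carry baseline minus
an event decrement (floored at 0); post-ICH has its own state utility;
PTS/CTEPH decrements apply to prevalent fractions; all dead states
contribute exactly 0. QALY-to-day conversion uses 365.25 days/year with
half-up rounding to one decimal (0.012 QALYs → 4.4 days).

## Sensitivity analysis

* **PSA.** Probabilities and utilities draw from beta distributions, costs
  from gamma, event-type splits from Dirichlet with the raw counts as
  concentration (zero counts are rejected loudly rather than silently
  regularised). Distributions are fitted by method of moments to the 95%
  CI, SE = (hi − lo)/3.92; parameters without a CI use the 25%-of-mean SE
  fallback. Each iteration applies one coherent draw to both arms (common
  random numbers) and re-runs the full pipeline; 2000 iterations in the
  default analysis. Mortality and official price lists (drug unit prices,
  informal-care tariff) are not sampled: the registry and tariff inputs
  carry no published uncertainty. All draws derive from a single seed and
  the run is bit-reproducible.
* **Tornado.** Each varied parameter is set to its CI bounds in turn with
  everything else at point values; entries are ranked by the absolute
  range of the incremental cost (incremental-QALY ranges are computed in
  the same pass) and the top 10 reported.

## Scenarios and budget impact

Seven predefined runs: base case; 6-month horizon; payer perspective;
low (57–68 kg: 12 500/10 000 IU at €8.06) and high (83–98 kg:
18 000/15 000 IU, placeholder price) dalteparin bands; real-world
treatment durations (3 months rivaroxaban vs 1 month dalteparin on the
6-month horizon); and arm-specific event-type distributions. The budget
impact takes per-patient per-category cost deltas at a 12-cycle cut-off
and scales them by the annual patient population (registry cancer count ×
VTE incidence / 1000; the exact product ≈ 8059 is used, with the rounded
8000 also reported); 95% intervals are percentiles of the same quantity
across PSA iterations. Full replacement is assumed — the number is the
absolute maximum, with no market-share phase-in.

## The synthetic fixture

`generate_fixture(seed)` emulates the study's input table. Verbatim,
provenance-flagged `paper_main_text` values: the six on-treatment 6-month
cumulative risks, the full cohort profile, dosing schedules and the two
published band prices, informal-care hour intensities, discount rates and
run configuration, and the arm-specific ICH shares (6.1%/17.6%) used by
the distribution scenario. Everything else — off-treatment risks, event
costs, utilities, mortality, chronic hazards, tariffs — is drawn uniformly
from ranges declared in `PLACEHOLDER_RANGES` and flagged
`synthetic_placeholder`. Two placeholders are calibrated rather than free:
flat monthly mortality is set so a drawn 40–60% of the cohort survives
5 years (a majority-metastatic population), and the rivaroxaban tablet
price range keeps oral therapy cheaper per month than dalteparin,
preserving the qualitative cost ordering of the drugs.

Consequently the pipeline's *structure* is fully exercised — dominance
verdicts, scenario orderings (larger dose band → larger savings), sign
patterns (treatment savings, extra bleeding costs), conservation and
reproducibility — but the *magnitudes* of costs, QALYs, quadrant shares
and budget totals move with the seed and are not estimates of the
published results. Passing tests demonstrate correctness of the machinery,
not calibration to the evidence base; a user with the real input table
gets the calibrated numbers by loading it with `load_parameter_set`.

## Problem sizes and numerics

The default state space is 7 tunnel-carrying states × 61 tunnel indices
plus 4 scalar states (431 cells); a 60-cycle two-arm evaluation takes
~15 ms, so the 2000-iteration PSA runs in ~20 s on one CPU. Conservation
holds to 1e−9 persons per cycle; transition rows normalise to 1e−12;
residual probabilities are floored at 0 only after an explicit
feasibility check. Tests use 10⁵–10⁶-draw sampling checks at 3-Monte-Carlo-SE
tolerances and a matrix-power oracle on small horizons.

## Known limitations

* Cohort expectations only — no microsimulation, no individual-level
  variance or patient heterogeneity beyond the weight-band scenarios.
* Background chronic conditions are marginal, so their interaction with
  specific health states (e.g. PTS utility in a post-ICH patient) is
  approximate.
* Treatment beyond 6 months (common when cancer stays active) is not
  modelled; the re-treatment rule only restarts therapy after a
  recurrence.
* Productivity and leisure losses are excluded by design, and the
  competing-risk status of the trial cumulative incidences is taken at
  face value.
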