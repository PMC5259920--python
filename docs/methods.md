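# Methods

## The decision problem

`vtecea` implements a lifetime Markov cohort model of anticoagulation for
venous thromboembolism (VTE). A cohort of patients who have just had an index
deep-vein thrombosis (DVT, 65.8%) or pulmonary embolism (PE, 34.2%), mean age
56.9 years and 58.7% male, starts anticoagulant treatment and is followed in
3-month cycles until death or age 100. Three strategies are compared from a
UK NHS perspective:

* **apixaban-18m** — apixaban 10 mg BID for one week, 5 mg BID to month 6,
  then 2.5 mg BID to month 18;
* **lmwh_vka-6m** — LMWH bridging (7 days) plus dose-adjusted VKA to month 6,
  then no treatment;
* **lmwh_vka-18m** — as above with VKA extended to month 18.

Costs (GBP, 2011/12) and QALYs are discounted at 3.5% per year; strategies
are compared by the ICER (incremental cost per QALY gained) against a
£20,000/QALY willingness-to-pay threshold.

## States and events

States: on-treatment and off-treatment index states (split by DVT/PE history,
because the long-term sequelae differ), a two-cycle re-treatment tunnel after
a recurrent event, semi-absorbing post-intracranial-bleed (IC) and chronic
thromboembolic pulmonary hypertension (CTEPH) states that admit only death,
and three absorbing death states (VTE-related, fatal bleed, other). Severe
post-thrombotic syndrome (PTS) is a background attribute of the alive
DVT-history population, not a state: an onset hazard acts on the eligible
mass and the affected fraction carries a lifelong utility decrement and a
quarterly cost.

Each cycle the cohort faces competing risks of: recurrent VTE (split into
VTE death / recurrent PE / recurrent DVT, with separate on- and off-treatment
splits), major bleeding (fatal / non-fatal IC / non-fatal non-IC), clinically
relevant non-major (CRNM) bleeding, adverse-event treatment discontinuation,
CTEPH onset (PE history only), and background death. Marginal per-cycle
probabilities are combined by an exponential-race allocation: with hazards
r_j = −ln(1 − p_j), the total event probability is 1 − exp(−Σ r_j) and event
j receives the share r_j/Σ r_j. This guarantees at most one structural
transition per cycle and reduces exactly to the marginal when only one risk
is non-zero; it is verified against a 10⁶-draw first-event simulation.

Transient events (recurrent DVT/PE, non-IC major bleed, CRNM bleed) are
expected-value pulses — an acute cost plus a duration-limited utility
decrement at incidence — after which the cohort continues in its originating
state. Treatment changes triggered by events (the 6-month re-treatment
course, the 14-day interruption after a non-IC major bleed for the 47.3% who
do not discontinue, the 2-day CRNM interruption) affect costs and utility
exposure only, never transition risks; risk levels change only when a patient
moves to the off-treatment state (IC bleed → permanent discontinuation;
52.7% discontinue after a non-IC major bleed; adverse-event
discontinuation; scheduled end of treatment).

Re-treatment tunnels are keyed by schedule origin: a recurrence on treatment
earns 6 more months of the arm's own drug and then rejoins the schedule; a
recurrence off treatment earns a 6-month LMWH/VKA course and then returns to
off-treatment. Off-origin tunnels always carry off-treatment risk levels.

## Risks and relative effects

Absolute time-segmented risks are those of the reference (apixaban) strategy:
trial-derived per-cycle probabilities to month 18, with "annual rate beyond
month 6" entries converted to the cycle under a constant hazard,
1 − (1 − p)^(1/4). Comparator risks apply constant relative risks on the
hazard scale, p′ = 1 − (1 − p)^RR — bounded in [0, 1) for any RR and equal to
p·RR to first order. The initial LMWH/VKA set applies for months 0–6, the
extended-VKA set (network-meta-analysis) for months 6–18 on treatment, and
the extended-placebo set off treatment; the off-treatment major-bleed risk
uses the trial's absolute annual rate (0.48%) directly rather than an RR.
Beyond month 18 (the limit of trial observation) untreated patients face a
time-declining recurrence schedule (below), and major/CRNM bleeding hazards
in every alive, non-semi-absorbing state are multiplied by 1.97 per decade of
age past the age at month 18.

For lifelong-treatment scenarios the extended-phase risks, prices and
relative effects simply continue (the final printed risk segment persists),
with the ageing bleed multiplier applied.

## Mortality

Background mortality comes from an annual life table (`age, qx_male,
qx_female`), sex-weighted by the cohort mix, converted to the cycle under a
constant hazard within each year of age, and capped by certain death at the
table's end. Excess mortality is applied as hazard ratios multiplied on the
hazard scale: every alive patient carries the post-VTE HR; CTEPH and post-IC
states carry an additional factor.

The analysis this model reproduces used national UK life tables, which are
not redistributable here; all packaged runs use a deterministic synthetic
Gompertz–Makeham table (annual hazard A + B·e^{θa}) calibrated to modern
UK-like longevity — life expectancy at birth 79.1 (male) / 83.3 (female)
years, 26.3 years remaining at age 56.9 for the cohort mix. It is smooth and
monotone in adult age but is explicitly not any national release; users can
substitute a real table CSV.

## Costs and utilities

Drug costs are daily prices times on-treatment days (7 induction days at the
initial apixaban price, or 7 LMWH days at course start), net of interruption
days. VKA courses carry INR monitoring (£122.18 in the first cycle of each
course, £58.72 per subsequent cycle), a one-off self-injection education cost
and per-day administration for the 8% unable to self-inject. Event costs are
charged at incidence; IC bleeds add a first-3-months maintenance cost at
incidence and a per-cycle long-term cost while in the post-IC state, CTEPH a
per-cycle long-term cost, PTS £18 per cycle on the affected fraction.

Utility is baseline 0.825 minus the on-treatment decrement (0.002 apixaban,
0.013 LMWH/VKA), with duration-weighted event decrements at incidence
(days/365.25 × decrement). The post-IC and CTEPH states use their acute state
utilities (0.33, 0.65) for the remainder of life — the source prints no
separate long-term values. Accrual is start-of-cycle with no half-cycle
correction by default (a config flag enables it), matching the era's
spreadsheet convention; under the flag, state accruals use the cycle-average
occupancy and mid-cycle discounting.

## Auxiliary inputs the source does not print

Three inputs are required but unpublished; they ship as clearly flagged
assumptions (`source: assumption` in the parameter file and fixture
manifest), and `vtecea base` writes a sensitivity table over all of them:

* **Excess-mortality hazard ratios** — post-VTE 2.0, CTEPH 4.0, post-IC 2.5,
  typical of the retrospective-cohort literature. Values up to ~5 were
  examined; larger post-VTE HRs shorten the horizon enough to push the
  base-case ICERs away from the published values, so the literature-typical
  2.0 is kept.
* **Late off-treatment recurrence schedule** — annual probabilities 0.11,
  0.05, 0.045, 0.030, 0.022 over years 0–1, 1–3, 3–5, 5–10, 10+ beyond month
  18, reproducing the cumulative recurrence curve of the 10-year
  post-cessation cohort study (≈11%, 20%, 29%, 40% at 1, 3, 5, 10 years).
  The schedule is keyed to model time past month 18, identically in every
  arm.
* **PTS interpretation** — the 8.1% figure is read as a cumulative 5-year
  incidence converted to a constant per-cycle hazard over 20 cycles
  (re-opened for 5 years after each recurrent DVT); a literal
  8.1%-per-cycle reading is available behind `pts_interpretation`.

## Probabilistic and one-way sensitivity

Every parameter with a published 95% CI receives a distribution by domain:
beta for probabilities, fractions and utilities (concentration solved so the
central 95% width matches the CI; the analytic mean equals the point estimate
to 1e-6), gamma for costs (same construction), and lognormal for relative
risks and hazard ratios (ln RR normal with σ = ln(hi/lo)/(2·1.96) about the
log point estimate — the standard convention for ratio estimates, making the
point estimate the median). The width of these families is not monotone in
concentration when the mean sits near a domain edge, so the solver roots on
the high-concentration branch. Event-split fractions are drawn independently
(beta weighted by the published event counts) and renormalized to the
simplex. Administered prices without CIs stay fixed in the PSA but move ±30%
in the one-way analysis.

The PSA re-runs the full model for every draw; the engine broadcasts all
arithmetic over a trailing draw dimension, so 2000 draws × 3 arms complete in
a few seconds on one CPU. The CEAC reports, per willingness-to-pay value, the
fraction of draws in which each strategy has the highest net monetary benefit
(WTP × QALYs − cost). The one-way analysis is evaluated the same way, with
scenario 0 the base case and each parameter at its low/high bound in turn.

## Numerical conventions

Marginal probabilities are clipped at 1 − 1e-12 before log transforms;
occupancy is asserted to sum to 1 within 1e-9 every cycle (the recurrence
split routes the DVT share as a complement so conservation is exact);
survivors at the age cap move to other-cause death; runs stop early once
alive mass falls below 1e-9. Toy models with closed-form answers (geometric
survival, a single event pulse, a two-arm analytic ICER) are packaged in
`vtecea.synthetic` and the engine reproduces them to 1e-10 relative.

## What the synthetic data does and does not show

The synthetic life table emulates the *shape* of modern high-income
mortality, not any specific national table, and the packaged parameter set is
a transcription of the published inputs. Passing tests therefore demonstrate
that the model machinery is correct and that the published deterministic
results follow from the published inputs under documented auxiliary
assumptions — not that the numbers would be identical under the exact
(undeposited) life table and unpublished hazard ratios. Two published
scenario figures (the lifelong-apixaban vs 6-month comparison and the
simplified-mortality comparison against 18-month LMWH/VKA) could not be
brought within tolerance by any defensible setting of the auxiliary inputs
without sacrificing the base-case reproduction; the package reports its own
computed values for them. The probability of cost-effectiveness at £20,000 is
likewise sensitive to the margin between the bleed-RR lower bound ICER and
the threshold and computes at ~80% here.

## Known limitations

Cohort-level expectation only (no microsimulation, no memory of multiple
recurrences); no further VTE or bleeding after IC bleed or CTEPH; PTS
eligibility approximates per-patient 5-year windows with aggregate exposure
buckets; treatment interruptions do not alter risks; secular mortality
improvement and EVPI/EVPPI are out of scope.
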