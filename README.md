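# vtecea

A lifetime Markov cohort cost-effectiveness model of anticoagulation for
venous thromboembolism (VTE), for health economists and methodologists who
want a fully scripted, testable reimplementation of a classic
decision-analytic comparison: 18 months of apixaban (initial plus extended
treatment) versus low-molecular-weight heparin bridging with a vitamin K
antagonist (LMWH/VKA) given for 6 or 18 months, from a UK NHS perspective.

## The model

A cohort with an index DVT (65.8%) or PE (34.2%), mean age 56.9 years, steps
through 3-month cycles until death. Each cycle it faces competing risks of
recurrent VTE (non-fatal DVT, non-fatal PE, or VTE death), major bleeding
(fatal, intracranial, non-intracranial), clinically relevant non-major
bleeding, adverse-event discontinuation, CTEPH (after PE), severe
post-thrombotic syndrome (after DVT, tracked as a background attribute), and
background mortality from an age-and-sex life table with excess-mortality
hazard ratios. Marginal per-cycle probabilities `p_j` are combined as an
exponential race — total event probability `1 − exp(−Σ r_j)` with
`r_j = −ln(1 − p_j)`, shared in proportion to `r_j` — so at most one
transition occurs per cycle. Comparator risks apply constant relative risks
on the hazard scale, `p′ = 1 − (1 − p)^RR`. Costs and QALYs accrue per cycle
(discounted at 3.5%/yr) and strategies are ranked by the ICER,
`ΔCost/ΔQALY`, against £20,000/QALY; probabilistic uncertainty is summarized
by cost-effectiveness acceptability curves built from net monetary benefit,
`WTP × QALYs − Cost`.

Because the national life table used by the original analysis is not
redistributable, the package ships a deterministic synthetic
Gompertz–Makeham table calibrated to modern UK-like longevity; any life
table CSV (`age,qx_male,qx_female`) can be substituted. See
`docs/methods.md` for the full model description, the auxiliary assumptions
and their sensitivity analysis, and known limitations.

## Worked example

```python
import vtecea as v

params = v.default_paper_parameters()   # the published input set
table = v.default_life_table()          # synthetic UK-like life table
base = v.run_base_case(params, table)

inc = base.vs_lmwh_vka_6m
print(f"dCost £{inc.delta_cost:.0f}, dQALY {inc.delta_qaly:.3f}, "
      f"ICER £{inc.icer:.0f}/QALY")
```

prints

```
dCost £768, dQALY 0.103, ICER £7429/QALY
```

— apixaban for 18 months costs £768 more per patient than 6 months of
LMWH/VKA (higher drug acquisition, partly offset by monitoring and event
savings), gains 0.103 quality-adjusted life-years, and therefore costs about
£7,400 per QALY gained, well below the usual £20,000 threshold. The same
result object holds the comparison against 18-month LMWH/VKA (ICER
≈ £8,600/QALY) and per-1000-patient event counts by type.

The same analyses are available from the command line:

```bash
vtecea fixture --out fixture            # parameter YAML + life table + manifest
vtecea base --out results               # deterministic results + auxiliary sensitivity
vtecea owsa --out results               # tornado CSVs
vtecea psa --draws 2000 --seed 2017 --out results   # CEAC + draw cloud
vtecea scenario --apixaban-months lifelong --comparator-months 6
```

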