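"""Markov engine: toy-model oracles, conservation, symmetry, accrual arithmetic."""

import copy

import numpy as np
import pytest

from vtecea.engine import (
    ALIVE_STATES,
    accrue_outcomes,
    base_arms,
    count_events,
    make_arm,
    run_arm,
    run_model,
)
from vtecea.parameters import Param
from vtecea.synthetic import flat_life_table, zero_risk_parameters


def test_pure_mortality_toy_matches_geometric_series(toys):
    t = toys["pure_mortality"]
    trace = run_model(t.arms[0], t.params, t.life_table)
    assert trace.n_cycles == t.expected["n_cycles"]
    for k in (0, 1, 5, 20):
        alive = trace.occupancy[k, ALIVE_STATES].sum()
        assert alive == pytest.approx(t.expected["occupancy_after_k"](k), rel=1e-10)
    o = accrue_outcomes(trace, t.arms[0], t.params)
    assert o.ly_undiscounted == pytest.approx(t.expected["ly_undiscounted"], rel=1e-10)
    assert o.qaly_undiscounted == pytest.approx(t.expected["qaly_undiscounted"], rel=1e-10)


def test_event_pulse_toy_cost_and_qaly(toys):
    t = toys["event_pulse"]
    o = run_arm(t.arms[0], t.params, t.life_table)
    assert o.cost_events == pytest.approx(t.expected["cost_events"], rel=1e-10)
    assert o.ly_undiscounted == pytest.approx(t.expected["ly_undiscounted"], rel=1e-10)
    assert o.qaly_undiscounted == pytest.approx(t.expected["qaly_undiscounted"], rel=1e-10)
    assert o.cost_anticoagulant == 0.0 and o.cost_monitoring_admin == 0.0


def test_analytic_icer_toy(toys):
    from vtecea.analyses import incremental

    t = toys["analytic_icer"]
    inc = incremental(
        run_arm(t.arms[0], t.params, t.life_table),
        run_arm(t.arms[1], t.params, t.life_table),
    )
    assert inc.delta_cost == pytest.approx(t.expected["delta_cost"], rel=1e-10)
    assert inc.delta_qaly == pytest.approx(t.expected["delta_qaly"], rel=1e-10)
    assert inc.icer == pytest.approx(t.expected["icer"], rel=1e-9)
    assert inc.delta_ly == pytest.approx(0.0, abs=1e-12)


def test_mass_conservation_full_model(paper_params, life_table):
    for arm in base_arms():
        trace = run_model(arm, paper_params, life_table)
        totals = trace.occupancy.sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-9)
        for arr in trace.events.values():
            assert np.all(arr >= -1e-15)


def test_run_is_deterministic(paper_params, life_table):
    arm = make_arm("apixaban", 18.0)
    t1 = run_model(arm, paper_params, life_table)
    t2 = run_model(arm, paper_params, life_table)
    assert np.array_equal(t1.occupancy, t2.occupancy)
    for k in t1.events:
        assert np.array_equal(t1.events[k], t2.events[k])


def test_identical_arm_definitions_give_zero_increments(paper_params, life_table):
    from vtecea.analyses import incremental

    arm = make_arm("apixaban", 18.0)
    inc = incremental(
        run_arm(arm, paper_params, life_table), run_arm(arm, paper_params, life_table)
    )
    assert inc.delta_cost == 0.0 and inc.delta_qaly == 0.0 and inc.delta_ly == 0.0
    assert inc.tag == "undefined"


def test_comparator_equals_reference_when_effects_and_prices_equalized(life_table):
    """With all relative effects at 1 and drug/monitoring cost parity, the
    LMWH/VKA arm reproduces the apixaban arm exactly (structural symmetry)."""
    from vtecea.parameters import default_paper_parameters

    p = default_paper_parameters()
    for re_set in p.relative_effects.values():
        for name in ("rr_recurrent_vte", "rr_major_bleed", "rr_crnm_bleed"):
            getattr(re_set, name).value = 1.0
        if re_set.rr_other_discontinuation is not None:
            re_set.rr_other_discontinuation.value = 1.0
    # placebo absolute override would otherwise differ from the reference risks
    p.relative_effects["extended_placebo"].major_bleed_absolute_annual = None
    c = p.costs
    init, ext = c.apixaban_initial_daily.value, c.apixaban_extended_daily.value
    c.lmwh_daily.value = init - ext  # 7*lmwh + d*vka == 7*init + (d-7)*ext
    c.vka_daily.value = ext
    c.lmwh_education_oneoff.value = 0.0
    c.lmwh_admin_daily.value = 0.0
    c.monitoring_first_cycle.value = 0.0
    c.monitoring_subsequent_cycle.value = 0.0
    p.utilities.decrement_lmwh_vka.value = p.utilities.decrement_apixaban.value

    oa = run_arm(make_arm("apixaban", 18.0), p, life_table)
    ov = run_arm(make_arm("lmwh_vka", 18.0), p, life_table)
    assert ov.qaly == pytest.approx(oa.qaly, rel=1e-12)
    assert ov.cost_total == pytest.approx(oa.cost_total, rel=1e-9)
    assert ov.ly == pytest.approx(oa.ly, rel=1e-12)


def test_accrual_arithmetic_single_cycle_on_treatment():
    """First-cycle QALY accrual is 0.25 x (baseline - on-treatment decrement)."""
    p = zero_risk_parameters()
    p.utilities.decrement_apixaban = Param(0.002, kind="decrement")
    lt = flat_life_table(0.0)
    o = run_arm(make_arm("apixaban", 3.0), p, lt, keep_per_cycle=True)
    assert o.per_cycle["qaly"].iloc[0] == pytest.approx(0.25 * (0.825 - 0.002), rel=1e-12)
    assert o.per_cycle["qaly"].iloc[0] == pytest.approx(0.205750, abs=1e-9)
    # off treatment afterwards: no decrement
    assert o.per_cycle["qaly"].iloc[1] == pytest.approx(0.25 * 0.825, rel=1e-12)


def test_incident_pe_pulse_cost_and_decrement():
    """A recurrent PE costs 1340.41 and decrements utility by 0.32 x 30/365.25."""
    p = zero_risk_parameters()
    prob = 0.5
    p.risks["recurrent_vte"].segments[0].prob = Param(prob, kind="probability")
    p.recurrent_split_on.fraction_vte_death.value = 0.0
    p.recurrent_split_on.fraction_pe.value = 1.0
    p.recurrent_split_on.fraction_dvt.value = 0.0
    lt = flat_life_table(0.0)
    o = run_arm(make_arm("apixaban", 3.0), p, lt, keep_per_cycle=True)
    assert o.events_per_1000["recurrent_pe"] == pytest.approx(1000 * prob, rel=1e-10)
    assert o.cost_events == pytest.approx(prob * 1340.41, rel=1e-10)
    expected_dip = prob * 0.32 * 30 / 365.25
    full = 0.25 * 0.825
    assert o.per_cycle["qaly"].iloc[0] == pytest.approx(full - expected_dip, rel=1e-10)


def test_count_events_additivity(base_case, paper_params, life_table):
    trace = run_model(make_arm("apixaban", 18.0), paper_params, life_table)
    ev = count_events(trace, 1000)
    assert ev["recurrent_vte_composite"] == pytest.approx(
        ev["recurrent_dvt"] + ev["recurrent_pe"] + ev["vte_death"], rel=1e-12
    )
    assert ev["major_bleed"] == pytest.approx(
        ev["fatal_bleed"] + ev["ic_bleed"] + ev["nonic_major_bleed"], rel=1e-12
    )


def test_discounted_not_above_undiscounted(base_case):
    for o in base_case.outcomes.values():
        assert o.ly <= o.ly_undiscounted + 1e-12
        assert o.qaly <= o.qaly_undiscounted + 1e-12
        assert o.qaly <= o.ly
        assert min(o.cost_anticoagulant, o.cost_monitoring_admin, o.cost_events) >= 0


def test_dominance_sanity_cost_and_utility_monotonicity(paper_params, life_table):
    """Raising an event cost weakly raises total cost; raising a decrement
    weakly lowers QALYs."""
    arm = make_arm("apixaban", 18.0)
    o0 = run_arm(arm, paper_params, life_table)

    p = copy.deepcopy(paper_params)
    p.costs.event_crnm_bleed.value *= 2
    assert run_arm(arm, p, life_table).cost_total > o0.cost_total

    p = copy.deepcopy(paper_params)
    p.utilities.decrement_pts.value = 0.2
    assert run_arm(arm, p, life_table).qaly < o0.qaly


def test_absorbing_death_and_age_cap(paper_params, life_table):
    trace = run_model(make_arm("lmwh_vka", 6.0), paper_params, life_table)
    # cohort fully dead at the end of the run
    assert trace.occupancy[-1, ALIVE_STATES].sum() == pytest.approx(0.0, abs=1e-9)
    dead = trace.occupancy[:, 14:].sum(axis=1)
    assert np.all(np.diff(dead) >= -1e-12)  # death is absorbing


def test_trace_export_frame(paper_params, life_table):
    trace = run_model(make_arm("apixaban", 18.0), paper_params, life_table)
    df = trace.to_frame()
    assert len(df) == trace.n_cycles
    assert {"cycle", "age", "on_dvt", "pts_fraction", "ev_major_bleed"} <= set(df.columns)
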