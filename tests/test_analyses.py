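"""Incremental CEA, tornado, PSA/CEAC and duration scenarios."""

import copy
import math

import numpy as np
import pytest

from vtecea.analyses import (
    IncrementalResult,
    incremental,
    run_owsa,
    run_psa,
    run_scenario_durations,
    simplified_mortality_parameters,
)
from vtecea.engine import make_arm, run_arm
from vtecea.parameters import iter_params


class _Stub:
    def __init__(self, cost, qaly, ly=10.0):
        self.cost_anticoagulant = cost
        self.cost_monitoring_admin = 0.0
        self.cost_events = 0.0
        self.cost_total = cost
        self.qaly = qaly
        self.ly = ly
        self.events_per_1000 = {}


def test_incremental_identical_outcomes_undefined():
    inc = incremental(_Stub(100.0, 5.0), _Stub(100.0, 5.0))
    assert inc.delta_cost == 0 and inc.delta_qaly == 0
    assert inc.icer is None and inc.tag == "undefined"


def test_incremental_dominance_tags():
    assert incremental(_Stub(90.0, 5.1), _Stub(100.0, 5.0)).tag == "dominant"
    assert incremental(_Stub(110.0, 4.9), _Stub(100.0, 5.0)).tag == "dominated"
    inc = incremental(_Stub(637.0, 5.063), _Stub(100.0, 5.0))
    assert inc.tag == "icer"
    assert inc.icer == pytest.approx(537.0 / 0.063, rel=1e-12)


def test_icer_from_rounded_components_matches_table_style_arithmetic():
    """Reconstructing the ratio from rounded table rows: (1023-385-101)/0.063."""
    inc = IncrementalResult(
        delta_cost=537.2,
        delta_qaly=0.0630,
        delta_ly=0.046,
        icer=537.2 / 0.0630,
        tag="icer",
        delta_cost_anticoagulant=1023.4,
        delta_cost_monitoring_admin=-385.2,
        delta_cost_events=-100.9,
    )
    assert inc.icer_from_rounded_components() == pytest.approx(
        (1023 - 385 - 101) / 0.063, rel=1e-12
    )


def test_base_case_internal_consistency(base_case):
    """The ICER recomputed from the run's own rounded cost components and
    rounded delta-QALY agrees with the reported ICER to rounding error."""
    for inc in (base_case.vs_lmwh_vka_6m, base_case.vs_lmwh_vka_18m):
        approx = inc.icer_from_rounded_components()
        # worst-case rounding: 1.5 GBP on costs, half a point on the 3-dp QALY
        bound = (1.5 + abs(inc.icer) * 5e-4) / (abs(inc.delta_qaly) - 5e-4)
        assert abs(approx - inc.icer) <= bound


def test_base_case_cost_directions(base_case):
    """The reference strategy trades higher drug spend for lower monitoring."""
    oa = base_case.outcomes["apixaban-18m"]
    for label in ("lmwh_vka-6m", "lmwh_vka-18m"):
        oc = base_case.outcomes[label]
        assert oa.cost_anticoagulant > oc.cost_anticoagulant
        assert oa.cost_monitoring_admin < oc.cost_monitoring_admin


def test_owsa_unused_parameters_have_zero_spread(paper_params, life_table):
    """Extended-VKA effects never enter the comparison against 6-month LMWH/VKA."""
    entries = {e.parameter: e for e in run_owsa(paper_params, life_table, "lmwh_vka-6m")}
    for name in (
        "relative_effects.extended_vka.rr_major_bleed",
        "relative_effects.extended_vka.rr_recurrent_vte",
    ):
        assert entries[name].spread == pytest.approx(0.0, abs=1e-6)
    # while a parameter that drives the comparison has material spread
    assert entries["costs.apixaban_extended_daily"].spread > 1000


def test_owsa_sorted_by_spread(paper_params, life_table):
    entries = run_owsa(paper_params, life_table, "lmwh_vka-18m")
    spreads = [e.spread for e in entries]
    assert spreads == sorted(spreads, reverse=True)
    assert entries[0].parameter == "relative_effects.extended_vka.rr_major_bleed"


def test_psa_all_fixed_is_step_function(paper_params, life_table):
    p = copy.deepcopy(paper_params)
    for _, prm in iter_params(p):
        prm.ci_low = prm.ci_high = None
    res = run_psa(p, life_table, n_draws=8, seed=5)
    probs = res.probabilities.to_numpy()
    assert set(np.unique(probs)) <= {0.0, 1.0}
    np.testing.assert_allclose(probs.sum(axis=1), 1.0)


def test_psa_seed_reproducible_and_ceac_sums_to_one(paper_params, life_table):
    r1 = run_psa(paper_params, life_table, n_draws=100, seed=9)
    r2 = run_psa(paper_params, life_table, n_draws=100, seed=9)
    assert r1.probabilities.equals(r2.probabilities)
    assert r1.draws.equals(r2.draws)
    np.testing.assert_allclose(r1.probabilities.sum(axis=1), 1.0, atol=1e-12)
    r3 = run_psa(paper_params, life_table, n_draws=100, seed=10)
    assert not r3.draws.equals(r1.draws)


def test_psa_mean_consistent_with_deterministic(paper_params, life_table, base_case):
    """Monte-Carlo mean of the incremental QALY cloud sits near the
    deterministic value (medians of the ratio draws keep it slightly offset,
    so the check is SE-based on a moderate sample)."""
    res = run_psa(paper_params, life_table, n_draws=400, seed=123)
    det = base_case.vs_lmwh_vka_6m.delta_qaly
    dq = res.draws["delta_qaly_vs_6m"]
    se = dq.std(ddof=1) / math.sqrt(len(dq))
    assert abs(dq.mean() - det) < max(3 * se, 0.3 * abs(det))


def test_nmb_tie_at_wtp_equal_to_icer(base_case):
    inc = base_case.vs_lmwh_vka_18m
    oa = base_case.outcomes["apixaban-18m"]
    oc = base_case.outcomes["lmwh_vka-18m"]
    wtp = inc.icer
    nmb_a = wtp * oa.qaly - oa.cost_total
    nmb_c = wtp * oc.qaly - oc.cost_total
    assert nmb_a == pytest.approx(nmb_c, abs=1e-6)


def test_scenario_base_durations_reproduce_base_case(paper_params, life_table, base_case):
    inc = run_scenario_durations(paper_params, life_table, 18.0, 6.0)
    assert inc.icer == pytest.approx(base_case.vs_lmwh_vka_6m.icer, rel=1e-12)
    assert inc.delta_qaly == pytest.approx(base_case.vs_lmwh_vka_6m.delta_qaly, rel=1e-12)


def test_lifelong_comparison_directions(paper_params, life_table):
    """Lifelong apixaban versus lifelong LMWH/VKA: far fewer bleeding events."""
    inc = run_scenario_durations(paper_params, life_table, math.inf, math.inf)
    assert inc.delta_events_per_1000["major_bleed"] < 0
    assert inc.delta_events_per_1000["crnm_bleed"] < 0
    assert inc.delta_qaly > 0


def test_simplified_mortality_parameters(paper_params):
    q = simplified_mortality_parameters(paper_params)
    assert q.settings.hr_post_vte.value == 1.0
    assert q.settings.hr_post_ic_bleed.value == 1.0
    assert q.long_term.bleed_age_multiplier_per_decade.value == 1.0
    # CTEPH excess mortality is retained (those patients are not event-free)
    assert q.settings.hr_cteph.value == paper_params.settings.hr_cteph.value


def test_simplified_mortality_lengthens_life(paper_params, life_table, base_case):
    q = simplified_mortality_parameters(paper_params)
    o = run_arm(make_arm("apixaban", 18.0), q, life_table)
    assert o.ly > base_case.outcomes["apixaban-18m"].ly
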