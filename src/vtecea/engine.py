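"""Markov cohort engine: lifetime simulation of one treatment arm.

State space (3-month cycles, cohort fractions):

* On-treatment and off-treatment index states, split by event history
  (DVT vs PE) because the long-term sequelae differ (PTS after DVT,
  CTEPH after PE).
* A 6-month (2-cycle) re-treatment tunnel after a recurrent event, split by
  the re-treatment drug. Following the published model, the tunnel carries
  the drug's costs and utility decrement only; transition risks continue to
  follow the patient's scheduled on/off-treatment position ("treatment
  changes did not affect risks, only costs and utilities").
* Semi-absorbing post-intracranial-bleed and CTEPH states (death-only exits).
* Three absorbing death states (VTE-related, fatal bleed, other causes) so
  the cause-of-death ledger stays reproducible.

Severe PTS is a background attribute, not a state: a per-cycle onset hazard
acts on the eligible DVT-history occupancy and the affected fraction accrues
a lifelong utility decrement and quarterly cost.

Transient events (recurrent DVT/PE, non-IC major bleed, CRNM bleed) are
expected-value pulses: cost plus a duration-limited utility decrement at
incidence, with the cohort returning to (or continuing in) its originating
state. Competing risks within a cycle are allocated by the exponential-race
rule in :mod:`vtecea.hazards`, so at most one structural transition happens
per cycle.

All arithmetic broadcasts over trailing draw dimensions, so the same code
runs the deterministic model and a fully vectorized probabilistic analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hazards import age_bleed_multiplier, apply_relative_risk, combine_competing, rescale_prob
from .mortality import LifeTable, background_death_prob, excess_death_prob
from .parameters import ModelParameters

__all__ = [
    "ArmSchedule",
    "make_arm",
    "base_arms",
    "CohortTrace",
    "Outcomes",
    "run_model",
    "accrue_outcomes",
    "count_events",
    "run_arm",
]

DAYS_PER_YEAR = 365.25

# state indices; tunnels are keyed by schedule origin (on/off treatment), which
# also determines the re-treatment drug: on-origin uses the arm's own drug,
# off-origin uses the LMWH/VKA policy course
ON_DVT, ON_PE, OFF_DVT, OFF_PE = 0, 1, 2, 3
RT1_DVT_ON, RT1_PE_ON, RT2_DVT_ON, RT2_PE_ON = 4, 5, 6, 7
RT1_DVT_OFF, RT1_PE_OFF, RT2_DVT_OFF, RT2_PE_OFF = 8, 9, 10, 11
POST_IC, CTEPH_STATE = 12, 13
DEAD_VTE, DEAD_BLEED, DEAD_OTHER = 14, 15, 16
N_STATES = 17

ALIVE_STATES = list(range(14))
DVT_HISTORY_STATES = [ON_DVT, OFF_DVT, RT1_DVT_ON, RT2_DVT_ON, RT1_DVT_OFF, RT2_DVT_OFF]
PE_HISTORY_STATES = [ON_PE, OFF_PE, RT1_PE_ON, RT2_PE_ON, RT1_PE_OFF, RT2_PE_OFF]
RT1_ON_STATES, RT2_ON_STATES = [RT1_DVT_ON, RT1_PE_ON], [RT2_DVT_ON, RT2_PE_ON]
RT1_OFF_STATES, RT2_OFF_STATES = [RT1_DVT_OFF, RT1_PE_OFF], [RT2_DVT_OFF, RT2_PE_OFF]

EVENT_KEYS = [
    "recurrent_dvt",
    "recurrent_pe",
    "vte_death",
    "major_bleed",
    "fatal_bleed",
    "ic_bleed",
    "nonic_major_bleed",
    "crnm_bleed",
    "ae_discontinuation",
    "cteph_onset",
    "pts_onset",
    "other_death",
    "interruption_days_apixaban",
    "interruption_days_lmwh_vka",
]


@dataclass
class ArmSchedule:
    """A treatment strategy: which drug, and for how many months.

    ``duration_months`` may be ``inf`` for lifelong treatment. The drug's
    dosing phases (induction week, long-term, extended) are encoded in the
    costing rules rather than enumerated, because they only affect prices.
    """

    label: str
    drug: str  # "apixaban" | "lmwh_vka"
    duration_months: float

    def on_treatment(self, month: float) -> bool:
        return month < self.duration_months

    def relative_effects_key(self, month: float):
        """Which published RR set applies to on-treatment risks at ``month``."""
        if self.drug == "apixaban":
            return None  # reference strategy: absolute risks as printed
        return "initial_lmwh_vka" if month < 6.0 else "extended_vka"


def make_arm(drug: str, duration_months: float) -> ArmSchedule:
    if drug not in ("apixaban", "lmwh_vka"):
        raise ValueError(f"unknown drug {drug!r}")
    dur = "lifelong" if math.isinf(duration_months) else f"{duration_months:g}m"
    return ArmSchedule(f"{drug}-{dur}", drug, duration_months)


def base_arms() -> tuple[ArmSchedule, ArmSchedule, ArmSchedule]:
    """The three base-case strategies: apixaban 18 m, LMWH/VKA 6 m and 18 m."""
    return make_arm("apixaban", 18.0), make_arm("lmwh_vka", 6.0), make_arm("lmwh_vka", 18.0)


@dataclass
class CohortTrace:
    """State occupancancy, PTS attribute and incident events over all cycles."""

    arm: ArmSchedule
    n_cycles: int
    cycle_years: float
    starting_age: float
    occupancy: np.ndarray  # (n_cycles + 1, N_STATES, ...) at cycle starts
    pts_mass: np.ndarray  # (n_cycles + 1, ...)
    events: dict[str, np.ndarray]  # each (n_cycles, ...)

    def alive(self, k: int):
        return self.occupancy[k, ALIVE_STATES].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Cycle-by-cycle export (deterministic runs only)."""
        if self.occupancy.ndim != 2:
            raise ValueError("to_frame supports scalar (non-vectorized) traces only")
        names = [
            "on_dvt", "on_pe", "off_dvt", "off_pe",
            "rt1_dvt_on", "rt1_pe_on", "rt2_dvt_on", "rt2_pe_on",
            "rt1_dvt_off", "rt1_pe_off", "rt2_dvt_off", "rt2_pe_off",
            "post_ic", "cteph", "dead_vte", "dead_bleed", "dead_other",
        ]
        df = pd.DataFrame(self.occupancy[:-1], columns=names)
        df.insert(0, "cycle", np.arange(self.n_cycles))
        df.insert(1, "age", self.starting_age + np.arange(self.n_cycles) * self.cycle_years)
        df["pts_fraction"] = self.pts_mass[:-1]
        for key, arr in self.events.items():
            df[f"ev_{key}"] = arr
        return df


@dataclass
class Outcomes:
    """Discounted per-patient accruals and undiscounted event counts."""

    ly: np.ndarray
    qaly: np.ndarray
    cost_anticoagulant: np.ndarray
    cost_monitoring_admin: np.ndarray
    cost_events: np.ndarray
    ly_undiscounted: np.ndarray
    qaly_undiscounted: np.ndarray
    events_per_1000: dict[str, np.ndarray] = field(default_factory=dict)
    per_cycle: pd.DataFrame | None = None

    @property
    def cost_total(self):
        return self.cost_anticoagulant + self.cost_monitoring_admin + self.cost_events


# --------------------------------------------------------------------------
# per-cycle risk contexts
# --------------------------------------------------------------------------


def _late_recurrence_cycle_prob(p: ModelParameters, month: float):
    """Per-cycle recurrent-VTE probability for untreated patients beyond month 18.

    The untreated-cohort schedule is keyed to model time past the trial
    horizon (month 18), identically in every arm.
    """
    years_beyond = (month - 18.0) / 12.0
    for band in p.long_term.late_recurrence_schedule:
        if band.start_year <= years_beyond < band.end_year:
            return rescale_prob(band.annual_prob.value, 1.0, p.settings.cycle_years)
    band = p.long_term.late_recurrence_schedule[-1]
    return rescale_prob(band.annual_prob.value, 1.0, p.settings.cycle_years)


def _cycle_contexts(p: ModelParameters, arm: ArmSchedule, month: float, age: float):
    """Marginal per-cycle event risks for the on- and off-treatment contexts."""
    cyc_months = p.settings.cycle_years * 12.0
    apix = p.risks
    ageing_on = month >= p.settings.ageing_applies_after_months
    mult = (
        age_bleed_multiplier(
            age,
            p.population.starting_age + p.settings.ageing_applies_after_months / 12.0,
            p.long_term.bleed_age_multiplier_per_decade.value,
        )
        if ageing_on
        else 1.0
    )

    # --- on-treatment ---
    rr_key = arm.relative_effects_key(month)
    vte_on = apix["recurrent_vte"].per_cycle(month, cyc_months)
    mb_on = apix["major_bleed"].per_cycle(month, cyc_months)
    crnm_on = apix["crnm_bleed"].per_cycle(month, cyc_months)
    disc_on = apix["ae_discontinuation"].per_cycle(month, cyc_months)
    if rr_key is not None:
        rrs = p.relative_effects[rr_key]
        vte_on = apply_relative_risk(vte_on, rrs.rr_recurrent_vte.value)
        mb_on = apply_relative_risk(mb_on, rrs.rr_major_bleed.value)
        crnm_on = apply_relative_risk(crnm_on, rrs.rr_crnm_bleed.value)
        if rrs.rr_other_discontinuation is not None:
            disc_on = apply_relative_risk(disc_on, rrs.rr_other_discontinuation.value)
    if ageing_on:
        mb_on = apply_relative_risk(mb_on, mult)
        crnm_on = apply_relative_risk(crnm_on, mult)

    # --- off-treatment ---
    placebo = p.relative_effects["extended_placebo"]
    if month < 18.0:
        vte_off = apply_relative_risk(vte_on_reference(apix, month, cyc_months), placebo.rr_recurrent_vte.value)
    else:
        vte_off = _late_recurrence_cycle_prob(p, month)
    if placebo.major_bleed_absolute_annual is not None:
        mb_off = rescale_prob(placebo.major_bleed_absolute_annual.value, 1.0, p.settings.cycle_years)
    else:
        mb_off = apply_relative_risk(apix["major_bleed"].per_cycle(month, cyc_months), placebo.rr_major_bleed.value)
    crnm_off = apply_relative_risk(apix["crnm_bleed"].per_cycle(month, cyc_months), placebo.rr_crnm_bleed.value)
    if ageing_on:
        mb_off = apply_relative_risk(mb_off, mult)
        crnm_off = apply_relative_risk(crnm_off, mult)

    on = {"vte": vte_on, "mb": mb_on, "crnm": crnm_on, "disc": disc_on}
    off = {"vte": vte_off, "mb": mb_off, "crnm": crnm_off, "disc": 0.0}
    return on, off


def vte_on_reference(apix, month, cyc_months):
    return apix["recurrent_vte"].per_cycle(month, cyc_months)


# --------------------------------------------------------------------------
# the cohort run
# --------------------------------------------------------------------------


def run_model(arm: ArmSchedule, p: ModelParameters, life_table: LifeTable) -> CohortTrace:
    """Step the cohort through its lifetime for one arm; deterministic.

    The whole cohort starts in the on-treatment index states (DVT/PE mix per
    the trial population); the run ends when the cohort is dead or reaches
    the maximum age, at which point survivors are moved to other-cause death.
    """
    s = p.settings
    cyc = s.cycle_years
    cyc_months = cyc * 12.0
    start_age = p.population.starting_age
    male_frac = float(np.asarray(p.population.male_fraction.value).reshape(-1)[0])
    n_cycles = int(math.ceil((s.max_age - start_age) / cyc))

    # broadcast shape across any vectorized (sampled) parameter leaves
    shape = np.broadcast_shapes(
        *(np.shape(prm_val) for prm_val in _numeric_leaves(p))
    )

    occ = np.zeros((n_cycles + 1, N_STATES) + shape)
    pts = np.zeros((n_cycles + 1,) + shape)
    events = {k: np.zeros((n_cycles,) + shape) for k in EVENT_KEYS}

    dvt0 = p.population.index_dvt_fraction.value
    pe0 = p.population.index_pe_fraction.value
    if arm.duration_months > 0:
        occ[0, ON_DVT], occ[0, ON_PE] = (np.broadcast_to(dvt0, shape), np.broadcast_to(pe0, shape))
    else:
        occ[0, OFF_DVT], occ[0, OFF_PE] = (np.broadcast_to(dvt0, shape), np.broadcast_to(pe0, shape))

    # PTS exposure queue: (remaining eligible mass, cycles left in 5-y window)
    horizon_cycles = int(round(p.long_term.pts_horizon_years / cyc))
    literal_pts = p.long_term.pts_interpretation == "literal-per-cycle"
    if literal_pts:
        h_pts = p.long_term.pts_cumulative_probability.value
    else:
        h_pts = rescale_prob(
            p.long_term.pts_cumulative_probability.value, p.long_term.pts_horizon_years, cyc
        )
    pts_queue: list[list] = [[occ[0, ON_DVT] + occ[0, OFF_DVT], horizon_cycles]]

    cteph_cycle = rescale_prob(
        p.long_term.cteph_probability.value, p.long_term.cteph_period_years, cyc
    )
    hr_vte = p.settings.hr_post_vte.value
    hr_cteph_total = hr_vte * p.settings.hr_cteph.value
    hr_ic_total = hr_vte * p.settings.hr_post_ic_bleed.value

    split_on, split_off = p.recurrent_split_on, p.recurrent_split_off
    bs = p.major_bleed_split
    disc_frac = p.policy.discontinue_after_nonic_major_bleed.value

    for k in range(n_cycles):
        month = k * cyc_months
        age = start_age + k * cyc
        cur = occ[k]
        nxt = occ[k + 1]

        q_bg = background_death_prob(life_table, age, male_frac, cyc)
        death_base = excess_death_prob(q_bg, hr_vte)
        death_ic = excess_death_prob(q_bg, hr_ic_total)
        death_cteph = excess_death_prob(q_bg, hr_cteph_total)

        on_ctx, off_ctx = _cycle_contexts(p, arm, month, age)
        is_on = arm.on_treatment(month)
        sched_ctx = on_ctx if is_on else off_ctx
        sched_split = split_on if is_on else split_off
        # continuation of the main schedule for the next cycle
        next_on = arm.on_treatment(month + cyc_months)
        on_cont = {True: {"dvt": ON_DVT, "pe": ON_PE}, False: {"dvt": OFF_DVT, "pe": OFF_PE}}[next_on]

        dvt_death_blend_num = 0.0
        dvt_death_blend_den = 0.0
        new_recurrent_dvt = 0.0

        def process(state, hist, ctx, split, continuation, drug_now, origin):
            """Route one state's occupancy through this cycle's competing risks."""
            nonlocal dvt_death_blend_num, dvt_death_blend_den, new_recurrent_dvt
            m = cur[state]
            marginals = {
                "vte": ctx["vte"],
                "mb": ctx["mb"],
                "crnm": ctx["crnm"],
                "disc": ctx["disc"],
                "death": death_base,
            }
            if hist == "pe":
                marginals["cteph"] = cteph_cycle
            eff, stay = combine_competing(marginals)
            eff = {kk: vv * m for kk, vv in eff.items()}
            stay_m = stay * m

            off_state = OFF_DVT if hist == "dvt" else OFF_PE
            rt1 = {
                ("on", "dvt"): RT1_DVT_ON, ("on", "pe"): RT1_PE_ON,
                ("off", "dvt"): RT1_DVT_OFF, ("off", "pe"): RT1_PE_OFF,
            }

            # recurrent VTE composite
            v = eff["vte"]
            d_vte = v * split.fraction_vte_death.value
            d_pe = v * split.fraction_pe.value
            d_dvt = v - d_vte - d_pe  # complement keeps mass conserved exactly
            nxt[DEAD_VTE] += d_vte
            nxt[rt1[(origin, "pe")]] += d_pe
            nxt[rt1[(origin, "dvt")]] += d_dvt
            events["vte_death"][k] += d_vte
            events["recurrent_pe"][k] += d_pe
            events["recurrent_dvt"][k] += d_dvt
            new_recurrent_dvt += d_dvt

            # major bleed
            b = eff["mb"]
            fatal = b * bs.fraction_fatal.value
            nonfatal = b - fatal
            ic = nonfatal * bs.fraction_ic_of_nonfatal.value
            nonic = nonfatal - ic
            nxt[DEAD_BLEED] += fatal
            nxt[POST_IC] += ic
            if drug_now is not None:  # on some treatment: bleed-driven discontinuation
                nonic_off = nonic * disc_frac
                nonic_stay = nonic - nonic_off
                nxt[off_state] += nonic_off
                nxt[continuation] += nonic_stay
                events[f"interruption_days_{drug_now}"][k] += (
                    nonic_stay * p.policy.interruption_days_nonic_major_bleed
                    + eff["crnm"] * p.policy.interruption_days_crnm_bleed
                )
            else:
                nxt[continuation] += nonic
            events["major_bleed"][k] += b
            events["fatal_bleed"][k] += fatal
            events["ic_bleed"][k] += ic
            events["nonic_major_bleed"][k] += nonic

            # CRNM bleed: transient, return to continuation
            nxt[continuation] += eff["crnm"]
            events["crnm_bleed"][k] += eff["crnm"]

            # adverse-event discontinuation
            nxt[off_state] += eff["disc"]
            events["ae_discontinuation"][k] += eff["disc"]

            # CTEPH onset (PE history only)
            if hist == "pe":
                nxt[CTEPH_STATE] += eff["cteph"]
                events["cteph_onset"][k] += eff["cteph"]

            nxt[DEAD_OTHER] += eff["death"]
            events["other_death"][k] += eff["death"]
            nxt[continuation] += stay_m

            if hist == "dvt":
                dvt_death_blend_num = dvt_death_blend_num + (eff["death"] + d_vte + fatal)
                dvt_death_blend_den = dvt_death_blend_den + m

        retreat_drug = p.policy.retreatment_drug_off_treatment
        # index on/off states
        process(ON_DVT, "dvt", on_ctx, split_on, on_cont["dvt"], arm.drug, "on")
        process(ON_PE, "pe", on_ctx, split_on, on_cont["pe"], arm.drug, "on")
        process(OFF_DVT, "dvt", off_ctx, split_off, OFF_DVT, None, "off")
        process(OFF_PE, "pe", off_ctx, split_off, OFF_PE, None, "off")
        # re-treatment tunnels carry costs only; risks follow the schedule
        # origin (on-origin: the arm's scheduled position; off-origin: the
        # off-treatment risk profile), and a recurrence restarts the tunnel
        process(RT1_DVT_ON, "dvt", sched_ctx, sched_split, RT2_DVT_ON, arm.drug, "on")
        process(RT1_PE_ON, "pe", sched_ctx, sched_split, RT2_PE_ON, arm.drug, "on")
        process(RT2_DVT_ON, "dvt", sched_ctx, sched_split, on_cont["dvt"], arm.drug, "on")
        process(RT2_PE_ON, "pe", sched_ctx, sched_split, on_cont["pe"], arm.drug, "on")
        process(RT1_DVT_OFF, "dvt", off_ctx, split_off, RT2_DVT_OFF, retreat_drug, "off")
        process(RT1_PE_OFF, "pe", off_ctx, split_off, RT2_PE_OFF, retreat_drug, "off")
        process(RT2_DVT_OFF, "dvt", off_ctx, split_off, OFF_DVT, retreat_drug, "off")
        process(RT2_PE_OFF, "pe", off_ctx, split_off, OFF_PE, retreat_drug, "off")

        # semi-absorbing states: death only
        for state, dq in ((POST_IC, death_ic), (CTEPH_STATE, death_cteph)):
            m = cur[state]
            nxt[DEAD_OTHER] += m * dq
            events["other_death"][k] += m * dq
            nxt[state] += m * (1.0 - dq)

        # absorbing death states
        for state in (DEAD_VTE, DEAD_BLEED, DEAD_OTHER):
            nxt[state] += cur[state]

        # --- PTS background attribute ---
        dvt_death_rate = np.where(
            np.asarray(dvt_death_blend_den) > 1e-300,
            dvt_death_blend_num / np.maximum(dvt_death_blend_den, 1e-300),
            0.0,
        )
        pts_now = pts[k]
        onset = 0.0
        if literal_pts:
            eligible = np.maximum(cur[DVT_HISTORY_STATES].sum(axis=0) - pts_now, 0.0)
            onset = h_pts * eligible
        else:
            remaining = []
            for mass, left in pts_queue:
                o = h_pts * mass
                onset = onset + o
                mass = (mass - o) * (1.0 - dvt_death_rate)
                if left - 1 > 0:
                    remaining.append([mass, left - 1])
            pts_queue = remaining
            if np.any(np.asarray(new_recurrent_dvt) > 0):
                pts_queue.append([new_recurrent_dvt, horizon_cycles])
        events["pts_onset"][k] = onset
        pts[k + 1] = (pts_now + onset) * (1.0 - dvt_death_rate)

        total = nxt.sum(axis=0)
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise AssertionError(f"occupancy mass not conserved at cycle {k}: {total}")

        alive = nxt[ALIVE_STATES].sum(axis=0)
        if np.max(alive) < 1e-9:
            n_cycles = k + 1
            occ = occ[: n_cycles + 1]
            pts = pts[: n_cycles + 1]
            events = {kk: vv[:n_cycles] for kk, vv in events.items()}
            break

    # age cap: survivors move to other-cause death after the final cycle
    final_alive = occ[n_cycles, ALIVE_STATES].sum(axis=0)
    occ[n_cycles, DEAD_OTHER] += final_alive
    occ[n_cycles, ALIVE_STATES] = 0.0
    pts[n_cycles] = 0.0

    return CohortTrace(
        arm=arm,
        n_cycles=n_cycles,
        cycle_years=cyc,
        starting_age=start_age,
        occupancy=occ,
        pts_mass=pts,
        events=events,
    )


def _numeric_leaves(p: ModelParameters):
    from .parameters import iter_params

    for _, prm in iter_params(p):
        yield prm.value


# --------------------------------------------------------------------------
# accrual
# --------------------------------------------------------------------------


def accrue_outcomes(
    trace: CohortTrace, arm: ArmSchedule, p: ModelParameters, keep_per_cycle: bool = False
) -> Outcomes:
    """Discounted life-years, QALYs and costs by category from a cohort trace.

    Accrual is start-of-cycle (no half-cycle correction unless configured);
    events are costed and utility-decremented at incidence.
    """
    s = p.settings
    cyc = s.cycle_years
    cyc_days = cyc * DAYS_PER_YEAR
    K = trace.n_cycles
    shape = trace.occupancy.shape[2:]

    c = p.costs
    u = p.utilities
    ev = trace.events

    v = (1.0 + s.discount_rate) ** (-(np.arange(K) * cyc))
    occ = trace.occupancy[:K]
    if s.half_cycle_correction:
        occ = 0.5 * (trace.occupancy[:K] + trace.occupancy[1 : K + 1])
        v = (1.0 + s.discount_rate) ** (-((np.arange(K) + 0.5) * cyc))
    pts = trace.pts_mass[:K]
    vx = v.reshape((K,) + (1,) * len(shape))

    alive = occ[:, ALIVE_STATES].sum(axis=1)
    ly_c = cyc * alive

    # state utilities
    u_apix = u.baseline.value - u.decrement_apixaban.value
    u_vka = u.baseline.value - u.decrement_lmwh_vka.value
    u_off = u.baseline.value
    on_drug_u = u_apix if arm.drug == "apixaban" else u_vka
    util = (
        (occ[:, ON_DVT] + occ[:, ON_PE]) * on_drug_u
        + (occ[:, OFF_DVT] + occ[:, OFF_PE]) * u_off
        + occ[:, RT1_ON_STATES + RT2_ON_STATES].sum(axis=1) * on_drug_u
        + occ[:, RT1_OFF_STATES + RT2_OFF_STATES].sum(axis=1) * u_vka
        + occ[:, POST_IC] * u.ic_bleed_acute.value.value
        + occ[:, CTEPH_STATE] * u.cteph_acute.value.value
        - pts * u.decrement_pts.value
    )
    qaly_c = cyc * util

    # transient-event utility pulses (duration-limited decrements)
    def pulse(item):
        return item.value.value * item.days / DAYS_PER_YEAR

    qaly_c = qaly_c - (
        ev["recurrent_dvt"] * pulse(u.decrement_dvt)
        + ev["recurrent_pe"] * pulse(u.decrement_pe)
        + ev["nonic_major_bleed"] * pulse(u.decrement_nonic_bleed)
        + ev["crnm_bleed"] * pulse(u.decrement_crnm_bleed)
    )
    # treatment interruptions relieve the on-treatment decrement
    qaly_c = qaly_c + (
        ev["interruption_days_apixaban"] * u.decrement_apixaban.value
        + ev["interruption_days_lmwh_vka"] * u.decrement_lmwh_vka.value
    ) / DAYS_PER_YEAR

    # --- anticoagulant costs ---
    apix_first = 7.0 * c.apixaban_initial_daily.value + (cyc_days - 7.0) * c.apixaban_extended_daily.value
    apix_cont = cyc_days * c.apixaban_extended_daily.value
    vka_first = 7.0 * c.lmwh_daily.value + cyc_days * c.vka_daily.value
    vka_cont = cyc_days * c.vka_daily.value

    k_idx = np.arange(K).reshape((K,) + (1,) * len(shape))
    on_mass = occ[:, ON_DVT] + occ[:, ON_PE]
    arm_first = apix_first if arm.drug == "apixaban" else vka_first
    arm_cont = apix_cont if arm.drug == "apixaban" else vka_cont
    rt1_on = occ[:, RT1_ON_STATES].sum(axis=1)
    rt2_on = occ[:, RT2_ON_STATES].sum(axis=1)
    rt1_off = occ[:, RT1_OFF_STATES].sum(axis=1)
    rt2_off = occ[:, RT2_OFF_STATES].sum(axis=1)
    anticoag_c = on_mass * np.where(k_idx == 0, arm_first, arm_cont)
    anticoag_c = anticoag_c + (
        rt1_on * arm_first
        + rt2_on * arm_cont
        + rt1_off * vka_first
        + rt2_off * vka_cont
    )
    anticoag_c = anticoag_c - (
        ev["interruption_days_apixaban"] * c.apixaban_extended_daily.value
        + ev["interruption_days_lmwh_vka"] * c.vka_daily.value
    )

    # --- monitoring and administration (VKA courses only) ---
    lmwh_admin_course = (
        c.lmwh_education_oneoff.value
        + c.lmwh_admin_daily.value * c.lmwh_duration_days * (1.0 - c.self_inject_fraction.value)
    )
    vka_first_cycle_cost = c.monitoring_first_cycle.value + lmwh_admin_course
    monitor_c = (
        rt1_off * vka_first_cycle_cost + rt2_off * c.monitoring_subsequent_cycle.value
    )
    if arm.drug == "lmwh_vka":
        monitor_c = monitor_c + on_mass * np.where(
            k_idx == 0, vka_first_cycle_cost, c.monitoring_subsequent_cycle.value
        )
        monitor_c = monitor_c + (
            rt1_on * vka_first_cycle_cost + rt2_on * c.monitoring_subsequent_cycle.value
        )

    # --- event-related costs ---
    event_c = (
        ev["recurrent_dvt"] * c.event_dvt.value
        + (ev["recurrent_pe"] + ev["vte_death"]) * c.event_pe_or_vte_death.value
        + ev["ic_bleed"] * (c.event_ic_bleed_acute.value + c.event_ic_bleed_maintenance.value)
        + (ev["nonic_major_bleed"] + ev["fatal_bleed"]) * c.event_nonic_major_bleed.value
        + ev["crnm_bleed"] * c.event_crnm_bleed.value
        + ev["cteph_onset"] * c.event_cteph_acute.value
        + occ[:, POST_IC] * c.ic_bleed_long_term_per_cycle.value
        + occ[:, CTEPH_STATE] * c.cteph_long_term_per_cycle.value
        + pts * c.pts_per_cycle.value
    )

    cohort = p.population.cohort_size
    events_per_1000 = {
        key: cohort * ev[key].sum(axis=0)
        for key in EVENT_KEYS
        if not key.startswith("interruption")
    }
    events_per_1000["recurrent_vte_composite"] = (
        events_per_1000["recurrent_dvt"]
        + events_per_1000["recurrent_pe"]
        + events_per_1000["vte_death"]
    )

    per_cycle = None
    if keep_per_cycle and not shape:
        per_cycle = pd.DataFrame(
            {
                "cycle": np.arange(K),
                "discount": v,
                "ly": ly_c,
                "qaly": qaly_c,
                "cost_anticoagulant": anticoag_c,
                "cost_monitoring_admin": monitor_c,
                "cost_events": event_c,
            }
        )

    return Outcomes(
        ly=(ly_c * vx).sum(axis=0),
        qaly=(qaly_c * vx).sum(axis=0),
        cost_anticoagulant=(anticoag_c * vx).sum(axis=0),
        cost_monitoring_admin=(monitor_c * vx).sum(axis=0),
        cost_events=(event_c * vx).sum(axis=0),
        ly_undiscounted=ly_c.sum(axis=0),
        qaly_undiscounted=qaly_c.sum(axis=0),
        events_per_1000=events_per_1000,
        per_cycle=per_cycle,
    )


def count_events(trace: CohortTrace, cohort_size: int = 1000) -> dict[str, np.ndarray]:
    """Undiscounted expected lifetime event counts scaled to the cohort size."""
    out = {
        key: cohort_size * trace.events[key].sum(axis=0)
        for key in EVENT_KEYS
        if not key.startswith("interruption")
    }
    out["recurrent_vte_composite"] = (
        out["recurrent_dvt"] + out["recurrent_pe"] + out["vte_death"]
    )
    return out


def run_arm(
    arm: ArmSchedule, p: ModelParameters, life_table: LifeTable, keep_per_cycle: bool = False
) -> Outcomes:
    """Convenience: run the cohort and accrue outcomes in one call."""
    trace = run_model(arm, p, life_table)
    return accrue_outcomes(trace, arm, p, keep_per_cycle=keep_per_cycle)
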