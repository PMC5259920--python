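"""Model input set: domain types, published defaults, validation, I/O, sampling.

The parameter tree mirrors the published decision model's input tables:
time-segmented absolute event risks for the reference (apixaban) strategy,
relative treatment effects for the comparators, event-type splits, long-term
sequela risks, UK costs, utilities, the trial population profile, treatment
policy rules, and analysis settings.  Every numeric leaf is a :class:`Param`
carrying its 95% CI (where one was published), a domain ``kind`` used to pick
its sampling family, and a ``source`` flag separating published values from
the package's documented auxiliary assumptions.
"""

from __future__ import annotations

import copy
import dataclasses
import math
import typing
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

__all__ = [
    "Param",
    "RiskSegment",
    "RiskSchedule",
    "RelativeEffectSet",
    "RecurrentSplit",
    "MajorBleedSplit",
    "LongTermRisks",
    "LateRecurrenceBand",
    "CostInputs",
    "UtilityItem",
    "UtilityInputs",
    "PopulationProfile",
    "PolicyInputs",
    "AnalysisSettings",
    "ModelParameters",
    "ParameterDistribution",
    "default_paper_parameters",
    "load_parameters",
    "save_parameters",
    "validate_parameters",
    "build_distribution",
    "sample_parameters",
    "sample_parameter_draws",
    "iter_params",
    "parameter_table",
]

_Z95 = float(stats.norm.ppf(0.975))

# sampling family by domain kind (the publication names no families)
_FAMILY_BY_KIND = {
    "probability": "beta",
    "fraction": "beta",
    "utility": "beta",
    "decrement": "beta",
    "cost": "gamma",
    "rr": "lognormal",
    "hr": "lognormal",
    "other": "fixed",
}


@dataclass
class Param:
    """One numeric model input with optional 95% CI and provenance."""

    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    kind: str = "other"
    source: str = "paper"

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None

    @property
    def family(self) -> str:
        if not self.has_ci or self.ci_low == self.ci_high:
            return "fixed"
        return _FAMILY_BY_KIND.get(self.kind, "fixed")


def P(value, lo=None, hi=None, kind="other", source="paper") -> Param:
    return Param(value, lo, hi, kind, source)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class RiskSegment:
    """Absolute risk over [start_month, end_month) on a stated scale."""

    start_month: float
    end_month: float
    prob: Param
    scale: str = "per-cycle"  # per-cycle | annual | per-period


@dataclass
class RiskSchedule:
    """Time-segmented absolute risks for one event kind (reference strategy)."""

    event_kind: str
    segments: list[RiskSegment] = field(default_factory=list)

    def per_cycle(self, month: float, cycle_months: float = 3.0):
        """Per-cycle probability for the cycle starting at ``month``.

        'annual' and 'per-period' entries are rescaled to the cycle under a
        constant hazard; 'per-cycle' entries are used as printed.
        """
        from .hazards import rescale_prob

        for seg in self.segments:
            if seg.start_month <= month < seg.end_month:
                v = seg.prob.value
                if seg.scale == "per-cycle":
                    return v
                if seg.scale == "annual":
                    return rescale_prob(v, 12.0, cycle_months)
                if seg.scale == "per-period":
                    return rescale_prob(v, seg.end_month - seg.start_month, cycle_months)
                raise ValueError(f"unknown risk scale {seg.scale!r}")
        # beyond the printed schedule the final segment's level persists
        seg = self.segments[-1]
        v = seg.prob.value
        if seg.scale == "per-cycle":
            return v
        if seg.scale == "annual":
            return rescale_prob(v, 12.0, cycle_months)
        return rescale_prob(v, seg.end_month - seg.start_month, cycle_months)


@dataclass
class RelativeEffectSet:
    """Constant relative risks of a comparator versus the reference strategy."""

    comparator_label: str
    rr_recurrent_vte: Param = field(default_factory=lambda: P(1.0, kind="rr"))
    rr_major_bleed: Param = field(default_factory=lambda: P(1.0, kind="rr"))
    rr_crnm_bleed: Param = field(default_factory=lambda: P(1.0, kind="rr"))
    rr_other_discontinuation: Optional[Param] = None
    # absolute annual probability that bypasses RR application (trial footnote)
    major_bleed_absolute_annual: Optional[Param] = None


@dataclass
class RecurrentSplit:
    """Split of the recurrent-VTE composite into death / PE / DVT."""

    context: str  # on-treatment | off-treatment
    fraction_vte_death: Param = field(default_factory=lambda: P(0.0, kind="fraction"))
    fraction_pe: Param = field(default_factory=lambda: P(0.0, kind="fraction"))
    fraction_dvt: Param = field(default_factory=lambda: P(1.0, kind="fraction"))


@dataclass
class MajorBleedSplit:
    fraction_fatal: Param = field(default_factory=lambda: P(0.0, kind="fraction"))
    fraction_ic_of_nonfatal: Param = field(default_factory=lambda: P(0.0, kind="fraction"))
    fraction_nonic_of_nonfatal: Param = field(default_factory=lambda: P(1.0, kind="fraction"))


@dataclass
class LateRecurrenceBand:
    """Annual recurrence probability for untreated patients, by years beyond month 18."""

    start_year: float
    end_year: float
    annual_prob: Param = field(default_factory=lambda: P(0.0, kind="probability", source="assumption"))


@dataclass
class LongTermRisks:
    cteph_probability: Param = field(default_factory=lambda: P(0.0125, kind="probability"))
    cteph_period_years: float = 2.1
    pts_cumulative_probability: Param = field(default_factory=lambda: P(0.081, kind="probability"))
    pts_horizon_years: float = 5.0
    # cumulative-over-horizon (default) or literal-per-cycle
    pts_interpretation: str = "cumulative-over-horizon"
    late_recurrence_schedule: list[LateRecurrenceBand] = field(default_factory=list)
    bleed_age_multiplier_per_decade: Param = field(default_factory=lambda: P(1.97))


@dataclass
class CostInputs:
    """UK 2011/12 unit costs (GBP)."""

    apixaban_initial_daily: Param = field(default_factory=lambda: P(4.39, kind="cost"))
    apixaban_extended_daily: Param = field(default_factory=lambda: P(2.20, kind="cost"))
    lmwh_daily: Param = field(default_factory=lambda: P(9.02, kind="cost"))
    vka_daily: Param = field(default_factory=lambda: P(0.015, kind="cost"))
    lmwh_education_oneoff: Param = field(default_factory=lambda: P(17.50, kind="cost"))
    lmwh_admin_daily: Param = field(default_factory=lambda: P(9.04, kind="cost"))
    self_inject_fraction: Param = field(default_factory=lambda: P(0.92, kind="fraction"))
    lmwh_duration_days: float = 7.0
    monitoring_first_cycle: Param = field(default_factory=lambda: P(122.18, kind="cost"))
    monitoring_subsequent_cycle: Param = field(default_factory=lambda: P(58.72, kind="cost"))
    event_dvt: Param = field(default_factory=lambda: P(389.72, kind="cost"))
    event_pe_or_vte_death: Param = field(default_factory=lambda: P(1340.41, kind="cost"))
    event_ic_bleed_acute: Param = field(default_factory=lambda: P(2760.57, kind="cost"))
    event_ic_bleed_maintenance: Param = field(default_factory=lambda: P(4387.76, kind="cost"))
    ic_bleed_long_term_per_cycle: Param = field(default_factory=lambda: P(672.53, kind="cost"))
    event_cteph_acute: Param = field(default_factory=lambda: P(1888.23, kind="cost"))
    cteph_long_term_per_cycle: Param = field(default_factory=lambda: P(4182.56, kind="cost"))
    event_nonic_major_bleed: Param = field(default_factory=lambda: P(1043.26, kind="cost"))
    event_crnm_bleed: Param = field(default_factory=lambda: P(133.56, kind="cost"))
    pts_per_cycle: Param = field(default_factory=lambda: P(18.00, kind="cost"))


@dataclass
class UtilityItem:
    """A utility or decrement that applies for a fixed number of days."""

    value: Param
    days: float


@dataclass
class UtilityInputs:
    baseline: Param = field(default_factory=lambda: P(0.825, kind="utility"))
    # state utilities (replace baseline while in the state)
    ic_bleed_acute: UtilityItem = field(
        default_factory=lambda: UtilityItem(P(0.33, kind="utility"), 30.0)
    )
    cteph_acute: UtilityItem = field(
        default_factory=lambda: UtilityItem(P(0.65, kind="utility"), 30.0)
    )
    # on-treatment decrements (apply throughout treatment)
    decrement_apixaban: Param = field(default_factory=lambda: P(0.002, kind="decrement"))
    decrement_lmwh_vka: Param = field(default_factory=lambda: P(0.013, kind="decrement"))
    # transient event decrements (duration-limited pulses)
    decrement_dvt: UtilityItem = field(
        default_factory=lambda: UtilityItem(P(0.11, kind="decrement"), 30.0)
    )
    decrement_pe: UtilityItem = field(
        default_factory=lambda: UtilityItem(P(0.32, kind="decrement"), 30.0)
    )
    decrement_nonic_bleed: UtilityItem = field(
        default_factory=lambda: UtilityItem(P(0.30, kind="decrement"), 30.0)
    )
    decrement_crnm_bleed: UtilityItem = field(
        default_factory=lambda: UtilityItem(P(0.0054, kind="decrement"), 2.0)
    )
    decrement_pts: Param = field(default_factory=lambda: P(0.07, kind="decrement"))


@dataclass
class PopulationProfile:
    starting_age: float = 56.9
    male_fraction: Param = field(default_factory=lambda: P(0.587, kind="fraction"))
    index_dvt_fraction: Param = field(default_factory=lambda: P(0.658, kind="fraction"))
    index_pe_fraction: Param = field(default_factory=lambda: P(0.342, kind="fraction"))
    cohort_size: int = 1000


@dataclass
class PolicyInputs:
    discontinue_after_nonic_major_bleed: Param = field(
        default_factory=lambda: P(0.527, kind="fraction")
    )
    interruption_days_nonic_major_bleed: float = 14.0
    interruption_days_crnm_bleed: float = 2.0
    retreatment_months: float = 6.0
    retreatment_drug_off_treatment: str = "lmwh_vka"


@dataclass
class AnalysisSettings:
    cycle_years: float = 0.25
    discount_rate: float = 0.035
    wtp_threshold: float = 20000.0
    psa_draws: int = 2000
    wtp_max: float = 50000.0
    wtp_step: float = 1000.0
    max_age: float = 100.0
    seed: int = 2017
    half_cycle_correction: bool = False
    # excess-mortality hazard ratios: cited by the publication but unprinted;
    # packaged defaults are documented assumptions
    hr_post_vte: Param = field(default_factory=lambda: P(2.0, kind="hr", source="assumption"))
    hr_cteph: Param = field(default_factory=lambda: P(4.0, kind="hr", source="assumption"))
    hr_post_ic_bleed: Param = field(default_factory=lambda: P(2.5, kind="hr", source="assumption"))
    ageing_applies_after_months: float = 18.0


@dataclass
class ModelParameters:
    """Complete validated input set for the decision model."""

    risks: dict[str, RiskSchedule] = field(default_factory=dict)
    relative_effects: dict[str, RelativeEffectSet] = field(default_factory=dict)
    recurrent_split_on: RecurrentSplit = field(default_factory=lambda: RecurrentSplit("on-treatment"))
    recurrent_split_off: RecurrentSplit = field(default_factory=lambda: RecurrentSplit("off-treatment"))
    major_bleed_split: MajorBleedSplit = field(default_factory=MajorBleedSplit)
    long_term: LongTermRisks = field(default_factory=LongTermRisks)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    population: PopulationProfile = field(default_factory=PopulationProfile)
    policy: PolicyInputs = field(default_factory=PolicyInputs)
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)


# --------------------------------------------------------------------------
# published defaults
# --------------------------------------------------------------------------


def default_paper_parameters() -> ModelParameters:
    """The complete published input set, with every printed 95% CI attached.

    Quantities the publication cites but does not print (excess-mortality
    hazard ratios; the untreated late-recurrence schedule beyond month 18)
    are filled with packaged defaults flagged ``source="assumption"``.
    """
    risks = {
        "recurrent_vte": RiskSchedule(
            "recurrent_vte",
            [
                RiskSegment(0, 3, P(0.0171, 0.012, 0.022, "probability")),
                RiskSegment(3, 6, P(0.0048, 0.0022, 0.0075, "probability")),
                RiskSegment(6, 9, P(0.0048, 0.0001, 0.011, "probability")),
                RiskSegment(9, 12, P(0.0059, 0.0007, 0.011, "probability")),
                RiskSegment(12, 15, P(0.0012, 0.0, 0.0035, "probability")),
                RiskSegment(15, 18, P(0.0036, 0.0, 0.0076, "probability")),
            ],
        ),
        "major_bleed": RiskSchedule(
            "major_bleed",
            [
                RiskSegment(0, 3, P(0.0041, 0.0017, 0.0065, "probability")),
                RiskSegment(3, 6, P(0.0015, 0.0, 0.0030, "probability")),
                RiskSegment(6, math.inf, P(0.0024, 0.0, 0.0057, "probability"), "annual"),
            ],
        ),
        "crnm_bleed": RiskSchedule(
            "crnm_bleed",
            [
                RiskSegment(0, 3, P(0.0265, 0.0204, 0.0326, "probability")),
                RiskSegment(3, 6, P(0.0120, 0.0078, 0.0161, "probability")),
                RiskSegment(6, math.inf, P(0.0300, 0.0182, 0.0412, "probability"), "annual"),
            ],
        ),
        "ae_discontinuation": RiskSchedule(
            "ae_discontinuation",
            [
                RiskSegment(0, 6, P(0.0487, 0.0405, 0.0568, "probability"), "per-period"),
                RiskSegment(6, math.inf, P(0.0667, 0.0498, 0.0835, "probability"), "annual"),
            ],
        ),
    }

    relative_effects = {
        "initial_lmwh_vka": RelativeEffectSet(
            "initial_lmwh_vka",
            rr_recurrent_vte=P(1.18, 0.83, 1.66, "rr"),
            rr_major_bleed=P(3.26, 1.84, 5.79, "rr"),
            rr_crnm_bleed=P(2.09, 1.66, 2.63, "rr"),
            rr_other_discontinuation=P(1.07, 0.85, 1.35, "rr"),
        ),
        "extended_placebo": RelativeEffectSet(
            "extended_placebo",
            rr_recurrent_vte=P(5.33, 3.02, 9.40, "rr"),
            rr_major_bleed=P(2.07, 0.38, 11.24, "rr"),
            rr_crnm_bleed=P(0.78, 0.43, 1.40, "rr"),
            rr_other_discontinuation=None,
            major_bleed_absolute_annual=P(0.0048, kind="probability"),
        ),
        "extended_vka": RelativeEffectSet(
            "extended_vka",
            rr_recurrent_vte=P(0.42, 0.16, 1.06, "rr"),
            rr_major_bleed=P(7.7, 1.09, 76.40, "rr"),
            rr_crnm_bleed=P(3.84, 1.55, 9.38, "rr"),
            rr_other_discontinuation=P(1.33, 0.75, 1.87, "rr"),
        ),
    }

    # splits: published percentages; event counts (n) give the beta weights
    split_on = RecurrentSplit(
        "on-treatment",
        fraction_vte_death=P(0.2154, *_count_ci(28, 130), kind="fraction"),
        fraction_pe=P(0.3769, *_count_ci(49, 130), kind="fraction"),
        fraction_dvt=P(0.4077, *_count_ci(53, 130), kind="fraction"),
    )
    split_off = RecurrentSplit(
        "off-treatment",
        fraction_vte_death=P(0.1188, *_count_ci(12, 101), kind="fraction"),
        fraction_pe=P(0.2475, *_count_ci(25, 101), kind="fraction"),
        fraction_dvt=P(0.6337, *_count_ci(64, 101), kind="fraction"),
    )
    bleed_split = MajorBleedSplit(
        fraction_fatal=P(0.1346, *_count_ci(0.1346 * 100, 100), kind="fraction"),
        fraction_ic_of_nonfatal=P(0.1397, *_count_ci(0.1397 * 100, 100), kind="fraction"),
        fraction_nonic_of_nonfatal=P(0.8603, *_count_ci(0.8603 * 100, 100), kind="fraction"),
    )

    long_term = LongTermRisks(
        cteph_probability=P(0.0125, 0.0003, 0.0246, "probability"),
        cteph_period_years=2.1,
        pts_cumulative_probability=P(0.081, 0.059, 0.104, "probability"),
        pts_horizon_years=5.0,
        pts_interpretation="cumulative-over-horizon",
        # untreated recurrence beyond the trial horizon: annual hazards shaped
        # on the 10-year prospective post-cessation cohort (cumulative recurrence
        # roughly 11% / 20% / 29% / 40% at 1 / 3 / 5 / 10 years)
        late_recurrence_schedule=[
            LateRecurrenceBand(0, 1, P(0.11, kind="probability", source="assumption")),
            LateRecurrenceBand(1, 3, P(0.05, kind="probability", source="assumption")),
            LateRecurrenceBand(3, 5, P(0.045, kind="probability", source="assumption")),
            LateRecurrenceBand(5, 10, P(0.030, kind="probability", source="assumption")),
            LateRecurrenceBand(10, math.inf, P(0.022, kind="probability", source="assumption")),
        ],
        bleed_age_multiplier_per_decade=P(1.97),
    )

    costs = CostInputs(
        lmwh_education_oneoff=P(17.50, 12.25, 22.75, "cost"),
        lmwh_admin_daily=P(9.04, 6.33, 11.75, "cost"),
        self_inject_fraction=P(0.92, 0.64, 1.00, "fraction"),
        event_dvt=P(389.72, 272.80, 506.64, "cost"),
        event_pe_or_vte_death=P(1340.41, 938.29, 1742.54, "cost"),
        event_ic_bleed_acute=P(2760.57, 2017.43, 3252.62, "cost"),
        event_ic_bleed_maintenance=P(4387.76, 3685.78, 5107.61, "cost"),
        ic_bleed_long_term_per_cycle=P(672.53, 473.01, 894.93, "cost"),
        event_cteph_acute=P(1888.23, 1379.02, 2225.48, "cost"),
        cteph_long_term_per_cycle=P(4182.56, 2927.79, 5437.33, "cost"),
        event_nonic_major_bleed=P(1043.26, 785.90, 1192.06, "cost"),
        event_crnm_bleed=P(133.56, 113.86, 147.78, "cost"),
        pts_per_cycle=P(18.00, 12.60, 23.40, "cost"),
    )

    utilities = UtilityInputs(
        baseline=P(0.825, 0.825 - _Z95 * 0.003, 0.825 + _Z95 * 0.003, "utility"),
        ic_bleed_acute=UtilityItem(P(0.33, 0.140, 0.530, "utility"), 30.0),
        cteph_acute=UtilityItem(P(0.65, 0.400, 0.890, "utility"), 30.0),
        decrement_apixaban=P(0.002, 0.000, 0.006, "decrement"),
        # printed CI upper bound 0.0047 is inconsistent with the mean 0.013
        # (mean outside its own interval); read as 0.047
        decrement_lmwh_vka=P(0.013, 0.000, 0.047, "decrement"),
        decrement_dvt=UtilityItem(P(0.11, 0.00, 0.31, "decrement"), 30.0),
        decrement_pe=UtilityItem(P(0.32, 0.09, 0.59, "decrement"), 30.0),
        decrement_nonic_bleed=UtilityItem(P(0.30, 0.09, 0.460, "decrement"), 30.0),
        decrement_crnm_bleed=UtilityItem(P(0.0054, 0.00, 0.0195, "decrement"), 2.0),
        decrement_pts=P(0.07, 0.00, 0.24, "decrement"),
    )

    return ModelParameters(
        risks=risks,
        relative_effects=relative_effects,
        recurrent_split_on=split_on,
        recurrent_split_off=split_off,
        major_bleed_split=bleed_split,
        long_term=long_term,
        costs=costs,
        utilities=utilities,
        population=PopulationProfile(),
        policy=PolicyInputs(),
        settings=AnalysisSettings(),
    )


def _count_ci(k: float, n: float) -> tuple[float, float]:
    """Approximate 95% CI for a proportion observed as k events out of n."""
    p = k / n
    se = math.sqrt(max(p * (1 - p), 1e-12) / n)
    return max(0.0, p - _Z95 * se), min(1.0, p + _Z95 * se)


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------


def validate_parameters(p: ModelParameters) -> list[str]:
    """Return a list of invariant violations (empty means valid)."""
    out: list[str] = []

    for path, prm in iter_params(p):
        if prm.has_ci and not (prm.ci_low <= prm.value <= prm.ci_high):
            out.append(f"{path}: value {prm.value} outside its CI [{prm.ci_low}, {prm.ci_high}]")
        if prm.kind in ("probability", "fraction", "utility", "decrement"):
            if not (0.0 <= prm.value <= 1.0):
                out.append(f"{path}: {prm.kind} {prm.value} outside [0, 1]")
        elif prm.kind in ("rr", "hr"):
            if not prm.value > 0:
                out.append(f"{path}: {prm.kind} {prm.value} must be > 0")
        elif prm.kind == "cost":
            if prm.value < 0:
                out.append(f"{path}: cost {prm.value} must be >= 0")

    for name, sched in p.risks.items():
        month = 0.0
        for i, seg in enumerate(sched.segments):
            if not math.isclose(seg.start_month, month, abs_tol=1e-9):
                out.append(
                    f"risks.{name}.segments[{i}]: starts at month {seg.start_month}, expected {month}"
                    " (segments must be contiguous from month 0)"
                )
            if seg.end_month <= seg.start_month:
                out.append(f"risks.{name}.segments[{i}]: empty or inverted segment")
            month = seg.end_month
        if not sched.segments:
            out.append(f"risks.{name}: no segments")

    for label, split in (
        ("recurrent_split_on", p.recurrent_split_on),
        ("recurrent_split_off", p.recurrent_split_off),
    ):
        s = split.fraction_vte_death.value + split.fraction_pe.value + split.fraction_dvt.value
        if abs(s - 1.0) > 1e-9:
            out.append(f"{label}: fractions sum to {s}, expected 1")
    s = (
        p.major_bleed_split.fraction_ic_of_nonfatal.value
        + p.major_bleed_split.fraction_nonic_of_nonfatal.value
    )
    if abs(s - 1.0) > 1e-9:
        out.append(f"major_bleed_split: non-fatal fractions sum to {s}, expected 1")

    s = p.population.index_dvt_fraction.value + p.population.index_pe_fraction.value
    if abs(s - 1.0) > 1e-9:
        out.append(f"population: index DVT+PE fractions sum to {s}, expected 1")

    for item_name in (
        "ic_bleed_acute",
        "cteph_acute",
        "decrement_dvt",
        "decrement_pe",
        "decrement_nonic_bleed",
        "decrement_crnm_bleed",
    ):
        item = getattr(p.utilities, item_name)
        if item.days <= 0:
            out.append(f"utilities.{item_name}: duration {item.days} days must be > 0")

    if p.settings.cycle_years <= 0:
        out.append("settings.cycle_years must be > 0")
    if p.settings.discount_rate < 0:
        out.append("settings.discount_rate must be >= 0")
    if p.settings.max_age <= p.population.starting_age:
        out.append("settings.max_age must exceed the starting age")

    bands = p.long_term.late_recurrence_schedule
    yr = 0.0
    for i, band in enumerate(bands):
        if not math.isclose(band.start_year, yr, abs_tol=1e-9):
            out.append(
                f"long_term.late_recurrence_schedule[{i}]: starts at year {band.start_year},"
                f" expected {yr} (bands must be contiguous from 0)"
            )
        yr = band.end_year
    return out


# --------------------------------------------------------------------------
# serialization (YAML, structure-checked)
# --------------------------------------------------------------------------


def _unstructure(obj):
    if isinstance(obj, Param):
        d = {"value": obj.value}
        if obj.has_ci:
            d["ci_low"] = obj.ci_low
            d["ci_high"] = obj.ci_high
        if obj.kind != "other":
            d["kind"] = obj.kind
        if obj.source != "paper":
            d["source"] = obj.source
        return d
    if dataclasses.is_dataclass(obj):
        return {f.name: _unstructure(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _unstructure(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_unstructure(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return float("inf")
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _structure(typ, data, path: str):
    origin = typing.get_origin(typ)
    if origin is typing.Union:
        args = [a for a in typing.get_args(typ) if a is not type(None)]
        if data is None:
            return None
        return _structure(args[0], data, path)
    if typ is Param:
        if isinstance(data, (int, float)):
            return Param(float(data))
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a number or mapping for a parameter")
        allowed = {"value", "ci_low", "ci_high", "kind", "source"}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
        return Param(
            float(data["value"]),
            data.get("ci_low"),
            data.get("ci_high"),
            data.get("kind", "other"),
            data.get("source", "paper"),
        )
    if dataclasses.is_dataclass(typ):
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping for {typ.__name__}")
        hints = typing.get_type_hints(typ)
        names = {f.name for f in dataclasses.fields(typ)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(typ):
            if f.name in data:
                kwargs[f.name] = _structure(hints[f.name], data[f.name], f"{path}.{f.name}")
        return typ(**kwargs)
    if origin in (list,):
        (elem,) = typing.get_args(typ)
        return [_structure(elem, v, f"{path}[{i}]") for i, v in enumerate(data)]
    if origin in (dict,):
        _, val = typing.get_args(typ)
        return {k: _structure(val, v, f"{path}.{k}") for k, v in data.items()}
    if typ is float:
        return float(data)
    if typ is int:
        return int(data)
    if typ is bool:
        return bool(data)
    if typ is str:
        return str(data)
    return data


def _deep_merge(base: dict, override: dict, path: str = "parameters") -> dict:
    out = dict(base)
    for k, v in override.items():
        here = f"{path}.{k}"
        if k in out and isinstance(out[k], dict) and isinstance(v, dict):
            out[k] = _deep_merge(out[k], v, here)
        elif k in out and isinstance(out[k], dict) and isinstance(v, (int, float)) and "value" in out[k]:
            merged = dict(out[k])
            merged["value"] = v
            out[k] = merged
        else:
            out[k] = v
    return out


def save_parameters(p: ModelParameters, path) -> None:
    """Write the full parameter set to YAML (round-trips bit-identically)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_unstructure(p), fh, sort_keys=False)


def load_parameters(path) -> ModelParameters:
    """Load parameters from YAML; partial files override the published defaults.

    Unknown keys are rejected with the offending key named; values outside
    their domain raise with the parameter path.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    base = _unstructure(default_paper_parameters())
    merged = _deep_merge(base, data)
    p = _structure(ModelParameters, merged, "parameters")
    violations = validate_parameters(p)
    if violations:
        raise ValueError("invalid parameters:\n" + "\n".join(violations))
    return p


# --------------------------------------------------------------------------
# parameter traversal, distributions, sampling
# --------------------------------------------------------------------------


def iter_params(obj, path: str = ""):
    """Yield (path, Param) for every numeric leaf, in deterministic order."""
    if isinstance(obj, Param):
        yield path, obj
        return
    if dataclasses.is_dataclass(obj):
        for f in dataclasses.fields(obj):
            yield from iter_params(getattr(obj, f.name), f"{path}.{f.name}" if path else f.name)
        return
    if isinstance(obj, dict):
        for k, v in obj.items():
            yield from iter_params(v, f"{path}.{k}" if path else str(k))
        return
    if isinstance(obj, list):
        for i, v in enumerate(obj):
            yield from iter_params(v, f"{path}[{i}]")


def get_param(p: ModelParameters, path: str) -> Param:
    for candidate, prm in iter_params(p):
        if candidate == path:
            return prm
    raise KeyError(path)


@dataclass
class ParameterDistribution:
    """A sampling distribution matched to a mean and 95% CI."""

    family: str  # beta | gamma | lognormal | fixed
    mean: float
    args: tuple = ()

    def frozen(self):
        if self.family == "beta":
            a, b = self.args
            return stats.beta(a, b)
        if self.family == "gamma":
            shape, scale = self.args
            return stats.gamma(shape, scale=scale)
        if self.family == "lognormal":
            mu, sigma = self.args
            return stats.lognorm(sigma, scale=math.exp(mu))
        raise ValueError(f"no frozen form for family {self.family!r}")

    def analytic_mean(self) -> float:
        if self.family == "fixed":
            return self.mean
        return float(self.frozen().mean())

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        dist = self.frozen()
        return dist.ppf(rng.uniform(size=size))


def build_distribution(mean: float, ci_low, ci_high, family: str) -> ParameterDistribution:
    """Construct a distribution whose mean equals ``mean`` and whose central
    95% interval approximates [ci_low, ci_high].

    beta and gamma distributions keep the analytic mean exact and solve for
    the concentration/shape whose 2.5-97.5 percentile width matches the CI
    width (percentile matching); lognormal takes the log-scale sigma from the
    CI ratio, sigma = ln(ci_high/ci_low)/(2 z_0.975), with the log-mean set to
    preserve the arithmetic mean.
    """
    if family == "fixed" or ci_low is None or ci_high is None or ci_low == ci_high:
        return ParameterDistribution("fixed", float(mean))
    if not (ci_low <= mean <= ci_high):
        raise ValueError(f"mean {mean} outside CI [{ci_low}, {ci_high}]")
    width = float(ci_high - ci_low)

    if family == "beta":
        if not (0.0 < mean < 1.0):
            raise ValueError(f"beta requires mean in (0, 1), got {mean}")

        def beta_width(log_kappa):
            kappa = math.exp(log_kappa)
            d = stats.beta(mean * kappa, (1 - mean) * kappa)
            return float(d.ppf(0.975) - d.ppf(0.025))

        kappa = math.exp(_solve_width(beta_width, width))
        return ParameterDistribution("beta", float(mean), (mean * kappa, (1 - mean) * kappa))

    if family == "gamma":
        if mean <= 0:
            raise ValueError(f"gamma requires mean > 0, got {mean}")

        def gamma_width(log_shape):
            shape = math.exp(log_shape)
            d = stats.gamma(shape, scale=mean / shape)
            return float(d.ppf(0.975) - d.ppf(0.025))

        shape = math.exp(_solve_width(gamma_width, width))
        return ParameterDistribution("gamma", float(mean), (shape, mean / shape))

    if family == "lognormal":
        if ci_low <= 0 or mean <= 0:
            raise ValueError("lognormal requires positive mean and CI")
        # ratio estimates: ln(RR) ~ Normal(ln point estimate, sigma), the
        # usual convention for relative risks and hazard ratios, so the point
        # estimate is the median and the CI is matched exactly
        sigma = math.log(ci_high / ci_low) / (2 * _Z95)
        mu = math.log(mean)
        return ParameterDistribution("lognormal", float(mean), (mu, sigma))

    raise ValueError(f"unknown family {family!r}")


def _solve_width(width_fn, target: float) -> float:
    """Log-concentration whose central 95% width matches ``target``.

    The width is not monotone over all concentrations (it vanishes both for
    point masses and, when the mean is extreme, for very diffuse shapes), so
    the root is taken on the well-behaved decreasing branch: scan downward
    from high concentration to bracket the first sign change. If the target
    is wider than the family can achieve at this mean, the most diffuse
    attainable shape is used (CI matched as closely as possible).
    """
    grid = np.linspace(30.0, -7.0, 75)
    prev = None
    for g in grid:
        if width_fn(g) - target > 0:
            if prev is None:
                return float(g)
            return float(optimize.brentq(lambda x: width_fn(x) - target, g, prev, xtol=1e-12))
        prev = g
    widths = [width_fn(g) for g in grid]
    return float(grid[int(np.argmax(widths))])


def _renormalize_simplexes(p: ModelParameters) -> None:
    for split in (p.recurrent_split_on, p.recurrent_split_off):
        total = (
            split.fraction_vte_death.value + split.fraction_pe.value + split.fraction_dvt.value
        )
        split.fraction_vte_death.value = split.fraction_vte_death.value / total
        split.fraction_pe.value = split.fraction_pe.value / total
        split.fraction_dvt.value = split.fraction_dvt.value / total
    ms = p.major_bleed_split
    total = ms.fraction_ic_of_nonfatal.value + ms.fraction_nonic_of_nonfatal.value
    ms.fraction_ic_of_nonfatal.value = ms.fraction_ic_of_nonfatal.value / total
    ms.fraction_nonic_of_nonfatal.value = ms.fraction_nonic_of_nonfatal.value / total
    pop = p.population
    total = pop.index_dvt_fraction.value + pop.index_pe_fraction.value
    pop.index_dvt_fraction.value = pop.index_dvt_fraction.value / total
    pop.index_pe_fraction.value = pop.index_pe_fraction.value / total


def _sample_into(p: ModelParameters, rng: np.random.Generator, size=None) -> ModelParameters:
    drawn = copy.deepcopy(p)
    for _, prm in iter_params(drawn):
        dist = build_distribution(prm.value, prm.ci_low, prm.ci_high, prm.family)
        if dist.family != "fixed":
            prm.value = dist.sample(rng, size=size)
            # a draw is a point input; the source CI no longer brackets it
            prm.ci_low = prm.ci_high = None
    _renormalize_simplexes(drawn)
    return drawn


def sample_parameters(p: ModelParameters, seed: int) -> ModelParameters:
    """One coherent probabilistic draw of every uncertain parameter.

    Deterministic for a fixed seed; simplex groups (event splits, index-event
    mix) are renormalized to sum to 1 after independent sampling.
    """
    return _sample_into(p, np.random.default_rng(seed))


def sample_parameter_draws(p: ModelParameters, seed: int, n_draws: int) -> ModelParameters:
    """Vectorized sampling: every uncertain leaf becomes an array of draws.

    The engine broadcasts over these arrays, so one model run evaluates all
    draws; draw ``i`` of the result equals an independent scalar draw.
    """
    return _sample_into(p, np.random.default_rng(seed), size=n_draws)


def parameter_table(p: ModelParameters) -> pd.DataFrame:
    """Flattened parameter table: name, value, ci_low, ci_high, family, source."""
    rows = [
        {
            "name": path,
            "value": prm.value,
            "ci_low": prm.ci_low,
            "ci_high": prm.ci_high,
            "family": prm.family,
            "source": prm.source,
        }
        for path, prm in iter_params(p)
    ]
    return pd.DataFrame(rows)
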