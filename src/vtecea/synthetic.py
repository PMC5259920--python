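"""Synthetic inputs: a deterministic life table, the packaged parameter fixture,
and closed-form-checkable toy models.

The national life table the analysis calls for is not redistributable with
the package, so runs ship with a synthetic Gompertz-Makeham table calibrated
to modern UK-like longevity (period life expectancy at birth around 79 years
for males and 83 for females). It is smooth, monotone in adult ages, and
deterministic, so every downstream result is reproducible; it is explicitly
not any specific national release.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mortality import LifeTable
from .parameters import (
    ModelParameters,
    Param,
    default_paper_parameters,
    iter_params,
    save_parameters,
)

__all__ = [
    "GompertzMakehamSpec",
    "SexOffset",
    "generate_life_table",
    "default_life_table",
    "flat_life_table",
    "paper_fixture",
    "toy_models",
    "ToyModel",
    "zero_risk_parameters",
]


@dataclass
class GompertzMakehamSpec:
    """Hazard mu(a) = A + B exp(theta * a) per year at age ``a``."""

    makeham_a: float = 3.0e-4
    gompertz_b: float = 2.2e-5
    gompertz_theta: float = 0.0985
    max_age: int = 110

    def __post_init__(self) -> None:
        if self.makeham_a < 0 or self.gompertz_b <= 0 or self.gompertz_theta <= 0:
            raise ValueError("require A >= 0, B > 0, theta > 0")

    def annual_q(self, age: float) -> float:
        mu = self.makeham_a + self.gompertz_b * math.exp(self.gompertz_theta * age)
        return min(1.0, -math.expm1(-mu))


@dataclass
class SexOffset:
    """Female adjustment relative to the male spec (female mortality is lower
    at every adult age in modern high-income populations)."""

    b_factor: float = 0.5
    theta_delta: float = 0.0035


def generate_life_table(
    spec: GompertzMakehamSpec, sex_offset: SexOffset | None = None
) -> LifeTable:
    """Annual life table from a Gompertz-Makeham hazard; deterministic.

    The male column follows ``spec`` directly; the female column scales the
    Gompertz term down and steepens it slightly, giving the familiar
    female-advantage pattern that narrows at the oldest ages.
    """
    off = sex_offset or SexOffset()
    female = GompertzMakehamSpec(
        spec.makeham_a,
        spec.gompertz_b * off.b_factor,
        spec.gompertz_theta + off.theta_delta,
        spec.max_age,
    )
    ages = np.arange(0, spec.max_age + 1)
    qm = np.array([spec.annual_q(a) for a in ages])
    qf = np.array([female.annual_q(a) for a in ages])
    if np.any(qm[: min(60, spec.max_age)] >= 1.0 - 1e-9):
        raise ValueError("spec implies certain death before age 60")
    return LifeTable(ages, qm, qf)


def default_life_table() -> LifeTable:
    """The packaged synthetic table used by every no-download run."""
    return generate_life_table(GompertzMakehamSpec())


def flat_life_table(annual_q: float, max_age: int = 130) -> LifeTable:
    """Constant-hazard table for closed-form checks."""
    ages = np.arange(0, max_age + 1)
    q = np.full(len(ages), annual_q, dtype=float)
    return LifeTable(ages, q, q)


# --------------------------------------------------------------------------
# packaged fixture
# --------------------------------------------------------------------------


def paper_fixture(out_dir) -> dict[str, Path]:
    """Write the full published parameter set, the synthetic life table, and a
    provenance manifest distinguishing published values from packaged
    assumptions. Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = default_paper_parameters()
    params_path = out / "parameters.yaml"
    save_parameters(p, params_path)
    lt_path = out / "life_table.csv"
    default_life_table().to_csv(lt_path)
    manifest = {
        "parameters": str(params_path.name),
        "life_table": str(lt_path.name),
        "life_table_source": "synthetic Gompertz-Makeham (not a national release)",
        "published_values": [path for path, prm in iter_params(p) if prm.source == "paper"],
        "assumed_values": [path for path, prm in iter_params(p) if prm.source == "assumption"],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {"parameters": params_path, "life_table": lt_path, "manifest": manifest_path}


# --------------------------------------------------------------------------
# toy models with closed-form answers
# --------------------------------------------------------------------------


@dataclass
class ToyModel:
    name: str
    params: ModelParameters
    life_table: LifeTable
    arms: list
    expected: dict


def zero_risk_parameters() -> ModelParameters:
    """Published structure with every event risk, sequela, excess-mortality
    hazard ratio, cost and decrement zeroed; the scaffold for toy models."""
    p = default_paper_parameters()
    for sched in p.risks.values():
        for seg in sched.segments:
            seg.prob = Param(0.0, kind="probability")
    for re_set in p.relative_effects.values():
        if re_set.major_bleed_absolute_annual is not None:
            re_set.major_bleed_absolute_annual = Param(0.0, kind="probability")
    p.long_term.cteph_probability = Param(0.0, kind="probability")
    p.long_term.pts_cumulative_probability = Param(0.0, kind="probability")
    for band in p.long_term.late_recurrence_schedule:
        band.annual_prob = Param(0.0, kind="probability", source="assumption")
    p.long_term.bleed_age_multiplier_per_decade = Param(1.0)
    p.settings.hr_post_vte = Param(1.0, kind="hr", source="assumption")
    p.settings.hr_cteph = Param(1.0, kind="hr", source="assumption")
    p.settings.hr_post_ic_bleed = Param(1.0, kind="hr", source="assumption")
    p.settings.discount_rate = 0.0
    for f in (
        "apixaban_initial_daily", "apixaban_extended_daily", "lmwh_daily", "vka_daily",
        "lmwh_education_oneoff", "lmwh_admin_daily", "monitoring_first_cycle",
        "monitoring_subsequent_cycle",
    ):
        setattr(p.costs, f, Param(0.0, kind="cost"))
    p.utilities.decrement_apixaban = Param(0.0, kind="decrement")
    p.utilities.decrement_lmwh_vka = Param(0.0, kind="decrement")
    return p


def toy_models() -> dict[str, ToyModel]:
    """Three analytically solvable models exercised against the engine.

    * ``pure_mortality``: a single untreated cohort facing only a constant
      0.25/cycle death risk; occupancy decays geometrically and undiscounted
      life-years follow the finite geometric series.
    * ``event_pulse``: one certain CRNM bleed in the first cycle and nothing
      else; the only accruals are the bleed's cost and its 2-day utility dip.
    * ``analytic_icer``: two riskless arms differing only in a drug price and
      an on-treatment utility decrement, giving an exactly computable ICER.
    """
    from .engine import make_arm

    out: dict[str, ToyModel] = {}

    # (a) geometric decay: per-cycle death 0.25  <=>  annual q = 1 - 0.75^4
    p = zero_risk_parameters()
    lt = flat_life_table(1.0 - 0.75**4)
    k_max = math.ceil((p.settings.max_age - p.population.starting_age) / p.settings.cycle_years)
    # engine stops once alive mass < 1e-9; the series below is truncated the same way
    k_stop = next(k for k in range(1, k_max + 1) if 0.75**k < 1e-9)
    out["pure_mortality"] = ToyModel(
        name="pure_mortality",
        params=p,
        life_table=lt,
        arms=[make_arm("apixaban", 0.0)],
        expected={
            "n_cycles": k_stop,
            "ly_undiscounted": 0.25 * (1 - 0.75**k_stop) / 0.25,
            "qaly_undiscounted": p.utilities.baseline.value * (1 - 0.75**k_stop),
            "occupancy_after_k": lambda k: 0.75**k,
        },
    )

    # (b) one certain CRNM bleed at cycle 0 while on treatment, then nothing
    p = zero_risk_parameters()
    p.risks["crnm_bleed"].segments[0].prob = Param(1.0, kind="probability")
    p.policy.interruption_days_crnm_bleed = 0.0
    lt = flat_life_table(0.0)
    n_cycles = math.ceil((p.settings.max_age - p.population.starting_age) / p.settings.cycle_years)
    horizon_years = 0.25 * n_cycles
    out["event_pulse"] = ToyModel(
        name="event_pulse",
        params=p,
        life_table=lt,
        arms=[make_arm("apixaban", 3.0)],
        expected={
            "cost_events": p.costs.event_crnm_bleed.value,
            "ly_undiscounted": horizon_years,
            "qaly_undiscounted": p.utilities.baseline.value * horizon_years
            - p.utilities.decrement_crnm_bleed.value.value
            * p.utilities.decrement_crnm_bleed.days
            / 365.25,
        },
    )

    # (c) two riskless arms, analytic ICER of exactly 10000 GBP/QALY
    p = zero_risk_parameters()
    n_tx_cycles = 4  # 12 months of treatment
    daily = 100.0 / (n_tx_cycles * 0.25 * 365.25)  # -> delta cost 100
    p.costs.apixaban_initial_daily = Param(daily, kind="cost")
    p.costs.apixaban_extended_daily = Param(daily, kind="cost")
    p.utilities.decrement_apixaban = Param(0.0, kind="decrement")
    p.utilities.decrement_lmwh_vka = Param(0.01, kind="decrement")  # -> delta QALY +0.01
    lt = flat_life_table(0.0)
    out["analytic_icer"] = ToyModel(
        name="analytic_icer",
        params=p,
        life_table=lt,
        arms=[make_arm("apixaban", 12.0), make_arm("lmwh_vka", 12.0)],
        expected={"delta_cost": 100.0, "delta_qaly": 0.01, "icer": 10000.0},
    )
    return out
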