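"""Background mortality from an annual life table, plus condition-specific excess.

The model weights male and female annual death probabilities by the cohort sex
mix, converts them to the 3-month cycle under a constant hazard within each
year of age, and applies multiplicative hazard ratios for states that carry
excess mortality (history of VTE, CTEPH, prior intracranial bleed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hazards import rescale_prob

__all__ = ["LifeTable", "MortalityModifiers", "background_death_prob", "excess_death_prob"]


@dataclass
class LifeTable:
    """Annual death probabilities by integer age and sex.

    ``ages`` must be contiguous integers; ``qx_male``/``qx_female`` are the
    probabilities of dying within the year of age. Beyond ``max(ages)`` the
    table is treated as certain death (the engine's absorbing age cap).
    """

    ages: np.ndarray
    qx_male: np.ndarray
    qx_female: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx_male = np.asarray(self.qx_male, dtype=float)
        self.qx_female = np.asarray(self.qx_female, dtype=float)
        if not (len(self.ages) == len(self.qx_male) == len(self.qx_female)):
            raise ValueError("life table columns must have equal length")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("life table ages must be contiguous integers")
        for name, q in (("qx_male", self.qx_male), ("qx_female", self.qx_female)):
            if np.any((q < 0) | (q > 1)):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            older = self.ages >= 40
            if np.any(np.diff(q[older]) < -1e-12):
                warnings.warn(
                    f"{name} is not monotone non-decreasing beyond age 40",
                    stacklevel=2,
                )

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        expected = ["age", "qx_male", "qx_female"]
        if list(df.columns) != expected:
            raise ValueError(f"life table must have columns {expected}, got {list(df.columns)}")
        return cls(df["age"].to_numpy(), df["qx_male"].to_numpy(), df["qx_female"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age": self.ages, "qx_male": self.qx_male, "qx_female": self.qx_female}
        ).to_csv(path, index=False)

    def annual_q(self, age: float, male_fraction: float) -> float:
        """Sex-weighted annual death probability at floor(age)."""
        idx = int(np.floor(age))
        if idx < self.ages[0]:
            raise ValueError(f"age {age} below life-table range (starts {self.ages[0]})")
        if idx > self.ages[-1]:
            return 1.0
        i = idx - int(self.ages[0])
        return float(male_fraction * self.qx_male[i] + (1.0 - male_fraction) * self.qx_female[i])

    def life_expectancy(self, age: float, male_fraction: float, step_years: float = 1 / 48) -> float:
        """Remaining life expectancy by fine-step numeric integration.

        Uses the same constant-hazard-within-year reading of qx as the engine;
        serves as the analytic oracle for the engine's life-years.
        """
        t = 0.0
        surv = 1.0
        total = 0.0
        while surv > 1e-12 and age + t <= self.ages[-1] + 1:
            q = self.annual_q(age + t, male_fraction)
            p_step = rescale_prob(min(q, 1 - 1e-12), 1.0, step_years)
            total += surv * step_years
            surv *= 1.0 - p_step
            t += step_years
        return total


@dataclass
class MortalityModifiers:
    """Hazard ratios applied multiplicatively to background mortality.

    ``post_vte`` covers the excess mortality of a VTE history beyond the
    VTE-related and bleeding deaths the model tracks explicitly; ``cteph``
    and ``post_ic_bleed`` are additional factors for those semi-absorbing
    states (multiplied with ``post_vte`` on the hazard scale).
    """

    post_vte: float = 1.0
    cteph: float = 1.0
    post_ic_bleed: float = 1.0

    def __post_init__(self) -> None:
        for name in ("post_vte", "cteph", "post_ic_bleed"):
            v = getattr(self, name)
            if np.any(np.asarray(v) < 1.0):
                warnings.warn(f"mortality hazard ratio {name}={v} is below 1", stacklevel=2)


def background_death_prob(
    table: LifeTable, age: float, male_fraction: float, cycle_years: float = 0.25
) -> float:
    """Per-cycle background death probability at the cohort's current age."""
    q = table.annual_q(age, male_fraction)
    if q >= 1.0:
        return 1.0
    return rescale_prob(q, 1.0, cycle_years)


def excess_death_prob(base, hazard_ratio):
    """Apply a hazard-ratio product to a per-cycle death probability.

    1 - (1 - base)^HR; monotone in the hazard ratio and exact under the
    constant-hazard reading of ``base``.
    """
    base = np.asarray(base, dtype=float)
    if np.any(base >= 1.0):
        return np.where(base >= 1.0, 1.0, excess_death_prob(np.minimum(base, 1 - 1e-12), hazard_ratio))
    out = -np.expm1(np.log1p(-base) * np.asarray(hazard_ratio, dtype=float))
    return out if out.ndim else float(out)
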