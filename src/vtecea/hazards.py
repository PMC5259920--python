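"""Rate-probability conversions, relative-risk application, and competing risks.

Every transformation in this module assumes a constant hazard within the
period concerned, the standard convention for cohort state-transition
models with short cycles. All functions broadcast over numpy arrays so the
engine can evaluate many probabilistic-sensitivity draws in one pass.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

__all__ = [
    "prob_to_rate",
    "rate_to_prob",
    "rescale_prob",
    "apply_relative_risk",
    "age_bleed_multiplier",
    "combine_competing",
]

# Marginal probabilities are clipped just below 1 so that log/exp transforms
# stay finite; the induced error is far below every tolerance used here.
_P_MAX = 1.0 - 1e-12


def prob_to_rate(p, t: float = 1.0):
    """Constant hazard (per year) equivalent to probability ``p`` over ``t`` years.

    r = -ln(1 - p) / t.  Inverse of :func:`rate_to_prob`.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("probability must lie in [0, 1)")
    if t <= 0:
        raise ValueError("duration must be positive")
    out = -np.log1p(-p) / t
    return out if out.ndim else float(out)


def rate_to_prob(r, t: float = 1.0):
    """Probability of an event over ``t`` years under constant hazard ``r`` per year."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("rate must be non-negative")
    if t <= 0:
        raise ValueError("duration must be positive")
    out = -np.expm1(-r * t)
    return out if out.ndim else float(out)


def rescale_prob(p, t_from: float, t_to: float):
    """Re-express probability ``p`` over ``t_from`` years as one over ``t_to`` years.

    1 - (1-p)^(t_to/t_from); e.g. an annual probability to a 3-month cycle.
    """
    p = np.asarray(np.clip(p, 0.0, _P_MAX), dtype=float)
    out = -np.expm1(np.log1p(-p) * (t_to / t_from))
    return out if out.ndim else float(out)


def apply_relative_risk(p_cycle, rr):
    """Scale a per-cycle probability by a relative risk on the hazard scale.

    The probability is converted to a rate, multiplied by ``rr`` and converted
    back: 1 - (1 - p)^rr.  This keeps the result in [0, 1) for any rr > 0,
    and agrees with naive multiplication p*rr to first order as p -> 0.
    """
    p = np.asarray(np.clip(p_cycle, 0.0, _P_MAX), dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any(rr < 0):
        raise ValueError("relative risk must be non-negative")
    out = -np.expm1(np.log1p(-p) * rr)
    return out if out.ndim else float(out)


def age_bleed_multiplier(current_age, reference_age, factor_per_decade=1.97):
    """Ageing multiplier on bleeding hazards: factor^((age - ref)/10).

    The model raises major and CRNM bleeding hazards with age once the cohort
    has moved past the trial-observed period (first 18 months); before then the
    trial rates already embody ageing and the multiplier is not applied.
    """
    return np.asarray(factor_per_decade, dtype=float) ** (
        (np.asarray(current_age, dtype=float) - reference_age) / 10.0
    )


def combine_competing(marginals: Mapping[str, object]):
    """Allocate competing per-cycle marginal probabilities to first events.

    Each marginal probability ``p_j`` is interpreted as the probability that
    event ``j`` would occur during the cycle in the absence of the others
    (constant hazard r_j = -ln(1 - p_j)).  Running the cycle as a race of
    independent exponentials gives:

    * total event probability  P = 1 - exp(-sum r_j) = 1 - prod(1 - p_j)
    * event j's share          P * r_j / sum(r_j)

    which guarantees at most one structural transition per cycle.  With a
    single non-zero marginal the allocation reduces exactly to that marginal.

    Returns ``(effective, stay)`` where ``effective`` maps each event name to
    its allocated probability and ``stay = 1 - P`` exactly.
    """
    names = list(marginals)
    ps = [np.asarray(np.clip(marginals[k], 0.0, _P_MAX), dtype=float) for k in names]
    rates = [-np.log1p(-p) for p in ps]
    total_rate = sum(rates)
    log_stay = sum(np.log1p(-p) for p in ps)
    stay = np.exp(log_stay)
    total_p = 1.0 - stay  # exact complement so shares + stay sum to 1
    safe_total = np.where(np.asarray(total_rate) > 0, total_rate, 1.0)
    effective = {}
    for name, r in zip(names, rates):
        share = np.where(np.asarray(total_rate) > 0, total_p * r / safe_total, 0.0)
        effective[name] = share if share.ndim else float(share)
    return effective, (stay if np.asarray(stay).ndim else float(stay))
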