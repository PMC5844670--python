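"""Closed-form power, detectable-effect, and sample-size machinery.

All calculations use the two-sided normal-approximation for a two-arm
comparison of follow-up means::

    power = Phi( d / sqrt(V * (1/m1 + 1/m2)) - z_{1-alpha/2} )

with analysis arm sizes ``m_i = n_i * (1 - attrition)`` and variance factor
``V = 1 - rho**2`` under baseline-adjusted (ANCOVA) analysis, ``V = 1``
otherwise.  Note the cancellation ``V / (1 - a) = 1`` at the package
defaults (a = 0.25, rho = 0.5): baseline adjustment exactly pays for
attrition there.

The cmRCT solver searches the smallest number offered treatment from a
finite eligible pool of size E (the remainder being controls), with the
target effect diluted by the consent rate.  Detectable effects are printed
at three decimals, and feasibility comparisons are made at that printed
precision — the convention under which the motivating trial's 62%-consent
design is exactly feasible.
"""

from __future__ import annotations

import math
from dataclasses import replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import norm

from .params import (
    DesignParams,
    InfeasibleParametersError,
    InvalidDesignError,
    InvalidPoolError,
    PoolSpec,
    PRCTPlan,
    SampleSizePlan,
)

__all__ = [
    "analytic_power",
    "detectable_effect",
    "effect_rescale",
    "cmrct_sample_size",
    "min_consent_rate",
    "prct_sample_size",
    "min_eligible_pool",
    "design_report",
    "feasibility_grid",
    "round_half_up",
]

#: Printed precision of detectable effects; feasibility is judged at this
#: precision.
EFFECT_DECIMALS = 3


def round_half_up(x: float, decimals: int) -> float:
    """Round to `decimals` places with ties away from zero.

    Operates on the shortest decimal representation of ``x`` so that e.g.
    the float 0.205 (stored as 0.204999...) still prints as 0.21 at two
    decimals, matching how such values are conventionally reported.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _comparison_se(n1: float | np.ndarray, n2: float | np.ndarray,
                   params: DesignParams) -> float | np.ndarray:
    """Standard error of the standardized arm difference at analysis."""
    retain = 1.0 - params.attrition
    m1 = np.asarray(n1, dtype=float) * retain
    m2 = np.asarray(n2, dtype=float) * retain
    if np.any(m1 <= 0) or np.any(m2 <= 0):
        raise InvalidDesignError("arm size after attrition must be positive")
    return np.sqrt(params.variance_factor * (1.0 / m1 + 1.0 / m2))


def _check_arms(n1: int, n2: int) -> None:
    if n1 < 2 or n2 < 2:
        raise InvalidDesignError(
            f"each arm needs at least 2 participants, got ({n1}, {n2})")


def analytic_power(d_offer: float, n1: int, n2: int,
                   params: DesignParams) -> float:
    """Power to detect an offer-of-treatment effect with arms (n1, n2).

    ``d_offer`` is on the offer-of-treatment scale (already diluted by any
    nonconsent).  At ``d_offer = 0`` the value is ``alpha/2``: the mass of
    one tail of the two-sided test.
    """
    if d_offer < 0:
        raise InvalidDesignError(f"d_offer must be >= 0, got {d_offer}")
    _check_arms(n1, n2)
    se = _comparison_se(n1, n2, params)
    z_crit = norm.ppf(1.0 - params.alpha / 2.0)
    return float(norm.cdf(d_offer / se - z_crit))


def detectable_effect(n1: int, n2: int, params: DesignParams) -> float:
    """Smallest offer-scale effect detectable at the target power.

    Inverse of :func:`analytic_power` in ``d_offer``; minimized over
    ``n1 + n2 = E`` at the balanced split.
    """
    _check_arms(n1, n2)
    z = norm.ppf(1.0 - params.alpha / 2.0) + norm.ppf(params.power_target)
    return float(z * _comparison_se(n1, n2, params))


def _detectable_vec(n1: np.ndarray, n2: np.ndarray,
                    params: DesignParams) -> np.ndarray:
    z = norm.ppf(1.0 - params.alpha / 2.0) + norm.ppf(params.power_target)
    return z * _comparison_se(n1, n2, params)


def effect_rescale(d: float, c: float, direction: str = "dilute") -> float:
    """Convert between consenter-scale and offer-scale effects.

    ``dilute`` multiplies by the consent rate (the offered arm is a mix of
    consenters with effect d and nonconsenters with effect 0); ``undilute``
    divides, recovering the consenter-scale effect from an offer effect.
    """
    if not (0 < c <= 1):
        raise InvalidDesignError(f"consent rate must be in (0,1], got {c}")
    if direction == "dilute":
        return d * c
    if direction == "undilute":
        return d / c
    raise InvalidDesignError(
        f"direction must be 'dilute' or 'undilute', got {direction!r}")


def cmrct_sample_size(pool: PoolSpec, params: DesignParams) -> SampleSizePlan:
    """Smallest number offered treatment that reaches the power target.

    Searches n1 in [2, floor(E/2)] for the first split whose detectable
    offer effect, at the printed 3-decimal precision, does not exceed the
    (similarly printed) diluted target effect.  If no split qualifies, an
    infeasible plan is returned carrying the balanced-split achievable
    power.
    """
    E = pool.n_eligible
    if E < 4:
        raise InvalidPoolError(f"eligible pool must hold >= 4, got {E}")
    target = params.target_offer_effect
    target_rounded = round_half_up(target, EFFECT_DECIMALS)

    n1s = np.arange(2, E // 2 + 1)
    dstar = _detectable_vec(n1s, E - n1s, params)
    feasible_mask = np.round(dstar, EFFECT_DECIMALS) <= target_rounded + 1e-12

    if feasible_mask.any():
        n1 = int(n1s[np.argmax(feasible_mask)])
        feasible = True
    else:
        n1 = E // 2
        feasible = False
    n2 = E - n1
    d_off = detectable_effect(n1, n2, params)
    return SampleSizePlan(
        n_offered=n1,
        n_control=n2,
        expected_consenters=int(round(params.consent_rate * n1)),
        detectable_offer_effect=d_off,
        detectable_consent_effect=d_off / params.consent_rate,
        achieved_power=analytic_power(target, n1, n2, params),
        feasible=feasible,
    )


def min_consent_rate(pool: PoolSpec, params: DesignParams) -> int:
    """Minimum consent rate (whole percent) at which the pool suffices.

    The balanced split of the eligible pool gives the smallest detectable
    offer effect; dividing by the consenter-scale target effect yields the
    consent rate below which no allocation reaches the power target.
    """
    E = pool.n_eligible
    if E < 4:
        raise InvalidPoolError(f"eligible pool must hold >= 4, got {E}")
    d_balanced = detectable_effect(E // 2, E - E // 2, params)
    return int(round_half_up(100.0 * d_balanced / params.d_consent, 0))


def prct_sample_size(params: DesignParams) -> PRCTPlan:
    """Comparator plan for a conventional consent-then-randomize pRCT.

    Nonconsenters never enter the trial, so the randomized sample targets
    the undiluted consenter-scale effect; the consent rate only inflates
    the number that must be invited.
    """
    z = norm.ppf(1.0 - params.alpha / 2.0) + norm.ppf(params.power_target)
    d = params.d_consent
    per_arm = 2.0 * params.variance_factor * z * z / (
        d * d * (1.0 - params.attrition))
    per_arm = math.ceil(round(per_arm, 9))
    n_consented = 2 * per_arm
    n_invited = math.ceil(round(n_consented / params.consent_rate, 9))
    return PRCTPlan(per_arm=per_arm, n_consented=n_consented,
                    n_invited=n_invited)


def _fig2_params(params: DesignParams) -> DesignParams:
    # Cohort-requirement curves assume no attrition and an unadjusted
    # variance factor.
    return replace(params, attrition=0.0, analysis_mode="unadjusted")


def min_eligible_pool(params: DesignParams, f: float) -> int:
    """Smallest eligible pool supporting the design when a fraction f is offered.

    Computed in cohort-requirement mode: no attrition and unadjusted
    variance.  ``round(f*E)`` patients (at least 2, at most E-2) are offered
    and the remainder are controls; the smallest E whose detectable offer
    effect does not exceed the diluted target is returned (exact
    comparison, no printed-precision slack).
    """
    if not (0 < f <= 0.5):
        raise InvalidDesignError(f"fraction offered must be in (0, 0.5], got {f}")
    p = _fig2_params(params)
    target = p.target_offer_effect
    z = norm.ppf(1.0 - p.alpha / 2.0) + norm.ppf(p.power_target)
    # Ignoring the integer rounding of f*E, E solves
    # z^2 * (1/f + 1/(1-f)) / E = target^2; scan a safely padded range.
    approx = z * z * (1.0 / f + 1.0 / (1.0 - f)) / (target * target)
    e_hi = int(2 * approx) + 64
    E = np.arange(4, e_hi)
    n1 = np.clip(np.rint(f * E).astype(int), 2, None)
    n1 = np.minimum(n1, E - 2)
    dstar = _detectable_vec(n1, E - n1, p)
    ok = dstar <= target + 1e-12
    if not ok.any():  # pragma: no cover - padded bound makes this unreachable
        raise InfeasibleParametersError(
            "no finite pool satisfies the requested design")
    return int(E[np.argmax(ok)])


def design_report(pool: PoolSpec, params: DesignParams,
                  consent_grid: list[float]) -> pd.DataFrame:
    """Side-by-side cmRCT and pRCT requirements over a consent-rate grid.

    One row per consent rate: the diluted (offer-scale) detectable target,
    the cmRCT solver output (or an infeasibility marker), and the pRCT
    comparator columns.  Reproduces the structure of the published
    requirements table for the motivating trial.
    """
    if not consent_grid:
        raise InvalidDesignError("consent_grid must be non-empty")
    rows = []
    for c in consent_grid:
        pc = replace(params, consent_rate=c)
        plan = cmrct_sample_size(pool, pc)
        prct = prct_sample_size(pc)
        row = {
            "consent_pct": int(round_half_up(100 * c, 0)),
            "cmrct_effect": round_half_up(pc.target_offer_effect,
                                          EFFECT_DECIMALS),
            "cmrct_feasible": plan.feasible,
            "cmrct_selected": plan.n_offered if plan.feasible else None,
            "cmrct_consented": plan.expected_consenters if plan.feasible else None,
            "cmrct_treatment_arm": plan.n_offered if plan.feasible else None,
            "cmrct_control_arm": plan.n_control if plan.feasible else None,
            "prct_effect": params.d_consent,
            "prct_invited": prct.n_invited,
            "prct_consented": prct.n_consented,
            "prct_per_arm": prct.per_arm,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def feasibility_grid(params: DesignParams,
                     effects: list[float],
                     consents: list[float],
                     fractions: list[float]) -> pd.DataFrame:
    """Minimum eligible-pool sizes over an (effect, consent, fraction) grid.

    The tabular counterpart of the cohort-requirement curves: for every
    combination, the smallest eligible pool able to detect the
    consenter-scale effect at the target power when the given fraction is
    offered treatment.
    """
    rows = []
    for d in effects:
        for c in consents:
            p = replace(params, d_consent=d, consent_rate=c,
                        effect_scale="consenters")
            for f in fractions:
                rows.append({
                    "d_consent": d,
                    "consent_rate": c,
                    "fraction_offered": f,
                    "min_eligible_pool": min_eligible_pool(p, f),
                })
    return pd.DataFrame(rows)
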