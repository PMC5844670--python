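"""Parameter containers for cmRCT and pRCT design calculations.

A cohort-multiple RCT (cmRCT, a "Trials within Cohorts" design) offers an
experimental treatment to a random subset of the treatment-eligible members
of a standing cohort; every other eligible member silently forms the control
arm.  Because nonconsenting offered patients must stay in the treatment arm,
the mean arm difference is diluted by the consent rate, and because the
eligible pool is finite, arbitrarily unbalanced designs are not available.
These dataclasses carry the scalar inputs of those calculations and validate
their ranges eagerly, so every downstream formula can assume clean values.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DesignParams",
    "PoolSpec",
    "SampleSizePlan",
    "PRCTPlan",
    "InvalidDesignError",
    "InvalidPoolError",
    "InfeasibleParametersError",
]

#: Consent rate realized in the motivating telephone-coaching trial (207 of
#: 504 offered), used as the package-wide default.
DEFAULT_CONSENT_RATE = 207 / 504


class InvalidDesignError(ValueError):
    """A design parameter is outside its valid range."""


class InvalidPoolError(ValueError):
    """The eligible pool is too small or inconsistently specified."""


class InfeasibleParametersError(ValueError):
    """No finite design satisfies the requested constraints."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidDesignError(msg)


@dataclass(frozen=True)
class DesignParams:
    """Scalar inputs of a two-arm continuous-outcome power calculation.

    Parameters
    ----------
    alpha
        Two-sided significance level.
    power_target
        Target power (1 - beta).
    d_consent
        Standardized mean treatment effect among consenters, in units of the
        outcome standard deviation.
    consent_rate
        Anticipated fraction of offered patients who consent, in (0, 1].
    attrition
        Fraction of outcome data lost at follow-up (missing completely at
        random, both arms equally), in [0, 1).
    rho
        Correlation between baseline and follow-up outcome scores, in [0, 1).
    analysis_mode
        ``"baseline_adjusted"`` (analysis of covariance; variance factor
        1 - rho**2) or ``"unadjusted"`` (variance factor 1).
    effect_scale
        Whether ``d_consent`` refers to the effect in ``"consenters"``
        (diluted by the consent rate before powering) or is already an
        ``"offered"``-scale effect.
    """

    alpha: float = 0.05
    power_target: float = 0.80
    d_consent: float = 0.25
    consent_rate: float = DEFAULT_CONSENT_RATE
    attrition: float = 0.25
    rho: float = 0.5
    analysis_mode: str = "baseline_adjusted"
    effect_scale: str = "consenters"

    def __post_init__(self) -> None:
        _check(0 < self.alpha < 1, f"alpha must be in (0,1), got {self.alpha}")
        _check(0 < self.power_target < 1,
               f"power_target must be in (0,1), got {self.power_target}")
        _check(self.d_consent > 0,
               f"d_consent must be positive, got {self.d_consent}")
        _check(0 < self.consent_rate <= 1,
               f"consent_rate must be in (0,1], got {self.consent_rate}")
        _check(0 <= self.attrition < 1,
               f"attrition must be in [0,1), got {self.attrition}")
        _check(0 <= self.rho < 1, f"rho must be in [0,1), got {self.rho}")
        _check(self.analysis_mode in ("baseline_adjusted", "unadjusted"),
               f"analysis_mode must be 'baseline_adjusted' or 'unadjusted', "
               f"got {self.analysis_mode!r}")
        _check(self.effect_scale in ("consenters", "offered"),
               f"effect_scale must be 'consenters' or 'offered', "
               f"got {self.effect_scale!r}")

    @property
    def variance_factor(self) -> float:
        """Residual-variance multiplier of the follow-up comparison."""
        if self.analysis_mode == "baseline_adjusted":
            return 1.0 - self.rho ** 2
        return 1.0

    @property
    def target_offer_effect(self) -> float:
        """Offer-of-treatment scale effect to power for (diluted if needed)."""
        if self.effect_scale == "consenters":
            return self.d_consent * self.consent_rate
        return self.d_consent


@dataclass(frozen=True)
class PoolSpec:
    """Size and structure of the eligible pool inside the host cohort.

    Either ``eligible_count`` is given directly or it is derived as
    ``round(cohort_size * eligibility_rate)``.
    """

    cohort_size: int = 4377
    eligible_count: int | None = 1306
    eligibility_rate: float | None = None
    fraction_offered: float = 504 / 1306

    def __post_init__(self) -> None:
        if self.cohort_size < 2:
            raise InvalidPoolError(
                f"cohort_size must be >= 2, got {self.cohort_size}")
        if self.eligible_count is None and self.eligibility_rate is None:
            raise InvalidPoolError(
                "one of eligible_count or eligibility_rate is required")
        if self.eligibility_rate is not None and not (
                0 < self.eligibility_rate <= 1):
            raise InvalidPoolError(
                f"eligibility_rate must be in (0,1], got {self.eligibility_rate}")
        if not (0 < self.fraction_offered < 1):
            raise InvalidPoolError(
                f"fraction_offered must be in (0,1), got {self.fraction_offered}")
        e = self.n_eligible
        if e < 2:
            raise InvalidPoolError(f"eligible pool must hold >= 2, got {e}")
        if e > self.cohort_size:
            raise InvalidPoolError(
                f"eligible_count {e} exceeds cohort_size {self.cohort_size}")

    @property
    def n_eligible(self) -> int:
        """Resolved eligible-pool size E."""
        if self.eligible_count is not None:
            return int(self.eligible_count)
        return int(round(self.cohort_size * self.eligibility_rate))


@dataclass(frozen=True)
class SampleSizePlan:
    """Output of the cmRCT sample-size solver.

    ``n_offered + n_control`` always equals the eligible-pool size: in a
    cmRCT every eligible patient is in exactly one arm.  ``feasible`` is
    False when even the balanced split cannot reach the power target, in
    which case ``achieved_power`` reports the balanced-split maximum.
    """

    n_offered: int
    n_control: int
    expected_consenters: int
    detectable_offer_effect: float
    detectable_consent_effect: float
    achieved_power: float
    feasible: bool

    @property
    def n_eligible(self) -> int:
        return self.n_offered + self.n_control


@dataclass(frozen=True)
class PRCTPlan:
    """Conventional pragmatic-RCT comparator plan.

    Nonconsenters are excluded before randomization, so the randomized
    sample is independent of the consent rate; only the number that must be
    invited grows as consent falls.
    """

    per_arm: int
    n_consented: int
    n_invited: int
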