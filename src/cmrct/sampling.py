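"""Selection machinery for offering treatment inside a standing cohort.

In a cmRCT, everyone eligible but not selected is automatically a control,
so any departure from equal selection probabilities creates a systematic
arm difference.  ``uniform_select`` is the only valid scheme;
``weighted_select`` (oversampling of a stratum) and the current-eligibility
top-up rule are provided deliberately, to quantify the biases they induce.
Arm membership is determined once, at selection: noncontactable, withdrawn,
or newly ineligible participants are metadata, never a filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionRecord",
    "UniformityWarning",
    "uniform_select",
    "weighted_select",
    "expected_arm_composition",
    "topup_select",
]


class UniformityWarning(UserWarning):
    """The selection scheme violates the equal-probability requirement."""


@dataclass(frozen=True)
class SelectionRecord:
    """Ids selected for the treatment offer in one wave.

    ``wave`` 1 is the initial selection; 2+ are top-ups.  ``notes`` holds
    free-form metadata such as per-stratum inclusion probabilities or
    validity warnings.
    """

    selected: np.ndarray
    wave: int
    rule: str
    seed: int
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = np.unique(np.asarray(self.selected))
        if ids.size != np.asarray(self.selected).size:
            raise ValueError("selected ids must be unique")
        object.__setattr__(self, "selected", ids)

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready one-row-per-id representation."""
        return pd.DataFrame({
            "id": self.selected,
            "wave": self.wave,
            "rule": self.rule,
            "seed": self.seed,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SelectionRecord":
        if df.empty:
            raise ValueError("selection frame is empty")
        return cls(selected=df["id"].to_numpy(),
                   wave=int(df["wave"].iloc[0]),
                   rule=str(df["rule"].iloc[0]),
                   seed=int(df["seed"].iloc[0]))


def uniform_select(pool: np.ndarray, n: int, seed: int,
                   wave: int = 1) -> SelectionRecord:
    """Simple random sample without replacement from the eligible pool.

    The complement of the selection within the pool is the control arm.
    """
    pool = np.asarray(pool)
    if n > pool.size:
        raise ValueError(f"cannot select {n} from a pool of {pool.size}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n, replace=False)
    return SelectionRecord(selected=chosen, wave=wave, rule="uniform",
                           seed=seed)


def weighted_select(pool: np.ndarray, weights: np.ndarray, n: int, seed: int,
                    wave: int = 1) -> SelectionRecord:
    """Sequential without-replacement draws proportional to remaining weight.

    Implemented with exponential sort keys (draw ``Exp(1)/w_i`` per id and
    keep the n smallest), which is distributionally identical to drawing
    one id at a time with probability proportional to the weights of the
    ids still in the pool.  Emits :class:`UniformityWarning`: unequal
    selection probabilities violate the cmRCT design requirement and
    unbalance the control arm.
    """
    pool = np.asarray(pool)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != pool.shape:
        raise ValueError("weights must align one-to-one with pool ids")
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    if n > pool.size:
        raise ValueError(f"cannot select {n} from a pool of {pool.size}")
    warnings.warn(
        "weighted selection gives eligible patients unequal inclusion "
        "probabilities, violating the cmRCT uniform-selection requirement",
        UniformityWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    keys = rng.standard_exponential(pool.size) / weights
    chosen = pool[np.argsort(keys)[:n]]
    return SelectionRecord(selected=chosen, wave=wave, rule="weighted",
                           seed=seed)


def expected_arm_composition(p: float, w: float,
                             f: float) -> tuple[float, float]:
    """Expected stratum fractions of the two arms under w:1 oversampling.

    ``p`` is the stratum fraction of the pool, ``w`` the selection weight
    ratio for that stratum, ``f`` the sampling fraction.  The offered-arm
    fraction uses the small-f closed form ``w*p / (w*p + 1 - p)``; the
    control arm follows from exact conservation of stratum mass::

        offered*f + control*(1-f) = p
    """
    if not (0 < p < 1):
        raise ValueError(f"stratum fraction must be in (0,1), got {p}")
    if w <= 0:
        raise ValueError(f"weight ratio must be positive, got {w}")
    if not (0 < f < 1):
        raise ValueError(f"sampling fraction must be in (0,1), got {f}")
    offered = w * p / (w * p + (1.0 - p))
    control = (p - f * offered) / (1.0 - f)
    return offered, control


def topup_select(cohort: pd.DataFrame, prior: SelectionRecord, n: int,
                 seed: int, rule: str = "topup_baseline") -> SelectionRecord:
    """Select a later top-up wave for the treatment offer.

    Under ``topup_baseline`` (the valid rule) candidates are every
    baseline-eligible, never-previously-selected participant — explicitly
    including those now uncontactable, withdrawn, or no longer eligible,
    who would otherwise silently land in the control arm.  Under
    ``topup_current`` (provided only to demonstrate the hazard) candidates
    are refiltered on follow-up eligibility, which implies a different
    control pool for the top-up wave than for the first; a
    :class:`UniformityWarning` is emitted.
    """
    if rule not in ("topup_baseline", "topup_current"):
        raise ValueError(f"unknown top-up rule {rule!r}")
    base = cohort.loc[cohort["eligible_baseline"], "id"].to_numpy()
    candidates = np.setdiff1d(base, prior.selected)
    if rule == "topup_current":
        warnings.warn(
            "top-up on current eligibility implies a different control pool "
            "for the top-up wave than for the initial wave; analysis of the "
            "combined trial is not well defined",
            UniformityWarning, stacklevel=2)
        current = cohort.loc[cohort["eligible_followup"], "id"].to_numpy()
        candidates = np.intersect1d(candidates, current)
    if n > candidates.size:
        raise ValueError(
            f"cannot top-up {n} from {candidates.size} remaining candidates")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n, replace=False)
    return SelectionRecord(selected=chosen, wave=prior.wave + 1, rule=rule,
                           seed=seed)
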