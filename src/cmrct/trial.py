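"""Trial execution, estimation, and Monte-Carlo experiments.

One simulated cmRCT: select ``n_offered`` from the baseline-eligible pool
(everyone else eligible is a control), draw consent among contactable
offered participants, add the treatment effect to consenters' follow-up
outcomes, and estimate the offer-of-treatment effect by least squares of
the follow-up outcome on baseline and an offered-arm indicator.  The
complier average causal effect (CACE) is the Wald ratio: offer effect
divided by the observed consent rate, with its standard error scaled the
same way — larger point estimate, proportionally larger uncertainty, no
free power.

``monte_carlo_power`` validates the closed-form power formula empirically;
``bias_experiment`` reproduces the design's selection hazards: dropping
nonconsenters from the offered arm, oversampling a stratum, and topping up
on current rather than baseline eligibility.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

from .cohort import SimConfig, generate_cohort
from .sampling import (
    SelectionRecord,
    topup_select,
    uniform_select,
    weighted_select,
)

__all__ = [
    "TrialResult",
    "MonteCarloSummary",
    "run_cmrct",
    "estimate_cace",
    "monte_carlo_power",
    "bias_experiment",
]

_SEED_MAX = 2 ** 31 - 1


@dataclass(frozen=True)
class TrialResult:
    """Estimates from one simulated trial (all effects in sigma units)."""

    offer_estimate: float
    offer_se: float
    cace_estimate: float
    cace_se: float
    ci_low: float
    ci_high: float
    p_value: float
    observed_consent: float
    n_offered: int
    n_control: int
    n_analyzed: int

    @property
    def arm_sizes(self) -> tuple[int, int]:
        return (self.n_offered, self.n_control)


@dataclass(frozen=True)
class MonteCarloSummary:
    """Replicate-level operating characteristics, with Monte-Carlo SEs."""

    empirical_power: float
    mc_se_power: float
    mean_offer_estimate: float
    mean_bias: float
    mc_se_bias: float
    sd_estimates: float
    mean_cace: float
    ci_coverage: float
    mc_se_coverage: float
    replicates_used: int


def _ancova(y1: np.ndarray, y0: np.ndarray, offered: np.ndarray,
            alpha: float) -> tuple[float, float, float, float, float]:
    """Least-squares fit of y1 on (1, y0, offered); stats for the arm term.

    Returns (estimate, se, p_value, ci_low, ci_high) with a t reference
    distribution on n - 3 degrees of freedom.
    """
    n = y1.size
    if n < 4:
        raise ValueError("analysis set too small for a baseline-adjusted fit")
    X = np.column_stack([np.ones(n), y0, offered.astype(float)])
    beta, _, _, _ = np.linalg.lstsq(X, y1, rcond=None)
    resid = y1 - X @ beta
    dof = n - 3
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[2, 2]))
    est = float(beta[2])
    tval = est / se
    p = 2.0 * float(student_t.sf(abs(tval), dof))
    crit = float(student_t.ppf(1.0 - alpha / 2.0, dof))
    return est, se, p, est - crit * se, est + crit * se


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n independent sub-seeds (< 2^31) from one root seed."""
    return np.random.default_rng(seed).integers(0, _SEED_MAX, size=n)


def _execute_trial(cohort: pd.DataFrame, offered_ids: np.ndarray,
                   config: SimConfig, consent_seed: int,
                   control_ids: np.ndarray | None = None,
                   analysis: str = "full") -> TrialResult:
    """Draw consent, apply treatment, and analyze a given allocation.

    ``control_ids`` defaults to the baseline-eligible complement of the
    offered set.  ``analysis="drop_nonconsenters"`` restricts the offered
    arm to consenters — the invalid per-protocol analysis used by the
    exclusion bias experiment.
    """
    ids = cohort["id"].to_numpy()
    offered = np.isin(ids, offered_ids)
    if control_ids is None:
        control = cohort["eligible_baseline"].to_numpy() & ~offered
    else:
        control = np.isin(ids, control_ids)

    rng = np.random.default_rng(consent_seed)
    u = rng.random(ids.size)
    consented = (offered & cohort["contactable"].to_numpy()
                 & (u < cohort["consent_propensity"].to_numpy()))

    # Record arm membership on the table: every baseline-eligible
    # participant ends up in exactly one arm.
    arm = np.where(offered, "offered",
                   np.where(control, "control", "not_in_trial"))
    cohort["arm"] = arm
    cohort["consented"] = consented

    y1 = cohort["y1"].to_numpy() + config.tau * consented
    in_trial = offered | control
    if analysis == "drop_nonconsenters":
        in_trial = (offered & consented) | control
    elif analysis != "full":
        raise ValueError(f"unknown analysis {analysis!r}")
    use = in_trial & ~cohort["attrited"].to_numpy()

    est, se, p, lo, hi = _ancova(y1[use], cohort["y0"].to_numpy()[use],
                                 offered[use], config.alpha)
    n_off = int(offered.sum())
    obs_c = float(consented.sum()) / n_off
    cace = est / obs_c if obs_c > 0 else np.nan
    cace_se = se / obs_c if obs_c > 0 else np.nan
    return TrialResult(
        offer_estimate=est, offer_se=se,
        cace_estimate=cace, cace_se=cace_se,
        ci_low=lo, ci_high=hi, p_value=p,
        observed_consent=obs_c,
        n_offered=n_off, n_control=int(control.sum()),
        n_analyzed=int(use.sum()),
    )


def run_cmrct(cohort: pd.DataFrame, n_offered: int | None = None,
              scheme: str = "uniform", seed: int = 0,
              weights: np.ndarray | None = None) -> TrialResult:
    """Select, offer, and analyze one cmRCT inside a generated cohort.

    The offered arm retains nonconsenters and noncontactables; the control
    arm is the rest of the baseline-eligible pool.  ``scheme`` is
    ``"uniform"`` (the valid design) or ``"weighted"`` (requires
    ``weights`` aligned with the eligible pool, in id order).  The trial
    seed drives both selection and consent, so identical (cohort, seed)
    reproduce the result bit for bit.  Arm assignments are written back
    onto the cohort table.
    """
    config: SimConfig = cohort.attrs["config"]
    if n_offered is None:
        n_offered = config.n_offered
    pool = cohort.loc[cohort["eligible_baseline"], "id"].to_numpy()
    if n_offered >= pool.size:
        raise ValueError(
            f"n_offered ({n_offered}) must be smaller than the eligible "
            f"pool ({pool.size})")
    sel_seed, consent_seed = _spawn_seeds(seed, 2)
    if scheme == "uniform":
        rec = uniform_select(pool, n_offered, int(sel_seed))
    elif scheme == "weighted":
        if weights is None:
            raise ValueError("weighted scheme requires weights")
        rec = weighted_select(pool, weights, n_offered, int(sel_seed))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return _execute_trial(cohort, rec.selected, config, int(consent_seed))


def estimate_cace(result: TrialResult) -> float:
    """Wald complier-average-causal-effect estimate from a trial result.

    Offer-of-treatment effect divided by the observed consent rate; the
    standard error carried on the result scales by the same factor.
    """
    if result.observed_consent <= 0:
        raise ZeroDivisionError(
            "CACE is undefined when no offered participant consented")
    return result.offer_estimate / result.observed_consent


def monte_carlo_power(config: SimConfig) -> MonteCarloSummary:
    """Empirical power, bias, and coverage over seeded replicates.

    Each replicate regenerates a cohort and runs one trial; per-replicate
    seeds derive deterministically from ``config.seed``.  The true
    offer-of-treatment effect is ``tau * consent_rate``; coverage refers to
    the trial confidence interval for that quantity.
    """
    R = config.replicates
    seeds = _spawn_seeds(config.seed, 2 * R).reshape(R, 2)
    ests = np.empty(R)
    caces = np.empty(R)
    rejected = np.empty(R, dtype=bool)
    covered = np.empty(R, dtype=bool)
    truth = config.tau * config.consent_rate
    for r in range(R):
        cohort = generate_cohort(config, int(seeds[r, 0]))
        res = run_cmrct(cohort, seed=int(seeds[r, 1]))
        ests[r] = res.offer_estimate
        caces[r] = res.cace_estimate
        rejected[r] = res.p_value < config.alpha
        covered[r] = res.ci_low <= truth <= res.ci_high
    p_hat = float(rejected.mean())
    cov = float(covered.mean())
    sd = float(ests.std(ddof=1))
    return MonteCarloSummary(
        empirical_power=p_hat,
        mc_se_power=float(np.sqrt(p_hat * (1 - p_hat) / R)),
        mean_offer_estimate=float(ests.mean()),
        mean_bias=float(ests.mean() - truth),
        mc_se_bias=sd / float(np.sqrt(R)),
        sd_estimates=sd,
        mean_cace=float(np.nanmean(caces)),
        ci_coverage=cov,
        mc_se_coverage=float(np.sqrt(cov * (1 - cov) / R)),
        replicates_used=R,
    )


def _mc_rows(label_vals: dict[str, list[float]], R: int) -> pd.DataFrame:
    rows = []
    for label, vals in label_vals.items():
        arr = np.asarray(vals, dtype=float)
        row = {"procedure": label,
               "mean_estimate": float(np.nanmean(arr)),
               "mc_se": float(np.nanstd(arr, ddof=1) / np.sqrt(len(arr))),
               "replicates": R}
        rows.append(row)
    return pd.DataFrame(rows)


def bias_experiment(config: SimConfig, mode: str,
                    replicates: int | None = None,
                    seed: int | None = None, **options) -> pd.DataFrame:
    """Contrast a valid cmRCT procedure with a flawed variant.

    Modes
    -----
    ``exclusion``
        Requires ``gamma != 0`` (prognosis-linked consent).  Compares the
        full-retention offer-of-treatment analysis (unbiased for
        ``tau * consent_rate``) with dropping nonconsenters from the
        offered arm (a per-protocol contrast targeting ``tau``, biased
        whenever consent tracks prognosis).
    ``oversampling``
        Requires ``stratum_effect != 0``.  Compares uniform selection with
        ``weight_ratio``:1 oversampling of the ``female`` stratum,
        reporting per-arm stratum composition alongside estimates.
        ``n_offered`` may be overridden to control the sampling fraction.
    ``topup``
        Runs a two-wave trial (``wave1`` then a top-up to
        ``config.n_offered``) under the baseline-eligibility top-up rule
        and the current-eligibility rule, reporting how far the implied
        control pool drifts from the fixed baseline partition.

    Returns a comparison table with one row per procedure: mean estimate,
    Monte-Carlo SE, the procedure's target quantity, and its bias.
    """
    R = replicates if replicates is not None else config.replicates
    root = config.seed if seed is None else seed
    seeds = _spawn_seeds(root, 3 * R).reshape(R, 3)

    if mode == "exclusion":
        return _exclusion_experiment(config, R, seeds)
    if mode == "oversampling":
        return _oversampling_experiment(config, R, seeds, **options)
    if mode == "topup":
        return _topup_experiment(config, R, seeds, **options)
    raise ValueError(f"unknown bias-experiment mode {mode!r}")


def _exclusion_experiment(config: SimConfig, R: int,
                          seeds: np.ndarray) -> pd.DataFrame:
    if config.gamma == 0:
        raise ValueError(
            "exclusion experiment requires prognosis-linked consent "
            "(gamma != 0); with ignorable consent both analyses are unbiased")
    full = np.empty(R)
    dropped = np.empty(R)
    for r in range(R):
        cohort = generate_cohort(config, int(seeds[r, 0]))
        pool = cohort.loc[cohort["eligible_baseline"], "id"].to_numpy()
        rec = uniform_select(pool, config.n_offered, int(seeds[r, 1]))
        res_full = _execute_trial(cohort, rec.selected, config,
                                  int(seeds[r, 2]))
        res_drop = _execute_trial(cohort, rec.selected, config,
                                  int(seeds[r, 2]),
                                  analysis="drop_nonconsenters")
        full[r] = res_full.offer_estimate
        dropped[r] = res_drop.offer_estimate
    out = _mc_rows({"retain_all": full, "drop_nonconsenters": dropped}, R)
    out["target"] = [config.tau * config.consent_rate, config.tau]
    out["bias"] = out["mean_estimate"] - out["target"]
    return out


def _oversampling_experiment(config: SimConfig, R: int, seeds: np.ndarray,
                             weight_ratio: float = 2.0,
                             n_offered: int | None = None) -> pd.DataFrame:
    if config.stratum_effect == 0:
        raise ValueError(
            "oversampling experiment requires a stratum-outcome association "
            "(stratum_effect != 0)")
    n_off = n_offered if n_offered is not None else config.n_offered
    ests = {"uniform": np.empty(R), "weighted": np.empty(R)}
    off_frac = {"uniform": np.empty(R), "weighted": np.empty(R)}
    ctl_frac = {"uniform": np.empty(R), "weighted": np.empty(R)}
    import warnings as _warnings
    for r in range(R):
        cohort = generate_cohort(config, int(seeds[r, 0]))
        eligible = cohort["eligible_baseline"].to_numpy()
        pool = cohort.loc[eligible, "id"].to_numpy()
        female = (cohort.loc[eligible, "stratum"] == "female").to_numpy()
        weights = np.where(female, weight_ratio, 1.0)
        recs = {"uniform": uniform_select(pool, n_off, int(seeds[r, 1]))}
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            recs["weighted"] = weighted_select(pool, weights, n_off,
                                               int(seeds[r, 1]))
        fem_ids = pool[female]
        for name, rec in recs.items():
            res = _execute_trial(cohort, rec.selected, config,
                                 int(seeds[r, 2]))
            ests[name][r] = res.offer_estimate
            controls = np.setdiff1d(pool, rec.selected)
            off_frac[name][r] = np.isin(rec.selected, fem_ids).mean()
            ctl_frac[name][r] = np.isin(controls, fem_ids).mean()
    out = _mc_rows(ests, R)
    out["offered_female_frac"] = [off_frac[k].mean() for k in ests]
    out["control_female_frac"] = [ctl_frac[k].mean() for k in ests]
    out["target"] = config.tau * config.consent_rate
    out["bias"] = out["mean_estimate"] - out["target"]
    return out


def _topup_experiment(config: SimConfig, R: int, seeds: np.ndarray,
                      wave1: int | None = None) -> pd.DataFrame:
    n1 = wave1 if wave1 is not None else config.n_offered // 2
    n2 = config.n_offered - n1
    ests = {"topup_baseline": np.empty(R), "topup_current": np.empty(R)}
    pool_change = {"topup_baseline": np.empty(R), "topup_current": np.empty(R)}
    import warnings as _warnings
    for r in range(R):
        cohort = generate_cohort(config, int(seeds[r, 0]))
        ids = cohort["id"].to_numpy()
        baseline_pool = ids[cohort["eligible_baseline"].to_numpy()]
        current_pool = ids[cohort["eligible_followup"].to_numpy()]
        w1 = uniform_select(baseline_pool, n1, int(seeds[r, 1]))
        rec_b = topup_select(cohort, w1, n2, int(seeds[r, 2]))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            rec_c = topup_select(cohort, w1, n2, int(seeds[r, 2]),
                                 rule="topup_current")
        for name, rec in (("topup_baseline", rec_b), ("topup_current", rec_c)):
            offered = np.union1d(w1.selected, rec.selected)
            fixed_control = np.setdiff1d(baseline_pool, offered)
            if name == "topup_baseline":
                control = fixed_control
            else:
                # Control pool the current-eligibility rule implies for the
                # top-up wave.
                control = np.setdiff1d(current_pool, offered)
            sym = np.setdiff1d(control, fixed_control).size + \
                np.setdiff1d(fixed_control, control).size
            pool_change[name][r] = sym / fixed_control.size
            res = _execute_trial(cohort, offered, config, int(seeds[r, 2]),
                                 control_ids=control)
            ests[name][r] = res.offer_estimate
    out = _mc_rows(ests, R)
    out["control_pool_change"] = [pool_change[k].mean() for k in ests]
    out["target"] = config.tau * config.consent_rate
    out["bias"] = out["mean_estimate"] - out["target"]
    return out
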