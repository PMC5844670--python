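# Methods

## Design problem

A cohort-multiple RCT (cmRCT) offers an experimental treatment to a random
subset of the treatment-eligible members of a standing cohort; all other
eligible members form the control arm without being informed. Two features
drive everything in this package: offered patients who decline must remain
in the treatment arm (their counterparts in the control arm cannot be
identified, so removing them would bias the comparison), and the control
arm is the complement of the offered arm within a *finite* eligible pool.
The first dilutes the detectable arm difference by the consent rate; the
second couples the two arm sizes, so that power cannot be bought by
offering more patients indefinitely.

## Power model

All closed forms use the two-sided normal approximation for a comparison of
follow-up means:

    power = Φ( d / sqrt( V · (1/m1 + 1/m2) ) − z_{1−α/2} ),  m_i = n_i (1 − a)

* `d` — standardized offer-of-treatment effect (σ units). When the design
  targets an effect in *consenters*, it is first diluted: `d = c · d_consent`.
* `a` — attrition, applied multiplicatively to both analysis arms (missing
  completely at random). Default 0.25.
* `V` — residual-variance factor: `1 − ρ²` for a baseline-adjusted (ANCOVA)
  analysis with baseline–follow-up correlation `ρ` (default 0.5), or 1
  unadjusted. A change-score factor `2(1−ρ)` is deliberately not offered:
  it is incompatible with the conventional per-arm sizes this formula
  reproduces.
* Quantiles at double precision; no continuity correction. At `d = 0` the
  formula returns α/2 (one tail of the two-sided test), not 0.

Note the cancellation `V/(1−a) = 0.75/0.75 = 1` at the defaults: the
precision gained by baseline adjustment exactly offsets 25% attrition, and
baseline-adjusted results coincide with the unadjusted no-attrition ones.
This identity is asserted in the test suite at 1e−12.

The detectable effect inverts the power formula:
`d* = (z_{1−α/2} + z_{1−β}) · sqrt(V (1/m1 + 1/m2))`, minimized over
`n1 + n2 = E` at the balanced split.

### cmRCT sample-size search

`cmrct_sample_size` scans `n1` from 2 to `floor(E/2)` and returns the first
split whose detectable offer effect, **rounded to the 3 decimals at which
such effects are conventionally printed**, does not exceed the similarly
rounded diluted target. The printed-precision comparison is a deliberate
convention: detectable effects are quoted at 3 dp, and a design whose
detectable effect rounds to the quoted target is treated as adequate. Its
consequence is a tolerance band of roughly ±0.005 on achieved power
(designs in the band sit at 0.795–0.805), and near the feasibility boundary
the smallest qualifying `n1` can be noticeably below the balanced split,
because a plateau of mildly unbalanced splits rounds to the same 3-dp
detectable effect. If no split qualifies, the plan is flagged infeasible
and reports the balanced-split achievable power — the maximum the pool
supports.

`min_consent_rate` divides the balanced-split detectable effect by the
consenter-scale target and reports the nearest whole percent: below this
consent rate no allocation of the pool reaches the power target.

### pRCT comparator

The conventional consent-then-randomize comparator excludes nonconsenters
before randomization, so its per-arm size solves the *undiluted* balanced
formula, `per_arm = ceil( 2 V z² / (d² (1−a)) )`, and consent only inflates
invitations: `invited = ceil(2 · per_arm / c)`. Ceilings are taken after
rounding away float noise at 1e−9 so that exact ratios (e.g. `504/0.9`)
do not spuriously round up.

### Cohort-requirement mode

`min_eligible_pool` answers the planning question "how many eligible
patients must the cohort contain if a fraction `f` will be offered
treatment?". It uses no attrition and the unadjusted variance factor — the
convention for such planning curves — and an exact (unrounded) feasibility
comparison, scanning E upward with `n1 = round(f·E)` clipped to [2, E−2].
The required pool scales as `1/(c·d)²` and is minimized at `f = 0.5`.

### Rounding conventions

Printed detectable effects use 3 decimals, percentages and expected
consenter counts the nearest integer, sample sizes always ceilings.
Reported roundings are half-up on the shortest decimal representation of
the float (so 0.205 prints as 0.21, as a person would round it), never
banker's rounding.

## Simulator

### Generating model

Per cohort member: latent baseline `Z0 ~ N(0,1)`, innovation `ε ~ N(0,1)`,
null follow-up `Z1 = ρ Z0 + sqrt(1−ρ²) ε`; observed `Y0 = Z0 + δ(F − p_F)`
and `Y1 = Z1 + δ(F − p_F)` where `F` is a binary stratum indicator (default
fraction 0.33) and `δ` its outcome shift (default 0, used only by the
oversampling experiment). Both outcomes are marginally standard under the
null with `corr(Y0, Y1) = ρ`, so the simulator's parameters are exactly the
power formula's. Treatment adds `τ` to the follow-up outcome of consenting
offered participants at trial time.

Eligibility is Bernoulli(`e`) with default `e = 1306/4377`; between waves a
fraction `churn_loss = 0.30` of the eligible lose eligibility and
`churn_gain = 0.17` of the ineligible gain it, independently of outcomes.
Contactability is Bernoulli(`1 − noncontact_rate`), default 51/504.
Attrition is MCAR Bernoulli(`a`) at follow-up, both arms equally.

### Consent

Offered participants consent when contactable and a uniform draw falls
below the propensity

    Φ( sqrt(1+γ²) · Φ⁻¹(c′) + γ · Z1 ),    c′ = c / (1 − noncontact_rate),

where the prognosis score is the latent null follow-up outcome `Z1`. The
`sqrt(1+γ²)` calibration keeps the marginal consent rate among all offered
participants exactly `c` for every strength `γ` of the consent–prognosis
link (asserted in the tests at n = 2·10⁵). Linking consent to `Z1` rather
than to `Y0` alone matters: selection on the baseline would be absorbed by
the baseline-adjusted estimator, whereas selection on follow-up prognosis
biases any analysis that drops nonconsenters — which is precisely the
hazard the exclusion experiment demonstrates. `γ = 0` recovers ignorable
consent.

### Estimation and testing

The trial estimator regresses the follow-up outcome on baseline and an
offered-arm indicator by least squares over all non-attrited trial
participants, with a two-sided t test (df = n−3) at the configured α and a
95% confidence interval. The fit is a closed-form 3-parameter OLS in numpy
(the Monte-Carlo loops make per-replicate model objects wasteful); a unit
test verifies coefficient, standard error, and p-value against statsmodels
to 1e−10 on a seeded trial. The CACE is the Wald ratio
`offer_estimate / observed_consent`, SE scaled by the same factor,
undefined at zero consent.

### Randomness

One root seed per run. `monte_carlo_power` and `bias_experiment` derive
per-replicate (cohort, trial) sub-seeds by drawing 31-bit integers from
`numpy.random.default_rng(root_seed)`; each trial further splits its seed
into a selection stream and a consent stream the same way. Identical
(config, seed) therefore reproduce cohorts and results bit for bit.

### What the simulator does and does not emulate

It reproduces the features the closed forms model — dilution, finite-pool
allocation, attrition, baseline correlation, noncontact, churn — under
Gaussian outcomes, an exactly linear baseline link, and MCAR attrition.
Real cohorts add skewed or bounded outcomes, informative (outcome-linked)
attrition and churn, and treatment-timing variability; passing tests here
validate the arithmetic of the design formulas and the direction and rough
size of the selection biases, not robustness to those violations.

One validity-domain caveat: the closed form treats the diluted effect
`c·τ` as fixed, while in a simulated trial the realized consent rate varies
binomially around `c`. Because power is concave in the effect over the
usual operating range, this variation pulls empirical power slightly below
the formula (a Jensen effect of a few tenths of a percentage point for an
offered arm of ~250). The power-agreement checks therefore use offered
arms of ≥400, where the effect is second order; for smaller offered arms
the formula should be read as accurate to within about half a percentage
point of power.

## Bias experiments

* **exclusion** (requires `γ ≠ 0`): the same simulated trials analyzed with
  full retention versus dropping offered nonconsenters. Retention targets
  the offer effect `c·τ` and is unbiased by randomization; the exclusion
  analysis targets `τ` but inherits the prognosis selection of consenters
  (with `τ = 0` and `γ = 1` its bias is ≈ +0.46σ while retention stays at
  zero, at default sizes).
* **oversampling** (requires `δ ≠ 0`): uniform versus 2:1 weighted selection
  of the female stratum from a 33%-female pool. Weighted selection is
  performed with exponential sort keys, which is distributionally identical
  to sequential draws proportional to remaining weights; at small sampling
  fractions the offered arm approaches `wp/(wp+1−p) ≈ 0.496`, and the
  control-arm composition follows from exact stratum-mass conservation
  (`offered·f + control·(1−f) = p`, giving ≈0.28 at f = 0.227). Exact
  per-wave inclusion probabilities of weighted sampling without replacement
  are intractable, so composition checks pair the small-f closed form with
  a simulation oracle.
* **topup**: a two-wave offer under the baseline-eligibility top-up rule
  (candidates = baseline-eligible, never selected — including uncontactable
  and churned-out members) versus the current-eligibility rule. The
  baseline rule keeps a single fixed control pool (pool-change measure
  exactly 0) and an unbiased estimate; the current rule's implied control
  pool differs from the fixed partition by the churn flows (~100% of the
  pool membership churns under the 30%/17% defaults), which is the
  structural defect — the combined trial no longer has one well-defined
  control group.

## Problem sizes

Monte-Carlo checks in the test suite use 5,000 replicates for operating
characteristics (power, type-I error, estimator means; Monte-Carlo SE on a
rate ≈ 0.006), 1,000–1,500 for bias contrasts, and a few hundred for unit
smoke checks; full-cohort tables of 4,377 are regenerated per replicate.
The independent ANCOVA power oracle runs vectorized at 20,000 replicates.

## Known limitations

Continuous outcomes only (no binary/survival endpoints), no cluster or
adaptive extensions, no multiplicity handling across multiple trials in one
cohort, no informative attrition, and no instrumental-variable estimators
beyond the Wald/CACE ratio. The sample-size search's printed-precision
feasibility convention means "feasible" designs can sit at 79.5% power for
an 80% target; use the reported `achieved_power` when the distinction
matters.
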