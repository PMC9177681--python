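# Methods

## The inference problem

On every no-think trial the participant's report is binary: the
suppressed memory intruded (`y = 1`) or it did not (`y = 0`).  The
analysis treats the participant as an observer of their own control
performance: a *perceptual model* turns the history of ratings into a
pre-outcome belief `μ̂₁⁽ᵗ⁾ ∈ (0,1)` that the next cue will intrude
(the model's input at trial *t* is the previous outcome,
`u⁽ᵗ⁾ = y⁽ᵗ⁻¹⁾`; every filter starts from a 0.5 belief), and a
*response model* scores how well those beliefs predict the actual
ratings.  Two derived quantities drive all downstream analyses: the
belief itself (predictive-control signal, defined on every trial) and
the positive prediction error `PE⁺ = 1 − μ̂₁` on intrusion trials
(reactive-control demand).

## Perceptual models

Three filters share the generic form `new belief = old belief +
weight × prediction error` and differ in the weight dynamics:

* **Rescorla–Wagner** — constant weight `α ∈ [0,1]`.
* **Kalman filter** — the gain evolves as
  `K ← (K + πω)/(K + πω + 1)`, with `π` the belief reliability and
  `ω` the process uncertainty; uncertainty-weighted but non-volatile
  learning.  The gain stays in [0,1] for any positive `π, ω`
  (initial gain `K₀ = 0.5`).
* **Two-level binary HGF** — beliefs are hierarchical: level 1 is the
  Bernoulli intrusion event, level 2 a Gaussian random walk on its
  log-odds tendency with step variance `exp(ω)`.  Per trial, with
  `s()` the logistic sigmoid:

  ```
  μ̂₁ = s(μ₂)                    π̂₁ = 1 / (μ̂₁ (1 − μ̂₁))
  δ₁ = y − μ̂₁
  π₂ = 1 / (σ₂ + exp(ω)) + μ̂₁ (1 − μ̂₁)
  σ₂ = 1 / π₂                    μ₂ ← μ₂ + σ₂ δ₁
  ```

  Larger second-level uncertainty ⇒ larger updates; `ω` sets the
  participant-specific update speed.  Defaults `μ₂⁽⁰⁾ = 0`,
  `σ₂⁽⁰⁾ = 1`; `μ₂` is clamped to ±36 so the sigmoid stays finite in
  float64, and the posterior variance is positive by construction.

Each filter runs from three evidence *sources*: the chronological
trial sequence (**state**), each item's own repetition history
(**item** — the filter restarts per item, with the item's repetition
count as its time axis; items with fewer than two usable repetitions
are flagged and excluded), and their fusion (**combined**).  For the
HGF the fusion is precision-weighted with the Bernoulli prediction
precision `π̂₁ = 1/(μ̂₁(1−μ̂₁))` — the only first-level precision a
two-level binary filter defines; for RW/KF, which carry no belief
precision, the two sources are averaged.  The fusion is defined from
an item's second repetition onward; before that the trial carries the
state belief.

## Response model and estimation

Beliefs map to rating probabilities through a beta density with
`α_b = θν`, `β_b = ν − α_b`; `ν > 0` is the inverse decision noise.
Binary outcomes are evaluated at `ŷ = clamp(y, ε, 1−ε)` with
`ε = 1e−4` (the density degenerates at exactly 0/1), and beliefs are
clamped identically.  Model accuracy is the summed negative
log-likelihood.

Two numerical properties of this clamped density shape the whole
pipeline and are worth stating explicitly:

* **`ν < 1` is degenerate.**  Both shape parameters drop below 1 and
  the density becomes U-shaped: *any* belief assigns enormous density
  to *both* clamped extremes, so the likelihood rewards `ν → 0`
  regardless of the data.  Estimation therefore bounds `ν ≥ 1`.
* **Certainty is penalised near `ν = 1`.**  As `θ → 0/1` one shape
  parameter vanishes and the normaliser `−ln Γ(·)` diverges: the
  density at the matching outcome *sinks* for near-certain beliefs.
  Consequently the best-fitting trajectories hover at moderate
  beliefs, and parameters whose main signature is belief saturation
  (RW `α`, high `ω`) are weakly identified from binary ratings (see
  Validation below).  Properties that presume "confident tracking
  wins" hold only in the sharp regime (fixed large `ν`), and are
  tested there.

MAP estimation maximises log-likelihood plus Gaussian log-priors in
the estimation space: HGF `ω` native with `N(−3, 16)` (high variance
to capture between-participant spread); KF `log π, log ω ~ N(0, 4)`;
RW `logit α ~ N(0, 1)`; `log ν ~ N(0, 4)`, truncated at `log ν ≥ 0`
as above.  A quasi-Newton optimizer (L-BFGS-B, box bounds well outside
the plausible range) runs from 5 starts — the prior mean plus
jittered starts (sd/4); the best objective is kept, a failed start is
dropped, and if all fail the prior-mean parameters are returned with
`converged=False` (trajectories are still produced).  The fit reports
both the pure accuracy and the accuracy-plus-shrinkage objective;
model selection consumes the latter's negative as a log-evidence
score that accounts for accuracy and (prior) complexity.

A descriptive `prior_stuck` flag marks fits whose `ω` stayed within
0.05 of the prior mean.  Note that on genuinely stochastic ~50/50
sequences a *correct* MAP moves `ω` below −3 (flatter beliefs fit
better), so the flag describes the fit, not a property of stochastic
data.

## The synthetic-data generator

The generator emulates a virtual TNT experiment: 18 no-think items ×
8 repetitions spread over 4 sessions (144 suppression trials, each
item exactly twice per session, pseudo-random order without immediate
repeats).  A virtual participant carries one of the nine models with
parameters drawn per simulation, and on each trial

1. produces its model's predicted belief,
2. subtracts a **suppression factor** `s` and adds Gaussian noise
   (sd 0.2),
3. rates "intrusion" iff the resulting value exceeds 0.5 — this is
   exactly the rating that maximises the cumulative beta-model
   log-accuracy at any `ν` (the simulations fix `ν = e⁰ = 1`, the
   unbiased mapping), with ties resolved to "no intrusion" —
4. and updates its filter with its own rating.

The suppression factor exists to keep belief trajectories from
tilting toward 1 and to produce the canonical behavioural pattern: an
intrusion proportion starting near 0.5 and declining toward ~0.3
across the four sessions.  It is tuned per model by grid search
(16-point grid on [0, 0.15], 40 agents per grid value with common
random numbers, mean-squared error against the packaged linear
0.5 → 0.3 reference profile; ties go to the smallest factor).

Two generator settings were calibrated once, before any recovery
analysis, and then frozen:

* **Noise scale.**  The belief noise is the sole stochastic channel
  of the threshold response.  At small scales (sd ≤ 0.15) the
  response is nearly deterministic, the filter's self-confirming loop
  locks trajectories at an extreme within one session, and at least
  one HGF source produces flat or undershooting session profiles at
  every suppression value.  sd = 0.2 is the smallest scale on the
  grid {0.05, 0.1, 0.15, 0.2} at which all three tuned HGF sources
  decline monotonically while tracking the reference within
  |MD| < 0.1; it is the package default.  A Bernoulli response rule
  (`y ~ Bernoulli(θ)`, noise in the response channel itself) is
  available as an option; it yields clean declines for every family
  but makes the mean prediction error exactly `−s` by construction.
* **Sampling distributions.**  Simulation parameters are drawn from
  an "empirical" regime representing plausible fitted values rather
  than from the wide estimation priors: `ω ~ N(−3, 1)` (a
  subject-level spread of ~1 is what group-level t-statistics of this
  task size imply), RW `logit α ~ N(−2, 1)` and KF
  `log π, log ω ~ N(−2, 1)` (median learning rates ~0.1, the slow
  regime consistent with a 0.5 → 0.3 decline over 144 trials).
  Sampling from the wide estimation priors
  (`sample_params(..., regime="prior")`) inflates recovery
  correlations mechanically through the enormous between-draw spread
  and is kept only for sensitivity analyses.

Coupling-parameter fixtures for the group statistics draw a per-
subject imbalance angle `N(group mean, spread)` and decompose a
positive resultant magnitude onto the predictive/reactive axes, so
the true angular structure is known exactly.

## Validation analyses and what they show

* **Falsification** — 50 virtual subjects × 20 parameter draws per
  model (the published large-scale regime, 200 × 100, is a parameter
  away); ratings averaged over draws, summarised per session, scored
  by mean difference (MD) and mean per-subject correlation (MC)
  against the reference profile.  The tuned HGF sources decline
  monotonically with |MD| < 0.1.
* **Trajectory / model recovery** — generate from one source variant,
  fit all variants, select by trajectory correlation or summed
  accuracy; aggregate into a row-stochastic confusion matrix and
  Bayes-invert it with a uniform prior.  Exact ties split uniformly;
  degenerate (constant) trajectories are discarded and counted.
* **Parameter recovery** — within each virtual subject, the Pearson
  correlation between generating and fitted parameters across draws,
  averaged over subjects.  At the desk scale (50 × 20) the item-source
  HGF `ω` recovers moderately (r ≈ 0.4–0.5) and the KF `ω` not at all
  (r ≈ 0) — the item filter's per-item restarts keep trajectories in
  the informative mid-range.  State-source `ω` and RW `α` do **not**
  recover under this generator (r ≈ 0 and r < 0): their signature is
  trajectory saturation, precisely what the response model's
  certainty penalty makes invisible (RW: inverts — fast generators
  produce saturated data best fit by slow parameters).  Passing
  recovery for the item source therefore says nothing about state/RW
  recovery on real data, and the package reports all of them honestly
  rather than tuning the generator per target.
* **Power** — the frequency of significant two-sample t-tests on
  fitted `ω` over simulated two-group cohorts; the effect size is a
  required input, to be chosen in the range of the empirical group
  differences under study.

The generator emulates rating *statistics* (item structure,
session-wise decline, stochasticity); it does not emulate reaction
times, think trials, stimulus content, or behavioural exclusions, so
green validation here does not certify those aspects of real data
handling.

## Model selection

Random-effects BMS treats the model identity as a random effect:
`r ~ Dirichlet(α₀ = 1)`, subjects multinomial.  The variational
update iterates subject posteriors `g_nk ∝ exp(L_nk + ψ(α_k) −
ψ(Σα))` against `α = α₀ + Σₙ g_n` to a 1e−6 tolerance (hard failure
after 10⁴ iterations).  Exceedance probabilities are Monte-Carlo
frequencies of `argmax r` over 10⁶ seeded Dirichlet draws (chunked);
the Bayesian omnibus risk is `1/(1 + exp(F₁ − F₀))` with `F₁` the
converged variational free energy and `F₀ = Σₙ (logsumexp(Lₙ) −
log K)` the equal-frequency null; `PXP = XP(1−BOR) + BOR/K` holds to
machine precision by construction and is verified to 1e−12.  Family
evidence pools members by logsumexp minus log family size (uniform
within-family prior), making the family score invariant to
duplicating a member.  The between-group test compares the pooled
free energy against the sum of group-wise free energies at equal
prior odds.  BMA weights each subject's parameters by their
subject-level model posteriors, rows validated to sum to 1; group
analyses compute the weights within each group separately.

## Group statistics

**Imbalance geometry.**  The frame places 0° at the bottom of the
y-axis, anticlockwise positive, angles in (−180°, 180°].  Negative
predictive couplings project onto +45°, positive onto −135°; negative
reactive onto −45°, positive onto +135°.  The printed one-argument
arctangent of the resultant is quadrant-ambiguous, so the angle is
computed with the two-argument arctangent in this frame — the only
convention under which predictive dominance gives `θ > 0` and perfect
balance gives 0°.  A zero resultant is undefined (NaN, subject
flagged).  Circular means come from the resultant of unit vectors;
the 95% CI is a 2000-resample percentile bootstrap on deviations
wrapped around the point estimate (stable across ±180°).  Watson's
two-sample U² uses the standard rank formulation on circle fractions
with a seeded 10⁴-permutation p-value — rotation-invariant and free
of distributional assumptions.

**Contrast battery.**  Four one-tailed effect families on
subject-level coupling parameters — control × group interactions
(focal group more negative predictive−reactive difference), within-
group control effects, and reactive / predictive negative-coupling
tests — with Benjamini–Hochberg FDR *within* each family, 2000-
resample bootstrap CIs of the mean, `Pp` = bootstrap probability that
the mean lies on its observed side of zero (the closest reproducible
analogue of a posterior sign probability; swap in a Bayesian t-test
if preferred), and a ROPE Bayes factor for the one-sample families:
the standardised effect `d = mean/sd` gets a unit-information
`N(0,1)` prior, the approximate posterior `N(d̂·n/(n+1), 1/(n+1))` is
sampled 90,000 times, and `BF = P_prior(|d| < 0.1) / P_post(|d| <
0.1)` — greater than 1 when the posterior vacates the region of
practical equivalence, read on the conventional 3/10/30/100 bands.
Groups with fewer than 3 subjects are skipped.  The whole-hippocampus
region defaults to the *sum* of rostral and caudal couplings (mean
available).

**Symptom correlations.**  Subscale severities are residualised on
the total severity within group (ordinary least squares), so adjusted
scores are uncorrelated with overall symptom load.  Spearman
correlations carry 2000-resample joint-subject bootstrap 95% CIs;
dependent (two symptom dimensions, one group) and independent (one
dimension, two groups) correlation differences are bootstrap-based
with 90% CIs, `Z = |Δρ| / sd(Δρ*)` and a two-sided normal p;
BH-FDR over each family.  Missing scores are pairwise-deleted with
the used n reported.

## Problem sizes

Desk-scale defaults — 50 subjects × 20 draws for recovery and
falsification, 16-point suppression grids, 2000 bootstrap resamples,
10⁴ permutations, 10⁶ Dirichlet draws — keep any single analysis
within minutes on one core while leaving the estimators' qualitative
behaviour unchanged; the published-scale regimes are reached by
passing the corresponding sizes explicitly.

## Known limitations

* The deposited subject-level coupling dataset is not redistributed;
  the real-data imbalance numbers require placing its files under
  `data/deposited/` (see `tests/test_acceptance.py`).
* State-source and RW parameter recovery fail under this generator
  for the structural reason documented above; conclusions about those
  parameters on real data should not rely on this pipeline's
  estimates.
* The response model's certainty penalty (and the `ε` clamp that
  shapes it) is inherited from the beta-density observation model;
  alternative response models (e.g. probit/softmax links) are outside
  the current scope.
* DCM model inversion, ROI extraction and voxelwise statistics are
  out of scope: the package builds the modulatory inputs and consumes
  the resulting coupling parameters.
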