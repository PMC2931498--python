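# Methods

This note documents the statistical procedures implemented in `volprof`,
the choices made where the methodology leaves details open, and what the
synthetic-data calibration does and does not establish.

## Effectiveness indicators

Episodes of care are reconstructed as daily ordinal level-of-care sequences
from half-open interval records `[start_day, end_day)`, day 0 being the
index (fracture) admission.  Levels are 1 home, 2 nursing home, 3
health-center inpatient ward, 4 hospital, 5 death; death is absorbing.
Days not covered by any institutional record are community days (level 1):
discharge registers record institutional care only, so absence of a record
means the patient was at home.

Two indicators are computed per patient over a follow-up window:

* **Four-month mortality** — level 5 observed on any day in
  `[0, window]`.
* **Maintainability** — satisfactory unless the level *increases* between
  consecutive days at some day in `[1, window]`.  Only the first such
  backward step is recorded, and it is classified as
  * *death* for any step into level 5,
  * *referral to a higher-level provider* for the inpatient escalation
    3 → 4,
  * *readmission* for every other increase (community levels 1–2 back into
    institutional care, and 1 → 2).

Operationalization choices: "four months" is `window_days = 120`
(4 × 30 days), configurable per run.  The transition → label map above is a
package decision — the three category names are standard but no published
transition table exists; the map is an explicit, overridable argument of
`maintainability`.  The 1 → 2 step counts as a backward step (it is an
intensity increase under the level ordering); trajectories are resolved at
daily resolution, so same-day transits through intermediate levels are not
representable.  Death within the window implies an unsuccessful episode by
construction (a step to level 5 is an increase), and the property suite
asserts this implication on random trajectories.

## Risk adjustment

Per outcome, a maximum-likelihood logistic regression of the outcome on the
standard case-mix encoding: age per decade (linear on the logit scale), sex
(male = 1), fracture type (reference: femoral neck), care history
(reference: recent short-term care; levels absent from a subset are dropped
automatically), and ten binary comorbidity flags.  Age per decade is a
package decision: only a per-decade scaling makes odds ratios near 2
plausible for an age main effect in this population.  Fitting is Newton
maximum likelihood via statsmodels (`tol = 1e-10`, complete-case rows);
rank-deficient designs and separation raise structured errors naming the
offending columns.

Discrimination is the c-statistic, computed by the Mann–Whitney rank-sum
identity with half credit for ties (equal to the all-pairs definition, which
the tests enumerate directly on small inputs).

Provider aggregation sums observed outcomes, predicted probabilities, and
patient counts per provider.  When the model contains an intercept and is
fitted by ML on the same records, `ΣE = ΣO` exactly (logistic score
equation); the tests assert this to 1e-6.

## Hierarchical volume models

`O_i ~ Poisson(E_i e^{θ_i})`, `θ_i ~ N(α_i, σ²)` with the mean / linear /
cutoff / spline trend families and the vague priors stated in the README.
Volumes are centered and scaled to unit variance internally before knot
placement and fitting — the raw pooled volumes span two orders of magnitude
and a vague `N(0, 10⁶)` slope prior mixes poorly on that scale.  Slopes are
available on both scales (`gamma` standardized, `gamma_raw` per raw volume
unit); the cutoff family's step is scale-free.  The cutoff point is always
user-supplied, never estimated (estimating it invites multimodal
posteriors).  Providers with `E_i ≤ 0` are rejected with an error naming
them.

### Spline basis

The spline family uses the low-rank thin-plate construction: knots `κ_j` at
the `j/(k+1)` sample quantiles (j = 1..k, default k = 5) of standardized
volume, radial basis `Z_K[i,j] = |z_i − κ_j|³`, penalty
`Ω[j,l] = |κ_j − κ_l|³`, and design `w = Z_K Ω^{−1/2}` so the coefficients
`b_j` carry an exchangeable `N(0, σ_b²)` prior.  The cubed-distance penalty
is symmetric but *indefinite* (it is conditionally positive definite only),
so no real symmetric square root exists; `Ω^{±1/2}` are the SVD-based
factors standard for this construction.  They satisfy
`Ω^{1/2} Ω^{−1/2} = I` exactly, which is what the basis reconstruction
needs, and the tests assert those identities rather than a (non-existent)
`Ω^{1/2}Ω^{1/2} = Ω` identity.  The design object stores the knots,
standardization, and factor so the basis can be re-evaluated on a trend
grid.

### Sampler

Posterior simulation is Metropolis-within-Gibbs, fully vectorized over
providers:

* **θ_i** — componentwise *independence* Metropolis–Hastings.  The
  conditional is log-concave (Poisson log-likelihood plus normal prior); its
  mode is found by a few guarded Newton steps from the precision-weighted
  compromise of the likelihood mode `log((O_i + ½)/E_i)` and the prior mean
  `α_i`, and the proposal is Student-t(5) with the Laplace scale.  A
  heavy-tailed proposal is essential, not cosmetic: the conditional's left
  tail decays only as `e^{O θ}`, heavier than any Gaussian, and an
  independence sampler is uniformly ergodic only when the proposal's tails
  dominate the target's — with a Gaussian proposal an over-dispersed start
  can acquire an unbounded importance weight and never move.  Acceptance is
  ≈ 0.93–1.0 and draws are nearly uncorrelated, which keeps the Monte Carlo
  error of DIC small.
* **(α, γ, b)** — one conjugate multivariate-normal draw given θ and the
  precisions.
* **τ, τ_b** — conjugate gamma draws.

Chains start over-dispersed (crude `log O/E` ratios shifted by opposite
offsets per chain).  Defaults follow the published analysis settings — two
chains, 100,000 iterations after 10,000 burn-in, five knots — with thinning
10 to bound memory; every summary is thinning-invariant in expectation.
Given a seed, fits are bit-reproducible (chains draw from spawned
`SeedSequence` streams).  Overflowing likelihood evaluations in extreme tail
states are handled by rejecting the proposal (−∞ log-ratio), never by
clipping a kept draw.

Correctness is established distributionally: the large-count Poisson limit
(200 providers with E = 1000 and true ratio 1.2 recovers a posterior mean in
[1.17, 1.23]), equivalence of the γ-degenerate linear family with the mean
family (Kolmogorov–Smirnov distance of α draws < 0.05), offset invariance
(doubling all E halves the fitted ratio), 95% credible-interval coverage of
true linear and cutoff effects in ≥ 17/20 simulations, and Gelman–Rubin
statistics < 1.1 on all example runs.

A boundary case worth knowing: with a *single* provider the
between-provider variance is unidentified, and under the `Γ(10⁻⁶, 10⁻⁶)`
precision prior the α marginal is so heavy-tailed that its posterior *mean*
on the ratio scale is unstable by design of the prior, not by sampler
defect.  Summaries of α for degenerate provider sets should use quantiles;
the provider-level ratio `e^{θ_i}` remains likelihood-identified and stable.

### Model comparison and outputs

`DIC = D̄ + pD` with `pD = D̄ − D(plug-in)`.  The deviance includes the
`log O_i!` constant.  The default plug-in is the posterior mean of the
`θ_i` — the likelihood's direct parameters, matching the hierarchical-model
convention of BUGS-era software; a trend-focused alternative (plug-in at the
posterior mean of `α_i`) is available via `dic(..., focus="trend")`.
Comparison tables rank families by DIC with ties broken by smaller pD, and
report one decimal.  The Gelman–Rubin statistic is the classic potential
scale reduction factor `√(((n−1)/n · W + B/n)/W)` across chains.  Shrunk
provider rates are posterior summaries of `e^{θ_i}` times the population
mean rate; trend curves evaluate each family's `e^{α(z)}` over a volume
grid per draw, flagging extrapolation beyond the fitted volume range.

## Synthetic registry

The generator emulates the structure of a national hip-fracture register
extract at its published scale: 22,857 patients across 52 hospitals by
default, with a rehabilitation-subset preset (10,384 home-dwelling patients
aged 65+, 272 units, long-term-care level absent).  It provides the study
conditions for every calibration test:

* **Providers** — log-normal volume shares (σ = 1.2 hospitals, 1.0 rehab
  units, spanning roughly two orders of magnitude; illustrative, not an
  inference about any particular country) converted to integer volumes by
  largest-remainder rounding (min 1, sums exactly to the patient count).
  True effects `θ_i = g(z_i) + N(0, provider_sd²)`, default sd 0.1 on the
  log scale (the true between-provider dispersion is unreported anywhere;
  0.1 is a moderate value and the tests vary it), with `g` a configurable
  none/linear/cutoff volume effect.
* **Patients** — covariates drawn independently at the published marginal
  prevalences; age truncated-normal with the published mean (77.4, subset
  81.1) and sd 9 (subset 7) years, a typical dispersion for hip-fracture
  cohorts.  Independence is a simplification: real case-mix is correlated
  (age with care history, comorbidity clustering), so the generator slightly
  understates the confounding structure a real register would show.
* **Outcomes** — per outcome, probability `logit⁻¹(β₀ + x'β + θ_i)` with β
  the log odds ratios of the published risk models and β₀ calibrated by
  root finding so the achieved population rate matches the published
  baseline (18.8% mortality, 43.7% unsuccessful maintainability; subset
  16.5%/46.5%) within 0.002.  Death is drawn first; maintainability is then
  drawn conditionally with probability `(p_M − p_D)/(1 − p_D)` for
  survivors, preserving both marginals while enforcing that death implies
  an unsuccessful episode.  Among unsuccessful patients who die, a
  calibrated fraction receives death as the *first* event so that
  first-event shares match the published mix (32.8/35.3/32.0%; subset
  23.9/36.3/39.9%) while the remaining deaths follow an earlier readmission
  or referral — this is what lets total mortality (18.8%) exceed the
  death-type first-event rate (14.3%).
* **Trajectories** — hospital stay from day 0 (LOS 1 + Poisson(6)),
  optional health-center rehabilitation spell, then a monotone
  non-increasing tail for successful episodes; unsuccessful episodes get
  exactly one backward step at a uniformly drawn event day consistent with
  their assigned type, and patients who die do so within the window.  Home
  spells are not emitted as records, exercising the fill logic of the
  reconstruction.  The indicators recover every generated flag and event
  type exactly (round-trip test).  Real trajectories are messier — transfer
  chains, multiple backward steps, seasonal admission patterns — so passing
  tests establish the *pipeline's* correctness and calibration, not the
  realism of any particular trajectory.

With these defaults the fitted risk models discriminate at c ≈ 0.71
(mortality) and c ≈ 0.63 (maintainability), bracketed by the published 0.74
and 0.65 — evidence that independent covariates at the published marginals
and odds ratios reproduce the reported predictive power to within a few
hundredths, with the residual gap plausibly due to the missing covariate
correlations.

## Problem sizes and numerical settings in tests

The test suite and acceptance script fit at reduced MCMC lengths (2 chains,
4,000–30,000 post-burn-in iterations depending on the check) and moderate
provider counts (40–200); the model defaults keep the full published run
length.  Recovery and model-selection checks use 20 replicates with
thresholds that account for both the statistical behavior of DIC (which
prefers a true smaller model in roughly 70–85% of null replicates, not
always) and residual Monte Carlo error.  Intercept calibration tolerance is
0.002 on the rate scale; logistic convergence is `tol = 1e-10`; the spline
factor requires the penalty's condition number below 1e12.

## Known limitations

* Single provider level; no surgeon or operative-team nesting.
* Poisson likelihood only; no over-dispersion beyond the normal random
  effect.
* Risk adjustment and the volume model are fitted in two stages, so
  uncertainty in β is not propagated into E_i.
* The maintainability indicator is not condition-specific: any backward
  step counts, whatever its clinical reason.
* The generator draws covariates independently and one backward step per
  episode; it is a calibration instrument, not a patient-level simulator of
  Finnish care pathways.
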