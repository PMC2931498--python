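# volprof

Hierarchical Bayesian profiling of the **volume–effectiveness relationship**
in health care: do providers that treat more patients achieve better
outcomes?  The package implements the full register-based workflow for the
hip-fracture setting — episode-of-care reconstruction, patient-level risk
adjustment, and provider-level Bayesian Poisson trend models — together with
a synthetic-registry generator so the whole pipeline can be exercised,
tested, and calibrated without access to confidential register data.

It is written for health-services researchers and biostatisticians who work
with administrative discharge registers and want volume–outcome analyses
that (1) adjust for case-mix at the patient level, (2) model the volume
effect at the provider level, and (3) shrink small-provider estimates
instead of over-interpreting their noise.

## The model

Each patient has case-mix covariates `x_j` (age, sex, fracture type, care
history, ten comorbidity flags) and binary outcomes: four-month mortality,
and *unsuccessful maintainability* — a register-derived indicator that fires
when the patient's daily level-of-care trajectory (1 home, 2 nursing home,
3 health-center ward, 4 hospital, 5 death) takes a backward (intensity-
increasing) step within four months of the fracture.  The first backward
step is classified as a death, a readmission, or a referral to a
higher-level provider.

Risk adjustment is a logistic regression `logit P(Y_j = 1) = x_j'β`,
aggregated per provider `i` into observed events `O_i = Σ Y_j`, expected
events `E_i = Σ logit⁻¹(x_j'β)`, and pooled volume `z_i`.  The provider
model is a Poisson log-linear random-effects model with the expected count
as offset:

    O_i ~ Poisson(E_i · exp(θ_i)),   θ_i ~ N(α_i, σ²)

with four nested trend families

    mean:    α_i = α
    linear:  α_i = α + γ z_i
    cutoff:  α_i = α + γ 1[z_i > c]
    spline:  α_i = α + γ z_i + Σ_j b_j w_ij,   b_j ~ N(0, σ_b²)

where the `w_ij` are a low-rank thin-plate spline basis with knots at sample
quantiles of volume.  Priors are vague: `α, γ ~ N(0, 10⁶)`, precisions
`τ = 1/σ²` and `τ_b = 1/σ_b²` ~ `Γ(10⁻⁶, 10⁻⁶)`.  `exp(α)` is the general
risk-adjusted O/E ratio; `exp(θ_i)` times the mean rate is provider `i`'s
shrunk risk-adjusted rate.  Posteriors are simulated by MCMC (independence
Metropolis–Hastings within Gibbs; see `docs/methods.md`), convergence is
monitored with the Gelman–Rubin statistic, and families are compared by the
deviance information criterion, DIC = D̄ + pD.

## Worked example

```python
import numpy as np
from volprof import synthetic_registry as synth, risk_adjustment as ra
from volprof import volume_models as vm, reporting

cfg = synth.default_config(n_patients=8000, n_providers=40, seed=42)
registry = synth.generate_registry(cfg)
pat = registry.patients

model = ra.fit_risk_model(pat, "unsuccessful_maintainability")
print(f"patients: {len(pat)}, unsuccessful maintainability: "
      f"{100*pat.unsuccessful_maintainability.mean():.1f}%")
print(f"c-statistic: {model.c_statistic:.2f}")
print(f"male OR: {np.exp(model.params['male']):.2f}")

agg = ra.aggregate_providers(pat, model, "provider_id")
mean_rate = agg["O"].sum() / agg["z"].sum()

summaries = {}
for family in ("mean", "linear", "spline"):
    spec = vm.VolumeModelSpec(family=family, iterations=20_000, burn_in=4_000, seed=1)
    samples = vm.fit(spec, agg)
    summaries[family] = vm.summarize(samples, agg, mean_rate=mean_rate)

print(reporting.comparison_report(summaries)[["family", "DIC", "pD", "delta_DIC"]]
      .to_string(index=False))
```

prints

```
patients: 8000, unsuccessful maintainability: 43.9%
c-statistic: 0.62
male OR: 1.45
family   DIC  pD  delta_DIC
linear 259.2 2.7        0.0
  mean 259.3 1.9        0.0
spline 260.4 3.5        1.1
```

Read this as: 43.9% of the simulated patients had a backward step within
four months; the risk model discriminates at c = 0.62; men have 1.45 times
the odds of an unsuccessful episode.  The three trend families fit this
(null-effect) registry almost equally — the linear and mean models are
within 0.1 DIC of each other, so there is no evidence of a volume trend, as
expected for data generated without one.

## Command-line pipeline

The same workflow runs end to end from the shell, writing CSV/JSON
artifacts, comparison tables, volume–rate figures, and a digest manifest:

```sh
volprof all --config run.yaml --seed 20100813 --outdir results/
```

Stages (`simulate`, `indicators`, `adjust`, `fit`, `compare`) can be run
individually; see `volprof --help`.

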