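"""Hierarchical Bayesian Poisson models for the volume-effectiveness trend.

Model
-----
Per provider i with observed events O_i, risk-adjusted expected events E_i
and pooled volume z_i::

    O_i ~ Poisson(E_i * exp(theta_i))          (log E_i acts as an offset)
    theta_i ~ Normal(alpha_i, sigma^2)

with four trend families for alpha_i:

    mean:    alpha_i = alpha
    linear:  alpha_i = alpha + gamma * z_i
    cutoff:  alpha_i = alpha + gamma * 1[z_i > cutpoint]
    spline:  alpha_i = alpha + gamma * z_i + sum_j b_j w_ij,  b_j ~ N(0, sigma_b^2)

exp(alpha) is the general risk-adjusted O/E ratio and sigma^2 the
between-provider variance.  Vague priors: alpha, gamma ~ N(0, 1e6);
precisions tau = 1/sigma^2 and tau_b = 1/sigma_b^2 ~ Gamma(1e-6, 1e-6).

The spline uses the low-rank thin-plate construction: knots at sample
quantiles of the (standardized) volume, radial basis |z - kappa|^3, and
design w = Z_K @ Omega^{-1/2} with Omega_jl = |kappa_j - kappa_l|^3, so the
random coefficients b_j can carry an exchangeable normal prior.

Posterior simulation is Gibbs-within-Metropolis: adaptive random-walk
Metropolis updates for each theta_i (adaptation only during burn-in),
conjugate multivariate-normal updates for (alpha, gamma, b), and conjugate
gamma updates for the precisions.  Volumes are centered and scaled to unit
variance internally; slopes are reported on both scales.

Model comparison uses the deviance information criterion DIC = Dbar + pD
with pD = Dbar - D(posterior mean), focusing on the theta_i by default.
Convergence is monitored with the Gelman-Rubin potential scale reduction
factor across chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "VolumeModelSpec",
    "SplineDesign",
    "PosteriorSamples",
    "FitSummary",
    "VolumeModelError",
    "spline_design",
    "fit",
    "dic",
    "gelman_rubin",
    "shrunk_rates",
    "trend_curve",
    "summarize",
]

FAMILIES = ("mean", "linear", "cutoff", "spline")


class VolumeModelError(ValueError):
    pass


@dataclass(frozen=True)
class VolumeModelSpec:
    """Trend family, priors and MCMC settings.

    Defaults follow the published analysis settings: five spline knots, two
    chains, 100,000 iterations after 10,000 burn-in, vague normal priors on
    alpha and gamma and Gamma(1e-6, 1e-6) priors on the precisions.
    Thinning (default 10) bounds memory at the full run length; posterior
    summaries are thinning-invariant in expectation.
    """

    family: str = "mean"
    knots: int = 5
    cutpoint: float | None = None
    prior_coef_var: float = 1e6
    prior_tau_shape: float = 1e-6
    prior_tau_rate: float = 1e-6
    prior_tau_b_shape: float = 1e-6
    prior_tau_b_rate: float = 1e-6
    chains: int = 2
    iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise VolumeModelError(f"unknown family {self.family!r}; use {FAMILIES}")
        if self.family == "spline" and self.knots < 2:
            raise VolumeModelError("spline family needs knots >= 2")
        if self.family == "cutoff" and self.cutpoint is None:
            raise VolumeModelError("cutoff family needs an explicit cutpoint")
        if self.iterations <= 0 or self.burn_in < 0:
            raise VolumeModelError("iterations must be > 0 and burn_in >= 0")
        if self.thin < 1:
            raise VolumeModelError("thin must be >= 1")


@dataclass(frozen=True)
class SplineDesign:
    """Low-rank thin-plate basis: quantile knots and orthogonalized design.

    `omega_sqrt_inv` maps the raw radial basis |z - kappa|^3 to the design
    whose coefficients carry an exchangeable N(0, sigma_b^2) prior; it is
    stored so the basis can be re-evaluated at new volume grid points.
    """

    knots: np.ndarray          # standardized-scale knot locations, increasing
    w: np.ndarray              # (m, k) design matrix
    center: float
    scale: float
    omega_sqrt: np.ndarray     # (k, k)
    omega_sqrt_inv: np.ndarray # (k, k)

    def basis(self, volumes_raw: np.ndarray) -> np.ndarray:
        """Evaluate the orthogonalized radial basis at raw-scale volumes."""
        z = (np.asarray(volumes_raw, dtype=float) - self.center) / self.scale
        zk = np.abs(z[:, None] - self.knots[None, :]) ** 3
        return zk @ self.omega_sqrt_inv


def _standardize(volumes: np.ndarray) -> tuple[np.ndarray, float, float]:
    z = np.asarray(volumes, dtype=float)
    center = float(z.mean())
    scale = float(z.std())
    if scale == 0.0:
        return z - center, center, 1.0  # constant volumes: centered, unscaled
    return (z - center) / scale, center, scale


def _sym_svd_sqrt(omega: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SVD square root and inverse square root of the knot penalty matrix.

    The cubed-distance penalty is symmetric but indefinite (it is only
    conditionally positive definite), so the factor is taken through the
    singular value decomposition, the standard construction for low-rank
    thin-plate splines.  Satisfies sqrt @ sqrt_inv = I exactly.
    """
    u, s, vt = np.linalg.svd(omega)
    if s.min() <= s.max() * 1e-12:
        raise VolumeModelError(
            f"knot penalty matrix numerically singular "
            f"(condition number {s.max() / max(s.min(), 1e-300):.3g})"
        )
    sqrt = u @ np.diag(np.sqrt(s)) @ vt
    sqrt_inv = vt.T @ np.diag(1.0 / np.sqrt(s)) @ u.T
    return sqrt, sqrt_inv


def spline_design(volumes, k: int = 5) -> SplineDesign:
    """Build the k-knot low-rank thin-plate design from provider volumes.

    Knots sit at the j/(k+1) sample quantiles (j = 1..k) of the
    standardized volumes; the design is w = |z - kappa|^3 @ Omega^{-1/2}.
    """
    z_raw = np.asarray(volumes, dtype=float)
    if np.unique(z_raw).size < k + 2:
        raise VolumeModelError(
            f"need at least {k + 2} distinct volumes for {k} knots; "
            f"got {np.unique(z_raw).size} — reduce k"
        )
    z, center, scale = _standardize(z_raw)
    probs = np.arange(1, k + 1) / (k + 1)
    knots = np.quantile(z, probs)
    if np.any(np.diff(knots) <= 0):
        raise VolumeModelError("knot quantiles not strictly increasing; reduce k")
    omega = np.abs(knots[:, None] - knots[None, :]) ** 3
    omega_sqrt, omega_sqrt_inv = _sym_svd_sqrt(omega)
    zk = np.abs(z[:, None] - knots[None, :]) ** 3
    return SplineDesign(
        knots=knots,
        w=zk @ omega_sqrt_inv,
        center=center,
        scale=scale,
        omega_sqrt=omega_sqrt,
        omega_sqrt_inv=omega_sqrt_inv,
    )


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in MCMC draws, per chain.

    Coefficient draws are stored on the standardized volume scale; use
    `gamma_raw` for the slope per raw volume unit.  `theta` has shape
    (chains, n_draws, m) for m providers.
    """

    spec: VolumeModelSpec
    provider_ids: np.ndarray
    alpha: np.ndarray            # (chains, n)
    gamma: np.ndarray | None     # (chains, n) or None for mean family
    sigma2: np.ndarray           # (chains, n)
    theta: np.ndarray            # (chains, n, m)
    b: np.ndarray | None = None        # (chains, n, k), spline only
    sigma2_b: np.ndarray | None = None # (chains, n), spline only
    design: SplineDesign | None = None
    center: float = 0.0
    scale: float = 1.0
    z_min: float = -np.inf
    z_max: float = np.inf
    accept_rate: np.ndarray | None = None

    @property
    def gamma_raw(self) -> np.ndarray | None:
        """Slope per raw volume unit (cutoff steps are scale-free)."""
        if self.gamma is None:
            return None
        if self.spec.family == "cutoff":
            return self.gamma
        return self.gamma / self.scale

    def flat(self, name: str) -> np.ndarray:
        """All chains pooled, for a scalar parameter name."""
        arr = getattr(self, name)
        if arr is None:
            raise VolumeModelError(f"parameter {name!r} not sampled for this family")
        return arr.reshape(-1, *arr.shape[2:])


@dataclass
class FitSummary:
    family: str
    dic: float
    p_d: float
    d_bar: float
    rhat: dict = field(default_factory=dict)
    params: pd.DataFrame | None = None
    provider_rates: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# sampler

#: degrees of freedom of the Student-t independence proposal for theta
_PROPOSAL_DF = 5.0


def _fixed_design(spec: VolumeModelSpec, z_std: np.ndarray,
                  z_raw: np.ndarray, design: SplineDesign | None) -> np.ndarray:
    if spec.family == "mean":
        return np.ones((len(z_std), 1))
    if spec.family == "linear":
        return np.column_stack([np.ones(len(z_std)), z_std])
    if spec.family == "cutoff":
        return np.column_stack(
            [np.ones(len(z_std)), (z_raw > spec.cutpoint).astype(float)]
        )
    # spline
    assert design is not None
    return np.column_stack([np.ones(len(z_std)), z_std, design.w])


def _run_chain(
    spec: VolumeModelSpec,
    O: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    n_random: int,
    rng: np.random.Generator,
    init_offset: float,
):
    """One MCMC chain; returns thinned post-burn-in draws.

    theta updates are componentwise independence Metropolis-Hastings: the
    conditional density of theta_i given the trend and precision is
    log-concave (Poisson log-likelihood plus normal prior), so a Laplace
    approximation at its mode (found by a few vectorized Newton steps) makes
    an excellent proposal, accepting near 1 and giving almost uncorrelated
    draws.  The proposal is Student-t rather than Gaussian: the conditional's
    left tail decays only as exp(O*theta), heavier than any Gaussian, and an
    independence sampler is uniformly ergodic only when the proposal's tails
    dominate the target's.  (alpha, gamma, b) and the precisions are
    conjugate Gibbs draws.
    """
    m = len(O)
    p = X.shape[1]
    n_fixed = p - n_random

    # over-dispersed start
    theta = np.log((O + 0.5) / E) + init_offset
    eta = np.zeros(p)
    eta[0] = theta.mean() + 0.5 * init_offset
    tau = 1.0 / max(theta.var(), 0.05)
    tau_b = 1.0

    acc = np.zeros(m)

    n_keep = (spec.iterations) // spec.thin
    keep_alpha = np.empty(n_keep)
    keep_gamma = np.empty(n_keep) if p > 1 else None
    keep_sigma2 = np.empty(n_keep)
    keep_theta = np.empty((n_keep, m))
    keep_b = np.empty((n_keep, n_random)) if n_random else None
    keep_sigma2_b = np.empty(n_keep) if n_random else None

    XtX = X.T @ X
    prior_prec_fixed = 1.0 / spec.prior_coef_var
    total_iters = spec.burn_in + spec.iterations
    kept = 0

    lik_mode = np.log((O + 0.5) / E)
    lik_curv = O + 0.5  # Poisson curvature at its mode

    for it in range(total_iters):
        # --- theta: independence MH from the Laplace approximation
        alpha_i = X @ eta
        # Newton for the mode of the concave conditional log-density, started
        # from the precision-weighted compromise of likelihood and prior
        # modes; the start must not depend on the current theta
        # (independence proposal).
        mode = (lik_curv * lik_mode + tau * alpha_i) / (lik_curv + tau)
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(6):
                mu = E * np.exp(mode)
                stepn = (O - mu - tau * (mode - alpha_i)) / (mu + tau)
                stepn = np.where(np.isfinite(stepn), stepn, -1.0)
                mode = mode + np.clip(stepn, -4.0, 4.0)
        sd = 1.0 / np.sqrt(E * np.exp(mode) + tau)
        prop = mode + sd * rng.standard_t(_PROPOSAL_DF, size=m)

        def _logpost(t):
            return O * t - E * np.exp(t) - 0.5 * tau * (t - alpha_i) ** 2

        def _logq(t):  # t-density; per-provider scale terms cancel in the ratio
            u = (t - mode) / sd
            return -0.5 * (_PROPOSAL_DF + 1.0) * np.log1p(u * u / _PROPOSAL_DF)

        with np.errstate(over="ignore", invalid="ignore"):
            logr = _logpost(prop) - _logpost(theta) - _logq(prop) + _logq(theta)
        accept = np.log(rng.random(m)) < np.nan_to_num(logr, nan=-np.inf)
        theta = np.where(accept, prop, theta)
        if it >= spec.burn_in:
            acc += accept

        # --- coefficients: conjugate MVN
        prior_prec = np.full(p, prior_prec_fixed)
        if n_random:
            prior_prec[n_fixed:] = tau_b
        A = tau * XtX + np.diag(prior_prec)
        L = np.linalg.cholesky(A)
        bvec = tau * (X.T @ theta)
        mu = np.linalg.solve(A, bvec)
        eta = mu + np.linalg.solve(L.T, rng.standard_normal(p))

        # --- precision tau
        resid = theta - X @ eta
        tau = rng.gamma(
            spec.prior_tau_shape + 0.5 * m,
            1.0 / (spec.prior_tau_rate + 0.5 * float(resid @ resid)),
        )

        # --- precision tau_b (spline)
        if n_random:
            bcoef = eta[n_fixed:]
            tau_b = rng.gamma(
                spec.prior_tau_b_shape + 0.5 * n_random,
                1.0 / (spec.prior_tau_b_rate + 0.5 * float(bcoef @ bcoef)),
            )

        # --- store
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == spec.thin - 1:
            keep_alpha[kept] = eta[0]
            if keep_gamma is not None:
                keep_gamma[kept] = eta[1] if p > 1 else np.nan
            keep_sigma2[kept] = 1.0 / tau
            keep_theta[kept] = theta
            if n_random:
                keep_b[kept] = eta[n_fixed:]
                keep_sigma2_b[kept] = 1.0 / tau_b
            kept += 1

    acc_rate = acc / spec.iterations
    return (
        keep_alpha[:kept],
        keep_gamma[:kept] if keep_gamma is not None else None,
        keep_sigma2[:kept],
        keep_theta[:kept],
        keep_b[:kept] if keep_b is not None else None,
        keep_sigma2_b[:kept] if keep_sigma2_b is not None else None,
        acc_rate,
    )


def fit(spec: VolumeModelSpec, aggregates: pd.DataFrame) -> PosteriorSamples:
    """Draw from the posterior of the specified volume model.

    `aggregates` must carry columns ``provider_id, O, E, z``.  Providers
    with E <= 0 are rejected (the offset log E is undefined).  Chains start
    from over-dispersed points (crude log O/E ratios shifted by opposite
    offsets).  Fully deterministic given ``spec.seed``.
    """
    agg = aggregates.reset_index(drop=True)
    for col in ("provider_id", "O", "E", "z"):
        if col not in agg.columns:
            raise VolumeModelError(f"aggregates missing column {col!r}")
    O = agg["O"].to_numpy(dtype=float)
    E = agg["E"].to_numpy(dtype=float)
    z_raw = agg["z"].to_numpy(dtype=float)
    if np.any(E <= 0):
        bad = agg.loc[E <= 0, "provider_id"].tolist()
        raise VolumeModelError(f"providers with E <= 0 cannot be fitted: {bad}")
    if not np.all(np.isfinite(z_raw)):
        raise VolumeModelError("non-finite volumes")

    z_std, center, scale = _standardize(z_raw)
    design = spline_design(z_raw, spec.knots) if spec.family == "spline" else None
    X = _fixed_design(spec, z_std, z_raw, design)
    n_random = spec.knots if spec.family == "spline" else 0

    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(spec.chains)
    offsets = np.linspace(-1.0, 1.0, spec.chains) if spec.chains > 1 else [0.0]

    per_chain = [
        _run_chain(spec, O, E, X, n_random, np.random.default_rng(s), off)
        for s, off in zip(child_seeds, offsets)
    ]
    alpha = np.stack([c[0] for c in per_chain])
    gamma = (
        np.stack([c[1] for c in per_chain]) if per_chain[0][1] is not None else None
    )
    sigma2 = np.stack([c[2] for c in per_chain])
    theta = np.stack([c[3] for c in per_chain])
    b = np.stack([c[4] for c in per_chain]) if n_random else None
    sigma2_b = np.stack([c[5] for c in per_chain]) if n_random else None
    accept = np.stack([c[6] for c in per_chain])

    return PosteriorSamples(
        spec=spec,
        provider_ids=agg["provider_id"].to_numpy(),
        alpha=alpha,
        gamma=gamma,
        sigma2=sigma2,
        theta=theta,
        b=b,
        sigma2_b=sigma2_b,
        design=design,
        center=center,
        scale=scale,
        z_min=float(z_raw.min()),
        z_max=float(z_raw.max()),
        accept_rate=accept,
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries

def _poisson_deviance(theta: np.ndarray, O: np.ndarray, E: np.ndarray) -> np.ndarray:
    """-2 log-likelihood, log O! constant included; theta may be (n, m) or (m,)."""
    mu = E * np.exp(theta)
    ll = O * np.log(mu) - mu - gammaln(O + 1.0)
    return -2.0 * ll.sum(axis=-1)


def dic(
    samples: PosteriorSamples,
    aggregates: pd.DataFrame,
    focus: str = "theta",
) -> tuple[float, float, float]:
    """(DIC, pD, Dbar) with pD = Dbar - D(plug-in).

    focus="theta" (default) plugs in the posterior mean of the theta_i, the
    likelihood's direct parameters — the convention of hierarchical-model
    DIC as reported by BUGS-family samplers.  focus="trend" plugs in the
    posterior mean of alpha_i (the trend line), charging the provider
    effects to the likelihood instead.
    """
    agg = aggregates.reset_index(drop=True)
    O = agg["O"].to_numpy(dtype=float)
    E = agg["E"].to_numpy(dtype=float)
    theta = samples.theta.reshape(-1, samples.theta.shape[-1])
    if theta.size == 0:
        raise VolumeModelError("empty posterior sample")
    devs = _poisson_deviance(theta, O, E)
    d_bar = float(devs.mean())
    if focus == "theta":
        plug = theta.mean(axis=0)
    elif focus == "trend":
        z_std = (agg["z"].to_numpy(dtype=float) - samples.center) / samples.scale
        plug = _trend_alpha_draws(samples, z_std, agg["z"].to_numpy(float)).mean(axis=0)
    else:
        raise VolumeModelError(f"unknown DIC focus {focus!r}")
    d_hat = float(_poisson_deviance(plug, O, E))
    p_d = d_bar - d_hat
    return d_bar + p_d, p_d, d_bar


def gelman_rubin(samples: PosteriorSamples, parameter: str) -> float:
    """Potential scale reduction factor sqrt(((n-1)/n * W + B/n) / W)."""
    arr = getattr(samples, parameter, None)
    if arr is None:
        raise VolumeModelError(f"parameter {parameter!r} not available")
    if arr.ndim != 2:
        raise VolumeModelError("gelman_rubin expects a scalar parameter (chains, n)")
    c, n = arr.shape
    if c < 2:
        raise VolumeModelError("Gelman-Rubin requires >= 2 chains")
    if n < 10:
        raise VolumeModelError("Gelman-Rubin requires >= 10 draws per chain")
    chain_means = arr.mean(axis=1)
    W = float(arr.var(axis=1, ddof=1).mean())
    B = float(n * chain_means.var(ddof=1))
    if W == 0.0:
        return 1.0
    return math.sqrt(((n - 1) / n * W + B / n) / W)


def shrunk_rates(samples: PosteriorSamples, mean_rate: float) -> pd.DataFrame:
    """Posterior risk-adjusted rates exp(theta_i) * mean_rate per provider."""
    if not (0.0 < mean_rate < 1.0):
        raise VolumeModelError("mean_rate must lie in (0, 1)")
    ratio = np.exp(samples.theta.reshape(-1, samples.theta.shape[-1]))
    rates = ratio * mean_rate
    return pd.DataFrame(
        {
            "provider_id": samples.provider_ids,
            "rate_mean": rates.mean(axis=0),
            "rate_lo95": np.quantile(rates, 0.025, axis=0),
            "rate_hi95": np.quantile(rates, 0.975, axis=0),
        }
    )


def _trend_alpha_draws(
    samples: PosteriorSamples, z_std: np.ndarray, z_raw: np.ndarray
) -> np.ndarray:
    """alpha(z) per pooled draw, shape (n_draws, len(grid)); standardized-scale input."""
    spec = samples.spec
    alpha = samples.flat("alpha")
    if spec.family == "mean":
        return alpha[:, None] * np.ones(len(z_std))[None, :]
    gamma = samples.flat("gamma")
    if spec.family == "linear":
        return alpha[:, None] + gamma[:, None] * z_std[None, :]
    if spec.family == "cutoff":
        ind = (z_raw > spec.cutpoint).astype(float)
        return alpha[:, None] + gamma[:, None] * ind[None, :]
    # spline
    if samples.design is None:
        raise VolumeModelError("spline trend curve requires the stored SplineDesign")
    W = samples.design.basis(z_raw)
    b = samples.flat("b")
    return alpha[:, None] + gamma[:, None] * z_std[None, :] + b @ W.T


def trend_curve(
    samples: PosteriorSamples,
    volume_grid,
    design: SplineDesign | None = None,
) -> pd.DataFrame:
    """Posterior mean and 95% band of exp(alpha(z)) over a raw-volume grid.

    Grid points outside the fitted volume range are flagged in the
    `extrapolated` column.
    """
    grid = np.asarray(volume_grid, dtype=float)
    if design is not None and samples.design is None:
        samples = PosteriorSamples(**{**samples.__dict__, "design": design})
    if samples.spec.family == "spline" and samples.design is None:
        raise VolumeModelError("spline family requires a SplineDesign")
    z_std = (grid - samples.center) / samples.scale
    draws = np.exp(_trend_alpha_draws(samples, z_std, grid))
    return pd.DataFrame(
        {
            "volume": grid,
            "trend_mean": draws.mean(axis=0),
            "trend_lo95": np.quantile(draws, 0.025, axis=0),
            "trend_hi95": np.quantile(draws, 0.975, axis=0),
            "extrapolated": (grid < samples.z_min) | (grid > samples.z_max),
        }
    )


def summarize(
    samples: PosteriorSamples,
    aggregates: pd.DataFrame,
    mean_rate: float | None = None,
) -> FitSummary:
    """DIC, convergence diagnostics and parameter/provider summaries in one object."""
    dic_val, p_d, d_bar = dic(samples, aggregates)
    rhat = {"alpha": gelman_rubin(samples, "alpha"),
            "sigma2": gelman_rubin(samples, "sigma2")}
    if samples.gamma is not None:
        rhat["gamma"] = gelman_rubin(samples, "gamma")
    rows = []
    for name in ("alpha", "gamma", "sigma2", "sigma2_b"):
        arr = getattr(samples, name, None)
        if arr is None:
            continue
        flat = arr.reshape(-1)
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "q2.5": float(np.quantile(flat, 0.025)),
                "q97.5": float(np.quantile(flat, 0.975)),
            }
        )
    params = pd.DataFrame(rows)
    provider_rates = (
        shrunk_rates(samples, mean_rate) if mean_rate is not None else None
    )
    return FitSummary(
        family=samples.spec.family,
        dic=dic_val,
        p_d=p_d,
        d_bar=d_bar,
        rhat=rhat,
        params=params,
        provider_rates=provider_rates,
    )
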