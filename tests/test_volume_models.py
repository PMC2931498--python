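"""Hierarchical Poisson volume models: design construction, sampler behavior
in analytic limits, DIC, convergence diagnostics, and trend curves."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from volprof import volume_models as vm

from conftest import simulate_aggregates


def quick_spec(**kw):
    base = dict(family="mean", iterations=4000, burn_in=800, thin=4, seed=0)
    base.update(kw)
    return vm.VolumeModelSpec(**base)


def make_samples(alpha, theta, spec=None, gamma=None, sigma2=None, b=None,
                 design=None, center=0.0, scale=1.0, provider_ids=None):
    alpha = np.asarray(alpha, float)
    theta = np.asarray(theta, float)
    if sigma2 is None:
        sigma2 = np.full(alpha.shape, 0.01)
    if provider_ids is None:
        provider_ids = np.array([f"P{i}" for i in range(theta.shape[-1])])
    return vm.PosteriorSamples(
        spec=spec or quick_spec(),
        provider_ids=provider_ids,
        alpha=alpha,
        gamma=None if gamma is None else np.asarray(gamma, float),
        sigma2=np.asarray(sigma2, float),
        theta=theta,
        b=None if b is None else np.asarray(b, float),
        design=design,
        center=center,
        scale=scale,
    )


# ---------------------------------------------------------------- spec/design

def test_spec_validation():
    with pytest.raises(vm.VolumeModelError, match="unknown family"):
        vm.VolumeModelSpec(family="quadratic")
    with pytest.raises(vm.VolumeModelError, match="knots"):
        vm.VolumeModelSpec(family="spline", knots=1)
    with pytest.raises(vm.VolumeModelError, match="cutpoint"):
        vm.VolumeModelSpec(family="cutoff")
    with pytest.raises(vm.VolumeModelError, match="thin"):
        vm.VolumeModelSpec(thin=0)


def test_spline_design_shape_and_knots():
    rng = np.random.default_rng(0)
    vols = rng.lognormal(3.0, 1.0, 272)
    d = vm.spline_design(vols, k=5)
    assert d.w.shape == (272, 5)
    assert np.all(np.diff(d.knots) > 0)


def test_spline_design_factor_identities():
    rng = np.random.default_rng(1)
    d = vm.spline_design(rng.lognormal(3, 1, 100), k=5)
    omega = np.abs(d.knots[:, None] - d.knots[None, :]) ** 3
    # the factor pair inverts exactly and reproduces the raw radial basis
    np.testing.assert_allclose(d.omega_sqrt @ d.omega_sqrt_inv, np.eye(5), atol=1e-8)
    z = (rng.lognormal(3, 1, 40) - d.center) / d.scale
    zk = np.abs(z[:, None] - d.knots[None, :]) ** 3
    np.testing.assert_allclose((zk @ d.omega_sqrt_inv) @ d.omega_sqrt, zk, atol=1e-8)
    # and the factorization is consistent with the (indefinite) penalty
    np.testing.assert_allclose(
        d.omega_sqrt @ d.omega_sqrt_inv @ omega, omega, atol=1e-8
    )


def test_spline_design_degenerate_volumes_rejected():
    with pytest.raises(vm.VolumeModelError, match="distinct"):
        vm.spline_design(np.full(50, 7.0), k=5)


# -------------------------------------------------------------------- sampler

def test_single_provider_o_equals_e_centers_on_one():
    # with one provider the between-provider variance is unidentified and the
    # alpha posterior is heavy-tailed under the vague precision prior, so the
    # posterior is summarized by its median; the provider's own O/E ratio
    # exp(theta) is likelihood-identified and its mean is stable
    agg = pd.DataFrame({"provider_id": ["A"], "O": [50], "E": [50.0], "z": [50.0]})
    s = vm.fit(quick_spec(), agg)
    assert 0.8 <= float(np.median(np.exp(s.flat("alpha")))) <= 1.25
    assert 0.8 <= float(np.exp(s.flat("theta")).mean()) <= 1.25


def test_seed_determinism_and_sensitivity():
    rng = np.random.default_rng(11)
    agg, _ = simulate_aggregates(rng, m=30)
    s1 = vm.fit(quick_spec(seed=5), agg)
    s2 = vm.fit(quick_spec(seed=5), agg)
    np.testing.assert_array_equal(s1.alpha, s2.alpha)
    np.testing.assert_array_equal(s1.theta, s2.theta)
    s3 = vm.fit(quick_spec(seed=6), agg)
    assert not np.array_equal(s1.alpha, s3.alpha)


def test_nonpositive_expected_events_rejected():
    agg = pd.DataFrame(
        {"provider_id": ["A", "B"], "O": [1, 2], "E": [0.0, 3.0], "z": [5.0, 9.0]}
    )
    with pytest.raises(vm.VolumeModelError, match="E <= 0"):
        vm.fit(quick_spec(), agg)


def test_offset_invariance_doubling_e_halves_ratio():
    rng = np.random.default_rng(3)
    agg, _ = simulate_aggregates(rng, m=60, e_range=(50, 150), provider_sd=0.05)
    s1 = vm.fit(quick_spec(seed=1), agg)
    agg2 = agg.assign(E=2.0 * agg["E"])
    s2 = vm.fit(quick_spec(seed=1), agg2)
    r1 = float(np.exp(s1.flat("alpha")).mean())
    r2 = float(np.exp(s2.flat("alpha")).mean())
    assert r2 == pytest.approx(r1 / 2.0, rel=0.03)


def test_posterior_draw_shapes_and_positivity():
    rng = np.random.default_rng(4)
    agg, _ = simulate_aggregates(rng, m=25)
    spec = quick_spec(family="spline", knots=4, iterations=2000, burn_in=400, thin=2)
    s = vm.fit(spec, agg)
    n = spec.iterations // spec.thin
    assert s.alpha.shape == (2, n)
    assert s.theta.shape == (2, n, 25)
    assert s.b.shape == (2, n, 4)
    assert np.all(s.sigma2 > 0) and np.all(s.sigma2_b > 0)


# ------------------------------------------------------------------------ DIC

def test_dic_degenerate_posterior_has_zero_pd():
    theta0 = np.array([0.1, -0.2, 0.05])
    O = np.array([12, 5, 9])
    E = np.array([10.0, 7.0, 8.0])
    agg = pd.DataFrame({"provider_id": list("ABC"), "O": O, "E": E, "z": E})
    theta = np.tile(theta0, (2, 50, 1))
    s = make_samples(alpha=np.zeros((2, 50)), theta=theta)
    d, p_d, d_bar = vm.dic(s, agg)
    expected = -2 * poisson.logpmf(O, E * np.exp(theta0)).sum()
    assert p_d == pytest.approx(0.0, abs=1e-9)
    assert d == pytest.approx(expected, abs=1e-9)
    assert d_bar == pytest.approx(expected, abs=1e-9)


def test_dic_effective_parameters_bounded_on_null_data():
    rng = np.random.default_rng(6)
    agg, _ = simulate_aggregates(rng, m=40, provider_sd=0.05)
    s = vm.fit(quick_spec(seed=2), agg)
    _, p_d, _ = vm.dic(s, agg)
    assert 1.0 <= p_d <= 41.0


# --------------------------------------------------------------- diagnostics

def test_gelman_rubin_identical_chains():
    n = 500
    draws = np.random.default_rng(0).normal(size=n)
    s = make_samples(alpha=np.stack([draws, draws]), theta=np.zeros((2, n, 1)))
    assert vm.gelman_rubin(s, "alpha") == pytest.approx(np.sqrt((n - 1) / n))


def test_gelman_rubin_same_distribution_vs_disjoint():
    rng = np.random.default_rng(1)
    n = 2000
    same = np.stack([rng.normal(size=n), rng.normal(size=n)])
    s = make_samples(alpha=same, theta=np.zeros((2, n, 1)))
    assert vm.gelman_rubin(s, "alpha") < 1.05
    apart = np.stack([rng.normal(-10, 1, n), rng.normal(10, 1, n)])
    s2 = make_samples(alpha=apart, theta=np.zeros((2, n, 1)))
    assert vm.gelman_rubin(s2, "alpha") > 1.5


def test_gelman_rubin_requires_two_chains():
    s = make_samples(alpha=np.zeros((1, 100)), theta=np.zeros((1, 100, 1)))
    with pytest.raises(vm.VolumeModelError, match="2 chains"):
        vm.gelman_rubin(s, "alpha")


# --------------------------------------------------------------- shrunk rates

def test_shrunk_rates_near_mean_rate_when_o_equals_e():
    agg = pd.DataFrame(
        {
            "provider_id": [f"P{i}" for i in range(20)],
            "O": [100] * 20,
            "E": [100.0] * 20,
            "z": np.linspace(10, 200, 20),
        }
    )
    s = vm.fit(quick_spec(seed=9), agg)
    rates = vm.shrunk_rates(s, mean_rate=0.2)
    assert np.all(np.abs(rates["rate_mean"] - 0.2) < 0.02)


def test_small_provider_rate_is_shrunk_toward_global():
    rng = np.random.default_rng(12)
    agg, _ = simulate_aggregates(rng, m=40, e_range=(50, 100), provider_sd=0.05)
    small = pd.DataFrame(
        {"provider_id": ["tiny"], "O": [3], "E": [0.5], "z": [1.0]}
    )
    agg = pd.concat([agg, small], ignore_index=True)
    s = vm.fit(quick_spec(seed=3), agg)
    mean_rate = 0.2
    rates = vm.shrunk_rates(s, mean_rate).set_index("provider_id")
    crude = 3 / 0.5 * mean_rate
    global_rate = float(np.exp(s.flat("alpha")).mean()) * mean_rate
    tiny = rates.loc["tiny", "rate_mean"]
    assert global_rate < tiny < crude


def test_shrunk_rates_invariant_to_provider_relabeling():
    rng = np.random.default_rng(13)
    agg, _ = simulate_aggregates(rng, m=15)
    s = vm.fit(quick_spec(seed=4), agg)
    relabeled = agg.assign(provider_id=[f"X{i}" for i in range(15)])
    s2 = vm.fit(quick_spec(seed=4), relabeled)
    r1 = vm.shrunk_rates(s, 0.2)["rate_mean"].to_numpy()
    r2 = vm.shrunk_rates(s2, 0.2)["rate_mean"].to_numpy()
    np.testing.assert_array_equal(r1, r2)
    with pytest.raises(vm.VolumeModelError, match="mean_rate"):
        vm.shrunk_rates(s, 1.2)


# --------------------------------------------------------------- trend curves

def test_mean_family_trend_is_flat():
    n = 400
    rng = np.random.default_rng(14)
    alpha = rng.normal(0.1, 0.02, size=(2, n))
    s = make_samples(alpha=alpha, theta=np.zeros((2, n, 3)))
    s.z_min, s.z_max = 0.0, 100.0
    curve = vm.trend_curve(s, [10.0, 50.0, 90.0])
    expected = float(np.exp(alpha.reshape(-1)).mean())
    np.testing.assert_allclose(curve["trend_mean"], expected, rtol=1e-12)
    assert not curve["extrapolated"].any()
    curve2 = vm.trend_curve(s, [150.0])
    assert curve2["extrapolated"].all()


def test_spline_with_zero_coefficients_matches_linear_trend():
    rng = np.random.default_rng(15)
    vols = rng.lognormal(3, 1, 60)
    design = vm.spline_design(vols, k=5)
    n = 300
    alpha = rng.normal(0.0, 0.05, (2, n))
    gamma = rng.normal(0.1, 0.05, (2, n))
    center, scale = design.center, design.scale
    lin = make_samples(
        alpha=alpha, gamma=gamma, theta=np.zeros((2, n, 60)),
        spec=quick_spec(family="linear"), center=center, scale=scale,
    )
    spl = make_samples(
        alpha=alpha, gamma=gamma, theta=np.zeros((2, n, 60)),
        b=np.zeros((2, n, 5)), design=design,
        spec=quick_spec(family="spline"), center=center, scale=scale,
    )
    grid = np.linspace(vols.min(), vols.max(), 25)
    c_lin = vm.trend_curve(lin, grid)
    c_spl = vm.trend_curve(spl, grid)
    np.testing.assert_allclose(
        c_lin["trend_mean"], c_spl["trend_mean"], rtol=1e-10
    )


def test_spline_trend_requires_design():
    s = make_samples(
        alpha=np.zeros((2, 50)), gamma=np.zeros((2, 50)),
        theta=np.zeros((2, 50, 4)), b=np.zeros((2, 50, 5)),
        spec=quick_spec(family="spline"),
    )
    with pytest.raises(vm.VolumeModelError, match="SplineDesign"):
        vm.trend_curve(s, [1.0, 2.0])
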