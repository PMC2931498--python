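"""Shared fixtures: small synthetic registries and aggregate-level simulators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from volprof import synthetic_registry as synth


@pytest.fixture(scope="session")
def small_registry():
    """A 4,000-patient, 30-hospital registry (fast; session-cached)."""
    cfg = synth.default_config(n_patients=4_000, n_providers=30, seed=101)
    return synth.generate_registry(cfg)


@pytest.fixture(scope="session")
def full_registry():
    """Full-scale registry at the default study conditions (session-cached)."""
    return synth.generate_registry(synth.default_config(seed=7))


def simulate_aggregates(
    rng: np.random.Generator,
    m: int = 50,
    gamma: float = 0.0,
    cut_step: float | None = None,
    cutpoint: float | None = None,
    provider_sd: float = 0.1,
    e_range: tuple[float, float] = (20.0, 100.0),
) -> tuple[pd.DataFrame, dict]:
    """Provider aggregates drawn directly from the Poisson volume model.

    The linear effect acts per standardized volume unit; a cutoff effect adds
    `cut_step` above `cutpoint` on the raw scale.  Returns the aggregate
    table and the truth (gamma on the scale the fitter reports).
    """
    z = rng.lognormal(4.0, 1.0, m)
    zs = (z - z.mean()) / z.std()
    theta = gamma * zs + provider_sd * rng.standard_normal(m)
    if cut_step is not None:
        theta = theta + cut_step * (z > cutpoint)
    E = rng.uniform(*e_range, size=m)
    O = rng.poisson(E * np.exp(theta))
    agg = pd.DataFrame(
        {"provider_id": [f"P{i:03d}" for i in range(m)], "O": O, "E": E, "z": z}
    )
    return agg, {"gamma": gamma, "cut_step": cut_step, "sd": provider_sd}
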