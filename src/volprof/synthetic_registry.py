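"""Synthetic hip-fracture registry generator.

Produces a full synthetic registry — providers with volumes and true
log-rate effects, patients with case-mix covariates, binary outcomes, and
daily level-of-care interval records — with the statistical structure of a
national hip-fracture discharge-register extract: configurable covariate
marginals and odds ratios, calibrated baseline outcome rates, a configurable
true volume-effect curve on the provider log-rate scale, and care
trajectories whose first backward-step events follow configured type shares.

Outcome coherence: death within the follow-up window is itself a backward
step, so mortality = 1 forces unsuccessful maintainability.  Death is drawn
first from its own risk model; maintainability is then drawn conditionally
with probability (p_M - p_D) / (1 - p_D) for survivors, which preserves both
configured marginal rates.  Among unsuccessful patients who die, a
calibrated fraction has death as the *first* event; the rest suffer an
earlier readmission or referral and die later in the window, so first-event
type shares and the overall mortality rate can both match their targets.

Covariates are generated independently (only marginals are specified);
baseline logits are calibrated by root finding so the achieved population
rates match the configured baselines within 0.002.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .episodes import DEATH_LEVEL

__all__ = [
    "VolumeEffect",
    "GeneratorConfig",
    "Registry",
    "default_config",
    "rehab_config",
    "generate_providers",
    "generate_patients",
    "generate_outcomes",
    "generate_trajectories",
    "generate_registry",
]


@dataclass(frozen=True)
class VolumeEffect:
    """True provider-volume effect on the log-rate scale.

    linear: gamma per standardized volume unit; cutoff: `step` added to the
    log rate for providers with raw volume above `cutpoint`.
    """

    family: str = "none"  # none | linear | cutoff
    gamma: float = 0.0
    cutpoint: float | None = None
    step: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("none", "linear", "cutoff"):
            raise ValueError(f"unknown volume effect family {self.family!r}")
        if self.family == "cutoff" and self.cutpoint is None:
            raise ValueError("cutoff volume effect needs a cutpoint")


# Case-mix marginals of a national hip-fracture cohort (whole registry).
_MARGINALS_ALL = {
    "male": 0.297,
    "fracture": {"neck": 0.632, "trochanteric": 0.300, "subtrochanteric": 0.068},
    "care_history": {"long_term": 0.178, "recent_short_term": 0.236, "no_recent": 0.586},
    "comorbidity": {
        "cancer": 0.113,
        "diabetes": 0.101,
        "parkinson": 0.029,
        "cardiovascular": 0.342,
        "cerebrovascular": 0.189,
        "peripheral_vascular": 0.045,
        "chronic_pulmonary": 0.085,
        "peptic_ulcer": 0.037,
        "renal": 0.009,
        "rheumatologic": 0.053,
    },
    "age_mean": 77.4,
    "age_sd": 9.0,
}

# Odds ratios per outcome (whole registry); age is per decade.
_OR_MORTALITY_ALL = {
    "age_per10": 1.91,
    "male": 2.11,
    "fracture_trochanteric": 1.01,
    "fracture_subtrochanteric": 1.12,
    "care_long_term": 1.02,
    "care_no_recent": 0.46,
    "cancer": 1.68,
    "diabetes": 1.33,
    "parkinson": 1.14,
    "cardiovascular": 1.50,
    "cerebrovascular": 1.14,
    "peripheral_vascular": 1.20,
    "chronic_pulmonary": 1.24,
    "peptic_ulcer": 1.08,
    "renal": 2.05,
    "rheumatologic": 0.96,
}
_OR_MAINTAINABILITY_ALL = {
    "age_per10": 1.21,
    "male": 1.50,
    "fracture_trochanteric": 0.93,
    "fracture_subtrochanteric": 1.03,
    "care_long_term": 0.60,
    "care_no_recent": 0.54,
    "cancer": 1.46,
    "diabetes": 1.40,
    "parkinson": 1.30,
    "cardiovascular": 1.38,
    "cerebrovascular": 1.15,
    "peripheral_vascular": 1.28,
    "chronic_pulmonary": 1.30,
    "peptic_ulcer": 1.25,
    "renal": 1.98,
    "rheumatologic": 1.21,
}

# Home-dwelling 65+ subset transferred to rehabilitation units.
_MARGINALS_REHAB = {
    "male": 0.246,
    "fracture": {"neck": 0.621, "trochanteric": 0.313, "subtrochanteric": 0.066},
    "care_history": {"long_term": 0.0, "recent_short_term": 0.133, "no_recent": 0.867},
    "comorbidity": {
        "cancer": 0.122,
        "diabetes": 0.106,
        "parkinson": 0.030,
        "cardiovascular": 0.369,
        "cerebrovascular": 0.182,
        "peripheral_vascular": 0.049,
        "chronic_pulmonary": 0.093,
        "peptic_ulcer": 0.040,
        "renal": 0.009,
        "rheumatologic": 0.061,
    },
    "age_mean": 81.1,
    "age_sd": 7.0,
}
_OR_MORTALITY_REHAB = {
    "age_per10": 2.04,
    "male": 1.97,
    "fracture_trochanteric": 1.00,
    "fracture_subtrochanteric": 1.07,
    "care_no_recent": 0.40,
    "cancer": 1.77,
    "diabetes": 1.25,
    "parkinson": 1.22,
    "cardiovascular": 1.32,
    "cerebrovascular": 1.24,
    "peripheral_vascular": 1.56,
    "chronic_pulmonary": 1.27,
    "peptic_ulcer": 1.17,
    "renal": 1.83,
    "rheumatologic": 0.99,
}
_OR_MAINTAINABILITY_REHAB = {
    "age_per10": 1.27,
    "male": 1.52,
    "fracture_trochanteric": 0.89,
    "fracture_subtrochanteric": 0.90,
    "care_no_recent": 0.58,
    "cancer": 1.47,
    "diabetes": 1.40,
    "parkinson": 1.55,
    "cardiovascular": 1.28,
    "cerebrovascular": 1.22,
    "peripheral_vascular": 1.55,
    "chronic_pulmonary": 1.32,
    "peptic_ulcer": 1.28,
    "renal": 1.84,
    "rheumatologic": 1.34,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic registry; defaults emulate the whole-cohort extract."""

    n_patients: int = 22_857
    n_providers: int = 52
    marginals: Mapping = field(default_factory=lambda: dict(_MARGINALS_ALL))
    or_mortality: Mapping[str, float] = field(
        default_factory=lambda: dict(_OR_MORTALITY_ALL)
    )
    or_maintainability: Mapping[str, float] = field(
        default_factory=lambda: dict(_OR_MAINTAINABILITY_ALL)
    )
    baseline_mortality: float = 0.188
    baseline_maintainability: float = 0.437
    event_shares: Mapping[str, float] = field(
        default_factory=lambda: {"death": 0.328, "readmission": 0.353, "referral": 0.320}
    )
    volume_effect: VolumeEffect = field(default_factory=VolumeEffect)
    provider_sd: float = 0.1
    volume_lognorm_sigma: float = 1.2
    window_days: int = 120
    horizon_days: int = 181
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_mortality < 1.0):
            raise ValueError("baseline_mortality must lie in (0, 1)")
        if not (0.0 < self.baseline_maintainability < 1.0):
            raise ValueError("baseline_maintainability must lie in (0, 1)")
        if self.n_patients < self.n_providers:
            raise ValueError("need at least one patient per provider")
        if self.horizon_days < self.window_days + 1:
            raise ValueError("horizon_days must exceed window_days")


def default_config(**overrides) -> GeneratorConfig:
    """Whole-registry preset: 22,857 patients, 52 hospitals."""
    return GeneratorConfig(**overrides)


def rehab_config(**overrides) -> GeneratorConfig:
    """Rehabilitation-unit subset preset: 10,384 home-dwelling 65+ patients, 272 units."""
    base = dict(
        n_patients=10_384,
        n_providers=272,
        marginals=dict(_MARGINALS_REHAB),
        or_mortality=dict(_OR_MORTALITY_REHAB),
        or_maintainability=dict(_OR_MAINTAINABILITY_REHAB),
        baseline_mortality=0.165,
        baseline_maintainability=0.465,
        event_shares={"death": 0.239, "readmission": 0.363, "referral": 0.399},
        volume_lognorm_sigma=1.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass
class Registry:
    """Generated registry tables plus the manifest of true parameters."""

    providers: pd.DataFrame
    patients: pd.DataFrame
    intervals: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# providers

def generate_providers(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Provider table: right-skewed volumes summing to n_patients, true theta_i.

    Volumes are log-normal shares converted to integer counts by largest-
    remainder rounding with a minimum of one patient per provider.  The true
    provider effect is theta_i = g(z_i) + Normal(0, provider_sd^2) with g
    given by the configured volume effect (linear effects act on the
    standardized volume).
    """
    m = config.n_providers
    raw = rng.lognormal(mean=0.0, sigma=config.volume_lognorm_sigma, size=m)
    shares = raw / raw.sum()
    target = shares * config.n_patients
    vols = np.floor(target).astype(int)
    vols = np.maximum(vols, 1)
    deficit = config.n_patients - vols.sum()
    if deficit < 0:
        # minimum-1 clamp overshot: trim from the largest providers
        order = np.argsort(-vols)
        for idx in order:
            take = min(vols[idx] - 1, -deficit)
            vols[idx] -= take
            deficit += take
            if deficit == 0:
                break
        if deficit != 0:
            raise ValueError("infeasible volume allocation")
    elif deficit > 0:
        frac = target - np.floor(target)
        order = np.argsort(-frac)
        vols[order[:deficit]] += 1
    assert vols.sum() == config.n_patients and vols.min() >= 1

    z = vols.astype(float)
    eff = config.volume_effect
    if eff.family == "linear":
        sd = z.std() if z.std() > 0 else 1.0
        g = eff.gamma * (z - z.mean()) / sd
    elif eff.family == "cutoff":
        g = eff.step * (z > eff.cutpoint).astype(float)
    else:
        g = np.zeros(m)
    theta = g + config.provider_sd * rng.standard_normal(m)
    return pd.DataFrame(
        {
            "provider_id": [f"H{i + 1:03d}" for i in range(m)],
            "volume": vols,
            "theta_true": theta,
        }
    )


# ---------------------------------------------------------------------------
# patients

def generate_patients(
    config: GeneratorConfig, providers: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Patient covariate table; providers assigned by volume."""
    n = config.n_patients
    marg = config.marginals
    provider_id = np.repeat(
        providers["provider_id"].to_numpy(), providers["volume"].to_numpy()
    )
    rng.shuffle(provider_id)

    lo, hi = 50.0, 102.0
    age = rng.normal(marg["age_mean"], marg["age_sd"], size=n)
    while True:  # truncate by redraw
        bad = (age < lo) | (age > hi)
        if not bad.any():
            break
        age[bad] = rng.normal(marg["age_mean"], marg["age_sd"], size=int(bad.sum()))

    fr = marg["fracture"]
    fracture = rng.choice(
        list(fr.keys()), size=n, p=np.array(list(fr.values())) / sum(fr.values())
    )
    ch = marg["care_history"]
    care = rng.choice(
        list(ch.keys()), size=n, p=np.array(list(ch.values())) / sum(ch.values())
    )
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i + 1:06d}" for i in range(n)],
            "provider_id": provider_id,
            "age": age,
            "sex": rng.random(n) < marg["male"],
            "fracture_type": fracture,
            "care_history": care,
        }
    )
    df["sex"] = df["sex"].astype(int)
    for name, prev in marg["comorbidity"].items():
        df[name] = (rng.random(n) < prev).astype(int)
    return df


def _linear_predictor(
    df: pd.DataFrame, ors: Mapping[str, float], age_center: float
) -> np.ndarray:
    """Case-mix log-odds contribution (age centered for calibration stability)."""
    lp = np.log(ors["age_per10"]) * (df["age"].to_numpy() - age_center) / 10.0
    lp = lp + np.log(ors["male"]) * df["sex"].to_numpy()
    for lv in ("trochanteric", "subtrochanteric"):
        key = f"fracture_{lv}"
        if key in ors:
            lp = lp + np.log(ors[key]) * (df["fracture_type"] == lv).to_numpy()
    for lv in ("long_term", "no_recent"):
        key = f"care_{lv}"
        if key in ors:
            lp = lp + np.log(ors[key]) * (df["care_history"] == lv).to_numpy()
    for name, orv in ors.items():
        if name in df.columns and name not in ("age_per10", "male"):
            lp = lp + np.log(orv) * df[name].to_numpy()
    return lp


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Root-find beta0 so that mean(expit(beta0 + lp)) == target."""

    def f(b0: float) -> float:
        return float(expit(b0 + lp).mean()) - target

    b0 = brentq(f, -30.0, 30.0, xtol=1e-10)
    achieved = float(expit(b0 + lp).mean())
    if abs(achieved - target) > 0.002:
        raise ValueError(
            f"intercept calibration failed: achieved rate {achieved:.4f}, "
            f"target {target:.4f}"
        )
    return float(b0)


def generate_outcomes(
    config: GeneratorConfig,
    patients: pd.DataFrame,
    providers: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Draw coherent mortality / maintainability outcomes and first-event types.

    Returns the patient table with `mortality`, `unsuccessful_maintainability`
    and `first_event_type` columns, plus a dict of true intercepts.
    """
    df = patients.copy()
    theta = df["provider_id"].map(
        providers.set_index("provider_id")["theta_true"]
    ).to_numpy()
    age_center = config.marginals["age_mean"]

    lp_d = _linear_predictor(df, config.or_mortality, age_center) + theta
    lp_m = _linear_predictor(df, config.or_maintainability, age_center) + theta
    b0_d = _calibrate_intercept(lp_d, config.baseline_mortality)
    b0_m = _calibrate_intercept(lp_m, config.baseline_maintainability)
    p_d = expit(b0_d + lp_d)
    p_m = expit(b0_m + lp_m)

    dead = rng.random(len(df)) < p_d
    q = np.clip((p_m - p_d) / (1.0 - p_d), 0.0, 1.0)
    unsucc = dead | (rng.random(len(df)) < q)

    etype = np.array(["none"] * len(df), dtype=object)
    shares = config.event_shares
    n_unsucc = int(unsucc.sum())
    dead_idx = np.flatnonzero(dead)
    n_death_first = min(int(round(shares["death"] * n_unsucc)), dead_idx.size)
    death_first = rng.choice(dead_idx, size=n_death_first, replace=False)
    etype[death_first] = "death"
    rest = np.flatnonzero(unsucc & (etype == "none"))
    p_readm = shares["readmission"] / (shares["readmission"] + shares["referral"])
    etype[rest] = np.where(rng.random(rest.size) < p_readm, "readmission", "referral")

    df["mortality"] = dead.astype(int)
    df["unsuccessful_maintainability"] = unsucc.astype(int)
    df["first_event_type"] = etype
    truth = {
        "beta0_mortality": b0_d,
        "beta0_maintainability": b0_m,
        "achieved_mortality": float(dead.mean()),
        "achieved_maintainability": float(unsucc.mean()),
    }
    return df, truth


# ---------------------------------------------------------------------------
# trajectories

def _rle_intervals(pid: str, levels: np.ndarray) -> list[tuple[str, int, int, int]]:
    """Run-length encode institutional segments (levels >= 2; death as 1-day record)."""
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(levels)]])
    out = []
    for s, e in zip(starts, ends):
        lv = int(levels[s])
        if lv == DEATH_LEVEL:
            out.append((pid, int(s), int(s) + 1, lv))  # death date only
            break
        if lv >= 2:
            out.append((pid, int(s), int(e), lv))
    return out


def generate_trajectories(
    config: GeneratorConfig, patients: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Interval records whose reconstructed trajectories reproduce each outcome.

    Every patient starts in hospital at day 0.  Successful-maintainability
    patients get a monotone non-increasing trajectory; unsuccessful patients
    get exactly one backward step at a drawn event day matching their
    first-event type; patients who die do so within the window.  Home spells
    are not emitted (registers record only institutional care).
    """
    horizon = config.horizon_days
    window = config.window_days
    n = len(patients)

    los_hosp = 1 + rng.poisson(6.0, size=n)
    los_rehab = 5 + rng.poisson(20.0, size=n)
    use_rehab = rng.random(n) < 0.7
    u_day = rng.random(n)
    u_day2 = rng.random(n)
    restay = 1 + rng.poisson(5.0, size=n)
    readm_high = rng.random(n) < 0.5

    long_term = (patients["care_history"] == "long_term").to_numpy()
    mortality = patients["mortality"].to_numpy()
    etypes = patients["first_event_type"].to_numpy()
    pids = patients["patient_id"].to_numpy()

    records: list[tuple[str, int, int, int]] = []
    for i in range(n):
        final_lv = 2 if long_term[i] else 1
        rehab_lv = 3 if (use_rehab[i] and not long_term[i]) else final_lv
        lh = int(los_hosp[i])
        lr = int(los_rehab[i])
        lv = np.full(horizon, final_lv, dtype=np.int8)
        lv[:lh] = 4
        if rehab_lv > final_lv:
            lv[lh : lh + lr] = rehab_lv
        et = etypes[i]
        if et == "death":
            d = 1 + int(u_day[i] * window)  # day 1..window
            lv[d:] = DEATH_LEVEL
        elif et in ("readmission", "referral"):
            if mortality[i]:
                d = 2 + int(u_day[i] * (window - 2))       # 2..window-1
                d2 = d + 1 + int(u_day2[i] * (window - d)) # d+1..window
            else:
                d = 2 + int(u_day[i] * (window - 1))       # 2..window
                d2 = None
            lh_eff = min(lh, d - 1)
            lv[:lh_eff] = 4
            if et == "referral":
                prev_lv, new_lv = 3, 4
            else:
                prev_lv = 2 if long_term[i] else 1
                new_lv = 4 if readm_high[i] else 3
            lv[lh_eff:d] = prev_lv
            lv[d : d + int(restay[i])] = new_lv
            lv[d + int(restay[i]) :] = prev_lv
            if d2 is not None:
                lv[d2:] = DEATH_LEVEL
        records.extend(_rle_intervals(pids[i], lv))

    return pd.DataFrame(
        records, columns=["patient_id", "start_day", "end_day", "level"]
    )


def generate_registry(config: GeneratorConfig | None = None) -> Registry:
    """Run all generation stages under one seed; returns tables and manifest."""
    if config is None:
        config = default_config()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    providers = generate_providers(config, rng)
    patients = generate_patients(config, providers, rng)
    patients, truth = generate_outcomes(config, patients, providers, rng)
    intervals = generate_trajectories(config, patients, rng)
    manifest = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "n_providers": config.n_providers,
        "baseline_mortality": config.baseline_mortality,
        "baseline_maintainability": config.baseline_maintainability,
        "event_shares": dict(config.event_shares),
        "volume_effect": {
            "family": config.volume_effect.family,
            "gamma": config.volume_effect.gamma,
            "cutpoint": config.volume_effect.cutpoint,
            "step": config.volume_effect.step,
        },
        "provider_sd": config.provider_sd,
        "or_mortality": dict(config.or_mortality),
        "or_maintainability": dict(config.or_maintainability),
        **truth,
    }
    return Registry(
        providers=providers, patients=patients, intervals=intervals, manifest=manifest
    )
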