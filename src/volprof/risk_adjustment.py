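"""Patient-level logistic risk adjustment and provider aggregation.

Case-mix adjustment follows the indirect-standardization tradition: a
logistic regression of the binary outcome on patient characteristics gives
each patient a predicted probability, and per provider the observed events
O_i = sum(Y_j) and expected events E_i = sum(logit^-1(x_j beta)) are
accumulated together with the pooled patient volume z_i.  Discrimination is
summarized by the c-statistic (area under the ROC curve).

Covariate encoding
------------------
* ``age`` enters per decade (age / 10), linear on the logit scale.
* ``sex``: male = 1.
* ``fracture_type``: reference-cell dummies, reference = femoral neck.
* ``care_history``: reference = recent short-term care; levels absent from
  the data (e.g. long-term care in a home-dwelling subset) are dropped.
* ten binary comorbidity flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

__all__ = [
    "COMORBIDITIES",
    "FRACTURE_TYPES",
    "CARE_HISTORIES",
    "RiskModel",
    "build_design",
    "fit_risk_model",
    "predict_probability",
    "c_statistic",
    "aggregate_providers",
    "model_card",
]

COMORBIDITIES = [
    "cancer",
    "diabetes",
    "parkinson",
    "cardiovascular",
    "cerebrovascular",
    "peripheral_vascular",
    "chronic_pulmonary",
    "peptic_ulcer",
    "renal",
    "rheumatologic",
]

FRACTURE_TYPES = ["neck", "trochanteric", "subtrochanteric"]  # neck = reference
CARE_HISTORIES = ["recent_short_term", "long_term", "no_recent"]  # ref first


class RiskModelError(ValueError):
    """Raised for rank-deficient designs, separation, or non-convergence."""


@dataclass
class RiskModel:
    """Fitted logistic risk model: coefficients plus the encoding that built them."""

    outcome: str
    params: pd.Series
    cov_params: pd.DataFrame
    fracture_levels: list[str]
    care_levels: list[str]
    c_statistic: float
    n_fitted: int
    custom_terms: list[str] | None = None

    @property
    def term_names(self) -> list[str]:
        return list(self.params.index)


def build_design(
    df: pd.DataFrame,
    fracture_levels: list[str] | None = None,
    care_levels: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Encode patient records into a design matrix with an intercept column.

    When level lists are given (scoring with a fitted model), unseen
    categorical values raise; when omitted (fitting), non-reference levels
    present in the data define the dummies and empty levels are dropped.
    """
    bad_fr = set(df["fracture_type"]) - set(FRACTURE_TYPES)
    if bad_fr:
        raise RiskModelError(f"unknown fracture_type level(s): {sorted(bad_fr)}")
    bad_ch = set(df["care_history"]) - set(CARE_HISTORIES)
    if bad_ch:
        raise RiskModelError(f"unknown care_history level(s): {sorted(bad_ch)}")
    if fracture_levels is None:
        fracture_levels = [
            lv for lv in FRACTURE_TYPES[1:] if (df["fracture_type"] == lv).any()
        ]
    if care_levels is None:
        care_levels = [
            lv for lv in CARE_HISTORIES[1:] if (df["care_history"] == lv).any()
        ]
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    X["age_per10"] = df["age"].to_numpy(dtype=float) / 10.0
    X["male"] = df["sex"].to_numpy(dtype=float)
    for lv in fracture_levels:
        X[f"fracture_{lv}"] = (df["fracture_type"] == lv).astype(float)
    for lv in care_levels:
        X[f"care_{lv}"] = (df["care_history"] == lv).astype(float)
    for c in COMORBIDITIES:
        X[c] = df[c].to_numpy(dtype=float)
    return X, fracture_levels, care_levels


def fit_risk_model(
    df: pd.DataFrame, outcome: str, terms: list[str] | None = None
) -> RiskModel:
    """Maximum-likelihood logistic fit of `outcome` on the standard encoding.

    Rows with missing values in any model column are dropped (complete-case).
    `terms` restricts the design to an intercept plus the named numeric
    columns (an empty list fits intercept-only); by default the full
    standard encoding is used.

    Raises
    ------
    RiskModelError
        If the outcome is constant, the design is rank deficient (naming the
        offending columns), or Newton iterations fail to converge.
    """
    if terms is None:
        cols = ["age", "sex", "fracture_type", "care_history", *COMORBIDITIES, outcome]
    else:
        cols = [*terms, outcome]
    data = df.dropna(subset=[c for c in cols if c in df.columns])
    y = data[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise RiskModelError(f"outcome {outcome!r} is constant; cannot fit")
    if terms is not None:
        X = pd.DataFrame(index=data.index)
        X["intercept"] = 1.0
        for t in terms:
            X[t] = data[t].to_numpy(dtype=float)
        fr_levels: list[str] = []
        ch_levels: list[str] = []
    else:
        X, fr_levels, ch_levels = build_design(data)
    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j, name in enumerate(X.columns):
            sub = np.delete(Xv, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise RiskModelError(f"design matrix rank deficient; offending columns: {bad}")
    try:
        res = sm.Logit(y, Xv).fit(
            method="newton", maxiter=100, tol=1e-10, disp=False
        )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        raise RiskModelError(f"logistic fit failed (separation?): {e}") from e
    if not res.mle_retvals.get("converged", False):
        raise RiskModelError(
            f"logistic fit did not converge in {res.mle_retvals.get('iterations')} "
            f"iterations for outcome {outcome!r}"
        )
    params = pd.Series(res.params, index=X.columns, name=outcome)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    probs = 1.0 / (1.0 + np.exp(-(Xv @ res.params)))
    cstat = c_statistic(probs, y)
    return RiskModel(
        outcome=outcome,
        params=params,
        cov_params=cov,
        fracture_levels=fr_levels,
        care_levels=ch_levels,
        c_statistic=cstat,
        n_fitted=len(data),
        custom_terms=terms,
    )


def predict_probability(model: RiskModel, df: pd.DataFrame) -> np.ndarray:
    """Predicted event probabilities logit^-1(x beta) for each record."""
    if model.custom_terms is not None:
        X = pd.DataFrame(index=df.index)
        X["intercept"] = 1.0
        for t in model.custom_terms:
            X[t] = df[t].to_numpy(dtype=float)
    else:
        X, _, _ = build_design(df, model.fracture_levels, model.care_levels)
    X = X[model.term_names]
    eta = X.to_numpy() @ model.params.to_numpy()
    return 1.0 / (1.0 + np.exp(-eta))


def c_statistic(probabilities, outcomes) -> float:
    """Concordance index: P(score_event > score_nonevent), ties credited 1/2.

    Computed via the Mann-Whitney rank-sum identity, equivalent to averaging
    over all (event, non-event) pairs.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic undefined: both outcome classes required")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def aggregate_providers(
    df: pd.DataFrame, model: RiskModel, provider_field: str
) -> pd.DataFrame:
    """Aggregate observed/expected events and volume to the provider level.

    Returns a frame with columns ``provider_id, O, E, z`` (one row per
    provider that treated at least one patient).  With an intercept MLE fit
    on the same records, sum(E) equals sum(O) by the logistic score equation.
    """
    data = df.dropna(subset=[provider_field])
    probs = predict_probability(model, data)
    g = pd.DataFrame(
        {
            "provider_id": data[provider_field].to_numpy(),
            "Y": data[model.outcome].to_numpy(dtype=float),
            "p": probs,
        }
    ).groupby("provider_id", sort=True)
    out = g.agg(O=("Y", "sum"), E=("p", "sum"), z=("Y", "size")).reset_index()
    bad = out[(out["E"] <= 0) & (out["O"] > 0)]
    if len(bad):
        raise RiskModelError(
            f"providers with E=0 but O>0: {bad['provider_id'].tolist()}"
        )
    out["O"] = out["O"].astype(int)
    return out


def model_card(model: RiskModel) -> dict:
    """JSON-ready summary: coefficients, odds ratios with Wald 95% CIs, c-statistic."""
    se = np.sqrt(np.diag(model.cov_params.to_numpy()))
    zcrit = norm.ppf(0.975)
    terms = {}
    for name, beta, s in zip(model.term_names, model.params.to_numpy(), se):
        terms[name] = {
            "coef": float(beta),
            "se": float(s),
            "or": float(np.exp(beta)),
            "or_ci95": [float(np.exp(beta - zcrit * s)), float(np.exp(beta + zcrit * s))],
        }
    return {
        "outcome": model.outcome,
        "n_fitted": model.n_fitted,
        "c_statistic": model.c_statistic,
        "terms": terms,
    }
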