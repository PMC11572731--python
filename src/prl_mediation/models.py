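"""OLS engine and the three mediation-design model specifications.

The mediation design uses three linear models on the patient table:

* **total-effect model** — EDSS on race plus the full observed covariate set
  (age, sex, disease duration, DMT category, non-PRL FLAIR volume, zip-code
  income); its race coefficient is the covariate-adjusted total disparity.
* **mediator model** — PRL percentage on race, age and DMT; its race
  coefficient is alpha, the race effect on the mediator.
* **outcome model** — EDSS on race, the PRL percentage, age, DMT and non-PRL
  volume; its race coefficient is the direct effect (ADE) and its mediator
  coefficient is beta.

Race is coded 0/1 with BA = 1; DMT enters as two dummies (lower, untreated)
against the higher-efficacy reference; income is rescaled to $10,000 units to
condition the design matrix.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .cohort import CohortTable
from .errors import CollinearityError, ConfigurationError

ROLES = ("total_effect", "mediator", "outcome")

#: dummy coding of categorical columns: (reference level, dummies in order)
CATEGORICAL_CODING = {
    "race": ("WA", [("BA", "race_BA")]),
    "sex": ("female", [("male", "sex_male")]),
    "dmt": ("higher", [("lower", "dmt_lower"), ("untreated", "dmt_untreated")]),
}

#: column rescalings applied when building designs: column -> (suffix, factor)
COLUMN_SCALES = {"zip_income": ("_10k", 1e-4)}

TREATMENT_COLUMN = "race_BA"
MEDIATOR_COLUMN = "prl_percentage"


@dataclasses.dataclass
class ModelSpec:
    """Declarative regression specification for one mediation role."""

    role: str
    response: str
    treatment: str = "race"
    covariates: Sequence[str] = ()

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigurationError(f"role: must be one of {ROLES}, got {self.role!r}")
        has_mediator = MEDIATOR_COLUMN in self.covariates
        if self.role == "outcome" and not has_mediator:
            raise ConfigurationError(
                "covariates: outcome model must include the mediator column")
        if self.role != "outcome" and has_mediator:
            raise ConfigurationError(
                f"covariates: {self.role} model must not include the mediator")


def default_spec(role: str) -> ModelSpec:
    if role == "mediator":
        return ModelSpec(role, response=MEDIATOR_COLUMN, covariates=("age", "dmt"))
    if role == "outcome":
        return ModelSpec(role, response="edss",
                         covariates=(MEDIATOR_COLUMN, "age", "dmt", "non_prl_volume"))
    if role == "total_effect":
        return ModelSpec(role, response="edss",
                         covariates=("age", "sex", "disease_duration", "dmt",
                                     "non_prl_volume", "zip_income"))
    raise ConfigurationError(f"role: unknown role {role!r}")


def mediation_base_spec(outcome_spec: ModelSpec | None = None) -> ModelSpec:
    """Total-effect spec on the mediation covariate set (outcome minus mediator).

    This reduced model anchors the product-of-coefficients = difference-of-
    coefficients identity and supplies the residuals of the sensitivity
    analysis.
    """
    outcome_spec = outcome_spec or default_spec("outcome")
    covariates = tuple(c for c in outcome_spec.covariates if c != MEDIATOR_COLUMN)
    return ModelSpec("total_effect", response=outcome_spec.response,
                     treatment=outcome_spec.treatment, covariates=covariates)


def _expand_column(df: pd.DataFrame, column: str):
    """Yield (name, values) pairs for one spec column."""
    if column in CATEGORICAL_CODING:
        reference, dummies = CATEGORICAL_CODING[column]
        known = {reference} | {level for level, _ in dummies}
        seen = set(df[column].unique())
        if not seen <= known:
            raise ConfigurationError(
                f"{column}: unseen categorical level(s) {sorted(seen - known)}")
        for level, name in dummies:
            yield name, (df[column] == level).to_numpy(float)
    elif column in COLUMN_SCALES:
        suffix, factor = COLUMN_SCALES[column]
        yield column + suffix, df[column].to_numpy(float) * factor
    else:
        yield column, df[column].to_numpy(float)


def build_design(cohort: CohortTable | pd.DataFrame, spec: ModelSpec):
    """Build the design matrix, its column names, and the response vector.

    Column order is deterministic: intercept, treatment dummy, then the
    covariates in spec order (categoricals expanded in coding order).
    """
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    for col in (spec.response, spec.treatment, *spec.covariates):
        if col not in df.columns:
            raise ConfigurationError(f"{col}: column not present in cohort")
    names = ["intercept"]
    columns = [np.ones(len(df))]
    for name, values in _expand_column(df, spec.treatment):
        names.append(name)
        columns.append(values)
    for cov in spec.covariates:
        for name, values in _expand_column(df, cov):
            names.append(name)
            columns.append(values)
    X = np.column_stack(columns)
    y = df[spec.response].to_numpy(float)
    return X, names, y


@dataclasses.dataclass
class OLSFit:
    """Fitted OLS model: estimates, inference, residuals and bookkeeping."""

    names: Sequence[str]
    coef: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    resid: np.ndarray
    sigma: float
    n: int
    rank: int
    spec: ModelSpec | None = None

    @property
    def df_resid(self) -> int:
        return self.n - self.rank

    def coef_for(self, name: str) -> float:
        return float(self.coef[list(self.names).index(name)])

    def se_for(self, name: str) -> float:
        return float(self.se[list(self.names).index(name)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": list(self.names),
            "estimate": self.coef,
            "se": self.se,
            "t": self.tvalues,
            "p": self.pvalues,
        })


def fit_ols(X: np.ndarray, y: np.ndarray,
            names: Sequence[str] | None = None,
            spec: ModelSpec | None = None) -> OLSFit:
    """Ordinary least squares via pivoted QR with explicit rank checking.

    Raises :class:`CollinearityError` naming the dependent columns when the
    design is rank deficient, and :class:`ConfigurationError` when there are
    no residual degrees of freedom.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]

    Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        dependent = [names[j] for j in piv[rank:]]
        raise CollinearityError(
            f"design is rank deficient (rank {rank} < {p} columns); "
            f"dependent column(s): {dependent}", columns=dependent)
    if n <= rank:
        raise ConfigurationError(
            f"n: need n > rank ({rank}) observations, got {n}")

    coef = np.empty(p)
    coef[piv] = linalg.solve_triangular(R, Q.T @ y)
    resid = y - X @ coef
    rss = float(resid @ resid)
    sigma2 = rss / (n - rank)
    Rinv = linalg.solve_triangular(R, np.eye(p))
    xtx_inv = np.empty((p, p))
    xtx_inv[np.ix_(piv, piv)] = Rinv @ Rinv.T
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - rank)
    return OLSFit(names=names, coef=coef, se=se, tvalues=tvals, pvalues=pvals,
                  resid=resid, sigma=float(np.sqrt(sigma2)), n=n, rank=rank,
                  spec=spec)


def fit_spec(cohort: CohortTable | pd.DataFrame, spec: ModelSpec) -> OLSFit:
    X, names, y = build_design(cohort, spec)
    return fit_ols(X, y, names, spec=spec)


def fit_named_model(cohort: CohortTable | pd.DataFrame, role: str,
                    overrides: Mapping[str, ModelSpec] | None = None) -> OLSFit:
    """Fit the default (or overridden) model for one mediation role."""
    if overrides and role in overrides:
        spec = overrides[role]
    else:
        spec = default_spec(role)
    return fit_spec(cohort, spec)
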