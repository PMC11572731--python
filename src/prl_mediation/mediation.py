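"""ACME/ADE point estimation and nonparametric bootstrap inference.

In the linear mediator/outcome system without a treatment-mediator
interaction, the average causal mediation effect (ACME) is the product of
coefficients alpha*beta — alpha the mediator-model race coefficient, beta
the outcome-model mediator coefficient — and the average direct effect
(ADE) is the outcome-model race coefficient.  The total effect is their sum
and the proportion mediated is ACME / (ACME + ADE).  Inference resamples
patients with replacement, refits both models per replicate, and reports
percentile confidence intervals and sign-flip bootstrap p-values.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import (ConfigurationError, InsufficientDataError,
                     ResamplingDegeneracyError)
from .models import (MEDIATOR_COLUMN, TREATMENT_COLUMN, ModelSpec, OLSFit,
                     build_design, default_spec)

#: replicates with |total effect| below this are excluded from the
#: proportion-mediated bootstrap distribution (and counted as unstable)
TOTAL_EFFECT_TOL = 1e-6


@dataclasses.dataclass
class PointEstimates:
    acme: float
    ade: float
    total_effect: float
    prop_mediated: float  # NaN when the total effect is below tolerance

    @property
    def prop_defined(self) -> bool:
        return np.isfinite(self.prop_mediated)


def point_from_coefficients(alpha: float, beta: float, ade: float,
                            tol: float = TOTAL_EFFECT_TOL) -> PointEstimates:
    """Mediation quantities from the three structural coefficients."""
    acme = alpha * beta
    total = acme + ade
    prop = acme / total if abs(total) >= tol else float("nan")
    return PointEstimates(acme=acme, ade=ade, total_effect=total, prop_mediated=prop)


def point_estimates(mediator_fit: OLSFit, outcome_fit: OLSFit,
                    treatment: str = TREATMENT_COLUMN,
                    mediator: str = MEDIATOR_COLUMN,
                    tol: float = TOTAL_EFFECT_TOL) -> PointEstimates:
    """Product-of-coefficients mediation estimates from two fitted models.

    ``acme + ade == total_effect`` holds exactly by construction.
    """
    if mediator not in outcome_fit.names:
        raise ConfigurationError(
            f"outcome fit does not contain the mediator term {mediator!r}")
    alpha = mediator_fit.coef_for(treatment)
    beta = outcome_fit.coef_for(mediator)
    ade = outcome_fit.coef_for(treatment)
    return point_from_coefficients(alpha, beta, ade, tol=tol)


def percentile_ci(samples: Sequence[float], level: float) -> tuple[float, float]:
    """Percentile bootstrap interval via linear interpolation of order stats."""
    samples = np.asarray(samples, float)
    if samples.size < 2:
        raise InsufficientDataError("percentile_ci: need at least 2 samples")
    if not np.isfinite(samples).all():
        raise InsufficientDataError("percentile_ci: non-finite samples rejected")
    if not 0 < level < 1:
        raise ConfigurationError(f"level: must be in (0, 1), got {level}")
    lo, hi = np.quantile(samples, [(1 - level) / 2, 1 - (1 - level) / 2],
                         method="linear")
    return float(lo), float(hi)


def bootstrap_pvalue(samples: Sequence[float]) -> float:
    """Two-sided sign-flip p-value: 2 * min(frac <= 0, frac >= 0), capped at 1.

    Returns 0.0 when no sample crosses zero; :func:`pvalue_display` renders
    that case as "< 2/n_boot".
    """
    samples = np.asarray(samples, float)
    if samples.size < 100:
        raise InsufficientDataError("bootstrap_pvalue: need at least 100 samples")
    p = 2.0 * min(float(np.mean(samples <= 0)), float(np.mean(samples >= 0)))
    return min(p, 1.0)


def pvalue_display(p: float, n_boot: int) -> str:
    if p == 0.0:
        return f"< {2.0 / n_boot:g}"
    return f"{p:.6g}"


@dataclasses.dataclass
class MediationResult:
    """Full bootstrap mediation inference for one cohort."""

    acme: float
    ade: float
    total_effect: float
    prop_mediated: float
    ci_level: float
    ci: Mapping[str, tuple[float, float]]
    p_values: Mapping[str, float]
    p_display: Mapping[str, str]
    n_boot: int
    seed: int
    n_unstable: int          # replicates with |total effect| < tolerance
    n_redrawn: int           # rank-deficient replicates that were redrawn
    stratified: bool
    spec_digest: str | None = None

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["ci"] = {k: list(v) for k, v in self.ci.items()}
        return payload

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, blob: str) -> "MediationResult":
        payload = json.loads(blob)
        payload["ci"] = {k: tuple(v) for k, v in payload["ci"].items()}
        return cls(**payload)


def resample_indices(rng: np.random.Generator, n: int, n_draws: int,
                     groups: np.ndarray | None = None) -> np.ndarray:
    """Draw ``n_draws`` bootstrap index rows of length n.

    Unstratified: iid uniform over rows.  Stratified: iid uniform within each
    group's block of rows (group labels must be contiguous is not required;
    positions are drawn within each group and placed in group order).  The
    index stream is a pure function of the rng state, so an independent
    re-implementation fed the same stream reproduces the bootstrap exactly.
    """
    if groups is None:
        return rng.integers(0, n, size=(n_draws, n))
    blocks = []
    for g in pd.unique(groups):
        pos = np.flatnonzero(groups == g)
        blocks.append(pos[rng.integers(0, pos.size, size=(n_draws, pos.size))])
    return np.concatenate(blocks, axis=1)


def _batched_ols_coef(counts, X, y, row_outer, Xy):
    """Weighted-normal-equation OLS coefficients for a batch of resamples.

    ``counts`` is (B, n) multiplicity of each original row in the replicate;
    a weighted fit with integer weights equals OLS on the resampled rows.
    Returns (coefs, singular_mask).
    """
    XtX = np.einsum("bn,nij->bij", counts, row_outer, optimize=True)
    Xty = counts @ Xy
    B, p = Xty.shape
    coefs = np.full((B, p), np.nan)
    ok = np.ones(B, bool)
    try:
        coefs = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    except np.linalg.LinAlgError:
        for b in range(B):
            try:
                coefs[b] = np.linalg.solve(XtX[b], Xty[b])
            except np.linalg.LinAlgError:
                ok[b] = False
    # guard against near-singular solves that slipped through
    bad = ~np.isfinite(coefs).all(axis=1)
    ok &= ~bad
    return coefs, ~ok


def bootstrap_mediation(cohort: CohortTable, mediator_spec: ModelSpec | None = None,
                        outcome_spec: ModelSpec | None = None,
                        n_boot: int = 25000, ci_level: float = 0.95,
                        seed: int = 0, stratified: bool = False,
                        total_tol: float = TOTAL_EFFECT_TOL,
                        treatment: str = TREATMENT_COLUMN,
                        mediator: str = MEDIATOR_COLUMN) -> MediationResult:
    """Nonparametric bootstrap of ACME, ADE, total effect and proportion.

    Patients are resampled iid with replacement (full cohort by default,
    within race when ``stratified``); both models are refitted per replicate;
    confidence intervals use the percentile method.  Replicates whose designs
    are rank deficient are redrawn from the continuing index stream, capped
    at 1% of ``n_boot``.
    """
    if n_boot < 100:
        raise ConfigurationError(f"n_boot: need >= 100, got {n_boot}")
    if len(cohort) < 20:
        raise InsufficientDataError(
            f"bootstrap_mediation: need cohort n >= 20, got {len(cohort)}")
    mediator_spec = mediator_spec or default_spec("mediator")
    outcome_spec = outcome_spec or default_spec("outcome")

    Xm, names_m, ym = build_design(cohort, mediator_spec)
    Xo, names_o, yo = build_design(cohort, outcome_spec)
    i_alpha = names_m.index(treatment)
    i_beta = names_o.index(mediator)
    i_ade = names_o.index(treatment)
    n = len(cohort)

    outer_m = Xm[:, :, None] * Xm[:, None, :]
    outer_o = Xo[:, :, None] * Xo[:, None, :]
    Xym = Xm * ym[:, None]
    Xyo = Xo * yo[:, None]

    rng = np.random.default_rng(seed)
    groups = cohort.df["race"].to_numpy() if stratified else None
    max_redraws = max(1, int(np.ceil(0.01 * n_boot)))

    alpha = np.empty(n_boot)
    beta = np.empty(n_boot)
    ade = np.empty(n_boot)
    filled = 0
    n_redrawn = 0
    chunk = 5000
    pending = n_boot
    while pending > 0:
        draws = min(chunk, pending)
        idx = resample_indices(rng, n, draws, groups)
        offs = idx + (np.arange(draws) * n)[:, None]
        counts = np.bincount(offs.ravel(), minlength=draws * n) \
            .reshape(draws, n).astype(float)
        cm, bad_m = _batched_ols_coef(counts, Xm, ym, outer_m, Xym)
        co, bad_o = _batched_ols_coef(counts, Xo, yo, outer_o, Xyo)
        bad = bad_m | bad_o
        keep = ~bad
        k = int(keep.sum())
        alpha[filled:filled + k] = cm[keep, i_alpha]
        beta[filled:filled + k] = co[keep, i_beta]
        ade[filled:filled + k] = co[keep, i_ade]
        filled += k
        pending -= k
        n_redrawn += int(bad.sum())
        if n_redrawn > max_redraws:
            raise ResamplingDegeneracyError(
                f"{n_redrawn} rank-deficient bootstrap replicates exceed the "
                f"redraw cap ({max_redraws}, 1% of n_boot={n_boot})")

    acme_b = alpha * beta
    total_b = acme_b + ade
    stable = np.abs(total_b) >= total_tol
    n_unstable = int((~stable).sum())
    prop_b = acme_b[stable] / total_b[stable]

    point = point_estimates(
        _fit_for_point(Xm, ym, names_m), _fit_for_point(Xo, yo, names_o),
        treatment=treatment, mediator=mediator, tol=total_tol)

    dists = {"acme": acme_b, "ade": ade, "total_effect": total_b,
             "prop_mediated": prop_b}
    ci = {k: percentile_ci(v, ci_level) for k, v in dists.items() if v.size >= 2}
    p_values = {k: bootstrap_pvalue(v) for k, v in dists.items() if v.size >= 100}
    p_display = {k: pvalue_display(v, n_boot) for k, v in p_values.items()}

    digest = getattr(cohort, "config_digest", None)
    return MediationResult(
        acme=point.acme, ade=point.ade, total_effect=point.total_effect,
        prop_mediated=point.prop_mediated, ci_level=ci_level, ci=ci,
        p_values=p_values, p_display=p_display, n_boot=n_boot, seed=seed,
        n_unstable=n_unstable, n_redrawn=n_redrawn, stratified=stratified,
        spec_digest=digest)


def _fit_for_point(X, y, names):
    from .models import fit_ols
    return fit_ols(X, y, names)
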