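"""Sequential-ignorability sensitivity analysis for the ACME.

The mediation estimate assumes no unobserved confounder of the
mediator-outcome relationship.  The sensitivity parameter rho is the
correlation that such a confounder would induce between the disturbances of
the mediator model and the outcome model.  In the linear structural-equation
case the ACME re-identified at a hypothesized rho has the closed form

    ACME(rho) = alpha * (s1 / s2) * [rho~ - rho * sqrt((1 - rho~^2) / (1 - rho^2))]

where alpha is the mediator-model treatment coefficient, s1 and s2 are the
residual standard deviations of the reduced total-effect model (the outcome
regressed on treatment and covariates *without* the mediator) and of the
mediator model, and rho~ is the sample correlation of those two residual
vectors.  Two identities anchor the form: ACME(0) equals the
product-of-coefficients ACME exactly (Frisch-Waugh), and ACME(rho~) = 0 —
the observed residual correlation is the amount of confounding that would
explain away the entire mediation effect.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import ConfigurationError, DegenerateFitError
from .models import (MEDIATOR_COLUMN, TREATMENT_COLUMN, ModelSpec, OLSFit,
                     default_spec, fit_spec, mediation_base_spec)


def residual_correlation(total_fit: OLSFit, mediator_fit: OLSFit) -> float:
    """Pearson correlation rho~ of the two models' residual vectors."""
    r1 = np.asarray(total_fit.resid, float)
    r2 = np.asarray(mediator_fit.resid, float)
    if r1.shape != r2.shape:
        raise ConfigurationError(
            "residual vectors differ in length; fits must share the cohort")
    s1 = float(np.sqrt(r1 @ r1))
    s2 = float(np.sqrt(r2 @ r2))
    if s1 == 0.0 or s2 == 0.0:
        raise DegenerateFitError("zero-variance residuals; correlation undefined")
    return float((r1 @ r2) / (s1 * s2))


def acme_at_rho(total_fit: OLSFit, mediator_fit: OLSFit, rho: float,
                treatment: str = TREATMENT_COLUMN) -> float:
    """Evaluate the closed-form ACME at a hypothesized residual correlation."""
    if not abs(rho) < 1:
        raise ConfigurationError(f"rho: must satisfy |rho| < 1, got {rho}")
    alpha = mediator_fit.coef_for(treatment)
    rho_t = residual_correlation(total_fit, mediator_fit)
    r1 = np.asarray(total_fit.resid, float)
    r2 = np.asarray(mediator_fit.resid, float)
    scale = alpha * np.sqrt(float(r1 @ r1)) / np.sqrt(float(r2 @ r2))
    return float(scale * (rho_t - rho * np.sqrt((1 - rho_t ** 2) / (1 - rho ** 2))))


@dataclasses.dataclass
class SensitivityResult:
    """ACME(rho) over a grid, the observed rho~, and the zero crossing."""

    rho_grid: np.ndarray
    acme_of_rho: np.ndarray
    rho_tilde: float
    zero_crossing: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rho": self.rho_grid, "acme": self.acme_of_rho})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path) -> None:
        """Write an ACME(rho) curve figure (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.rho_grid, self.acme_of_rho)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.axvline(self.zero_crossing, color="crimson", ls="--", lw=0.8,
                   label=f"zero crossing {self.zero_crossing:.3f}")
        ax.set_xlabel(r"residual correlation $\rho$")
        ax.set_ylabel("ACME (EDSS points)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _bisect_zero(f, lo, hi, tol=1e-9, max_iter=200):
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise ConfigurationError("zero crossing not bracketed by the rho domain")
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        fm = f(mid)
        if fm == 0.0 or (hi - lo) / 2.0 < tol:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return (lo + hi) / 2.0


def sensitivity_curve(total_fit: OLSFit, mediator_fit: OLSFit,
                      grid: np.ndarray | None = None,
                      treatment: str = TREATMENT_COLUMN) -> SensitivityResult:
    """Tabulate ACME(rho) over a grid and locate its zero crossing.

    The default grid spans (-0.9, 0.9) in steps of 0.01.  The crossing is
    found by bisection on the closed form over (-0.999, 0.999) to 1e-6, so it
    does not depend on the grid resolution.
    """
    if grid is None:
        grid = np.round(np.arange(-0.9, 0.9 + 1e-12, 0.01), 10)
    grid = np.asarray(grid, float)
    if grid.size == 0 or np.abs(grid).max() >= 1:
        raise ConfigurationError("grid: values must lie within (-1, 1)")
    acme = np.array([acme_at_rho(total_fit, mediator_fit, r, treatment)
                     for r in grid])
    rho_t = residual_correlation(total_fit, mediator_fit)
    crossing = _bisect_zero(
        lambda r: acme_at_rho(total_fit, mediator_fit, r, treatment),
        -0.999, 0.999, tol=1e-9)
    return SensitivityResult(rho_grid=grid, acme_of_rho=acme,
                             rho_tilde=rho_t, zero_crossing=float(crossing))


def sensitivity_fits(cohort: CohortTable,
                     outcome_spec: ModelSpec | None = None) -> tuple[OLSFit, OLSFit]:
    """Fit the reduced total-effect and shared-covariate mediator models.

    Both models regress on the outcome model's covariates minus the mediator
    (treatment, age, DMT, non-PRL volume by default).  Sharing the covariate
    set is what makes the Frisch-Waugh anchor exact: the closed form at
    rho = 0 then reproduces alpha*beta with beta the outcome-model mediator
    coefficient, and it vanishes at rho = rho~.
    """
    base_spec = mediation_base_spec(outcome_spec)
    mediator_spec = ModelSpec("mediator", response=MEDIATOR_COLUMN,
                              treatment=base_spec.treatment,
                              covariates=base_spec.covariates)
    total_fit = fit_spec(cohort, base_spec)
    mediator_fit = fit_spec(cohort, mediator_spec)
    return total_fit, mediator_fit


def sensitivity_from_cohort(cohort: CohortTable,
                            outcome_spec: ModelSpec | None = None,
                            grid: np.ndarray | None = None) -> SensitivityResult:
    """Run the full sensitivity analysis for one cohort."""
    total_fit, mediator_fit = sensitivity_fits(cohort, outcome_spec)
    return sensitivity_curve(total_fit, mediator_fit, grid=grid)
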