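"""Single-document analysis report tying all pipeline stages together."""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .cohort import CohortTable
from .config import RunConfig
from .errors import RenderError
from .generate import generate_cohort
from .mediation import MediationResult, bootstrap_mediation, point_estimates
from .models import OLSFit, default_spec, fit_named_model
from .sensitivity import SensitivityResult, sensitivity_from_cohort
from .stats import ComparisonResult, table_one, table_one_frame, table_one_markdown

log = logging.getLogger("prl_mediation")

_STAGES = ("table_one", "model_fits", "mediation", "sensitivity")


@dataclasses.dataclass
class AnalysisReport:
    """All stage outputs of one run, renderable as markdown or JSON."""

    config_digest: str
    seed: int | None
    n_ba: int
    n_wa: int
    table_one: Sequence[ComparisonResult] | None = None
    model_fits: Mapping[str, OLSFit] | None = None
    mediation: MediationResult | None = None
    sensitivity: SensitivityResult | None = None
    version: str = __version__
    timestamp: str = ""

    def missing_stages(self):
        return [s for s in _STAGES if getattr(self, s) is None]


def run_analysis(config: RunConfig, cohort: CohortTable | None = None) -> AnalysisReport:
    """Execute every pipeline stage under one configuration.

    A pre-built cohort (e.g. read from CSV) bypasses the generator; otherwise
    the configured generator runs with the run seed.
    """
    config.validate()
    overrides = config.specs()
    if cohort is None:
        gen = config.generator
        if config.seed is not None:
            gen = gen.replace(seed=config.seed)
        log.info("generating cohort: mode=%s n=%d+%d seed=%s",
                 gen.mode, gen.n_ba, gen.n_wa, gen.seed)
        cohort = generate_cohort(gen)

    report = AnalysisReport(
        config_digest=config.digest(), seed=config.seed,
        n_ba=cohort.n_ba, n_wa=cohort.n_wa,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat())

    log.info("stage: table one")
    report.table_one = table_one(cohort)

    log.info("stage: model fits")
    report.model_fits = {
        role: fit_named_model(cohort, role, overrides)
        for role in ("total_effect", "mediator", "outcome")}

    log.info("stage: mediation bootstrap (n_boot=%d)", config.mediation.n_boot)
    med = config.mediation
    report.mediation = bootstrap_mediation(
        cohort,
        mediator_spec=overrides.get("mediator"),
        outcome_spec=overrides.get("outcome"),
        n_boot=med.n_boot, ci_level=med.ci_level,
        seed=config.seed if config.seed is not None else 0,
        stratified=med.stratified, total_tol=med.total_tol)

    log.info("stage: sensitivity analysis")
    report.sensitivity = sensitivity_from_cohort(
        cohort, outcome_spec=overrides.get("outcome"),
        grid=config.sensitivity.grid())
    return report


def _sig6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def render_report(report: AnalysisReport, format: str = "markdown") -> str:
    """Render the report; markdown shows 6 significant digits, JSON full."""
    missing = report.missing_stages()
    if missing:
        raise RenderError(f"report incomplete; missing stages: {missing}")
    if format == "json":
        return json.dumps(_report_payload(report, full=True), indent=2)
    if format == "markdown":
        return _render_markdown(report)
    raise RenderError(f"unknown format {format!r}")


def _report_payload(report: AnalysisReport, full: bool) -> dict:
    conv = (lambda x: x) if full else _sig6
    fits = {}
    for role, fit in report.model_fits.items():
        fits[role] = [
            {"term": t, "estimate": conv(float(b)), "se": conv(float(s)),
             "t": conv(float(tv)), "p": conv(float(p))}
            for t, b, s, tv, p in zip(fit.names, fit.coef, fit.se,
                                      fit.tvalues, fit.pvalues)]
    med = report.mediation.to_dict()
    if not full:
        med = json.loads(json.dumps(med), parse_float=lambda v: _sig6(float(v)))
    sens = report.sensitivity
    return {
        "version": report.version,
        "timestamp": report.timestamp,
        "config_digest": report.config_digest,
        "seed": report.seed,
        "n_ba": report.n_ba,
        "n_wa": report.n_wa,
        "table_one": table_one_frame(report.table_one).to_dict("records"),
        "model_fits": fits,
        "mediation": med,
        "sensitivity": {
            "rho_tilde": conv(float(sens.rho_tilde)),
            "zero_crossing": conv(float(sens.zero_crossing)),
            "rho_grid": [conv(float(v)) for v in sens.rho_grid],
            "acme_of_rho": [conv(float(v)) for v in sens.acme_of_rho],
        },
    }


def _md_fit_table(fit: OLSFit) -> str:
    lines = ["| term | estimate | se | t | p |", "|---|---|---|---|---|"]
    for t, b, s, tv, p in zip(fit.names, fit.coef, fit.se, fit.tvalues, fit.pvalues):
        lines.append(f"| {t} | {b:.6g} | {s:.6g} | {tv:.6g} | {p:.6g} |")
    return "\n".join(lines)


def _render_markdown(report: AnalysisReport) -> str:
    med = report.mediation
    sens = report.sensitivity
    parts = [
        "# PRL mediation analysis report",
        "",
        f"- package version: {report.version}",
        f"- config digest: `{report.config_digest}`",
        f"- seed: {report.seed}",
        f"- cohort: {report.n_ba} BA / {report.n_wa} WA patients",
        f"- generated: {report.timestamp}",
        "",
        "## Group comparisons (table one)",
        "",
        table_one_markdown(report.table_one),
        "",
    ]
    for role in ("total_effect", "mediator", "outcome"):
        parts += [f"## Model: {role}", "", _md_fit_table(report.model_fits[role]), ""]
    parts += [
        "## Mediation",
        "",
        f"- ACME: {med.acme:.6g} "
        f"(95% CI [{med.ci['acme'][0]:.6g}, {med.ci['acme'][1]:.6g}], "
        f"p {med.p_display['acme']})",
        f"- ADE: {med.ade:.6g} "
        f"(95% CI [{med.ci['ade'][0]:.6g}, {med.ci['ade'][1]:.6g}], "
        f"p {med.p_display['ade']})",
        f"- total effect: {med.total_effect:.6g} "
        f"(p {med.p_display['total_effect']})",
        f"- proportion mediated: {med.prop_mediated:.6g} "
        f"(p {med.p_display['prop_mediated']})",
        f"- bootstrap: {med.n_boot} replicates, seed {med.seed}, "
        f"{med.n_unstable} unstable, {med.n_redrawn} redrawn",
        "",
        "## Sensitivity (sequential ignorability)",
        "",
        f"- observed residual correlation rho~: {sens.rho_tilde:.6g}",
        f"- ACME zero crossing: {sens.zero_crossing:.6g}",
        f"- grid: {len(sens.rho_grid)} points in "
        f"[{sens.rho_grid[0]:.3g}, {sens.rho_grid[-1]:.3g}]",
        "",
    ]
    return "\n".join(parts)
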