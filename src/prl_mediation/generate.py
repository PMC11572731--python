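"""Synthetic MS cohort generator calibrated to the study population.

Two generator modes share the same covariate layer and outcome equation and
differ only in how the mediator (percentage of FLAIR lesions that are PRLs)
arises:

``linear``
    The mediator is an exact linear-Gaussian realization of the structural
    equation ``M = a0 + alpha*BA + b_age*age + b_lower*lower + b_untr*untreated
    + eps``.  It is unbounded (it can stray outside [0, 100]); this mode exists
    so that OLS on the generated data recovers the structural coefficients
    without truncation bias.

``count``
    Each patient draws a FLAIR lesion count from a zero-truncated negative
    binomial, a per-patient rim probability from a logit-normal (logistic of
    ``intercept + race_effect*BA + sd*Z``), and a PRL count from the binomial;
    the mediator is the realized percentage ``100 * prl_count / flair_count``,
    always in [0, 100].

The outcome (EDSS, kept latent-continuous by default) follows
``Y = c0 + gamma*BA + beta*M + b_age*age + b_lower*lower + b_untr*untreated
+ b_vol*non_prl_volume + eps``.  An optional latent standard-normal
confounder U is added with a common loading to both the mediator and the
outcome disturbance, breaking sequential ignorability on demand.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import CohortTable, COLUMNS
from .errors import CalibrationError, ConfigurationError

RACES = ("BA", "WA")


def _per_race(ba, wa):
    return {"BA": ba, "WA": wa}


@dataclasses.dataclass
class GeneratorConfig:
    """All distributional and structural parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 117 BA / 123 WA patients,
    covariate distributions matched to the published group summaries, the
    mediator-model race effect alpha = 4.65 percentage points, the
    outcome-model mediator effect beta = 0.021 and race direct effect
    gamma = 0.60 EDSS points, and count-model parameters calibrated to the
    published group mean PRL percentages (8.01 / 3.40) and PRL prevalences
    (55% / 39%).
    """

    n_ba: int = 117
    n_wa: int = 123
    mode: str = "linear"
    seed: int = 0

    # --- covariate layer (per-race distribution parameters) ---
    age_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(44.55, 43.00))
    age_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(12.09, 10.58))
    male_frac: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(28 / 117, 38 / 123))
    duration_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(11.00, 10.60))
    duration_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(7.52, 8.30))
    dmt_probs: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: {
            "BA": {"higher": 59 / 117, "lower": 38 / 117, "untreated": 20 / 117},
            "WA": {"higher": 64 / 123, "lower": 41 / 123, "untreated": 18 / 123},
        })
    income_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(66085.81, 120000.00))
    income_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(29486.83, 40388.69))
    # natural-scale moments of the lognormal non-PRL FLAIR lesion volume (mm^3)
    non_prl_volume_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(8029.30, 3600.00))
    non_prl_volume_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(9336.09, 5778.24))
    # truncation bounds for continuous covariates
    age_min: float = 18.0
    duration_min: float = 0.0
    income_min: float = 1000.0

    # --- FLAIR lesion counts (both modes; zero-truncated negative binomial) ---
    flair_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(23.83, 22.00))
    flair_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(20.77, 20.31))
    # mean volume (mm^3) of an individual rim lesion, used to build the total
    # FLAIR volume as non_prl_volume + sum of per-PRL volumes
    prl_lesion_volume_mean: float = 800.0
    prl_lesion_volume_sd: float = 400.0

    # --- mediator structural equation (linear mode) ---
    med_intercept: float = 5.3102
    alpha: float = 4.65          # race effect on PRL percentage (BA vs WA)
    med_age: float = -0.05
    med_dmt_lower: float = 0.5
    med_dmt_untreated: float = 0.5
    med_resid_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(15.25, 7.50))

    # --- outcome structural equation (EDSS) ---
    out_intercept: float = -0.8627
    gamma: float = 0.60          # direct race effect on EDSS
    beta: float = 0.021          # mediator effect on EDSS
    out_age: float = 0.05
    out_dmt_lower: float = -0.58
    out_dmt_untreated: float = -0.31
    out_non_prl_volume: float = 5e-5
    out_resid_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(1.9, 1.5))

    # --- count-mode rim-probability model (logit-normal overdispersed binomial)
    # Defaults are the calibrated solution for the published mean-percentage
    # and prevalence targets; ``calibrate_count_model`` recomputes them.
    count_logit_intercept: float = -3.683908
    count_race_effect: float = 0.646573
    count_overdisp_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: _per_race(1.261789, 0.862427))

    # --- unobserved-confounder channel and output shaping ---
    confounder_strength: float = 0.0
    round_edss: bool = False
    keep_latents: bool = False

    def validate(self) -> None:
        if self.mode not in ("linear", "count"):
            raise ConfigurationError(f"mode: must be 'linear' or 'count', got {self.mode!r}")
        if self.n_ba <= 0:
            raise ConfigurationError("n_ba: group size must be > 0")
        if self.n_wa <= 0:
            raise ConfigurationError("n_wa: group size must be > 0")
        sd_fields = ["age_sd", "duration_sd", "income_sd", "non_prl_volume_sd",
                     "flair_sd", "med_resid_sd", "out_resid_sd", "count_overdisp_sd"]
        for name in sd_fields:
            value = getattr(self, name)
            for race in RACES:
                if not value[race] > 0:
                    raise ConfigurationError(f"{name}[{race}]: sd must be > 0")
        for race in RACES:
            probs = self.dmt_probs[race]
            if set(probs) != {"higher", "lower", "untreated"}:
                raise ConfigurationError(f"dmt_probs[{race}]: need higher/lower/untreated")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"dmt_probs[{race}]: probabilities must be >= 0")
            if abs(sum(probs.values()) - 1.0) > 1e-8:
                raise ConfigurationError(f"dmt_probs[{race}]: probabilities must sum to 1")
            if not self.flair_sd[race] ** 2 > self.flair_mean[race]:
                raise ConfigurationError(
                    f"flair_sd[{race}]: variance must exceed the mean "
                    "(negative-binomial overdispersion)")
            if not 0 <= self.male_frac[race] <= 1:
                raise ConfigurationError(f"male_frac[{race}]: must be in [0, 1]")
        if self.confounder_strength < 0:
            raise ConfigurationError("confounder_strength: must be >= 0")

    def digest(self) -> str:
        """Stable hash of all semantic fields (seed excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("seed")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown generator field(s): {sorted(unknown)}")
        return cls(**payload)


# ---------------------------------------------------------------------------
# sampling helpers

def _truncated_normal(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    u = rng.uniform(size=size)
    # inverse-CDF draw restricted to [a, inf): deterministic in the rng stream
    return mean + sd * special.ndtri(special.ndtr(a) + u * (1.0 - special.ndtr(a)))


def _lognormal_from_moments(rng, mean, sd, size):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _nb_dispersion(mean, sd):
    # negative binomial: var = mu + mu^2/k  =>  k = mu^2 / (var - mu)
    return mean ** 2 / (sd ** 2 - mean)


def _sample_ztnb(rng, mean, sd, size):
    """Zero-truncated negative binomial lesion counts (every patient >= 1)."""
    k = _nb_dispersion(mean, sd)
    p = k / (k + mean)
    out = rng.negative_binomial(k, p, size=size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.negative_binomial(k, p, size=int(zero.sum()))


# ---------------------------------------------------------------------------
# count-model moments (quadrature, used by calibration and tests)

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(81)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def count_model_moments(logit_intercept: float, overdisp_sd: float,
                        flair_mean: float | None = None,
                        flair_sd: float | None = None,
                        fixed_count: int | None = None):
    """Exact (quadrature) mean PRL percentage and prevalence of >= 1 PRL.

    The per-patient rim probability is ``logistic(logit_intercept + sd*Z)``
    with standard-normal Z; the lesion count is either fixed (``fixed_count``)
    or zero-truncated negative binomial with the given natural-scale moments.
    Returns ``(mean_percentage, prevalence)``.
    """
    p = special.expit(logit_intercept + overdisp_sd * _GH_NODES)
    mean_pct = 100.0 * float(np.dot(_GH_WEIGHTS, p))
    if fixed_count is not None:
        none_prob = np.dot(_GH_WEIGHTS, (1.0 - p) ** fixed_count)
    else:
        if flair_mean is None or flair_sd is None:
            raise ConfigurationError("flair_mean/flair_sd: required unless fixed_count given")
        k = _nb_dispersion(flair_mean, flair_sd)
        # PGF of NB(mu, k) at s, corrected for zero truncation
        s = 1.0 - p
        pgf = (k / (k + flair_mean * (1.0 - s))) ** k
        p0 = (k / (k + flair_mean)) ** k
        none_prob = np.dot(_GH_WEIGHTS, (pgf - p0) / (1.0 - p0))
    return mean_pct, 1.0 - float(none_prob)


@dataclasses.dataclass
class CountModelParams:
    """Calibrated rim-probability parameters on the logit scale."""

    logit_intercept: float
    race_effect: float
    overdisp_sd: Mapping[str, float]
    achieved: Mapping[str, float]
    residuals: Mapping[str, float]


def _calibrate_one_race(mean_pct, prevalence, flair_mean, flair_sd):
    """Solve (logit intercept, overdispersion sd) for one race's targets."""

    def eta_for_mean(tau):
        lo, hi = -60.0, 20.0
        f = lambda eta: count_model_moments(eta, tau, flair_mean, flair_sd)[0] - mean_pct
        f_lo, f_hi = f(lo), f(hi)
        if f_lo * f_hi > 0:
            # mean target unreachable at this overdispersion; best endpoint
            return lo if abs(f_lo) < abs(f_hi) else hi
        return optimize.brentq(f, lo, hi, xtol=1e-12)

    def prev_gap(tau):
        eta = eta_for_mean(tau)
        return count_model_moments(eta, tau, flair_mean, flair_sd)[1] - prevalence

    lo, hi = 1e-6, 8.0
    g_lo, g_hi = prev_gap(lo), prev_gap(hi)
    if g_lo * g_hi > 0:
        # prevalence target unreachable at this mean; report best endpoint
        tau = lo if abs(g_lo) < abs(g_hi) else hi
        eta = eta_for_mean(tau)
        return eta, tau, prev_gap(tau)
    tau = optimize.brentq(prev_gap, lo, hi, xtol=1e-10)
    return eta_for_mean(tau), tau, 0.0


def calibrate_count_model(mean_pct: Mapping[str, float],
                          prevalence: Mapping[str, float],
                          flair_mean: Mapping[str, float] | None = None,
                          flair_sd: Mapping[str, float] | None = None,
                          tol_mean: float = 0.25,
                          tol_prevalence: float = 0.02) -> CountModelParams:
    """Calibrate the logit-normal rim model to per-race targets.

    ``mean_pct`` maps race to the target mean PRL percentage in (0, 100);
    ``prevalence`` maps race to the target fraction of patients with at least
    one PRL in (0, 1).  The solve is deterministic (quadrature + bracketed
    root finding, no simulation).  Raises :class:`CalibrationError` with the
    best residuals when the targets are unreachable within tolerance.
    """
    defaults = GeneratorConfig()
    flair_mean = flair_mean or defaults.flair_mean
    flair_sd = flair_sd or defaults.flair_sd
    for race in RACES:
        if not 0 < mean_pct[race] < 100:
            raise ConfigurationError(f"mean_pct[{race}]: must be in (0, 100)")
        if not 0 < prevalence[race] < 1:
            raise ConfigurationError(f"prevalence[{race}]: must be in (0, 1)")

    eta, tau, achieved, residuals = {}, {}, {}, {}
    for race in RACES:
        eta[race], tau[race], _ = _calibrate_one_race(
            mean_pct[race], prevalence[race], flair_mean[race], flair_sd[race])
        m, prev = count_model_moments(eta[race], tau[race],
                                      flair_mean[race], flair_sd[race])
        achieved[f"mean_pct_{race}"] = m
        achieved[f"prevalence_{race}"] = prev
        residuals[f"mean_pct_{race}"] = m - mean_pct[race]
        residuals[f"prevalence_{race}"] = prev - prevalence[race]

    bad = [k for k, v in residuals.items()
           if abs(v) > (tol_mean if k.startswith("mean") else tol_prevalence)]
    if bad:
        raise CalibrationError(
            f"targets unreachable within tolerance for {bad}; residuals {residuals}",
            residuals=residuals)
    return CountModelParams(
        logit_intercept=eta["WA"],
        race_effect=eta["BA"] - eta["WA"],
        overdisp_sd={"BA": tau["BA"], "WA": tau["WA"]},
        achieved=achieved,
        residuals=residuals,
    )


# ---------------------------------------------------------------------------
# cohort generation

def _generate_group(rng, config: GeneratorConfig, race: str, n: int):
    c = config
    age = _truncated_normal(rng, c.age_mean[race], c.age_sd[race], c.age_min, n)
    sex = np.where(rng.uniform(size=n) < c.male_frac[race], "male", "female")
    duration = _truncated_normal(rng, c.duration_mean[race], c.duration_sd[race],
                                 c.duration_min, n)
    dmt_levels = np.array(["higher", "lower", "untreated"])
    probs = np.array([c.dmt_probs[race][lv] for lv in dmt_levels])
    dmt = dmt_levels[rng.choice(3, size=n, p=probs)]
    income = _truncated_normal(rng, c.income_mean[race], c.income_sd[race],
                               c.income_min, n)
    non_prl_volume = _lognormal_from_moments(
        rng, c.non_prl_volume_mean[race], c.non_prl_volume_sd[race], n)
    flair_count = _sample_ztnb(rng, c.flair_mean[race], c.flair_sd[race], n)

    is_lower = (dmt == "lower").astype(float)
    is_untreated = (dmt == "untreated").astype(float)
    is_ba = 1.0 if race == "BA" else 0.0
    confounder = rng.standard_normal(n)

    med_eps = rng.normal(0.0, c.med_resid_sd[race], size=n) \
        + c.confounder_strength * confounder
    out_eps = rng.normal(0.0, c.out_resid_sd[race], size=n) \
        + c.confounder_strength * confounder

    if c.mode == "linear":
        mediator = (c.med_intercept + c.alpha * is_ba + c.med_age * age
                    + c.med_dmt_lower * is_lower + c.med_dmt_untreated * is_untreated
                    + med_eps)
        prl_count = np.clip(np.rint(np.clip(mediator, 0.0, 100.0) / 100.0
                                    * flair_count), 0, flair_count).astype(np.int64)
    else:
        eta = c.count_logit_intercept + c.count_race_effect * is_ba \
            + c.count_overdisp_sd[race] * (med_eps / c.med_resid_sd[race])
        prl_count = rng.binomial(flair_count, special.expit(eta))
        mediator = 100.0 * prl_count / flair_count

    prl_volume = np.zeros(n)
    with_prl = prl_count > 0
    if with_prl.any():
        per_lesion = _lognormal_from_moments(
            rng, c.prl_lesion_volume_mean, c.prl_lesion_volume_sd,
            int(prl_count.sum()))
        prl_volume[with_prl] = np.add.reduceat(
            per_lesion, np.concatenate([[0], np.cumsum(prl_count[with_prl])[:-1]]))
    flair_volume = non_prl_volume + prl_volume

    edss = (c.out_intercept + c.gamma * is_ba + c.beta * mediator
            + c.out_age * age + c.out_dmt_lower * is_lower
            + c.out_dmt_untreated * is_untreated
            + c.out_non_prl_volume * non_prl_volume + out_eps)
    if c.round_edss:
        edss = np.clip(np.rint(edss * 2.0) / 2.0, 0.0, 9.5)

    df = pd.DataFrame({
        "patient_id": [f"{race}-{i:05d}" for i in range(n)],
        "race": race,
        "age": age,
        "sex": sex,
        "disease_duration": duration,
        "dmt": dmt,
        "zip_income": income,
        "flair_count": flair_count,
        "flair_volume": flair_volume,
        "prl_count": prl_count,
        "prl_percentage": mediator,
        "non_prl_volume": non_prl_volume,
        "edss": edss,
    })
    latents = pd.DataFrame({
        "mediator_resid": med_eps,
        "outcome_resid": out_eps,
        "confounder": confounder,
    })
    return df, latents


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Generate a cohort under the structural model; bit-reproducible by seed.

    In count mode the logit-normal deviate of the rim-probability model reuses
    the mediator disturbance (scaled to unit variance), so the confounder
    channel perturbs the mediator in both modes through the same path.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    frames, latent_frames = [], []
    for race, n in (("BA", config.n_ba), ("WA", config.n_wa)):
        df, latents = _generate_group(rng, config, race, n)
        frames.append(df)
        latent_frames.append(latents)
    df = pd.concat(frames, ignore_index=True)[COLUMNS]
    latents = pd.concat(latent_frames, ignore_index=True) if config.keep_latents else None
    return CohortTable(df=df, seed=config.seed, mode=config.mode,
                       config_digest=config.digest(), latents=latents)
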