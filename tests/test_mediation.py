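"""Mediation point estimates, identities, and bootstrap machinery."""

import numpy as np
import pytest

from prl_mediation.errors import (ConfigurationError, InsufficientDataError,
                                  ResamplingDegeneracyError)
from prl_mediation.generate import GeneratorConfig, generate_cohort
from prl_mediation.mediation import (bootstrap_mediation, bootstrap_pvalue,
                                     percentile_ci, point_estimates,
                                     point_from_coefficients, pvalue_display)
from prl_mediation.models import (ModelSpec, build_design, default_spec,
                                  fit_named_model, fit_spec,
                                  mediation_base_spec)


class TestPointEstimates:
    def test_published_coefficients_reproduce_headline_quantities(self):
        # alpha = 4.65, beta = 0.021, direct effect 0.60
        pe = point_from_coefficients(4.65, 0.021, 0.60)
        assert pe.acme == pytest.approx(0.09765, rel=1e-12)
        assert pe.total_effect == pytest.approx(0.69765, rel=1e-12)
        assert pe.prop_mediated == pytest.approx(0.1400, abs=5e-4)
        assert round(pe.acme, 2) == 0.10

    def test_zero_mediator_effect_means_no_mediation(self):
        pe = point_from_coefficients(4.65, 0.0, 0.55)
        assert pe.acme == 0.0
        assert pe.prop_mediated == 0.0
        assert pe.total_effect == pe.ade

    def test_tiny_total_effect_flags_proportion_undefined(self):
        pe = point_from_coefficients(1.0, 1e-9, -1e-9)
        assert not pe.prop_defined
        assert np.isnan(pe.prop_mediated)
        assert np.isfinite(pe.acme) and np.isfinite(pe.ade)

    def test_decomposition_exact_on_generated_cohorts(self):
        for seed in (1, 5, 9):
            cohort = generate_cohort(GeneratorConfig(seed=seed))
            pe = point_estimates(fit_named_model(cohort, "mediator"),
                                 fit_named_model(cohort, "outcome"))
            assert pe.acme + pe.ade == pytest.approx(pe.total_effect, rel=1e-12)

    def test_product_equals_difference_with_shared_covariates(self):
        """With the mediator model on the outcome's covariate set, the
        product of coefficients equals the total-minus-direct difference."""
        base = mediation_base_spec()
        shared_mediator = ModelSpec("mediator", response="prl_percentage",
                                    covariates=base.covariates)
        for seed in (2, 7):
            cohort = generate_cohort(GeneratorConfig(seed=seed))
            med = fit_spec(cohort, shared_mediator)
            out = fit_named_model(cohort, "outcome")
            tot = fit_spec(cohort, base)
            pe = point_estimates(med, out)
            diff = tot.coef_for("race_BA") - out.coef_for("race_BA")
            assert pe.acme == pytest.approx(diff, rel=1e-10, abs=1e-12)


class TestPercentileCI:
    def test_constant_samples_collapse(self):
        assert percentile_ci([3.0, 3.0, 3.0], 0.95) == (3.0, 3.0)

    def test_median_convention(self):
        lo, hi = percentile_ci([1.0, 2.0, 3.0], 1e-9)
        assert lo == pytest.approx(2.0)
        assert hi == pytest.approx(2.0)

    def test_linear_interpolation_of_order_statistics(self):
        samples = np.arange(1.0, 1001.0)
        lo, hi = percentile_ci(samples, 0.95)
        # h = 1 + q (n - 1) with linear interpolation
        assert lo == pytest.approx(1 + 0.025 * 999, rel=1e-12)
        assert hi == pytest.approx(1 + 0.975 * 999, rel=1e-12)

    def test_widening_level_widens_interval(self, rng):
        samples = rng.normal(size=500)
        lo90, hi90 = percentile_ci(samples, 0.90)
        lo99, hi99 = percentile_ci(samples, 0.99)
        assert lo99 < lo90 and hi99 > hi90

    def test_non_finite_rejected(self):
        with pytest.raises(InsufficientDataError):
            percentile_ci([1.0, np.nan, 2.0], 0.95)


class TestBootstrapPvalue:
    def test_symmetric_samples_near_one(self, rng):
        p = bootstrap_pvalue(rng.normal(0, 1, 10000))
        assert p > 0.9

    def test_all_positive_reported_as_upper_bound(self, rng):
        samples = rng.uniform(0.1, 1.0, 500)
        p = bootstrap_pvalue(samples)
        assert p == 0.0
        assert pvalue_display(p, 500) == "< 0.004"

    def test_direct_counting(self):
        samples = np.concatenate([np.full(975, 1.0), np.full(25, -1.0)])
        assert bootstrap_pvalue(samples) == pytest.approx(0.05)

    def test_needs_at_least_100_samples(self):
        with pytest.raises(InsufficientDataError):
            bootstrap_pvalue(np.ones(50))


class TestBootstrap:
    def test_null_cohort_ci_contains_zero(self):
        config = GeneratorConfig(alpha=0.0, beta=0.0, seed=13)
        cohort = generate_cohort(config)
        res = bootstrap_mediation(cohort, n_boot=2000, seed=21)
        lo, hi = res.ci["acme"]
        assert lo <= 0.0 <= hi

    def test_seeded_bootstrap_reproducible(self, linear_cohort):
        a = bootstrap_mediation(linear_cohort, n_boot=500, seed=5)
        b = bootstrap_mediation(linear_cohort, n_boot=500, seed=5)
        assert a.to_json() == b.to_json()

    def test_matches_independent_loop_over_same_index_stream(self):
        """The vectorized bootstrap equals a naive per-replicate refit fed
        the identical resample index stream."""
        cohort = generate_cohort(GeneratorConfig(n_ba=10, n_wa=10, seed=8))
        n_boot, seed = 120, 44
        # age-only covariates: no sparse dummy can vanish from a resample
        med_spec = ModelSpec("mediator", response="prl_percentage",
                             covariates=("age",))
        out_spec = ModelSpec("outcome", response="edss",
                             covariates=("prl_percentage", "age"))
        res = bootstrap_mediation(cohort, mediator_spec=med_spec,
                                  outcome_spec=out_spec,
                                  n_boot=n_boot, seed=seed)
        Xm, names_m, ym = build_design(cohort, med_spec)
        Xo, names_o, yo = build_design(cohort, out_spec)
        n = len(cohort)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        acmes = np.empty(n_boot)
        for b in range(n_boot):
            rows = idx[b]
            cm, *_ = np.linalg.lstsq(Xm[rows], ym[rows], rcond=None)
            co, *_ = np.linalg.lstsq(Xo[rows], yo[rows], rcond=None)
            acmes[b] = cm[names_m.index("race_BA")] * co[names_o.index("prl_percentage")]
        lo, hi = np.quantile(acmes, [0.025, 0.975])
        assert res.n_redrawn == 0
        assert res.ci["acme"][0] == pytest.approx(lo, rel=1e-8, abs=1e-12)
        assert res.ci["acme"][1] == pytest.approx(hi, rel=1e-8, abs=1e-12)

    def test_stratified_resampling_keeps_group_sizes(self, linear_cohort):
        res = bootstrap_mediation(linear_cohort, n_boot=300, seed=3, stratified=True)
        assert np.isfinite(res.acme)
        assert res.n_redrawn == 0

    def test_degenerate_cohort_exceeds_redraw_cap(self):
        # 20 patients, but race nearly constant: many resamples lose the
        # minority group entirely and the redraw cap trips
        cohort = generate_cohort(GeneratorConfig(n_ba=1, n_wa=19, seed=2))
        with pytest.raises(ResamplingDegeneracyError):
            bootstrap_mediation(cohort, n_boot=500, seed=10)

    def test_parameter_validation(self, linear_cohort):
        with pytest.raises(ConfigurationError):
            bootstrap_mediation(linear_cohort, n_boot=50, seed=1)
        tiny = generate_cohort(GeneratorConfig(n_ba=5, n_wa=5, seed=1))
        with pytest.raises(InsufficientDataError):
            bootstrap_mediation(tiny, n_boot=500, seed=1)
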