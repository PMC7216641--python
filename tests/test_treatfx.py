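import math

import numpy as np
import pytest

from lipofx import (
    SamplerSettings,
    fit_panel,
    fit_treatment_model,
    inputs_from_dataset,
    percent_change,
)
from lipofx.synth import MetaboliteSpec, SyntheticConfig, generate_cohort
from lipofx.treatfx import TreatmentEffectFit, TreatmentRegressionInputs


def _simulated_inputs(n_per_arm=100, effect=0.0, seed=0, residual=0.25):
    met = MetaboliteSpec("m", baseline_log_mean=1.0, baseline_log_sd=0.4,
                         treatment_log_effect=effect, residual_log_sd=residual)
    cfg = SyntheticConfig(n_treated=n_per_arm, n_placebo=n_per_arm, metabolites=(met,), seed=seed)
    return inputs_from_dataset(generate_cohort(cfg), "m")


def _mcse(fit, name):
    d = fit.draws[name]
    return float(d.std() / math.sqrt(max(fit.ess_min, 1.0)))


class TestFitTreatmentModel:
    def test_null_effect_centered_at_zero(self, quick_sampler):
        fit = fit_treatment_model(_simulated_inputs(effect=0.0), sampler=quick_sampler)
        assert abs(fit.draws["beta_T"].mean()) < 2 * _mcse(fit, "beta_T") + 0.05

    def test_recovers_halving_effect(self, quick_sampler):
        fit = fit_treatment_model(
            _simulated_inputs(n_per_arm=200, effect=math.log(0.5), seed=42),
            sampler=quick_sampler,
        )
        assert fit.draws["beta_T"].mean() == pytest.approx(math.log(0.5), abs=0.05)

    def test_flat_priors_match_least_squares(self):
        # inflating the priors 1000x makes the posterior mean collapse onto
        # OLS on the log outcomes
        inp = _simulated_inputs(n_per_arm=100, effect=math.log(0.7), seed=7)
        fit = fit_treatment_model(
            inp, sampler=SamplerSettings(chains=4, iterations_per_chain=1500, seed=2),
            prior_scale=2500.0, prior_sigma_scale=2500.0,
        )
        X = np.column_stack([np.ones(inp.n), inp.T, inp.x])
        ols = np.linalg.lstsq(X, np.log(inp.y), rcond=None)[0]
        for i, name in enumerate(["intercept", "beta_T", "beta_x"]):
            assert abs(fit.draws[name].mean() - ols[i]) < 2 * _mcse(fit, name)

    def test_outcome_scaling_shifts_only_intercept(self, quick_sampler):
        inp = _simulated_inputs(n_per_arm=80, effect=math.log(0.8), seed=3)
        shifted = TreatmentRegressionInputs(
            y=inp.y * math.e, y_status=inp.y_status, x=inp.x, T=inp.T, S=inp.S, E=inp.E,
            lod_floor=inp.lod_floor * math.e,
        )
        f0 = fit_treatment_model(inp, sampler=quick_sampler)
        f1 = fit_treatment_model(shifted, sampler=quick_sampler)
        tol = 3 * (_mcse(f0, "beta_T") + _mcse(f1, "beta_T"))
        assert abs(f1.draws["beta_T"].mean() - f0.draws["beta_T"].mean()) < tol
        assert f1.draws["intercept"].mean() - f0.draws["intercept"].mean() == pytest.approx(
            1.0, abs=3 * (_mcse(f0, "intercept") + _mcse(f1, "intercept"))
        )

    def test_two_seeds_agree(self):
        inp = _simulated_inputs(n_per_arm=60, effect=math.log(0.9), seed=5)
        fits = [
            fit_treatment_model(inp, sampler=SamplerSettings(chains=2, iterations_per_chain=1500, seed=s))
            for s in (1, 99)
        ]
        tol = 3 * (_mcse(fits[0], "beta_T") + _mcse(fits[1], "beta_T"))
        assert abs(fits[0].draws["beta_T"].mean() - fits[1].draws["beta_T"].mean()) < tol

    def test_underpopulated_arm_rejected(self, quick_sampler):
        inp = _simulated_inputs(n_per_arm=10)
        inp.y_status[inp.T == 1] = "qc_rejected"
        inp.y[inp.T == 1] = np.nan
        with pytest.raises(ValueError, match="observed outcomes"):
            fit_treatment_model(inp, sampler=quick_sampler)

    def test_constant_indicator_dropped(self, quick_sampler):
        inp = _simulated_inputs(n_per_arm=30)
        inp.S[:] = 0.0
        fit = fit_treatment_model(inp, adjust_lipid_lowering=True, sampler=quick_sampler)
        assert "beta_S" in fit.dropped_terms
        assert "beta_E" in fit.draws or "beta_E" in fit.dropped_terms

    def test_unstandardized_baseline_rejected(self):
        inp = _simulated_inputs(n_per_arm=10)
        with pytest.raises(ValueError, match="standardized"):
            TreatmentRegressionInputs(
                y=inp.y, y_status=inp.y_status, x=inp.x + 5.0, T=inp.T, S=inp.S, E=inp.E,
                lod_floor=inp.lod_floor,
            )


class TestCensoredImputation:
    @pytest.fixture(scope="class")
    def censored_fit(self):
        from lipofx import apply_missingness

        met = MetaboliteSpec("m", baseline_log_mean=math.log(10.0), baseline_log_sd=0.4,
                             treatment_log_effect=math.log(0.4), residual_log_sd=0.25, lod=4.0)
        cfg = SyntheticConfig(n_treated=16, n_placebo=14, metabolites=(met,),
                              qc_missing_prob=0.02, seed=17)
        ds = apply_missingness(generate_cohort(cfg), cfg)
        inp = inputs_from_dataset(ds, "m")
        settings = SamplerSettings(chains=2, iterations_per_chain=1000, seed=17)
        return inp, fit_treatment_model(inp, sampler=settings)

    def test_every_censored_draw_respects_the_detection_floor(self, censored_fit):
        inp, fit = censored_fit
        below = fit.missing_kind == "below_lod"
        assert below.any()
        draws = fit.imputed[:, :, below]
        assert (draws > 0).all()
        assert (draws < fit.lod_floor).all()

    def test_mar_draws_are_unconstrained_positive(self, censored_fit):
        _, fit = censored_fit
        mar = fit.missing_kind == "qc_rejected"
        if mar.any():
            assert (fit.imputed[:, :, mar] > 0).all()

    def test_sigma_draws_positive(self, censored_fit):
        _, fit = censored_fit
        assert (fit.draws["sigma"] > 0).all()


class TestPercentChange:
    def _fit_with_constant_beta(self, value):
        draws = {k: np.zeros((2, 500)) for k in ("intercept", "beta_T", "beta_x", "sigma")}
        draws["beta_T"] = np.full((2, 500), value)
        return TreatmentEffectFit(
            draws=draws, imputed=np.empty((2, 500, 0)), missing_index=np.array([], int),
            missing_kind=np.array([], object), lod_floor=1.0, adjusted=False,
            rhat_max=1.0, ess_min=1000.0, converged=True,
        )

    def test_zero_effect_gives_zero_percent(self):
        s = percent_change(self._fit_with_constant_beta(0.0))
        assert (s.mean, s.ci_low, s.ci_high) == (0.0, 0.0, 0.0)

    def test_seventeen_percent_reduction(self):
        s = percent_change(self._fit_with_constant_beta(math.log(0.83)))
        assert s.mean == pytest.approx(17.0)

    def test_reduction_bounded_at_one_hundred(self):
        s = percent_change(self._fit_with_constant_beta(-50.0))
        assert s.mean == pytest.approx(100.0)
        assert s.ci_high <= 100.0

    def test_increase_reported_negative(self):
        s = percent_change(self._fit_with_constant_beta(math.log(1.13)))
        assert s.mean == pytest.approx(-13.0)


class TestFitPanel:
    def test_empty_analyte_list(self, paper_like_cohort, quick_sampler):
        out = fit_panel(paper_like_cohort, [], sampler=quick_sampler)
        assert out.empty

    def test_absent_analyte_skipped_and_rest_fitted(self, paper_like_cohort, quick_sampler):
        out = fit_panel(paper_like_cohort, ["NOT_A_METABOLITE", "Lp_a"], sampler=quick_sampler)
        assert out["target"].tolist() == ["Lp_a"]
        assert out.attrs["skipped"] == [("NOT_A_METABOLITE", "not present in dataset")]

    def test_catalog_ordering_and_truth_ordering(self, paper_like_cohort):
        settings = SamplerSettings(chains=2, iterations_per_chain=800, seed=5)
        analytes = ["M_LDL_P", "XS_VLDL_P", "M_VLDL_P"]
        out = fit_panel(paper_like_cohort, analytes, sampler=settings)
        # rows come back in catalog order regardless of request order
        assert out["target"].tolist() == ["M_VLDL_P", "XS_VLDL_P", "M_LDL_P"]

    def test_reproducible_under_fixed_seed(self, paper_like_cohort):
        settings = SamplerSettings(chains=2, iterations_per_chain=600, seed=9)
        a = fit_panel(paper_like_cohort, ["Lp_a"], sampler=settings)
        b = fit_panel(paper_like_cohort, ["Lp_a"], sampler=settings)
        assert a["mean"].tolist() == b["mean"].tolist()

    def test_fully_censored_arm_isolated(self, quick_sampler):
        mets = (
            MetaboliteSpec("good", 2.0, 0.3, residual_log_sd=0.2),
            MetaboliteSpec("bad", 2.0, 0.3, treatment_log_effect=-6.0,
                           residual_log_sd=0.2, lod=1.0),
        )
        cfg = SyntheticConfig(n_treated=12, n_placebo=12, metabolites=mets, seed=21)
        from lipofx import apply_missingness

        ds = apply_missingness(generate_cohort(cfg), cfg)
        out = fit_panel(ds, ["good", "bad"], sampler=quick_sampler)
        assert "good" in out["target"].tolist()
        skipped_names = [s[0] for s in out.attrs["skipped"]]
        assert skipped_names == ["bad"]
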