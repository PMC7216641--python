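import math

import numpy as np
import pytest

from lipofx import (
    CohortDataset,
    SamplerSettings,
    baseline_effect_correlation,
    fit_multilevel,
    run_all_subclasses,
)
from lipofx.mlmv import MultilevelFit, prior_rho_interval
from lipofx.synth import MetaboliteSpec, SubjectHyper, SyntheticConfig, generate_cohort

LPA = "Lp_a"
SUB = "M_VLDL_P"


def _pair_cohort(n_subjects=50, rho=-0.5, seed=0, sds=(0.30, 0.10, 0.35, 0.25)):
    """Treated-arm cohort from the coupled bivariate hierarchy."""
    sds = np.asarray(sds)
    corr = np.eye(4)
    corr[0, 3] = corr[3, 0] = rho
    hyper = SubjectHyper(
        mean=(math.log(230), math.log(0.83), math.log(10), math.log(0.5)),
        cov=np.outer(sds, sds) * corr,
    )
    mets = (
        MetaboliteSpec(LPA, math.log(230), 0.30, math.log(0.83), residual_log_sd=0.15),
        MetaboliteSpec(SUB, math.log(10), 0.35, math.log(0.5), residual_log_sd=0.25),
    )
    resid = np.array([[0.0225, 0.0054], [0.0054, 0.0324]])
    cfg = SyntheticConfig(
        n_treated=n_subjects, n_placebo=1, metabolites=mets, subject_hyper=hyper,
        residual_cov=resid, lpa_id=LPA, coupled_subclass_id=SUB, seed=seed,
    )
    return generate_cohort(cfg).restrict_to_arm(1)


def _constant_sigma_fit(sigma_subj):
    n = (2, 500)
    return MultilevelFit(
        hyper_mean=np.zeros((*n, 4)),
        sigma_subj=np.broadcast_to(sigma_subj, (*n, 4, 4)).copy(),
        sigma_resid=np.broadcast_to(np.eye(2), (*n, 2, 2)).copy(),
        subject_effects=np.zeros((*n, 4, 4)),
        rho=np.full(n, sigma_subj[0, 3] / math.sqrt(sigma_subj[0, 0] * sigma_subj[3, 3])),
        subject_ids=[f"s{i}" for i in range(4)],
        subclass_id=SUB, lpa_id=LPA, n_below_lod=0,
        rhat_max=1.0, ess_min=1000.0, converged=True,
    )


class TestCorrelationClosedForms:
    def test_identity_covariance_gives_zero(self):
        s = baseline_effect_correlation(_constant_sigma_fit(np.eye(4)))
        assert (s.mean, s.ci_low, s.ci_high) == (0.0, 0.0, 0.0)

    def test_known_off_diagonal(self):
        sig = np.eye(4)
        sig[0, 0], sig[3, 3] = 4.0, 9.0
        sig[0, 3] = sig[3, 0] = 0.5 * 2.0 * 3.0
        s = baseline_effect_correlation(_constant_sigma_fit(sig))
        assert s.mean == pytest.approx(0.5)


class TestFitMultilevel:
    def test_recovers_negative_correlation(self):
        ds = _pair_cohort(n_subjects=50, rho=-0.5, seed=300)
        fit = fit_multilevel(ds, SUB, SamplerSettings(chains=2, iterations_per_chain=2000, seed=0))
        s = baseline_effect_correlation(fit)
        assert s.ci_low <= -0.5 <= s.ci_high
        assert s.mean == pytest.approx(-0.5, abs=0.25)

    def test_diagonal_truth_centers_near_zero(self):
        covers = 0
        for seed in range(5):
            ds = _pair_cohort(n_subjects=30, rho=0.0, seed=400 + seed)
            fit = fit_multilevel(
                ds, SUB, SamplerSettings(chains=2, iterations_per_chain=1200, seed=seed)
            )
            s = baseline_effect_correlation(fit)
            covers += s.ci_low <= 0.0 <= s.ci_high
        assert covers >= 4

    def test_rho_draws_bounded_and_sigma_positive_definite(self):
        ds = _pair_cohort(n_subjects=20, seed=8)
        fit = fit_multilevel(ds, SUB, SamplerSettings(chains=2, iterations_per_chain=800, seed=1))
        assert (np.abs(fit.rho) <= 1.0).all()
        sample = fit.sigma_subj.reshape(-1, 4, 4)[::100]
        for s in sample:
            np.linalg.cholesky(s)  # raises if not positive definite

    def test_placebo_subjects_rejected(self, paper_like_cohort, quick_sampler):
        with pytest.raises(ValueError, match="placebo"):
            fit_multilevel(paper_like_cohort, SUB, quick_sampler)

    def test_too_few_subjects_rejected(self, quick_sampler):
        ds = _pair_cohort(n_subjects=3, seed=1)
        with pytest.raises(ValueError, match="at least 4"):
            fit_multilevel(ds, SUB, quick_sampler)

    def test_absent_subclass_rejected(self, quick_sampler):
        ds = _pair_cohort(n_subjects=8, seed=1)
        with pytest.raises(ValueError, match="absent"):
            fit_multilevel(ds, "S_HDL_P", quick_sampler)

    def test_missing_sample_treated_as_latent(self, quick_sampler):
        ds = _pair_cohort(n_subjects=12, seed=5)
        drop = ds.subjects["subject_id"].iloc[0]
        meas = ds.measurements[
            ~((ds.measurements["subject_id"] == drop) & (ds.measurements["visit"] == "week16"))
        ].reset_index(drop=True)
        ds2 = CohortDataset(ds.subjects, meas, ds.catalog)
        fit = fit_multilevel(ds2, SUB, quick_sampler)
        assert drop in fit.subject_ids
        assert np.isfinite(fit.rho).all()

    def test_hierarchy_collapses_with_tiny_subject_variance(self, quick_sampler):
        # when the generator's subject-level spread vanishes, the fitted
        # subject effects shrink onto the population means
        ds = _pair_cohort(n_subjects=20, seed=9, sds=(0.02, 0.02, 0.02, 0.02))
        fit = fit_multilevel(ds, SUB, quick_sampler)
        dev = fit.subject_effects - fit.hyper_mean[:, :, None, :]
        assert np.abs(dev.mean(axis=(0, 1))).max() < 0.25
        assert fit.sigma_subj.reshape(-1, 4, 4)[:, [0, 1, 2, 3], [0, 1, 2, 3]].mean() < 0.05

    def test_subject_percent_change_table(self):
        ds = _pair_cohort(n_subjects=10, seed=2)
        fit = fit_multilevel(ds, SUB, SamplerSettings(chains=2, iterations_per_chain=600, seed=3))
        tab = fit.subject_percent_change()
        assert len(tab) == 10
        assert (tab["reduction_low"] <= tab["reduction_mean"]).all()
        assert (tab["reduction_mean"] <= tab["reduction_high"]).all()
        # configured 50% mean reduction should be in the right ballpark
        assert 20 < tab["reduction_mean"].mean() < 75


class TestDegenerateCensoring:
    def test_fully_censored_subclass_is_uninformative(self, paper_like_config):
        from lipofx import apply_missingness, generate_cohort as gen

        ds = apply_missingness(gen(paper_like_config), paper_like_config)
        meas = ds.measurements.copy()
        treated = set(ds.arm_subjects(1))
        mask = (
            (meas["metabolite_id"] == "XL_VLDL_P")
            & (meas["visit"] == "week16")
            & meas["subject_id"].isin(treated)
        )
        meas.loc[mask, "status"] = "below_lod"
        meas.loc[mask, "concentration"] = np.nan
        ds2 = CohortDataset(ds.subjects, meas, ds.catalog).restrict_to_arm(1)
        fit = fit_multilevel(
            ds2, "XL_VLDL_P", SamplerSettings(chains=2, iterations_per_chain=2000, seed=3)
        )
        s = baseline_effect_correlation(fit)
        # with the post-treatment channel unobserved the correlation is
        # essentially unidentified: a wide CI straddling zero
        assert s.ci_low < -0.4 and s.ci_high > 0.4
        plo, phi = prior_rho_interval()
        assert (s.ci_high - s.ci_low) >= 0.7 * (phi - plo)


class TestRunAllSubclasses:
    @pytest.fixture(scope="class")
    def small_panel(self):
        """Treated arm with Lp(a) coupled only to medium VLDL; two other
        subclasses generated independently."""
        sds = np.array([0.30, 0.10, 0.35, 0.25])
        corr = np.eye(4)
        corr[0, 3] = corr[3, 0] = -0.6
        hyper = SubjectHyper(
            mean=(math.log(230), math.log(0.83), math.log(10), math.log(0.5)),
            cov=np.outer(sds, sds) * corr,
        )
        mets = (
            MetaboliteSpec(LPA, math.log(230), 0.30, math.log(0.83), residual_log_sd=0.15),
            MetaboliteSpec(SUB, math.log(10), 0.35, math.log(0.5), residual_log_sd=0.25),
            MetaboliteSpec("IDL_P", math.log(150), 0.4, math.log(0.47), residual_log_sd=0.25),
            MetaboliteSpec("S_HDL_P", math.log(5000), 0.4, 0.0, residual_log_sd=0.25),
        )
        cfg = SyntheticConfig(
            n_treated=40, n_placebo=1, metabolites=mets, subject_hyper=hyper,
            residual_cov=np.array([[0.0225, 0.0054], [0.0054, 0.0324]]),
            lpa_id=LPA, coupled_subclass_id=SUB, seed=77,
        )
        return generate_cohort(cfg).restrict_to_arm(1)

    def test_only_coupled_subclass_correlates(self, small_panel):
        settings = SamplerSettings(chains=2, iterations_per_chain=1500, seed=4)
        out = run_all_subclasses(small_panel, settings).set_index("subclass")
        assert out.loc[SUB, "rho_mean"] < -0.3
        for other in ("IDL_P", "S_HDL_P"):
            assert out.loc[other, "ci_low"] <= 0.0 <= out.loc[other, "ci_high"]

    def test_catalog_order_and_skips(self, small_panel):
        settings = SamplerSettings(chains=2, iterations_per_chain=400, seed=4)
        out = run_all_subclasses(small_panel, settings)
        assert out["subclass"].tolist() == ["M_VLDL_P", "IDL_P", "S_HDL_P"]
        assert len(out.attrs["skipped"]) == 11

    def test_seed_for_seed_repeatability(self, small_panel):
        settings = SamplerSettings(chains=2, iterations_per_chain=400, seed=12)
        a = run_all_subclasses(small_panel, settings)
        b = run_all_subclasses(small_panel, settings)
        assert a["rho_mean"].tolist() == b["rho_mean"].tolist()
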