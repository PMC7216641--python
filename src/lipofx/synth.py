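"""Synthetic two-arm cohort generator.

The restricted trial data (30 subjects with elevated Lp(a): 16 on the
PCSK9 inhibitor, 14 on placebo; NMR metabolomics at baseline and week 16)
are emulated by a generative model that is the exact inverse of the two
inference models in this package:

* every metabolite's baseline concentration is lognormal, and the week-16
  log concentration regresses to the metabolite mean (coefficient 0.8 by
  default) plus additive log-scale treatment / statin / ezetimibe effects
  and lognormal noise — the structure the treatment-effect regression
  assumes;
* one designated (Lp(a), subclass) pair is generated from the multilevel
  hierarchy instead: per-subject quadruples (α_L, β_L, α_y, β_y) from a
  4-variate normal with covariance Σ_subj, and per-sample bivariate
  lognormal noise with covariance Σ — so corr(α_L, β_y) is a known,
  recoverable truth;
* missingness is applied afterwards: values under a per-metabolite limit
  of detection become ``below_lod``, and surviving values are QC-rejected
  independently at a fixed rate.  The uncensored values are retained in a
  hidden truth channel that is never serialized.

One master seed drives four independent sub-streams (covariates, subject
effects, residuals, missingness), so toggling missingness does not change
the underlying concentrations.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .panel import MEASUREMENT_COLUMNS, CohortDataset, SubclassCatalog

__all__ = [
    "MetaboliteSpec",
    "SubjectHyper",
    "SyntheticConfig",
    "generate_cohort",
    "apply_missingness",
    "make_paper_like_config",
]

LPA_ID = "Lp_a"


@dataclasses.dataclass(frozen=True)
class MetaboliteSpec:
    """Generative parameters for one metabolite (all effects on the log scale)."""

    metabolite_id: str
    baseline_log_mean: float
    baseline_log_sd: float
    treatment_log_effect: float = 0.0
    statin_log_effect: float = 0.0
    ezetimibe_log_effect: float = 0.0
    residual_log_sd: float = 0.25
    lod: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_log_sd <= 0 or self.residual_log_sd <= 0:
            raise ValueError("log SDs must be positive")
        if self.lod < 0:
            raise ValueError("lod must be non-negative")


def _check_pd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} must be positive definite") from exc
    return mat


@dataclasses.dataclass(frozen=True)
class SubjectHyper:
    """Hyper-parameters of the subject-effect hierarchy for the coupled pair.

    ``mean`` is (θ_L, γ_L, θ_y, γ_y); ``cov`` the 4×4 Σ_subj.
    """

    mean: tuple[float, float, float, float]
    cov: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cov", _check_pd(np.asarray(self.cov), "Σ_subj"))
        if len(self.mean) != 4:
            raise ValueError("hyper mean must have 4 components")

    @property
    def rho(self) -> float:
        """The implied corr(α_L, β_y) — the generator's correlation truth."""
        c = self.cov
        return float(c[0, 3] / math.sqrt(c[0, 0] * c[3, 3]))


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification of a synthetic cohort."""

    n_treated: int
    n_placebo: int
    metabolites: tuple[MetaboliteSpec, ...]
    statin_prob: float = 0.6
    ezetimibe_prob: float = 0.23
    qc_missing_prob: float = 0.0
    subject_hyper: SubjectHyper | None = None
    residual_cov: np.ndarray | None = None  # 2×2, for the coupled pair
    lpa_id: str = LPA_ID
    coupled_subclass_id: str | None = None
    regression_to_mean: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_treated, self.n_placebo) < 1:
            raise ValueError("arm sizes must be >= 1")
        for p in (self.statin_prob, self.ezetimibe_prob, self.qc_missing_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        if self.residual_cov is not None:
            object.__setattr__(self, "residual_cov", _check_pd(self.residual_cov, "residual_Σ"))
        if self.coupled_subclass_id is not None:
            if self.subject_hyper is None or self.residual_cov is None:
                raise ValueError("coupled pair requires subject_hyper and residual_cov")
            ids = {m.metabolite_id for m in self.metabolites}
            for mid in (self.lpa_id, self.coupled_subclass_id):
                if mid not in ids:
                    raise ValueError(f"coupled metabolite {mid} missing from metabolite list")

    def metabolite(self, metabolite_id: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.metabolite_id == metabolite_id:
                return m
        raise KeyError(metabolite_id)

    def _streams(self) -> dict[str, np.random.Generator]:
        kids = np.random.SeedSequence(self.seed).spawn(4)
        names = ("covariates", "subject_effects", "residuals", "missingness")
        return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


def generate_cohort(config: SyntheticConfig, catalog: SubclassCatalog | None = None) -> CohortDataset:
    """Draw a fully observed cohort; deterministic under a fixed seed."""
    streams = config._streams()
    rng_cov = streams["covariates"]
    rng_subj = streams["subject_effects"]
    rng_res = streams["residuals"]

    n = config.n_treated + config.n_placebo
    ids = [f"S{i + 1:03d}" for i in range(n)]
    arm = np.array([1] * config.n_treated + [0] * config.n_placebo)
    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "arm": arm,
            "statin": (rng_cov.uniform(size=n) < config.statin_prob).astype(int),
            "ezetimibe": (rng_cov.uniform(size=n) < config.ezetimibe_prob).astype(int),
        }
    )

    pair = (
        {config.lpa_id, config.coupled_subclass_id}
        if config.coupled_subclass_id is not None
        else set()
    )
    logc: dict[str, np.ndarray] = {}  # metabolite -> (n, 2 visits)

    for spec in config.metabolites:
        if spec.metabolite_id in pair:
            continue
        base = spec.baseline_log_mean + spec.baseline_log_sd * rng_subj.standard_normal(n)
        drift = config.regression_to_mean * (base - spec.baseline_log_mean)
        effect = (
            spec.treatment_log_effect * arm
            + spec.statin_log_effect * subjects["statin"].to_numpy()
            + spec.ezetimibe_log_effect * subjects["ezetimibe"].to_numpy()
        )
        wk16 = (
            spec.baseline_log_mean + drift + effect
            + spec.residual_log_sd * rng_res.standard_normal(n)
        )
        logc[spec.metabolite_id] = np.column_stack([base, wk16])

    if pair:
        hyper = config.subject_hyper
        U = rng_subj.multivariate_normal(np.asarray(hyper.mean), hyper.cov, size=n)
        noise = rng_res.multivariate_normal(np.zeros(2), config.residual_cov, size=(n, 2))
        # treatment effects express only in the treated arm
        logL = np.column_stack([U[:, 0], U[:, 0] + U[:, 1] * arm]) + noise[:, :, 0]
        logY = np.column_stack([U[:, 2], U[:, 2] + U[:, 3] * arm]) + noise[:, :, 1]
        logc[config.lpa_id] = logL
        logc[config.coupled_subclass_id] = logY

    rows = []
    for spec in config.metabolites:
        vals = logc[spec.metabolite_id]
        for i, sid in enumerate(ids):
            for v, visit in enumerate(("baseline", "week16")):
                rows.append((sid, visit, spec.metabolite_id, math.exp(vals[i, v]), "observed"))
    measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return CohortDataset(subjects, measurements, catalog or SubclassCatalog())


def apply_missingness(dataset: CohortDataset, config: SyntheticConfig) -> CohortDataset:
    """Censor below-LOD values and QC-reject at random; keep a truth channel.

    The input must be fully observed.  Uses the missingness sub-stream of
    the config seed, so the retained values are identical to the fully
    observed dataset's.
    """
    if (dataset.measurements["status"] != "observed").any():
        raise ValueError("apply_missingness expects a fully observed dataset")
    rng = config._streams()["missingness"]
    meas = dataset.measurements.copy()
    truth = dataset.measurements.copy()
    lod = {m.metabolite_id: m.lod for m in config.metabolites}
    lod_vec = meas["metabolite_id"].map(lod).fillna(0.0).to_numpy(dtype=float)
    conc = meas["concentration"].to_numpy(dtype=float)
    is_below = conc < lod_vec
    qc = (~is_below) & (rng.uniform(size=len(meas)) < config.qc_missing_prob)
    meas.loc[is_below, "status"] = "below_lod"
    meas.loc[qc, "status"] = "qc_rejected"
    meas.loc[is_below | qc, "concentration"] = np.nan
    return CohortDataset(dataset.subjects, meas, dataset.catalog, truth)


#: Printed posterior-mean percent reductions used as generator truths:
#: the 14 subclass particle concentrations (negative = increase), plus the
#: headline Lp(a) / LDL-C / triglyceride effects.  Large/small HDL showed
#: no credible change and are set to 0.
PAPER_REDUCTIONS_PCT: dict[str, float] = {
    "XXL_VLDL_P": 80.0,
    "XL_VLDL_P": 90.0,
    "L_VLDL_P": 60.0,
    "M_VLDL_P": 50.0,
    "S_VLDL_P": 39.0,
    "XS_VLDL_P": 47.0,
    "IDL_P": 53.0,
    "L_LDL_P": 56.0,
    "M_LDL_P": 59.0,
    "S_LDL_P": 55.0,
    "XL_HDL_P": 24.0,
    "L_HDL_P": 0.0,
    "M_HDL_P": -13.0,
    "S_HDL_P": 0.0,
    LPA_ID: 17.0,
    "LDL_C": 67.0,
    "Serum_TG": 21.0,
}

#: Baseline geometric means (concentration units as measured: nmol/L for
#: Lp(a) and particle counts, mmol/L for LDL-C and triglycerides) — chosen
#: as plausible values for an elevated-Lp(a) population; the log scale of
#: the models makes the absolute level immaterial to effect recovery.
_BASELINE_GM: dict[str, float] = {
    "XXL_VLDL_P": 0.03,
    "XL_VLDL_P": 0.2,
    "L_VLDL_P": 2.0,
    "M_VLDL_P": 10.0,
    "S_VLDL_P": 30.0,
    "XS_VLDL_P": 40.0,
    "IDL_P": 150.0,
    "L_LDL_P": 180.0,
    "M_LDL_P": 160.0,
    "S_LDL_P": 180.0,
    "XL_HDL_P": 300.0,
    "L_HDL_P": 1200.0,
    "M_HDL_P": 2000.0,
    "S_HDL_P": 5000.0,
    LPA_ID: 230.0,
    "LDL_C": 3.5,
    "Serum_TG": 1.35,
}


def make_paper_like_config(seed: int = 0) -> SyntheticConfig:
    """A cohort specification mirroring the trial's published structure.

    16 treated / 14 placebo subjects; log-scale treatment effects
    ln(1 − r) for each printed percent reduction r; the medium-VLDL /
    Lp(a) pair coupled through Σ_subj with corr(α_L, β_y) = −0.5; limits
    of detection on the two largest VLDL fractions set at 40% of their
    baseline geometric mean, so they are frequently censored after an
    80–90% reduction; 2% QC rejection.
    """
    mets = []
    for mid, red in PAPER_REDUCTIONS_PCT.items():
        gm = _BASELINE_GM[mid]
        wide = mid in ("XXL_VLDL_P", "XL_VLDL_P")
        mets.append(
            MetaboliteSpec(
                metabolite_id=mid,
                baseline_log_mean=math.log(gm),
                baseline_log_sd=0.8 if wide else (0.30 if mid == LPA_ID else 0.4),
                treatment_log_effect=math.log(1.0 - red / 100.0),
                residual_log_sd=0.15 if mid == LPA_ID else 0.25,
                lod=0.4 * gm if wide else 0.0,
            )
        )
    sds = np.array([0.30, 0.10, 0.35, 0.25])  # (α_L, β_L, α_y, β_y)
    corr = np.eye(4)
    corr[0, 3] = corr[3, 0] = -0.5
    cov = np.outer(sds, sds) * corr
    hyper = SubjectHyper(
        mean=(math.log(230.0), math.log(0.83), math.log(10.0), math.log(0.5)),
        cov=cov,
    )
    resid = np.array([[0.15**2, 0.2 * 0.15 * 0.18], [0.2 * 0.15 * 0.18, 0.18**2]])
    return SyntheticConfig(
        n_treated=16,
        n_placebo=14,
        metabolites=tuple(mets),
        statin_prob=0.6,
        ezetimibe_prob=0.23,
        qc_missing_prob=0.02,
        subject_hyper=hyper,
        residual_cov=resid,
        lpa_id=LPA_ID,
        coupled_subclass_id="M_VLDL_P",
        seed=seed,
    )
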