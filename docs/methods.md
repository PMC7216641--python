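# Methods

## Setting and data model

The package targets a two-arm, two-visit trial: 16 subjects on a PCSK9
inhibitor and 14 on placebo, each with plasma NMR metabolomics at
baseline and week 16. Measurements arrive as long-format records
(subject × visit × metabolite) with three statuses: `observed` (a
strictly positive concentration), `below_lod` (under the platform's
limit of detection), and `qc_rejected` (removed by the platform's
automatic quality control). The 14 lipoprotein subclasses (6 VLDL, IDL,
3 LDL, 4 HDL, identified by average particle diameter from >75 nm down
to 8.7 nm) carry a canonical ordering used for all tabular and graphical
output. Concentrations are analysed on the natural-log scale
throughout; unit conversions (cholesterol ×38.7, triglycerides ×88.6
mmol/L→mg/dL; Lp(a) ÷2.5 nmol/L→mg/dL) and the Friedewald LDL-C formula
(TC − HDL-C − TG/2.2, refused above TG 4.52 mmol/L) are provided as
small utilities.

## Treatment-effect model

For one metabolite, with week-16 concentration y, standardized log
baseline x (centered/scaled to mean 0, sample SD 1 over observed
entries; a missing baseline sits at the mean), treatment indicator T and
optional statin/ezetimibe indicators S, E:

    log y_i ~ Normal(alpha + bT*T_i + bx*x_i [+ bS*S_i + bE*E_i], sigma)

Priors: Normal(0, 2.5) on alpha and all coefficients, half-Normal(0,
2.5) on sigma; both scales are arguments, and inflating them ×1000
reproduces least squares on the log outcomes to within Monte Carlo error
(this is a standing test). An indicator that is constant in the data is
dropped with a logged notice rather than left unidentified.

Missing outcomes are model parameters sampled jointly with the
coefficients. QC-rejected entries are missing at random and get the
model's predictive Normal(mu_i, sigma); below-LOD entries get the same
conditional truncated above at log(minimal observed concentration of
that metabolite), so every imputation draw lies strictly in (0, minimal
observed value). This truncation bound — the smallest *observed* value
rather than a nominal platform LOD — is deliberate: the platform does
not publish per-metabolite LODs, and the minimal observed value is a
data-driven upper envelope for them.

The sampler is Gibbs: the coefficient block and the missing-value block
have exactly Gaussian (or truncated-Gaussian) full conditionals; sigma,
whose half-Normal prior is not conjugate, is updated by univariate slice
sampling (stepping-out and shrinkage), which needs no tuning. Default
run: 4 chains × 2000 iterations, first half discarded as warmup.
Reported effect: percent reduction 100·(1 − exp(bT)), posterior mean
with equal-tailed (2.5, 97.5) percentile interval; negative values are
increases, and the reduction is bounded above by 100% by construction.

## Multilevel bivariate model

For treated subjects only (the model describes the on-treatment change;
placebo subjects are rejected), with L = Lp(a) and y = one subclass:

    [log L_i, log y_i] ~ MVN([mu_L_i, mu_y_i], Sigma)       (per sample)
    mu_L_i = alphaL_j + betaL_j * V2_i
    mu_y_i = alphay_j + betay_j * V2_i
    [alphaL, betaL, alphay, betay]_j ~ MVN(m, Sigma_subj)   (per subject)

The reported quantity is rho = corr(alphaL, betay), computed per draw
from Sigma_subj (never from point estimates) and summarized with mean
and equal-tailed 95% CI. A subject with a missing sample keeps it as a
fully latent parameter; below-LOD entries are truncated as in the
treatment model, applied to the subclass always and to Lp(a) by a flag
(default on).

Priors: Normal(0, 5) on the four hyper-means; on both covariances a
Huang–Wand hierarchical inverse-Wishart, Sigma ~ IW(nu + p − 1,
2·nu·diag(1/a_k)) with a_k ~ InvGamma(1/2, 1/A²), A = 2.5. This keeps
every update conjugate while giving half-t(nu, A) margins on the scales
and, with nu matched per dimension (nu = 6 for the 4×4 Sigma_subj, nu =
4 for the 2×2 residual Sigma), correlation margins proportional to
(1 − rho²)² resp. (1 − rho²) — the same margins as a shape-2 LKJ
correlation prior. A fixed-scale inverse-Wishart is avoided on purpose:
with subject-level variances of order 0.01–0.1 on the log scale, a unit
prior scale crushes posterior correlations toward zero.

The Gibbs sweep is partially collapsed: latent (missing or censored)
log concentrations are updated from their marginal Gaussian with the
subject effects integrated out, and the subject effects are then redrawn
exactly. The collapse matters in the fully censored regime — with a
centered update the latent week-16 values and the subject effects move
in lock-step and the chain effectively stops (R-hat ≈ 1.7 at 20k
iterations); collapsed, the same run mixes.

### Identifiability and attenuation

With two samples per subject the subject level is saturated: 4
observations face 4 subject parameters, so the marginal covariance of a
subject's data identifies only Sigma_subj-plus-residual combinations —
the split between Sigma_subj and Sigma is underidentified by exactly
dim(Sigma) = 3 directions and is resolved by the prior. Two practical
consequences, both verified by simulation:

* the posterior mean of rho is attenuated toward zero (residual variance
  partially absorbed into Var(betay) inflates the denominator, and the
  identified cross-moment trades off against the residual L–y
  covariance). At 50 subjects with true rho = −0.5 the replicate-mean
  posterior mean sits near −0.3, while CI *coverage* of the truth stays
  at the nominal rate;
* interval widths, not point estimates, are the trustworthy summary at
  trial scale (n = 16), where sign recovery is all that should be
  claimed.

This is a property of the model class (shared with any implementation of
it), not of the sampler: with residual noise sent to zero the posterior
mean tracks each replicate's realized sample correlation to within the
prior's ~7% shrink.

When a subclass is entirely below the LOD post-treatment, betay is
informed only through a shared upper bound and rho reverts essentially
to its prior. The reporting layer flags a correlation `uninformative`
when its CI is at least 90% as wide as the prior's 95% interval for rho
(computed by Monte Carlo from the Huang–Wand prior with a fixed internal
seed); such values should not be interpreted.

## Baseline-characteristics table

Continuous variables: two-sided Wilcoxon rank-sum, exact enumeration
when both arms have n ≤ 10 without ties, normal approximation with tie
and continuity correction otherwise (both callable explicitly).
Binary traits: Pearson chi-square on the 2×2 without Yates continuity
correction — the dialect is fixed by regression tests against published
example values, all four of which reproduce only without the
correction. Display: mean (SD), median [IQR] (25th/75th percentiles,
linear interpolation), or n (%) with half-up integer rounding.

## Synthetic cohorts

The generator is the exact inverse of the two models, so recovery tests
are well-posed. Per metabolite: baseline log concentration ~
Normal(mu, sd_baseline); week-16 log concentration = mu + k·(baseline −
mu) + bT·T + bS·S + bE·E + Normal(0, sd_residual), with
regression-to-mean coefficient k = 0.8 by default — the analysis adjusts
for baseline, so the generator must induce baseline–follow-up
correlation; 0.8 reflects the high tracking of lipoprotein measures over
16 weeks. One designated (Lp(a), subclass) pair is instead generated
from the multilevel hierarchy, with per-subject quadruples from
MVN(m, Sigma_subj) and bivariate residual Sigma, treatment effects
expressed only in the treated arm. Missingness is applied afterwards:
values below a per-metabolite LOD become `below_lod`, survivors are
QC-rejected independently at a configurable rate; the uncensored values
are kept in a truth channel that is never serialized, so fits cannot
read them. One master seed drives four independent sub-streams
(covariates, subject effects, residuals, missingness), making the
retained values invariant to toggling missingness.

The trial-like default configuration uses the published posterior-mean
reductions as generating truths (Lp(a) 17%, LDL-C 67%, triglycerides
21%; subclass reductions 80/90/60/50/39/47% across VLDL, 53% IDL,
56/59/55% LDL, 24/0/−13/0% HDL — the medium-HDL value is an increase,
and the two HDL fractions with no credible published change are set to
0), arm sizes 16/14, statin/ezetimibe prevalences 0.6/0.23, 2% QC
rejection, and LODs on the two largest VLDL fractions at 40% of their
baseline geometric mean so that an 80–90% reduction pushes most treated
week-16 values below detection — reproducing the real analysis's
censoring regime. Baseline geometric means and log-SDs (0.3–0.8) are
plausible values for an elevated-Lp(a) population; the models operate on
the log scale, so absolute levels do not affect effect recovery. The
residual covariance of the coupled pair (log-SDs 0.15 and 0.18,
correlation 0.2) stands for assay plus short-term within-subject
variability. What the generator does *not* emulate: cross-metabolite
correlations beyond the designated pair, platform-specific LOD
mechanisms (a sharp threshold stands in for them), non-lognormal tails,
and informative missingness — so passing recovery tests demonstrates
correctness of the inference machinery under the stated model, not
robustness to real-data violations of it.

## Validation studies and problem sizes

`lipofx.validation` packages the replicated studies used by the test
suite and the acceptance script, at sizes chosen to keep a full run in
the minutes range on one core: flat-prior/OLS equivalence at 100
subjects/arm (4 × 1500 iterations); 100 trial-scale (16/14) replicates
for coverage and recovery of a 17% reduction, and 100 null replicates
for nominal coverage of zero (2 × 1000 each); 20 multilevel replicates
at 50 subjects (4 × 2000) plus 20 at the trial's 16 (2 × 1500) for sign
recovery; a censoring-contract check asserting every below-LOD
imputation draw falls in (0, minimal observed value); a fully censored
degenerate fit (2 × 16000 — this posterior mixes slowly by nature, see
above) compared against the prior's rho interval; and 1000 identical-arm
rank-sum p-values tested for uniformity. User-facing defaults remain
4 × 2000 everywhere.

## Numerical notes

* Credible intervals are (2.5, 97.5) percentiles with linear
  interpolation (numpy default); given the draws they are reproducible
  bit-for-bit.
* R-hat is rank-normalized split R-hat; fits with max R-hat > 1.01 are
  flagged `warn_convergence` (stricter than the classical 1.1: these
  models are small and reruns cheap). Degenerate constant chains report
  R-hat 1.
* Truncated-normal draws use inverse-CDF sampling robust in far tails
  (scipy), so censored imputations cannot escape their bounds even when
  the linear predictor sits far above the ceiling.
* Chain seeds derive from a master seed via `SeedSequence` spawning;
  panel fits give each analyte an independent substream, making whole
  tables seed-for-seed repeatable.
* Forest plots fix the SVG hash salt and strip date metadata, so
  repeated renders of the same summaries are byte-identical.
* Positive definiteness of user-supplied covariances is checked by
  Cholesky; generated Sigma draws are inverse-Wishart and hence positive
  definite by construction.

## Known limitations

* The attenuation of the posterior-mean correlation described above is
  inherent to the saturated two-visit design; a third visit or an
  informative residual prior would break the ridge.
* The treatment model fits each metabolite independently; no sharing
  across the panel and no multiplicity adjustment (credible intervals
  are reported as-is).
* The multilevel model fits one subclass at a time against Lp(a); a
  joint 15-dimensional model is out of scope.
* Exact rank-sum enumeration is limited to n ≤ 10 per arm without ties;
  beyond that the tie-corrected normal approximation is used.
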