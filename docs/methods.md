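# Methods

## The problem

Psychiatric diagnoses co-occur far beyond chance, and dimensional nosologies
(internalizing/externalizing-style spectra) summarize that comorbidity with a
small number of correlated latent liabilities. `spectra` implements the full
workflow for adjudicating such structures on binary lifetime diagnoses from
EHR-style data: tetrachoric correlation estimation, confirmatory factor
analysis (CFA) of competing structures, multi-criterion model adjudication,
and external validation — together with a liability-threshold generator that
stands in for restricted clinical cohorts so every stage is testable.

## Liability-threshold generator (`spectra.synth`)

Each person has factor scores eta ~ MVN(0, Phi) over k dimensions (default
six: Fear, Distress, Externalizing, Substance Use, Thought Problems,
Neurodevelopmental Disorders). Diagnosis j's liability is

    y*_j = lambda_j' eta + e_j,

with the unique parts e drawn jointly from MVN(0, Theta), where Theta has
uniquenesses u_j = 1 - lambda_j' Phi lambda_j on the diagonal (solved so every
liability has unit variance; loadings stay standardized) and, off the
diagonal, the correlated-residual increments for designated diagnosis pairs.
Drawing the unique parts jointly from Theta is distribution-equivalent to
adding shared components pair by pair and also covers overlapping pairs (the
ADHD-subtype triangle). Diagnosis j is recorded iff y*_j > tau_j with
tau_j = probit(1 - prevalence_j), so the model-implied tetrachoric matrix is
exactly

    Sigma = Lambda Phi Lambda' + Theta_offdiag   (unit diagonal),

which the truth object carries as the recovery oracle. Residual increments
are specified on this implied-correlation scale; the corresponding
uniqueness-level correlation is r / sqrt(u_i u_j).

Each positive (person, diagnosis) is emitted as 1–4 raw codes drawn from a
per-diagnosis synonym list with uniform event dates, so the code-clustering
stage is exercised; dates are carried but unused (lifetime diagnoses).
External correlates are linear in the factor scores: continuous (identity +
normal noise), binary (probit link; a sex-at-birth analog loading positively
on Substance Use/Externalizing and negatively on Fear/Distress), and ordinal
(latent linear score cut at fixed thresholds; income and education analogs).
All randomness derives from one seed through per-component child streams.

### Preset choices and what they do not emulate

The default preset has 39 diagnoses over six factors (sizes 7/8/5/8/6/5),
primary loadings 0.43–0.55 on Fear and Distress and 0.60–0.80 elsewhere, a
Fear–Distress factor correlation of .898 with the remaining factor
correlations between .30 and .60, six correlated residuals
(MDD–dysthymia, schizophrenia–schizoaffective, OCD–OCPD, and the three
ADHD-subtype pairs) and one cross-loading (borderline PD on Thought
Problems). Within-cohort prevalences are compressed into [0.10, 0.40]
(ordered realistically — depressive and substance diagnoses most common, tic
disorders least) so that every pairwise 2x2 table stays well populated at the
simulation sizes used here (2,000–200,000 persons): with margins much below
10%, rare-pair tetrachorics carry sampling errors larger than the recovery
tolerances the tests assert. Real EHR cohorts have far more skewed margins,
plus care-seeking, coding-drift and misclassification processes that the
generator deliberately omits; passing tests therefore demonstrate the
correctness and stability of the estimation machinery under a faithful
latent structure, not robustness to those real-data pathologies.

## Tetrachoric estimation (`spectra.tetra`)

Estimation is two-step: thresholds fixed at univariate probits of the
margins, then the liability correlation rho maximizes the bivariate-normal
likelihood of the 2x2 counts (bounded 1-D optimization on [-0.999, 0.999],
xatol 1e-10, grid-search fallback). The bivariate normal CDF uses Owen's T
function (absolute error ~1e-15). Numerical conventions:

- any table with a zero cell gets +0.5 added to every cell (margins
  recomputed); disable via `zero_cell_add=0`;
- sign is canonicalized from the odds ratio before optimizing, making the
  estimate exactly antisymmetric under recoding either variable, and exactly
  0 at an odds ratio of 1;
- diagnoses with prevalence 0 or 1 are excluded with a report (tetrachoric
  undefined);
- an indefinite pairwise matrix is smoothed by alternating projections onto
  the PSD cone and the unit-diagonal set (stop at max elementwise change
  < 1e-8 or 200 iterations).

## CFA engine (`spectra.cfa`)

Models are written in a small SEM-style language (`F =~ a + b`, `a ~~ b`,
`general: on`). The implied matrix is Sigma(theta) = Lambda Phi Lambda' +
Theta with Theta's diagonal set so diag(Sigma) = 1; fitting minimizes

    F(theta) = sum_{i<j} w_ij (r_ij - sigma_ij(theta))^2

by trust-region least squares with an analytic Jacobian, five deterministic
starts (all loadings at 0.3–0.7, factor correlations at 0.3, residuals at 0;
ties to the first start), loadings bounded to [-1.2, 1.2] and correlations to
(-1, 1). ULS (w = 1) is the default; DWLS weights are reciprocal sampling
variances from a person-level jackknife of batches. Conventions: factor
variances fixed at 1 (standardized solution); per-factor sign fixed by a
non-negative loading sum; bifactor models make all factors mutually
orthogonal; Heywood solutions (uniqueness < 0 or |loading| > 1) are flagged,
not forbidden. A just-identified model (df = 0) fits normally with
incremental indices reported as undefined.

T = (n - 1) F is a pseudo-chi-square used only comparatively. With the
zero-correlation independence model as null: CFI = 1 - max(T - df, 0) /
max(T_null - df_null, T - df, 0); TLI truncated to [0, 1]; RMSEA =
sqrt(max(T - df, 0) / (df (n - 1))); SRMR = RMS of the unique off-diagonal
residuals. Standard errors come from a person-level nonparametric bootstrap
(default B = 100) rerunning the whole pipeline per resample with factor
signs aligned to the full-sample fit, because two-step estimation
invalidates naive ML standard errors.

## Adjudication (`spectra.adjudicate`)

Alternative indices per factor: magnitude = median |loading|, consistency =
sample SD of loadings, precision = mean bootstrap SE; cross-loadings count
toward every factor they load on. Pooled versions are emitted both over all
loadings (the comparison-table convention) and as the mean of per-factor
values — the within-factor pooling is what separates a coherent structure
from random assignments when factors legitimately differ in loading level.

- **Comparison table**: one row per model (CFI/TLI/RMSEA/SRMR/FL/SD/SE plus
  direction-aware ranks); no automatic winner.
- **Random-assignment null**: K refits with diagnoses permuted across
  factors, preserving the factor-size multiset by default (unconstrained
  assignment behind a flag); cross-loadings and residual pairs dropped;
  non-converged nulls excluded and counted, Heywood nulls retained flagged.
- **Split-half**: random disjoint halves (sizes within 1), full pipeline per
  half; per model the absolute fit-index differences and the ICC of the
  loading vectors; per index an ICC across models when several are supplied.
  The ICC is two-way absolute-agreement single-measure, ICC(A,1) — both
  halves estimate the same quantity on the same scale, so systematic offsets
  should be penalized.
- **Leave-one-out**: refit with each diagnosis removed (skipped if a factor
  would fall below two indicators); cell (j, k) is the signed change in j's
  primary loading when k is removed; signed summary statistics.
- **Candidate scan**: instead of analytic modification indices, each
  candidate cross-loading / residual pair is freed alone and the model
  refitted, warm-started from the base solution so the discrepancy drop is
  never negative; candidates are ranked by delta-F and nothing is
  auto-accepted.

## External validation (`spectra.external`)

MAP factor scores maximize N(eta; 0, Phi) x prod_j Phi((lambda_j' eta -
tau_j)/sqrt(u_j))^{y_j} (1 - ...)^{1-y_j}; the log posterior is strictly
concave, so a safeguarded Newton iteration (vectorized across persons,
uniqueness floored at 0.01 for Heywood indicators) converges globally.
Each correlate is regressed on each standardized score separately — simple
OLS for continuous/ordinal (treated as numeric), probit for binary — with a
person-level bootstrap (default B = 200) reusing the same resample across
factors so the coefficient vector's covariance supports a Wald-type test of
the flat-profile hypothesis (contrasts against the first factor, generalized
inverse with a flag if the bootstrap covariance is singular). Because the
covariance is estimated from B bootstrap replicates, the statistic is
referred to Hotelling's T-squared distribution (F with q and B - q degrees
of freedom) rather than a chi-square; the chi-square reference is
anti-conservative at moderate B (empirical level ~0.07 at B = 100 and
alpha = 0.05, versus ~0.05 under the T-squared reference). Scores are
standardized by their population SD, making estimates invariant to row
duplication. Because scores are shrunken posterior modes, coefficients are
attenuated relative to latent-variable regressions; outputs carry a note and
the comparative profile across factors is the supported inference. Joint
SEM-with-covariates estimation is a documented extension point, not
implemented.

## Pipeline and reproducibility (`spectra.pipeline`)

One config drives simulate/ingest -> collapse & filter -> tetrachoric ->
model ladder -> adjudication -> external validation. Every artifact is
tab-separated text; the manifest records seeds, per-stage status and SHA-256
digests, and a rerun with the same config and seed is byte-identical
(timestamps aside). A stage failure leaves a partial manifest and a nonzero
exit.

## Problem sizes used in tests and the acceptance script

Parameter-recovery, split-half, leave-one-out and external-correlate checks
run on one preset cohort of n = 20,000; model discrimination uses 20
replicates at n = 10,000; the permutation null uses K = 100 assignments at
n = 10,000 (the analysis driver defaults to K = 1,000); tetrachoric
calibration uses 200 replicates at n = 10,000; the profile-test level check
uses 400 (tests) / 200 (script) replicates at n = 2,000 with bootstrap
B = 100. Elementwise convergence of the tetrachoric matrix to the implied
matrix is checked at n = 200,000: at n = 50,000 the maximum error over 741
pairs concentrates around 3.3x the worst-pair SE (~0.013 at prevalence 0.10),
i.e. right at the 0.03 tolerance, so the check is run where the extreme
order statistic is comfortably inside it.

## Known limitations

- Fit indices are comparative only; T is not chi-square calibrated.
- No polychoric (>2 categories), no missing-data machinery, no ESEM, no
  measurement-invariance testing across demographic groups.
- Factor-score regression attenuates external-correlate coefficients; only
  profile comparisons across dimensions are interpreted.
- The generator omits care-seeking, coding drift and misclassification; its
  prevalence floor (0.10) is above realistic rates for rare disorders.
- Permutation-null and leave-one-out refits reuse the tetrachoric matrix of
  the full sample (the data do not change across refits); bootstrap SEs are
  the only stage that re-estimates correlations per replicate.
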