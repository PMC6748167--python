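# Methods

## Background and model

Bisulfite (BS) conversion cannot distinguish 5-methylcytosine (5-mC) from
5-hydroxymethylcytosine (5-hmC): both marks resist deamination, so a BS
measurement at a CpG reports the *sum* of the two modified fractions.
Pairing BS with oxidative bisulfite (oxBS), which converts 5-hmC before the
BS step, gives a second measurement of 5-mC alone, and the 5-hmC fraction is
recovered by estimation. At every cytosine the three states partition the
alleles:

    beta_mC + beta_hmC + beta_C = 1.

This package implements three layers on top of that identity.

### 1. Constrained maximum-likelihood estimation of (beta_mC, beta_hmC)

Treating the two channels as binomial measurements with totals n_BS, n_oxBS
and modified counts m_BS, m_oxBS, the joint log-likelihood

    L(beta_mC, beta_hmC) = log Binom(m_BS; n_BS, beta_mC + beta_hmC)
                         + log Binom(m_oxBS; n_oxBS, beta_mC)

is maximized over the simplex beta_mC >= 0, beta_hmC >= 0,
beta_mC + beta_hmC <= 1. The solution is closed-form:

* if m_BS/n_BS >= m_oxBS/n_oxBS, the channel proportions themselves are the
  MLE: beta_mC = m_oxBS/n_oxBS, beta_hmC = m_BS/n_BS - m_oxBS/n_oxBS;
* otherwise the optimum sits on the boundary beta_hmC = 0, where the two
  channels measure the same quantity and the problem collapses to a single
  pooled binomial proportion beta_mC = (m_BS + m_oxBS)/(n_BS + n_oxBS).
  Such calls carry a `boundary_flag`.

Boundary clipping is one of the two sources of the zero-enrichment seen in
estimated 5-hmC (the other being genuinely unhydroxymethylated sites).
Array intensities are not integer counts; matrix inputs supply beta values
plus per-channel totals and are converted by m = round(beta * n), which
preserves the binomial form while accepting array-style data. The boundary
convention (pooled proportion for beta_mC when beta_hmC is clipped) is a
package choice: published array pipelines do not document their convention
for this case, and the pooled proportion is the exact constrained MLE under
the binomial model. A naive subtraction estimator
(beta_hmC = max(0, beta_BS - beta_oxBS)) is provided for comparison; it
coincides with the MLE when channel totals are equal and the difference is
non-negative.

### 2. Separate per-mark beta regression (the "traditional" analysis)

Each mark is regressed on group plus covariates with a beta-distributed
response, logit mean link and a single precision phi per probe:

    y ~ Beta(mu * phi, (1 - mu) * phi),   logit(mu) = X @ beta.

The mean is modeled; the precision is a constant per fit (log link,
intercept only) — dispersion is not regressed on covariates, matching the
default of the GAMLSS-style frameworks this analysis descends from.
Fitting is by maximum likelihood (delegated to statsmodels' `BetaModel`);
standard errors come from the inverse observed information. Responses are
clamped into (epsilon, 1 - epsilon) with epsilon = 1e-6 ("squeeze") because
the beta likelihood is undefined at the boundary; the low-beta filter
removes most zero-heavy probes before modeling, so the squeeze touches few
values.

### 3. The paired repeated-measures mixed model

The package's core treats the two marks measured in one sample as repeated
measures of a single outcome, "DNA modification". For sample i and mark
j in {5-mC, 5-hmC}:

    y_ij ~ Beta(mu_ij * phi, (1 - mu_ij) * phi)
    logit(mu_ij) = x_ij' beta + u_i,    u_i ~ N(0, sigma_b^2)

with fixed effects: intercept, group, modification category, the
group x modification interaction, and additive covariates (glial
proportion, age by default). The shared random intercept u_i absorbs the
within-sample correlation between the two marks — the correlation that
separate models ignore. The interaction coefficient is the quantity of
interest: under treatment coding with the control group and the 5-mC level
as references, a positive interaction means the case group shifts the
balance toward a greater proportion of 5-hmC at the probe; negative, toward
5-mC. Swapping either reference flips the sign — results always state the
coding.

The full factorial (both main effects plus the interaction) is always
fitted: interaction-only parameterizations are not invariant to coding.

**Estimation.** The marginal likelihood integrates u_i out by adaptive
Gauss–Hermite quadrature: for each sample the integrand is re-centered at
its conditional mode (1-D Newton iteration with analytic first and second
derivatives of the beta log-density on the linear-predictor scale) and
re-scaled by the conditional curvature. Nine nodes are the default;
estimates move by less than 1e-3 between 5 and 15 nodes. The fixed effects,
log sigma_b and log phi are maximized jointly by L-BFGS-B; sigma_b is
floored at 1e-6 on the natural scale (at the floor the quadrature
degenerates and the marginal likelihood equals the independent
beta-regression likelihood exactly — a property the tests verify).
Covariates are internally centered and scaled for conditioning and the
coefficients and covariance mapped back afterwards. Standard errors come
from the inverse of a central-difference Hessian of the marginal negative
log-likelihood; variance parameters stuck at their floor span a flat
direction and are dropped from the Hessian before inversion.

**Inference.** Per-term tests are Wald tests with a Student-t reference:
df = n_obs - n_params for the fixed-effects regressions and
df = n_samples - n_groups (the classical paired-design error df) for the
mixed model. Normal-reference Wald tests were measurably anticonservative
at the design size this package targets (35 samples): null calibration gave
type-I ~0.07 at nominal 0.05, against ~0.055 with the t reference — and the
GAMLSS-style summaries the field reads are t-based. A likelihood-ratio
variant of the interaction test (full vs no-interaction fit, chi-square(1))
is available at roughly twice the cost.

**Batch.** An optional second, independent random intercept per batch can
be enabled (`include_batch_re`); it is integrated by an outer prior-scaled
Gauss–Hermite rule nested around the adaptive per-sample integral. It is
off by default — the motivating analyses found no batch structure worth
modeling.

## Multiple testing and classification

P-values are corrected per channel (5-mC, 5-hmC, interaction) by the
Benjamini–Hochberg step-up procedure, implemented directly so that probes
with missing p-values (non-converged fits) are excluded from the test count
m rather than penalizing valid tests. Flags: DMP/DHMP from the separate
models (default FDR < 0.10; a lenient raw p < 0.001 mode exists because
small per-mark studies rarely clear an FDR bar — precisely the regime the
paired model targets), DIP from the interaction (default FDR < 0.05).
Direction comes from the coefficient sign; exact zeros are classified as
"no direction" so the call is deterministic. The paired-vs-separate
comparison is set algebra over probe IDs: how many probes significant in
both separate models the paired model also finds, and how many probes each
approach finds alone.

## Filtering pipeline

Stages run in a fixed order: (1) samples with more than 10% failed probes
(detection p > 0.05) are excluded, then probes failing in any remaining
sample are removed; (2) blacklisted (cross-reactive / SNP) probes are
removed — the blacklist is consumed as an external input; (3) MLE
estimation; (4) probes whose across-sample mean 5-mC OR mean 5-hmC is below
0.1 are removed (strict inequality; the rule is probe-level and operates on
the *estimated* proportions, which is why it must follow estimation — it is
what removes the zero-inflated bulk of 5-hmC before beta regression);
(5) probes with any missing estimate are removed. Accounting is conserved
at every run: input = final + per-stage removals.

## Synthetic data generator

The generator emulates the statistical structure of paired BS/oxBS array
studies: a two-group design (13 control vs 22 case by default, with age and
glial-proportion covariates), per-probe beta-distributed 5-mC
(precision 30), rarer 5-hmC, a shared per-sample random intercept
(sigma_b = 0.5) inducing the within-sample correlation, optional exact
zeros in 5-hmC (default rate 0.3 — the literature gives no quantitative
rate; this is a free parameter chosen to produce a visibly zero-enriched
histogram, and is set to 0 when emulating a post-filter probe set), simplex
enforcement by proportional rescaling, and binomial channel noise at
array-scale totals (negative-binomial coverage, mean 100).

Planted effects cover the regimes where separate models break down:
scenario "A" (5-mC clearly down, 5-hmC modestly up — total modification
drops; defaults mc_effect = -1.0, hmc_effect = +0.5 on the logit scale in
the validation studies), scenario "B" (a pure transfer of mass between the
marks, parameterized on the proportion scale — default transfer 0.05 from a
0.45/0.15 base — so total modification is invariant by construction), and
single-mark effects. Effects for A are on the logit scale of each mark's
mean (the model's link scale); the truth table records the induced logit
differences for every scenario.

What the generator does *not* emulate: probe-type chemistry differences,
spatial correlation along the genome, cell-type mixtures, dye bias, or
technical replicates. Passing tests therefore demonstrate correctness of
the estimators and calibration of the tests under the stated stochastic
model, not robustness to array artifacts that upstream preprocessing is
assumed to have handled.

## Validation studies and problem sizes

The test suite and the reproduction script measure, by simulation:
agreement of the closed-form MLE with an exhaustive 1e-3 likelihood grid
(500 random signal pairs, tolerance 2e-3); simplex conservation (1e-9);
bias and 95% CI coverage of the separate-model group coefficient (1000
probes at n=35, phi=30); exact reduction of the mixed model to the
fixed-effects fit at sigma_b = 0 (1e-3); type-I error of the interaction
test on null probes (2000 probes in the test suite, 1000 in the
reproduction script; band [0.035, 0.065] at alpha = 0.05); power dominance
of the paired test over each separate test in the scenario-B regime
(500/300 probes); the fraction of probes significant in both separate
models that the paired model also flags (>= 95%); exactness of the BH
implementation against the literal step-up formula; fixture filter
accounting; and byte-level determinism of the pipeline. Sizes were chosen
to keep each study's Monte-Carlo error small relative to its acceptance
band while remaining runnable on a single CPU.

## Known limitations

* The Wald t-reference df for the mixed model is a single conventional
  value (samples minus groups) applied to every fixed effect; a
  Satterthwaite- or Kenward-Roger-style per-term df is not implemented.
* ML estimates of sigma_b and phi carry small-sample bias (sigma_b low,
  phi high), which leaves a mild attenuation of interaction estimates at
  n=35 (measured ~0.07 on a true effect of 0.8); no REML-type correction
  is applied.
* The zero-inflation of estimated 5-hmC is handled by filtering (the
  mean-beta rule), not by a zero-inflated likelihood.
* Exactly two modification categories per sample are supported; designs
  with additional marks (e.g. TAB-measured true 5-hmC alongside BS/oxBS)
  would need a generalization of the long-format layout.
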