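# Methods

## Scientific setting

`costdisc` models binary cost-benefit choices from two within-subject tasks
in which a high-reward/high-cost (HC) option competes with a
low-reward/low-cost (LC) option, under three pharmacological conditions
(placebo PLC, haloperidol HAL — a dopamine D2 antagonist, biperiden BIP — a
muscarinic M1 antagonist):

* **Effort task** — both options vary over 5 reward levels (2–16 apples) and
  5 grip-force levels (0–80% of the subject's maximum voluntary contraction,
  MVC); 125 trials per session in 5 blocks.
* **Delay task** — a fixed immediate 20 € option against 15 reward levels
  (20.20–260 €) crossed with 7 delays (1–60 days); each of the 105
  combinations appears once per block, 2 blocks, 210 trials, order
  pseudo-randomised and counterbalanced across sessions.

Because no trial-level behavioural data are publicly deposited for this
design, the package operates on synthetic cohorts whose generative structure
mirrors the study: 62 subjects (configurable) × 3 conditions × both tasks.

## The discounting model

Each option's subjective value (SV) is its reward devalued by its cost.
Four single-parameter discount forms are implemented; the forms selected by
model comparison are **parabolic** for effort and **hyperbolic** for delay:

    effort (parabolic):  SV = R − κ·E²
    delay (hyperbolic):  SV = R / (1 + exp(κ)·D)

with linear and exponential alternatives using their standard definitions.
The delay discount rate is parameterised as `exp(κ)` in *every* delay form
so that κ lives in log space (the empirical distribution of raw rates is
skewed toward zero) and additive shifts act on one common scale.

Drug effects enter as additive subject-level shift parameters on κ and on
the softmax inverse temperature β:

    κ(t) = κ_PLC + I_HAL(t)·sκ_HAL + I_BIP(t)·sκ_BIP
    β(t) = β_PLC + I_HAL(t)·sβ_HAL + I_BIP(t)·sβ_BIP
    P(choose HC) = logistic(β·(SV_HC − SV_LC))

**Effort units.** A discounting weight of κ ≈ 0.1 is dimensionally
commensurate with the 2–16 reward range only if effort is coded on a small
scale. The default coding is *deciles of MVC* (0–80% → 0–8), giving a
maximal parabolic devaluation of κ·64 ≈ 6.5 apples at κ = 0.102. Codings
`fraction`, `percent` and `level_index` are available; simulation and
fitting always share one coding, so recovery results are coding-invariant.

**β positivity.** The additive shift leaves the resolved β formally
unconstrained; it is floored at 1e-6 with a flag rather than hard-rejected,
and choice probabilities are clipped to [1e-12, 1−1e-12] before logs.

## Synthetic cohorts

Subject-level parameters are drawn from independent normal populations.
The default population means are literature-reported group-level estimates
of the fitted winning models (effort: κ 0.102, β 0.667, sκ_HAL 0.013,
sκ_BIP −0.012, sβ_HAL −0.089, sβ_BIP 0.127; delay: κ −4.621, β 0.356,
sκ_HAL −0.630, sκ_BIP −0.125, sβ_HAL −0.055, sβ_BIP −0.043). These are
estimates adopted as a plausible generative population, not ground truth.
Between-subject SDs are not available from the literature, so the defaults are the
package's own choices, fixed once: κ SD 0.04 (effort) / 1.0 (delay, log
scale — a typical spread of individual log discount rates), β SD 0.20 /
0.12, and for each shift half the magnitude of its population mean. No
parameter correlations are modelled (none are reported). Session order per
subject is a seeded permutation of the three conditions.

The generator does **not** emulate fatigue drift, session-order learning
effects, decision times, lapses, or mood/physiology covariates. Passing
recovery and calibration tests therefore demonstrates the internal
consistency of the estimation machinery under the model's own assumptions,
not robustness to the violations present in real data.

## Hierarchical estimation

Group means and SDs are estimated for every subject-level parameter
(placebo κ and β plus the four shifts each get their own population
distribution). Priors are weakly informative on the scale of each task
(no exact values are dictated by the study design): group means —
normal(0.05, 0.1) for effort κ, normal(−4, 2) for
delay log-κ, normal(0.5, 0.5) for β, normal(0, 0.5) for the shifts; group
SDs — half-normal with half the corresponding mean-prior scale. All are
configurable through `PriorSpec`.

Sampling is a Metropolis-within-Gibbs scheme written for this model:

1. component-wise random-walk Metropolis on each subject-level parameter,
   vectorised across subjects, with per-(subject, parameter) step sizes
   tuned to 44% acceptance by Robbins–Monro during warmup and frozen after;
2. conjugate Gibbs draws for the group means;
3. slice sampling (Neal's stepping-out) on log group SDs;
4. a joint *translation* move (shift a group mean and all its subject
   values together) and a joint *rescale* move (scale a group SD and all
   subject deviations together), each applied twice per iteration. These
   moves are what lets the centered parameterisation cross the funnel that
   otherwise stalls mixing when a group SD is small — without them the
   shift-parameter r-hats plateau near 1.1–1.2; with them the full-length
   run reaches max r-hat ≤ 1.01.

Presets: `full` = 4 chains × 4,000 draws after 3,000 warmup (the default);
`medium` = 4 × 1,000/1,000; `fast` = 2 × 500/500
for simulation studies and tests. One master seed fans out to per-chain
seeds via `numpy.random.SeedSequence`. Chains whose drug condition is
absent from the data automatically drop the corresponding shift parameters
(a placebo-only table yields the 2-parameter model used for form
comparison).

Convergence is summarised as split-chain r-hat (rank-normalised by default,
classic split formula available), threshold 1.01. HDIs are computed as the
narrowest contiguous interval containing ⌈0.95·n⌉ sorted draws — this exact
contract is implemented directly (arviz's floor-based window differs by one
draw when 0.95·n is an integer) and cross-checked against arviz and against
analytic normal quantiles in the tests.

## Model comparison

The four forms are fitted to the placebo subset and compared by
PSIS-smoothed leave-one-out cross-validation on the deviance scale (LOOIC),
pointwise **per trial**. Smoothing and Pareto-k diagnostics use
`arviz.psislw`; the fraction of k > 0.7 is reported per form. Pointwise
log-likelihoods are evaluated on a thinned grid of ≤ 1,000 posterior draws,
which bounds memory at no visible cost to the ranking.

## Validation and recovery

* **Posterior-predictive datasets**: 500 simulated datasets per subject
  from subject-level posterior draws; a seeded subset of 10 is assembled
  into cohort-level datasets and refitted.
* **Group-level recovery**: fraction of refit group-mean posteriors inside
  the reference 95% HDI, per parameter.
* **Subject-level recovery**: Pearson r between reference subject posterior
  means and refit means *averaged across the 10 datasets* (per-dataset
  correlations are logged alongside). Under the default populations the
  recovery correlations for κ and β exceed 0.8 in the scaled experiments;
  the shift parameters have deliberately small between-subject spread, so
  their subject-level correlations are weaker — an expected property of the
  generative choice, not an estimation failure.
* **Across-task correlation**: a bivariate-normal Bayesian correlation of
  placebo κ means across tasks, sampled with `emcee` (uniform prior on r
  via a tanh transform); "credible" means the 95% HDI excludes zero.

## Choice regression

The GLMM regresses the HC choice on drug (two indicators, placebo
reference), reward, cost, and all interactions, with a subject random
intercept and random slopes for every fixed effect. Effort-task reward and
cost enter as HC−LC differences; delay-task as absolute HC levels.
Non-binary predictors are centred and scaled to SD 0.5 (drug indicators are
left binary); interactions are products of the scaled mains — formed after
scaling, a choice the source analysis leaves open. Optional controls
(trial number, session) join as scaled mains plus drug interactions without
disturbing the core term set.

Priors: normal(0, 2.5) on fixed effects, half-normal(1) on random-effect
SDs. Random effects are modelled with a *diagonal* covariance (independent
SDs) rather than a full correlation matrix: with the component-wise sampler
the correlation structure would add substantial bookkeeping for no benefit
at the cohort sizes exercised here. The sampler mirrors the hierarchical
one and adds an exact Gibbs move along the likelihood-flat direction
(b_j + δ, u_·j − δ), which removes the fixed-effect/random-mean
degeneracy, plus a joint (τ_j, u_·j) rescale move. Possible separation is
detected from pinned fitted probabilities and logged as a warning.

## Problem sizes and numerical choices

Test and validation experiments run at reduced scale chosen once as part of
the study design: 20 subjects per task for recovery and convergence
experiments, 8–12 subjects for replicate-based calibration (HDI coverage,
form identification, regression calibration), with the `fast` preset for
replicates and the `full` preset where convergence itself is the claim.
Statistical assertions use explicit sampling-error bounds (binomial tests
at α = 0.01, 99% bounds for null-calibration counts) rather than point
equalities.

Degenerate inputs are handled explicitly: constant samples give zero-width
HDIs; a single draw reduces LOOIC to the plain deviance; zero-variance
inputs to the correlation raise; constant regression predictors raise
naming the column; design tables with fewer than two levels per dimension
are rejected.

## Known limitations

* The sampler is tailored to this model family; it is not a general PPL and
  does not expose gradient-based kernels.
* Between-subject SDs of the generative population are invented (labelled
  as such); absolute recovery numbers depend on them, directional and
  calibration claims much less so.
* LOOIC Pareto-k values are frequently high for hierarchical fits with
  subject-level parameters and short chains; rankings are still stable in
  the form-identification experiments, but individual LOOIC values at the
  `fast` preset should be treated as noisy.
* The GLMM omits random-effect correlations (see above).
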