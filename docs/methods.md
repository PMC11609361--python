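# Methods

## Scientific setting

Event-related potential (ERP) studies of psychosis have focused almost
exclusively on mean amplitudes, treating trial-to-trial fluctuation as noise.
This package implements the complementary analysis: treating the *within-person
variability* of single-trial ERP scores as a signal in its own right, asking
whether people with a lifetime psychosis diagnosis differ from a never-psychotic
(NP) comparison group not (only) in their average ERP but in how *consistent*
their single-trial responses are. The analysis chain is: score single trials
from epoched waveforms, apply a trial-count inclusion rule, fit a Bayesian
mixed-effects location-scale model (MELSM) per ERP component, justify the scale
portion by out-of-sample model comparison, apply pre-registered credible-
interval decision rules, and characterize the data psychometrically
(generalizability-theory dependability, standardized measurement error).

## The model

For trial *j* of participant *i*,

    y_ij ~ Normal(mu_ij, sigma_ij)
    mu_ij        = x_ij' beta + z_ij' u_i     (location portion)
    log sigma_ij = w_ij' eta  + z_ij' v_i     (scale portion)
    (u_i, v_i)   ~ MVN(0, diag(tau) Omega diag(tau))

Fixed effects on both portions are treatment-coded: intercept (reference event
in the NP group), event type, diagnostic group, and the event x group
interaction; the exploratory symptom models replace group by a standardized
continuous covariate and its event interaction. Random effects are a
per-person intercept and event slope on *both* portions — four correlated
effects per person. The scale portion uses a log link, so a coefficient
`eta_k` means a `100*(exp(eta_k)-1)` percent change in within-person SD.
The location-only comparison model is the same likelihood with a single
residual-SD parameter (lone scale intercept, no scale random effects) — the
classical homoscedastic multilevel model.

### Priors

The defaults are weakly informative and configurable (`PriorConfig`):

| block | prior | rationale |
| --- | --- | --- |
| location fixed effects | Normal(0, 10 uV), intercept centred at the sample mean | ERP scores live in the +-10 uV range |
| scale fixed effects | Normal(0, 1) on log-SD, intercept centred at log sample SD | a unit log-SD change is a 172% change in SD — generous |
| random-effect SDs | half-Student-t(3, 2.5) | standard weakly-informative choice for hierarchical SDs |
| random-effect correlations | LKJ(2) on the Cholesky factor | mild concentration toward independence |

Centering the two intercept priors at sample summaries makes the defaults
scale-aware without materially informing the contrasts of interest (all of
which are differences).

### Sampling

No Bayesian location-scale engine is available as a dependency, so estimation
is an in-package adaptive Hamiltonian Monte Carlo sampler: analytic gradients
of the joint log posterior (a non-centered random-effect parameterization;
the correlation Cholesky factor uses the canonical-partial-correlation
transform, with its handful of parameters differentiated by forward
differences of a small composite scalar), dual-averaging step-size adaptation
toward a 0.7 acceptance target, a Stan-style expanding-window warmup for a
diagonal mass matrix, and trajectories of fixed standardized length (default
6.0) with jittered leapfrog counts. Proposals with energy errors beyond 10^3
or non-finite gradients count as divergences. Correctness is tested against
conjugate posteriors, ordinary least squares (no-random-effect data),
restricted maximum likelihood (statsmodels MixedLM on the homoscedastic
reduction), and simulation-based recovery with ~95% credible-interval
coverage; calibration of the whole pipeline is exercised by the
parameter-recovery acceptance test rather than a separate simulation-based-
calibration harness.

Convergence is reported per parameter (split R-hat <= 1.01, bulk ESS >= 400
via ArviZ); violations attach warnings to the results object rather than
failing the fit, because the deliberately short chains used in the test-suite
simulations trip the ESS threshold while leaving medians and intervals
accurate enough for the properties being tested.

Point estimates are posterior medians; intervals are 95% equal-tailed
(percentile) credible intervals. Equal-tailed was chosen over highest-density
intervals for exact reproducibility from percentiles.

### Decision rules

For components predicted to show greater patient variability, the hypothesis
is *supported* when the 95% CrI of the group coefficient on the scale portion
excludes zero with patients more variable, and/or the CrI of the event x
group coefficient excludes zero with patients more variable for one event and
the groups comparable for the other. For the component predicted null (reward
positivity) the rule inverts: support requires both CrIs to contain zero. A
scale CrI excluding zero in the direction of *less* patient variability is
reported as "opposite". These rules are implemented verbatim in
`decide_hypothesis`.

### Model comparison (manipulation check)

Interpreting the scale portion is justified only if the location-scale model
predicts better out of sample than the location-only model. We estimate the
expected log predictive density by leave-one-out cross-validation with
Pareto-smoothed importance sampling: per observation, raw log ratios
`-log p(y_i | theta_s)`; the `M = min(0.2 S, 3 sqrt(S))` largest weights are
replaced with expected order statistics of a generalized Pareto distribution
fitted to the exceedances (Zhang–Stephens empirical-Bayes estimator with the
usual weak shape prior), truncated at the raw maximum; shape `k > 0.7` flags
unreliable observations. A model counts as better only under the registered
double rule: |Δelpd| > 4 **and** |Δelpd| > 2 SE(Δelpd), with the SE from the
paired pointwise differences; otherwise the fits are "comparable". The ArviZ
implementation is used in the test suite as an independent cross-check, never
as the implementation.

## Scoring

Epochs are baseline-adjusted by subtracting each trial's mean over the first
200 ms (the pre-event segment); single-trial scores are time-window mean
amplitudes with half-open `[start, end)` windows on the sample grid (avoids
double-counting shared endpoints; makes scores bit-reproducible). Shipped
component windows: MMN-D 265–315 ms at Fz, MMN-F 175–225 ms at Fz, P3a
250–450 ms at Cz, P3b 300–500 ms at Pz, ERN 0–100 ms at FCz, RewP 250–350 ms
at FCz. The collapsed localizer grand-averages the condition-difference wave
across all participants — equal weight per participant, groups pooled, a
choice the source protocol leaves open — finds the extremum of the requested
polarity in a search window, and returns ±25 ms around its latency (both
published MMN windows are 50 ms wide); ties break to the earliest latency,
and a wrong-sign extremum warns. The inclusion rule removes any participant
with fewer than 5 trials in *any* event cell (5 + 5 = 10 total trials is
retained).

## Reliability

Dependability of an n-trial average is `sigma2_p / (sigma2_p + sigma2_e / n)`
with person and residual variances from a one-way random-effects
decomposition; unbalanced trial counts are handled by REML (ANOVA/method-of-
moments start, boundary-checked, negative moment estimates truncated at zero
with a warning). The default reporting threshold is 0.70 — conventional, and
configurable, since the source analyses report curves without naming one.
Difference-score dependability is not computed from trial pairings (trials
are unpaired across events); characterizations are per group x event cell.
The standardized measurement error of a cell is `SD(trials) / sqrt(n)`.
Descriptive group comparisons recompute pooled-variance t statistics from
published summary means/SDs/ns and Pearson chi-square (no continuity
correction) from count tables.

## Synthetic data

The generator draws from exactly the model the analysis assumes (it is the
model's generative counterpart, not a waveform simulator): two diagnostic
groups x two events per component, unbalanced trial counts via i.i.d.
Bernoulli trial deletion (default rate 0.1) emulating artifact rejection, and
person-specific means *and* log-SDs with configurable fixed effects and
correlated random effects. Defaults mirror the duration-deviant mismatch
negativity coefficient table of the study this re-implements: location
(1.63, −2.61, 0.02, 0.46) uV; scale intercept log(2.49) with deviations
(0.01, 0.04, −0.02) in log-SD units; random-effect SDs (1.34, 1.39) uV for
the mean structure and (0.27, 0.02) for the variance structure; independence
between random effects (no correlations are published); 20 participants per
group and 30 trials per condition, the size used throughout the simulation
checks. One published-table ambiguity is worth recording: the caption says
SD-unit parameters are "shown on a log scale", which could make the printed
scale intercept 2.49 either log(SD) (residual SD ≈ 12 uV) or the SD in uV.
The generator default takes 2.49 uV as the residual SD; the deviations are
log-scale offsets under either reading, and no acceptance quantity depends on
the choice. A toy epoch renderer (constant baseline + Gaussian or boxcar
component bump scaled by the trial amplitude + white noise) exists purely to
exercise the scoring stage; it makes no claim of EEG realism (single channel,
no 1/f background, no ocular artifacts, no autocorrelation).

What passing tests therefore show: the pipeline recovers the truth *when the
generating process matches the model family*. Real EEG violates this in known
ways (non-Gaussian single-trial noise, trial-order drift, structured artifact
rejection), so passing here demonstrates correctness of the machinery, not
validity of the model for any particular dataset.

## Simulation sizes and numerical choices

The test suite chooses problem sizes that keep each property informative at
desk scale: the manipulation-check suite uses 40 participants x 30
trials/condition (one strongly heteroscedastic dataset with scale
random-intercept SD 0.3, and 20 homoscedastic replicates at 300 draws + 300
warmup x 2 chains; because the elpd difference carries finite-draw
Monte-Carlo error of order 1-2 while the decision threshold is 4, any
replicate landing near the threshold — in either direction — is re-evaluated
with 600-draw chains before its verdict counts); parameter recovery runs a
20-replicate smoke version of the
200-replicate design at its registered generating size (100/group, 40
trials), asserting |mean error| within 0.05 of zero — with a 2-MCSE
Monte-Carlo allowance for the location block, whose per-replicate sampling SD
(~0.2 uV) makes 20 replicates resolve bias only to ~0.05 uV — and pooled 95%
CrI coverage at 3-sigma binomial tolerance; the power check runs 50
replicates at 200 participants x 5 trials with a group scale effect of 0.15
log-SD units. Tie-breaks, degenerate inputs and overflow guards: localizer
ties go to the earliest latency; all-identical amplitudes yield zero variance
components rather than an optimizer failure; scale linear predictors beyond
|40| (log scale) are treated as divergent proposals; degenerate correlation
proposals (|partial correlation| -> 1) likewise.

## Known limitations

* Power at sparse designs is modest: at 200 participants with 5 trials per
  condition and the default between-person scale heterogeneity (0.27 log-SD
  units), a group scale effect of 0.15 log-SD units is detected (95% CrI
  excluding zero) in only about two-thirds of simulated replicates — the
  posterior SE of that contrast is ~0.065-0.07, so effects of this size need
  more trials or larger samples to reach 80% power.

* Static-trajectory HMC mixes more slowly per draw than a tuned NUTS; the
  short-chain defaults trade ESS for runtime and are flagged by the attached
  convergence warnings.
* The location-scale separation of the model is exact only under the Gaussian
  likelihood; no robust (e.g. Student-t) likelihood is provided.
* Difference-score (event-contrast) dependability is approximated from
  per-event components under independence, not from paired trials.
* The collapsed localizer weights participants equally; a trial-weighted
  variant is not implemented.
* No autoregressive trial-order effects, no multichannel structure, no
  frequentist MELSM.
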