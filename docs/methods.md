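# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data generators do and do not emulate.

## Task model

A session is 5 rounds × (1 rich + 1 poor) blocks in randomised order within
each round, each block time-limited to 270 s, with 60 s breaks between
rounds.  Trials are built from four delays, each a truncated exponential
with target mean 4.5 s on [3.5, 5.5] s: inter-trial interval, consideration
(offer → go-cue) delay, and — on pursued trials only — action-outcome and
feedback delays.  The truncation rate is solved by bisection so that the
*post-truncation* mean equals the target; because 4.5 is exactly the
midpoint of [3.5, 5.5], the solved rate is 0 and the distribution is uniform
on that interval.  The solver supports any feasible mean (either sign of
rate), so asymmetric configurations behave correctly.  A block admits a new
trial while its clock is below the limit; the trial then runs to completion,
so realised block durations slightly overshoot 270 s, as a real session
clock would.  The 1 s go-cue response window defines the behavioural
contract but consumes no clock time: reaction times are not modelled, and
the opportunity-cost bookkeeping (below) is exact only under that
convention.

Offer frequencies default to exact sixths (1/6, 1/3, 1/2), which round to
the task's nominal two-digit values and sum to one; a `verbatim_probs` mode
renormalises the nominal 0.16/0.33/0.50 instead.  The mid option's frequency
is identical across environments by construction and enforced as a config
invariant.

**Reward-rate model.**  One slot = ITI + consideration delay (9 s in
expectation); pursuit adds the action-outcome + feedback delays, i.e. one
more slot in expectation.  For a policy π and offer distribution p the
renewal reward rate is R(π) = Σ p(v)π(v)v / (1 + Σ p(v)π(v)) points per
slot; per-second rates divide by 9 s.  Breaks and the response window are
constant offsets and are excluded from the rate denominator.  The optimal
policy enumerates the 8 deterministic pursue-sets; ties break toward the
smaller set (equal rate at lower effort).  The classical diet-selection
property — pursue an option iff its value strictly exceeds the optimal
points-per-slot rate — is verified by enumeration in the tests rather than
assumed.

## Synthetic agents

Each agent pursues with probability
σ(β₀ + β_value·(v−10) + β_env·rich·[v = 10] + β_prev·prev + β_avg·(avg−c)),
mixed with a lapse: p = (1−λ)σ(·) + λ/2.  `prev` is the agent's decision at
the last same-option encounter coded ±0.5 (absent → term omitted); `avg` is
the mean offered value over the last 5 trials of the round (absent until 5
trials have passed), centred at the session-wide expected offer value
(21.67 points).  The environment term is gated to the mid option so that a
planted environment weight maps one-to-one onto the per-option environment
regression.  Per-option memory and the value window reset at round
boundaries, matching the trial-coding conventions.  Lapse defaults to 0.05
to prevent separation in downstream logistic fits; note that a lapse
attenuates recoverable slopes slightly (a planted 1.53 persistence weight
has an infinite-data recoverable value of ≈1.45), which is a property of the
generative model, not an estimator bias.  Cohorts draw each weight as
mean + Gaussian deviation with configurable SDs.

The agents are a measurement stand-in: their utility form exists to make
each regression's target coefficient recoverable with known ground truth,
not to model human learning (there is no belief updating beyond the sliding
window, no reaction times, no satiation).

## Trial coding and behavioural regressions

`code_trials` derives, within subject and (by default) within round:
previous policy (last same-option decision, ±0.5), previous action (decision
at t−1 regardless of option, ±0.5), policy/action switch indicators, switch
direction (pursue- vs reject-switch), congruence (pursue-switches are
environment-appropriate in poor blocks, reject-switches in rich blocks), the
five-trial average value, and conditional switch responses (a pursue-switch
is only defined where the previous policy was reject, and conversely).
Lookbacks never cross subjects; crossing rounds is available behind
`reset_at_round=False`, since blocks within a round share continuous
experience while rounds are separated by breaks.  The environment is coded
rich = 1 / poor = 0, so environment coefficients are negative when pursuit
is more likely in poor blocks.

The regression registry maps each analysis to response, fixed terms, random
terms and trial subset.  Covariate scaling: offer value and trial indices
enter z-scored (value globally, trial counters within subject), average
value centred; these affect intercepts and conditioning only, not the
planted/recovered coefficients of interest, which are on the raw coding
scales (±0.5 persistence, 0/1 environment).  Rows with undefined covariates
are dropped per fit.  Behavioural models are reported uncorrected; only ROI
families receive Holm correction.

## Mixed-effects logistic estimation

The GLMM maximises the Laplace-approximated marginal likelihood: per
subject, the random-effect vector is profiled by an inner Newton ascent (in
a scaled parameterisation b = diag(σ)u that stays positive-definite at the
σ = 0 boundary), and the outer optimisation over fixed effects and
random-effect SDs uses L-BFGS-B with numerical gradients, warm-starting from
a plain-logistic fit.  The random-effect covariance is diagonal
(independent random effects): the model formulas list random terms without
stating correlations, and the diagonal structure keeps small-cohort fits
stable; on shared data the implementation matches lme4's
`(1 + x || subject)` estimates to ~1e-4 (test-suite oracle).  Wald SEs come
from the numerically differentiated observed information with boundary
variance components excluded; p-values are two-sided normal.  Complete
separation is diagnosed before fitting (response constant within every
group) and after (|coefficient| > 12 names the offending term);
non-convergence is flagged on the result rather than raised.

## Synthetic BOLD

The HRF is the standard double gamma: peak delay 6 s, undershoot delay 16 s,
unit dispersions, peak:undershoot ratio 6, 32 s kernel, normalised to unit
peak.  Event regressors are 0.1 s boxcars on a TR/20 grid convolved with the
kernel and decimated to the TR grid (TR = 1.775 s).  ROI timecourses are
planted event amplitudes (expressed in noise-SD units so detection
thresholds are portable) plus stationary AR(1) Gaussian noise with
coefficient 0.3 — strong enough serial correlation to exercise the
no-prewhitening OLS contract.  Coupling adds gain(environment) × z(seed) to
a target region sample-wise, with the block indicator resampled to the TR
grid (boundaries midway between the last onset of one block and the first
of the next).

Voxel data plant a three-option pattern geometry: low and high options keep
their base patterns (a random orthonormal triple by default) in both
environments; the mid option's poor-block pattern is the unit-normalised
mixture (1−κ)·b_mid + κ·b_high.  With orthonormal bases and no noise the
cosine distance d2 = 1 − κ/√((1−κ)² + κ²) in closed form (κ = 0.6 →
H2 ≈ 0.832), which the tests pin.  Default geometry: 40 voxels, per-event
pattern amplitude 2 noise-SD units — chosen once so that single-subject
pattern estimates are informative but noisy, the regime in which the
brain–behaviour correlation is a meaningful recovery target.

The generator does *not* emulate: scanner drift, motion or physiological
noise, spatial autocorrelation between voxels, registration error,
haemodynamic nonlinearity, or any learning-related drift in neural
responses.  Passing recovery tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to real-data
artefacts.

## ROI timecourse inference

Per subject: voxel-average (if needed), z-normalise the full timecourse,
upsample ×20 with a cubic spline, epoch −2…+8 s around each offer onset at
TR/20 resolution (epochs of adjacent trials may overlap; trials whose window
leaves the session are dropped), and fit OLS at each epoch timepoint with
[constant, regressor of interest, z-scored trial number].  The registry
defines each model's regressor and subset — e.g. congruent pursue-switches
against all other mid-option trials in poor blocks; the congruent-change
contrast codes congruent pursue-switches +1 and congruent reject-switches
−1.  No pre-whitening is applied; the AR(1) noise is part of the calibration
contract.

**Leave-one-out peak inference.**  For each subject, the peak time is the
argmax of the absolute mean effect across the other N−1 subjects within
0–8 s post-onset (pre-onset effects would be acausal; ties break to the
earliest time), and the subject's own beta at that time is the readout.
The group statistic is the one-sample t of the readouts, but its p-value is
computed by sign-flip randomisation of whole subject curves with the LOO
selection re-run inside every flip (999 flips, fixed stream).  The naive
t-test is anticonservative under the global null — each fold's peak is
selected partly on the *other* subjects' noise, which positively correlates
the readouts even though each one is individually unbiased (measured naive
rejection ≈ 0.2 at α = 0.05 with these smoothness scales) — whereas the
sign-flip test is exact under subject independence and sign symmetry and
measures 0.04–0.05 in the calibration suite.  Families of ROI tests are
Holm-Bonferroni corrected; paired contrasts between effects use paired
t-tests.

**PPI.**  OLS of the target timecourse on [constant, z(seed),
z(seed)×(env − mean), env, trial count], with the measured (non-deconvolved)
seed.  With planted gains g_poor = 0.5, g_rich = 0 and rich coded 1 the
interaction coefficient is exactly g_rich − g_poor = −0.5 in the noise-free
limit, which the tests assert to 1e-6.

## RSA

Patterns are estimated per (option × block) cell — up to 30 onset
regressors plus constant and linear-trend nuisance — by one OLS fit per
voxel; empty cells are simply absent.  Distances are cosine dissimilarity or
1 − Pearson correlation, both immune to univariate scaling (Pearson also to
offsets).  Cross-block comparison uses non-contiguous same-environment
blocks only; block-space is the number of intervening blocks (blocks 4 and
6 are one block apart; an index-difference variant sits behind a flag).
Both orientations of each unordered block pair contribute, distances are
averaged within block-space level, levels not attainable in both
environments are discarded (so rich and poor estimates are matched), and
retained levels are averaged with equal weight.  A brute-force all-pairs
enumeration serves as the oracle for this estimator in the tests.
d1 = (low, mid | poor), d2 = (mid, high | poor), d3 = (low, mid | rich),
d4 = (mid, high | rich); H1 = d1 − d3, H2 = d4 − d2.  Brain–behaviour
coupling: Pearson correlation of H2 (and H1) with the per-subject
behavioural change score Δ = pursue-rate(poor) − pursue-rate(rich) for the
mid option, plus a two-sample t-test of H2 between environment-sensitive
(Δ ≥ 0) and insensitive (Δ < 0) subjects, Holm-corrected across ROIs.

## Recovery studies and problem sizes

All recovery studies live in `foragebold.recovery` and are the code path
shared by the test suite and `scripts/acceptance.py`.

- **Behavioural coefficients.**  100 replicate cohorts of 27 agents playing
  full task-clock sessions.  The persistence study plants 1.53 on the
  ±0.5-coded persistence term with between-subject SD 1.4 (≈ 0.28·√27, the
  heterogeneity implied by a group SE of 0.28 at n = 27); the environment
  study plants −0.19 with SD 0.2 (its group SE is dominated by
  within-subject sampling noise).  Other context weights are zero, lapse
  0.05.  Reported: replicate-mean estimate, mean Wald 95% half-width, and
  coverage of the planted value.
- **LOO calibration.**  One simulated 27-subject cohort's event tables are
  fixed; 1000 null replicates redraw only the AR(1) noise (the random
  quantity under the null) and 200 planted replicates add ±1 noise-SD
  congruent-switch amplitudes.  Subjects with no events of a given type are
  excluded from that regressor's group test, as they would be in practice.
- **RSA linkage.**  100 replicates; each simulates an adaptive cohort
  (mean environment weight −1, SD 0.8, persistence 0.8), sets each subject's
  warp κ = 0.5·max(0, −β_env) and correlates recovered H2 with Δ; a
  shuffled-κ control breaks the linkage, whose signed mean correlation
  should be ≈ 0 (the mean of |r| cannot fall below ≈ 0.16 at n = 27 even
  under a perfect null).
- **PPI.**  100 replicates of 27 subjects with planted gains (0.5 poor / 0
  rich, or a constant 0.25 for the null control), full OLS per subject and a
  group t-test on the interaction coefficients.

## Known limitations

- The mixed logit assumes independent (diagonal) random effects; correlated
  random-effect structures are not implemented.
- The LOO sign-flip p-value is a randomisation p (granularity 1/1000 at the
  default flip count).
- Pattern estimation uses plain OLS without noise normalisation; crossnobis
  or Mahalanobis variants are out of scope.
- The session simulator treats responses as instantaneous at the go-cue;
  trial counts per block are therefore at the upper end of what a human
  session with nonzero reaction times would produce.
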