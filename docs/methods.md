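# Methods

`revgen` simulates and analyzes serial probabilistic reversal-learning
sessions of the kind used to contrast *problem-general* ("abstract") with
*sensorimotor-specific* neural task representations. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic data can and cannot establish.

## Task model

A session presents three *problems* (port layouts) on a 3x3 nose-poke wall,
ports numbered 0-8 row-major. Each trial is initiation poke -> choice poke
-> 250-ms outcome cue -> reward or omission. One choice port pays with
probability 0.8, the other 0.2. An exponential moving average (EMA) of
correct choices with tau = 8 trials (update `ema += alpha (correct - ema)`,
`alpha = 1 - e^(-1/8)`) triggers a reversal 5-15 trials (uniform) after it
crosses 0.75; four reversal blocks complete a problem. One in four trials is
forced-choice (a fair coin picks the available port). Choices on forced
trials count toward the EMA like any other trial.

The EMA resets to 0.5 at every block start. With an always-correct agent,
`ema_n = 1 - 0.5 (1-alpha)^n` first crosses 0.75 at n = 6, a closed form
used as an oracle in the tests.

The three layout types share the A choice port (port 3); the initiation and
B ports move such that I3 = I1 and B3 = I2 — the same physical port plays
different task roles across problems, which is what lets the analyses
separate port coding from role coding. Layout order defaults to a random
permutation per session; the two-cohort synthetic study fixes the order
(1, 2, 3) so conditions align when neurons from different sessions are
stacked into pseudopopulations.

## Behavioral agent

Choices follow a logistic policy over the previous L = 12 trials' choices
(+/-1), outcomes (+/-1) and their products. Default weights: choice lag 1 =
0.3 (mild perseveration), interaction `1.2 e^{-(lag-1)/2.5}` (exponentially
decaying credit assignment), outcome weights 0. These values were chosen
once so that the agent holds ~85-90% correct in steady state under the
0.8/0.2 schedule — block lengths and reversal dynamics comparable to a
well-trained animal. The initiation-to-choice latency is log-normal (median
0.5 s, sigma_log 0.4, truncated at 5 s); the paper-level task statistics do
not constrain this distribution, so it is a package choice. The agent's own
trial-by-trial P(choose A) is stored as `policy_true`, the ground truth for
policy-recovery analyses. Out-of-sequence pokes (at the unchosen choice
port before the next initiation) are injected as a Bernoulli(0.05) event
per trial.

## Neural populations

Each neuron is an inhomogeneous Poisson process with intensity

    lambda(t) = clip0( policy_mod(t) x ( baseline x epoch_gains(t)
                                          + sum_k kernel_k(t) ) )

* `baseline` ~ log-normal (median 4 Hz, sigma_log 0.4).
* `epoch_gains`: while the animal occupies a port (initiation epoch
  [-0.25, +0.15] s around the initiation poke; choice epoch from 0.15 s
  before the choice poke to 0.8 s after outcome) the baseline is multiplied
  by a per-port gain and a per-(problem, port) *remap* gain; during the
  0.6 s after outcome also by a reward- or omission-specific gain.
* `kernel_k`: Gaussian bumps (width 60-150 ms) anchored to initiation,
  choice or outcome; outcome-anchored kernels carry separate reward and
  omission amplitudes. Kernel amplitudes inherit the port and remap gains
  of their anchor port, so remapping moves event responses between neurons.
* `policy_mod = max(0, 1 + g_policy (policy - 0.5))` with per-problem gain
  `g_policy ~ N(0, 0.6)`. The policy is centered before entering the gain so
  mean rates are policy-independent; the gain multiplies the whole intensity
  so policy coefficients inherit each neuron's temporal profile.

The `pfc_like` profile draws everything once per neuron and reuses it in
all problems, with weak port gains (sigma_log 0.1) and no remapping. The
`ca1_like` profile uses strong port gains (sigma_log 0.8) and re-draws the
remap and policy gains independently per problem. All generative parameters
are stored in the neuron metadata.

Spikes are realized by evaluating the intensity on a 5-ms grid (far below
any kernel width) and drawing bin-wise Poisson counts with uniform jitter —
exact for the piecewise-constant intensity.

## Alignment

Trials are aligned by linearly warping the initiation-to-choice interval
onto the cross-trial median; activity before initiation and after choice is
shifted rigidly with its anchor. Warped-interval spikes are weighted by
median/actual — the time-scaling factor of the warp — which is the unique
convention under which the expected weighted count per trial equals
rate x median interval regardless of the trial's true duration
(unit-tested as a conservation law on homogeneous Poisson trains). Rates
are evaluated every 40 ms from 1 s before initiation to 1 s after outcome
with a Gaussian kernel (sigma = 40 ms) truncated at 4 sigma (<1e-4 mass
loss); zero-length intervals are excluded with a warning. Multi-session
analyses share one grid built from the pooled median interval.

## Encoding regressions

Per timepoint, each neuron's rate across one problem's trials is regressed
on choice, outcome, choice x outcome (all +/-1), optionally the centered
policy and policy x choice. The population CPD pools SSEs across neurons
before forming `(SSE_reduced - SSE_full)/SSE_reduced` — neurons weighted by
their variance; per-neuron averaging is available by flag. Regressors
constant within a problem are dropped with a warning; reduced-model SSEs
below 1e-12 of the signal energy are treated as exactly explained.
Within-region null distributions roll the trial axis circularly with one
shared offset per permutation (preserving trial-order autocorrelation and
cross-neuron correlation); thresholds are percentiles of the
per-permutation peak over timepoints. Forced trials are included by
default (flag to exclude); rates are not z-scored by default.

## RSA

Fifteen conditions (3 problems x {initiation, A/B choice x reward/omission})
are summarized per neuron as mean rates in +/-20 ms windows around port
entries; the time course slides the choice windows 0 -> 0.76 s in 40-ms
steps while initiation windows stay fixed. Condition rows are correlated
across neurons after per-neuron demeaning. The six binary model RDMs (Port
— from actual port identities, so the I/B overlaps propagate; A-vs-B
choice; Outcome; Outcome-at-A-vs-B; Choice-vs-Initiation;
Problem-specific-A) plus a constant are regressed onto the
strict-lower-triangle vectorization (diagonal deleted), with CPDs as above.
Condition ordering is problem-major, stage-minor. A hook accepts
user-supplied extra RDMs.

## Decoding

A linear SVC (C = 1, one-vs-rest, features z-scored with training
statistics) classifies the seven trial stages from +/-20-ms windowed rates
(outcome stages offset +250 ms), trained on one problem and tested on
another, over all ordered problem pairs. Because neurons are not recorded
simultaneously, pseudotrials sample one event per neuron independently with
replacement, 100 per stage by default. Error probabilities: p_abstract =
mean diagonal; p_sequence = mean of the six A<->B same-position cells;
p_port = mean of the Initiation<->B-choice cells restricted to problem
pairs whose ports actually interchange (flagged undefined otherwise).

## SVD mode transfer

The activity matrix of a (problem, half) stacks per-neuron row-demeaned
trial-type averages (rewarded A, unrewarded A, rewarded B, unrewarded B,
each over the full grid). Halves split at the median trial index (odd trial
to the first half). Temporal transfer projects a target onto the source's
temporal modes and accumulates variance in source order; cellular transfer
uses the source's cellular modes; paired transfer accumulates the squared
diagonal of `U_src^T D_target V_src`, divided by the neuron count and
normalized by the peak of the mean within-problem curve. Within-problem
curves average both half orderings of each problem; cross-problem
comparisons use the second half of problem i against the first half of
problem i+1. The generalization gap is the trapezoid area between the mean
curves; between-cohort differences are tested by session shuffles.
Temporal-mode sign convention: the largest-magnitude element of each
temporal mode is positive.

## Policy geometry

Per problem, choice type and timepoint, rates of the selected trials are
regressed on [constant, centered policy, outcome]; the current-trial choice
predictor is dropped because the subset conditions on it. Beta vectors are
correlated across neurons for every problem pair and timepoint pair,
averaged over ordered pairs (plain averaging; Fisher-z by flag), and
summarized by the diagonal sum. Zero-variance beta vectors flag their cells
as missing rather than erroring.

## Surprise

With baseline mean/SD from a train window (default 10 trials, SD floored at
0.1 Hz), surprise is the squared z-distance of the test mean (10 trials
before a switch within-problem; 20 after it between-problem). Under
stationarity and a long baseline, E[s] = 1/n_test for the test-mean
statistic; short baselines inflate this by the usual estimation terms
(sigma^2/n_train and the small-sample bias of 1/sigma_hat^2), which is why
the scaling oracle uses a long train window. A per-trial variant provides
the trial-resolved time course. Switches without full windows are skipped
and counted.

## Movement control

Nose tracking is cleaned by likelihood (>= 0.9), a jump filter at 10 robust
SDs of the inter-frame displacement ((84th-16th percentile)/2, floored at
half the median step so uniform motion is not flagged), and a minimum run
length of 5. Gaps minimize `|D x|^2 + w |D x - D e|^2` (D = first
difference, e = mean ear trajectory, w = 10 so the nose tracks the ears
through occlusions); the sparse normal equations are solved exactly.
Occupancy is encoded by 200 Gaussian RBFs (sigma = 1 cm, centers sampled
from visited positions) reduced to 10 principal components; the achieved
variance share is reported, not enforced. Residualization regresses each
neuron's aligned rate on [components, speed, acceleration, constant],
sampling predictors at the session time of each warped grid point
(inverting the warp per trial); kinematics enter as scalar speed and its
derivative, with vector components available by flag.

## Permutation inference

Group contrasts shuffle sessions (or animals) between labels, enumerate all
assignments exhaustively when their number is at most n_perm (exact test),
and otherwise Monte-Carlo sample with the add-one p-value. Time-series
statistics contribute their peak over timepoints per permutation
(family-wise control). Two-sided tests use the peak absolute statistic; the
minimum attainable p is 1/#assignments and a warning is raised when it
exceeds 0.05.

## Synthetic study sizes

The packaged two-cohort study uses 6 sessions x 25 neurons per profile
(150-neuron pseudopopulations), 3 problems x 4 blocks per session with the
default agent, 100 pseudotrials per decoding stage and 200 permutations for
session shuffles. These sizes reliably reproduce the qualitative regional
double dissociation (cellular/paired mode gaps, RSA port vs stage/outcome
structure, decoding error patterns, policy-diagonal contrast) and are what
the tests and the acceptance script run.

## What the simulations do and do not show

The generator reproduces the block logic, choice statistics, event-locked
Poisson firing, port/remap/policy tuning and plausible kinematics, with
exact ground truth. It does not emulate bursting or refractory spike-train
structure, theta or other oscillatory modulation, slow representational
drift within a problem, inter-neuron noise correlations (beyond shared
policy/epoch modulation), or real pose-estimation artifacts beyond simple
likelihood drops. Passing tests therefore establish correctness and
calibration of the analyses under the generative model, not biological
conclusions about any recorded data.

A caveat on temporal transfer: re-drawing port and remap gains per problem
re-weights how much variance each shared temporal profile carries in each
problem, so the temporal generalization gap of problem-specific populations
is near zero but not exactly zero (a percent or two of the full-rank area,
against cellular/paired gaps an order of magnitude larger). Session-level
permutation tests are powerful enough to resolve this residual at some
random draws; the cellular-vs-temporal dissociation is what the profiles
are designed to exhibit, and it is large and stable.

## Known limitations

* The history-logistic fit is unregularized by default; near-deterministic
  agents can separate, in which case the optional ridge (lambda = 1e-3) is
  advised by the error message.
* The surprise baseline uses only 10 trials by default, so its absolute
  scale includes estimation inflation; comparisons (within vs between) are
  unaffected.
* Pseudopopulation analyses assume conditions are alignable across
  sessions; the study module fixes the layout order for this reason, and
  sessions with heterogeneous layout orders should be aligned by layout
  type before stacking.
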