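# Methods

This note documents the models implemented in `statebmi`, the assumptions
behind them, the default parameters and why they were chosen, and what the
synthetic testbed can and cannot say about real recordings.

## The decoding problem

Four intracortical-microstimulation patterns s₁…s₄ encode the quadrant of a
point mass on a 36 × 36 cm plane. Each stimulation evokes a cortical
response recorded as spike trains from N units over a post-stimulus window;
ongoing activity is recorded over a pre-stimulus window. The decoder's task
is to recover the stimulation pattern from single-trial activity; in the
closed loop, the posterior over patterns is turned into a force that drives
the mass toward a central target.

The scientific question is whether conditioning the decoder on the
*network state* — slow, stimulus-independent fluctuations of excitability
estimated from pre-stimulus activity — improves decoding and closed-loop
behavior. Three variants are compared, identical except for their input:
response only (SI), response plus time-averaged pre-stimulus activity
(SD-TA), response plus the full pre-stimulus time course (SD-TD).

## Synthetic sessions

No public recordings exist for this paradigm, so the generator in
`statebmi.neural_sim` produces sessions with the statistical structure the
method assumes. Its choices, and their rationale:

**Latent excitability.** A scalar trace x(t), shared by all units, sampled
per trial on a 1 ms grid spanning both windows. Its Gaussian core is a
stationary Ornstein–Uhlenbeck process (decorrelation time
`state_timescale`, default **0.8 s**, the slow-wave up/down-fluctuation
regime of anesthetized cortex) mixed with a delta-band sinusoid
(`state_oscillation_band` = 1–4 Hz, one frequency drawn per session —
anesthetized delta is quasi-regular within a session — random phase per
trial, `sine_weight` = 0.1 of the variance). The standardized mixture is
passed through a standardized lognormal (`state_skew` = 0.8), giving the
skewed marginal of cortical excitability: occasional strong up-states, a
quiet floor at about −1 sd. The skew matters mechanically: it lets the
additive coupling be strong without ever driving rates negative, so the
state–response relation stays linear and a linear decoder can learn it.
The marginal has zero mean and unit variance by construction.

**Rates and spikes.** Unit n's instantaneous rate is

    rate_n(t) = max(0, baseline + template_{n,s}(t)·drift(m) + g·scale_n·x(t))

with spikes drawn as an inhomogeneous Poisson process and all spikes in the
30 ms artifact-blanking interval removed. `baseline` is 25 spikes/s.
Templates rise at the end of the blank and decay with a 60 ms constant;
stimuli differ chiefly in overall evoked strength (relative amplitudes
0.3 / 1.0 / 1.7 / 2.4), plus a 30% preferred-pattern gain per unit
(preference assigned cyclically). Per-unit amplitudes are lognormal around
a 60 spikes/s peak. The coupling scale `scale_n` is proportional to the
unit's responsiveness, so excitability moves the population response along
the same amplitude axis that distinguishes the stimuli — precisely the
confound that makes decoding state-dependent: a weak response to a strong
pattern in a down-state resembles a strong response to a weak pattern.
Evoked rates drift linearly by `drift_fraction` = 0.205 from the first to
the last trial of the session, reproducing the ≈ +20% evoked-rate drift of
chronic anesthetized sessions.

**Calibration.** `state_coupling` g = 0.3 puts the coupling just inside the
no-rectification regime and was calibrated (once, on seeds disjoint from
any test seed) so that the SI decoder extracts ~0.8–1.2 bits per trial at
the default session size — a mid-range operating point where state
correction has room to help. Default sessions have 14 units and 100 trials
per pattern (400 trials), matching the recorded sessions this emulates
(10–15 units, 50–200 repetitions per pattern).

**What the generator does not emulate.** Spike sorting errors, electrode
drift and unit loss, non-Poisson firing statistics (bursting, refractory
structure), correlated noise beyond the single shared state, stimulus
adaptation, and any stimulus→state coupling (habituation bias) unless
explicitly enabled through `pre_stimulus_tuning`. Passing tests therefore
show that the pipeline behaves correctly *under the model's own
assumptions* — additive, low-dimensional, temporally structured state — not
that real recordings satisfy those assumptions.

## Binning

The pre-stimulus schedule uses 39 adaptive bins over 0.75 s: 9 × 50 ms,
then 10 × 20 ms, then 20 × 5 ms ending at onset — fine resolution where
ongoing activity is most predictive of the upcoming response, coarse where
only the slow trend matters. Post-stimulus bins are uniformly 5 ms wide
starting at the end of the blank. Bins are half-open [lo, hi); a spike at
onset belongs to no bin (it would be inside the blank). The SD-TA pre
feature is each unit's total pre-stimulus count divided by the number of
bins — proportional to the duration-weighted mean rate, so the arrangement
of unequal widths cannot bias it. MUA pooling sums counts across units per
bin.

## Decoder

PCA is fit on the training trials of each cross-validation fold (never on
the held-out trial) and the k leading components are retained; multiclass
LDA with a pooled, per-class Ledoit–Wolf-shrunk covariance is fit on the
scores. Posteriors follow from the linear discriminant scores by softmax;
winner-take-all replaces the posterior by a one-hot vector at its argmax
(ties broken toward the lowest pattern index) whenever the maximum exceeds
P_thr. The leave-one-out loop reuses the label-independent per-fold PCA
projections across the label permutations of the bias correction; inside
that loop the discriminant is evaluated by a direct numpy routine that is
numerically identical to refitting the scikit-learn estimator per fold
(asserted to 1e-10 in the tests).

**Default protocol.** The full nested hyperparameter search
(`optimize_parameters`: inner leave-one-out over P_thr, k, variant, signal
and window lengths, ties broken deterministically) is provided but costly;
the package's defaults stand in for representative optimized values and
were fixed on calibration seeds:

* signal = MUA — with ≲15 units and strength-coded stimuli, pooling is more
  robust than unit-resolved decoding, and it concentrates the state
  estimate into few dimensions;
* k = 6 — the task-relevant structure (amplitude axis, state direction,
  and their pre-stimulus counterparts) is low-dimensional, and a small
  score space keeps the discriminant well-estimated from ~400 trials;
* P_thr = 0.3 — an aggressive winner-take-all regime, so the confusion
  matrix reflects discrimination rather than posterior calibration;
* SD-TD reads the last 13 pre-stimulus bins (65 ms), where the state is
  most predictive of the response window; SD-TA averages the full 0.75 s
  window, as its definition implies.

## Information and bias correction

The confusion matrix column for presented pattern i is the mean thresholded
posterior over trials of that pattern (the normalization that makes each
column a distribution); its mutual information, in bits, is the performance
measure (2 bits = perfect decoding of four equiprobable patterns). Finite
trial counts bias the estimate upward, so the *entire* pipeline —
leave-one-out decode, confusion matrix, information — is rerun on label
permutations (class counts preserved; default 100 shuffles, minimum 20 for
reported numbers) and the mean shuffled information is subtracted. Negative
corrected values are reported as-is; clipping at zero would bias averages.
The state-only control runs the same pipeline on pre-stimulus features
alone: with no stimulus→state coupling in the generator it is statistically
zero, showing that SD gains come from conditioning rather than leakage.

## Closed loop

The workspace is a 36 cm square; the four force fields (8 mN) sit at the
quadrant centroids and point at the origin. The encoder maps position to
its quadrant (half-open convention on the axes; origin → region 1). Each
control step the oracle generates one trial — the latent state evolves
continuously across steps, so state-dependent decoders can track it in the
loop — the decoder emits a thresholded posterior, and the posterior-weighted
force drives the mass for dt = 0.25 s with the exact exponential solution
of m dv/dt = F − b v (m = 20 g, b = 0.4 N·s/m; velocity relaxation 50 ms,
per-step displacement ≈ 0.5 cm at terminal velocity). dt was set so that an
ideal decoder converges from every start position for any target radius
≥ 0.5 cm within the 100-step cap (at coarser steps the discrete approach
orbits outside small targets), while leaving imperfect decoders a
measurable signature in every metric. Target entry is detected on a
20-point sub-sampled within-step path, since the continuous trajectory can
sweep through the disc between step endpoints. Walls clamp position and
zero the inward velocity component. Velocity carries over between steps.

Metrics: convergence rate (% of trajectories entering the target),
mean steps among converging trajectories, closest approach to the origin
(mm, over recorded per-step positions), the signed component of the decoded
force toward the target, the mean angle between the decoded force and the
occupied region's field, and the within-trajectory variance
wtv = √(C_x² + C_y²), where C_x and C_y are the variances of the x and y
components of per-step displacements pooled over the repeats from one start
position. The root-sum-of-squares form was chosen for its units (squared
length); any monotone combination of C_x and C_y preserves every ordering
statement made about wtv.

## Numerical choices and edge cases

* Half-open bins throughout; out-of-window spikes are dropped with a
  warning, not an error (tolerant of edge effects in real recordings).
* PCA uses full SVD (deterministic); rank is cut at 1e-10 of the leading
  singular value; k is capped at the training-fold rank.
* A leave-one-out fold missing a class falls back to the training priors
  with a warning (cannot happen with balanced sessions).
* Zero decoded force has no direction: angular error and directed force
  return NaN and are excluded from averages.
* One master seed spawns independent per-trial substreams, so any single
  trial is reproducible without regenerating the session prefix.

## Problem sizes

Reported computations use sessions of 400 trials (14 units) for the
variant comparison, 200-trial 8-unit sessions for the null calibration, 20
bias shuffles per estimate (50 for the null calibration), and closed-loop
protocols of 8 starts × 10–20 repetitions; these replications keep the full
suite reproducible on a single CPU in minutes while leaving the reported
orderings stable across seeds.

## Known limitations

* The generator's state is one-dimensional and additive; real state
  dependence includes gain modulation and higher-dimensional structure
  that a linear conditional decoder would exploit less cleanly.
* With strength-coded stimuli the MUA default discards little information;
  for pattern-coded stimuli (distinct unit subsets per pattern) SUA
  decoding and larger k would be the right defaults.
* The SD-TD advantage shrinks as `state_timescale` decreases below the
  pre-window→response gap, and vanishes with `state_coupling` = 0, as it
  must.
* Shuffle bias correction subtracts the mean of a finite permutation
  sample; its s.e.m. is reported and should be compared against small
  corrected values.
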