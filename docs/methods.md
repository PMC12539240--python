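# Methods

This note documents the generative model, the synthetic task, the numerical
choices, and the known limitations of the `rlddm` package.

## Task model

Each run has 44 trials. A run's stimulus material is 4 cues (sounds in
audio-visual runs, vibration patterns in tactile-visual runs) and 4 visual
symbols, giving 16 cue×symbol combinations of which 4 are matching. Stimulus
sets carry complexity-class labels only (no audio/vibration content is
rendered): visual and auditory sets contain one low-, two medium- and one
high-complexity stimulus; tactile sets contain two low- (constant
frequency), one medium- (ramp) and one high-complexity (u-shaped) pattern.

Schedules are pseudo-randomised by seeded shuffle-and-repair: cue
frequencies default to uniform (11 per cue in 44 trials; a configuration
hook accepts arbitrary frequency vectors), no more than 3 consecutive trials
share a cue, the matching symbol's side is counterbalanced within ±1 per
cue, and the distractor symbol rotates over the three non-matching symbols
so all 16 pairings occur in a default-length run.

Feedback is valence-reversed on `round(rate × n_trials)` trials
(half-away-from-zero rounding; rates 0.05/0.10/0.20 give 2/4/9 trials of
44), spread over the cues with per-cue counts differing by at most 1.

The trial timeline is ITI → stimulus (2.0 s) → ISI → feedback (1.8 s), run
clock starting at 0 at the first ITI onset. Responses are accepted during
stimulus and ISI, so the per-trial response window is `2.0 s + ISI`. ITI and
ISI are gamma distributed with mean 1.87 s on [0.76, 3.45] and 3.45 s on
[2.28, 4.83] respectively: shape and scale are set so the *untruncated* mean
equals the target (moment heuristic `sd = (hi − lo)/4`), and out-of-range
draws are rejected. The residual truncation shift of the mean is below
0.05 s for these windows (measured ≈ 0.015 s for the ITI and ≈ 0.007 s for
the ISI at n = 10⁵) and is covered by a test.

The familiarisation floor of 134 trials reproduces the pre-scan protocol:
per modality a 13-trial guided instruction block plus a 44-trial behavioural
run, at least 10 self-paced practice trials before the first behavioural run
(practice before the second modality is repeated only when needed), and at
least 10 practice trials with the scanner response box.

## Generative model

Values for all 16 combinations start at 0.5 and live in [0, 1] with rewards
coded 1 (positive) / 0 (negative). Only the chosen combination is updated,
by the delta rule with learning rate η. Omissions receive neutral feedback:
no reward prediction error, no update, no likelihood term. Normalization of
the displayed pair (`V̄_left + V̄_right = 1`) is transient — the value table
stores raw values between trials. The drift rate is the normalized
difference times the drift weight `v_mod`; the diffusion has unit diffusion
coefficient (the scale is absorbed by `a` and `v_mod`), relative start point
z fixed at 0.5, upper boundary = left choice.

The WFPT density is evaluated with whichever of the small-time or
large-time series needs fewer terms at the requested absolute tolerance
(default 1e-10), with term counts from the standard truncation bounds on the
normalized-time density; the upper-boundary density uses the reflection
v → −v, z → 1 − z. Degenerate value pairs (both below 1e-12) normalize to
(0.5, 0.5) with a warning. A reaction time at or below τ yields a −∞
log-likelihood sentinel rather than an exception, so optimizers can probe
the boundary freely.

Forward simulation is Euler–Maruyama (default step 1e-3 s for behavioural
runs, 1e-4 s in the density cross-validation) with a Brownian-bridge
crossing probability per step, which removes the O(√dt) absorption bias of
naive discretization; bridge draws are skipped when the crossing probability
is below e⁻³⁰. A decision not completed inside the response window is an
omission. The simulator and the analytic density are independent routes to
the same law and are cross-checked in the tests (both-boundary integral
1 ± 1e-3 on a 3×3 (v, a) grid; Kolmogorov–Smirnov distance < 0.01 and
choice-probability gap < 0.01 against 10⁵ paths at (v, a, z) = (1, 2, 0.5)).

## Estimation

Each run is fitted separately by maximum likelihood. The objective sums
−log WFPT densities over usable trials (responded, not RT outliers) while
the value chain is propagated over *all* feedback-bearing trials, so
removing a trial from the likelihood does not break learning continuity
(outlier trials saw their feedback; omissions did not). Default bounds:
η ∈ [0, 1], a ∈ [0.3, 5], τ ∈ [0.1, 0.95 × min valid RT], v_mod ∈ [0, 20].
The global search is scipy's differential evolution (seeded, Sobol
initialization, total population 40, 200 generations by default) with
L-BFGS-B polish; identical (data, bounds, seed) gives identical estimates.
A convenience helper averages fitted learning rates over a participant's
runs for downstream use.

### Parameter recovery

Recovery draws generating parameters uniformly from priors chosen once from
plausible group-level behaviour in this paradigm (η ∈ [0.05, 0.5],
a ∈ [1.5, 3.5], τ ∈ [0.3, 1.3] s, v_mod ∈ [0.5, 6]), simulates each run on a
fresh schedule, refits, and reports Pearson/Spearman correlations, bias,
RMSE and MAE per parameter. The validation scale is 100 runs × 176 trials,
with the sample-size consistency check at 40 runs each of 44/176/704 trials
(the parameter draws are common across sizes, so the MAE comparison uses
common random numbers). On one CPU the full recovery study runs in under a
minute.

**Known limitation — the η×v_mod ridge.** When the generating learning
signal is weak (small η and/or small v_mod), the likelihood surface contains
a ridge along which a near-zero learning rate trades off against a very
large drift weight: value differences stay microscopic but are amplified
into similar drift trajectories. The ridge is nearly flat (a few tenths of a
nat) but tilted toward the v_mod bound, so the *genuine* maximum-likelihood
estimate occasionally lands at the bound even though the generating v_mod
was small. In roughly 1–4 % of prior draws at 176 trials this produces large
v_mod errors; rank correlations stay high (Spearman ≈ 0.8–0.9) while the
outlier-sensitive Pearson correlation of v_mod fluctuates between ≈ 0.45
and ≈ 0.95 across Monte-Carlo seeds. This is a property of per-run
box-constrained maximum likelihood for this model class, not of the
optimizer (enlarging the search budget does not change the estimates, and
profile likelihoods confirm the bound is the true optimum). Hierarchical or
penalized estimation would regularize the ridge but is deliberately out of
scope.

## Behavioural summaries

Preprocessing flags every trial as exactly one of valid / omission /
RT outlier. The fast-guess cutoff defaults to 0.2 s; the slow cutoff
defaults to the per-trial response window (both configurable). Bin metrics
split the run into 4 bins of 11 trials in presentation order. Accuracy is
correct responses over answered trials — omissions are always excluded from
the denominator, RT outliers are included by default (configurable), since
an outlying-latency response is still a choice. A bin with no answered
trials has *undefined* accuracy (flagged, never zero). Mean RT is computed
over correct answered trials. The above-chance criterion is accuracy
≥ 7/11 (63.64 %, inclusive) in at least 2 bins pooled across runs.

## Event export

Each trial contributes one stimulus (2.0 s) and one feedback (1.8 s) event.
Valid trials carry the normalized chosen value (taken at stimulus onset,
i.e. before that trial's feedback updates it) on the stimulus event and the
reward prediction error on the feedback event; omission and RT-outlier
trials become unmodulated no-interest events of their own types. Modulators
are not demeaned or orthogonalized by default (`center_modulators` offers
mean-centering for toolchains that do not demean internally). Tables are
BIDS-style TSVs with `n/a` for missing values, written to ≥ 6 significant
digits, and round-trippable. An onset-offset option shifts the run clock
into scanner time for externally recorded logs.

## Reproducibility

One global seed deterministically derives all stage seeds via a SHA-256
hash of (seed, stage name, run id), each below 2³¹, so any stage can be
re-run in isolation. The pipeline manifest records configuration, stage
seeds, and a content hash per output; identical configurations produce
identical hashes.

## What the synthetic data does and does not show

The generator reproduces the task's structure (trial counts, combination
space, feedback reversal statistics, interval distributions, response
windows) and produces behaviour from the fitted model family itself. It does
not emulate attention lapses, within-run parameter drift, motor errors,
cue-specific perceptual confusability, or age effects. Passing tests
therefore demonstrate internal consistency (the estimator recovers the
generative process; the summaries and exports are faithful to the data
given) — not that the model family is adequate for any particular empirical
dataset.
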