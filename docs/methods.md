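# Methods notes

This note records the models, conventions and numerical choices behind
`condpipe`, and what the synthetic-session validation does and does not
establish.

## Task model and session geometry

A session is a sequence of interleaved CS+/CS− trials. Relative to CS
onset: sound 0–2 s, silent trace 2–3 s, reward at exactly +3 s (CS+
only), and an analysis window extending to +4 s. The inter-trial interval
is defined as the gap between the end of one trial window (onset + 4 s)
and the next onset, drawn uniformly from `iti_range_s` (default 30–45 s).
Sessions default to 50 CS+ and 50 CS− trials; the CS− count is a
convention chosen for balance, since only the rewarded-trial count is
fixed by the task.

## Synthetic-session generator

The generator emulates the statistical structure the analyses assume,
not the biophysics. All quantities flow from one
`numpy.random.Generator` seeded by `SessionSpec.seed`; identical specs
give identical bundles.

**Licking.** Bouts are ~7 Hz regular trains with 10% inter-lick-interval
jitter. Post-learning, 90% of CS+ trials carry an anticipatory bout
starting 0.1–0.5 s into the trace that continues through reward
consumption; pre-learning, bouts start only after reward. Sparse baseline
licks occur at 0.05 Hz throughout.

**Spike trains.** Units are inhomogeneous Poisson around a 5 Hz baseline.
Planted response classes modulate additively:

- *evoked*: +5 Hz in 0–350 ms after either CS; the CS− response is scaled
  by a per-area learning gain (post-learning PFC: 0.3, emulating the
  learned CS− response reduction; CA1 and pre-learning: 1.0),
- *trace_up / trace_down*: ±5 Hz peak on CS+ trials, **ramping linearly
  from zero at trace onset to the peak at reward**. The ramp matters:
  with a constant sustained effect, every trace cell exceeds the
  lick-cell criterion inside the ±250 ms anticipatory-lick window and the
  taxonomy becomes unidentifiable; ramping delay-period activity is also
  the standard physiological picture. The planted trace-window mean
  effect is therefore half the peak (2.5 Hz),
- *lick*: +6 Hz in ±250 ms around each bout onset,
- *reward*: +5 Hz in 0–0.5 s post reward.

Per-area class fractions default to the learning-stage-dependent mix the
analyses expect (post-learning CA1 dominated by trace suppression, PFC by
trace activation; PFC sound-evoked fraction 0.20 at both stages with the
learning effect carried by the CS− gain).

**Assemblies.** An assembly is a set of member units that receive excess
near-synchronous spikes (uniform jitter within a shared 20 ms window,
per-member participation probability 0.9) at assembly event times. Events
combine a homogeneous background process (0.2 Hz), an in-trial process
biased to a configurable CS type and period (1.0 Hz inside the biased
windows), and ripple-coupled events (probability `ripple_coupling_p` per
ripple, optionally ramping linearly across the session to emulate
within-session reactivation growth). The default assembly set couples the
CS−-biased (i.e. CS+-suppressed) CA1 assembly to ripples, reproducing the
preferential ripple reactivation of CS+-suppressed hippocampal
assemblies.

**Shared low-rank drive.** `comm_rank > 0` adds a latent Gaussian process
(i.i.d. per 100 ms bin inside trial windows) loaded onto all units of
both areas with N(0, `comm_gain_hz`²) weights, realized by Poisson
addition/thinning. This is the recovery target for the reduced-rank
regression. It is **off by default** because the same cross-unit
correlation it creates is, correctly, extra co-activation structure under
the Marcenko–Pastur criterion; specs used for assembly-count validation
keep `comm_rank = 0`, and rank-recovery specs plant `comm_rank = 2` with
no assemblies. Each planted structure is validated under conditions where
it is the only structure of its kind.

**LFP.** Background is integrated white noise (1/f² spectrum) high-passed
at 0.5 Hz and scaled to 60 µV SD, plus 3 µV white noise. Ripples are
Gaussian-enveloped (σ = 15 ms) sinusoids at `ripple_freq_hz` (default
180 Hz) with a Gaussian laminar amplitude profile (σ = 1.5 channels)
peaking on a designated channel. The profile is normalized so that
`ripple_amp_uv` is the envelope amplitude **after** common-average
referencing on the peak channel — the CAR subtracts the cross-channel
mean of the profile, and without this compensation the planted amplitude
would not be the amplitude the detector thresholds. Artifacts are
identical bursts at ≥650 µV; they deliberately share the laminar profile
rather than being common-mode, because a strictly common-mode transient
would be removed by the CAR and could never exercise the high-cut
rejection rule. Ripple event times are Poisson at `ripple_rate_hz`
thinned to the inter-trial intervals, with a 0.3 s minimum separation and
a 0.25 s lick guard so that planted events are detectable by
construction. PFC coherence is created by adding a band-limited (60–100
Hz) component, gated to trial stimulus+trace windows with 50 ms ramps, to
all CA1 channels and the PFC channel.

## Analysis conventions

- **Windows are half-open** `[a, b)` everywhere (lick counting, binning,
  window scores) to prevent double counting at boundaries.
- **Learning criterion**: two-sample t-test of per-trial lick-count
  changes, CS+ vs CS−, α = 0.05, *and* CS+ mean above CS− mean (the
  one-directional reading of "significantly higher"). Degenerate
  zero-variance identical groups give p = 1.
- **Smoothing**: Gaussian-weighted moving average, 25 bins support,
  σ = 5 bins, reflection padding (conserves the per-trial count; only the
  filter family and width are fixed by convention, σ and padding are
  package choices).
- **z-scoring**: trial-averaged PSTHs are z-scored to the mean/SD of the
  −1–0 s baseline bins. Zero-SD units are flagged and excluded rather
  than producing ±inf.
- **±1 SD thresholds are inclusive** (`≥ +1`, `≤ −1`).
- **Lick-cell criterion**: the raw (unsmoothed) rate in ±250 ms around
  the first anticipatory lick is compared against the mean ± SD of the
  per-trial baseline-window rate, with the SD taken **across trials**.
  The alternative (SD across the bins of the averaged PSTH) shrinks as
  1/√n_trials and at realistic session sizes drops below sustained
  trace-cell modulation, flagging most trace cells as lick cells;
  the across-trials SD is invariant to trial count. Lick classification
  is undefined (not false) when fewer than five trials carry an
  anticipatory bout, since a one-trial average makes the rule pure noise.
- **Group statistics**: per-group mean ± SEM with unpaired rank-sum
  comparisons, plus a paired within-unit t contrast for CS+ vs CS−
  scores. The paired mean-sensitive contrast is reported because a
  minority of strongly responding cells carries the group effect, which
  median-based rank statistics cannot see at a few hundred units.
- **Decoding**: non-lick units only; stratified partitioning (degenerate
  folds are impossible by construction or raise); classifier is a linear
  maximum-margin machine with C = 1; single-session significance via
  label permutation, `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`.
- **RRR**: spike counts in 100 ms bins (chosen to give ≥10 samples per
  trial period), per-fold mean-centering, OLS with a 1e−8 ridge jitter on
  the Gram matrix only if singular (flagged). The reduced-rank estimator
  projects OLS predictions onto the top principal components of the
  training-set fitted values; at full rank it equals OLS exactly. The
  rank grid is 1…m because the 1-SEM rule needs the whole curve.
  Subsampling is without replacement with an independent RNG substream
  per replicate. The full-rank control defaults to a pure L2 penalty
  swept over {1e−3 … 1e2} and chosen by cross-validated R², reporting
  held-out MSE; an elastic-style L1 mixing weight is exposed for the
  alternative reading of the penalty family.
- **Ripple detection**: the envelope is the analytic-signal magnitude of
  the band-passed trace (4th-order Butterworth, forward-backward); the
  event time is the envelope peak within each supra-threshold epoch
  (needed for triggered averages); the 200 ms refractory rule keeps the
  earlier event; exclusion order is artifact → lick guard → refractory.
  Channel ties resolve to the lowest index.
- **Multitaper**: NW = 3 with 5 Slepian tapers per segment (exposed in
  config); magnitude coherence pooled over segments and tapers. The
  permutation test shuffles segment condition labels and is two-sided.
- **Assemblies**: correlation-matrix eigenvalues against the analytic
  Marcenko–Pastur edge; ICA (FastICA) run in the significant principal
  subspace with 5 seeded restarts keeping the run with maximal summed
  source kurtosis; patterns unit-norm with the largest-|weight| entry
  positive. Sliding activation bins are 20 ms with a 10 ms step.
  Ripple-triggered z-scoring uses inter-trial samples outside the 50 ms
  ripple centers; stimulus-triggered z-scoring uses the pre-stimulus
  period of both CS types. Triggered averages are smoothed with a 100 ms
  Gaussian window (σ = 20 ms). Blocks partition trials into 10 contiguous
  groups with sizes differing by at most one; reactivation+/− groups are
  defined by the sign of the session-mean ripple-window z. The
  significant-reactivation rule uses SD = 1.4826·MAD with an explicit
  MAD = 0 fallback. Pattern-truth matching for validation is greedy
  bipartite on |cosine|.

## Validation scale

The suite and the acceptance script validate on deliberately scaled-down
sessions — typically 20–50 trials per CS type, 8–15 s ITIs, 24–54 units
per area, and ripple rates of 0.15–0.2 Hz so that short sessions still
contain enough events for stable statistics. Full-scale defaults (50/50
trials, 30–45 s ITIs, 0.09 Hz awake-ripple rate) remain on `SessionSpec`.
Multi-seed checks use 20–100 seeds depending on the cost of one
replicate.

## What passing tests do and do not show

The generator provides exactly the structure each analysis assumes:
Poisson spiking, additive effects, stationary baselines, perfectly
labeled trials, ripples placed away from licks and artifacts. Passing
validation therefore demonstrates correctness of the implementations and
their calibration under model conditions — not robustness to bursting,
non-stationary baselines, drifting units, spike-sorting errors,
overlapping ripples, movement artifacts or volume conduction, none of
which are emulated. The LFP model has no theta, no spike leakage into
the ripple band, and a purely Gaussian laminar profile. Effect sizes in
Hz are package choices (the task fixes timing, not magnitudes), selected
so that planted structure is recoverable at the documented session
sizes.

## Known limitations

- Trace responses are modeled as linear ramps; real delay activity mixes
  ramps, boxcars and transients.
- The ±1 SD taxonomy inherits heavy tails from normalizing by a baseline
  SD estimated on ~2 effective samples after smoothing; on effect-free
  data the per-flag rate is an empirical ~0.37, far above the nominal
  Gaussian 2·Φ(−1) — a property of the rule, not a bug, and the null
  tests assert the empirical band.
- Single-session decoding significance uses label permutation; the
  across-session sign-rank of the multi-session design is available only
  when several sessions are pooled.
- The ITI-assembly variant and the 5%-quantile quadrant variant are
  parameter changes on the exposed surface, not separately validated
  paths.
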