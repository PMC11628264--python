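# Methods

## The model

`tvatoj` analyzes temporal-order judgments (TOJ) through the lens of the
Theory of Visual Attention (TVA), which treats visual encoding as a
fixed-capacity parallel exponential race into visual short-term memory.
A stimulus with encoding rate `v` (Hz) is encoded within exposure `t` with
probability `1 − exp(−v(t − t0))` for `t > t0` and 0 otherwise; the
threshold `t0` is exposed in `encoding_probability` but cancels in every
two-stimulus computation (both stimuli share it), so all TOJ math uses
`t0 = 0`.

In a two-stimulus TOJ the probe and reference race with rates `v_p` and
`v_r`, onsets offset by the stimulus onset asynchrony (SOA, probe minus
reference; negative = probe leads).  The probability of reporting the probe
first is piecewise in the SOA `s`:

- probe leads (`s < 0`): `1 − exp(−v_p|s|)·(1 − w)`
- probe trails (`s ≥ 0`): `exp(−v_r s)·w`

with `w = v_p/(v_p + v_r)`.  Both branches equal `w` at `s = 0`; the curve
is continuous and strictly decreasing.  The two estimands are the overall
processing capacity `C = v_p + v_r` (items/s) and the probe's relative
attentional weight `w`.  Classical psychophysics drops out in closed form:

- PSS (point of subjective simultaneity): `ln(2w)/v_r` for `w ≥ 0.5`,
  `−ln(2(1−w))/v_p` otherwise; its sign equals the sign of `w − 0.5`.
- DL (difference limen), defined here as half the SOA span between the 25%
  and 75% points of the curve: `[ln(4w)/v_r + ln(4(1−w))/v_p]/2` for
  `0.25 < w < 0.75` (numeric root-finding outside that band).  At `w = 0.5`
  this is exactly `ln 2/(C/2)`.  This definition reproduces the published
  group discrimination accuracies from the published capacities to within
  0.2%, which is why it was adopted.

Units: rates in Hz and times in seconds inside the math layer; trial tables
and all file formats carry SOA in milliseconds.

## Hierarchical inference

Trials are collapsed to binomial cells (participant x condition x SOA,
optionally split by repetition index or sliding window).  The generative
model is:

- Group level: per condition, a mean log-capacity `mu_logC` and (when the
  design identifies it) a mean logit-weight `mu_logitw`.
- Participant level: deviations `delta_i` from the group means, bivariate
  normal across the two instruction conditions with spreads
  `sigma` (half-normal priors) and a correlation `rho` under an LKJ(eta)
  prior (eta = 1 by default, i.e. flat over the correlation).
- Deterministic mapping through `C = exp(.)`, `w = logit^{-1}(.)`,
  `v_p = Cw`, `v_r = C(1−w)` and the race psychometric function to a
  probe-first probability per cell; `y ~ Binomial(n, theta)`.

Because sampling happens on the unconstrained scales, every posterior draw
satisfies `C > 0` and `0 < w < 1` by construction.

Hyper-priors (overridable via `ModelSpec.priors`): `mu_logC ~ N(log 40,
0.5)` — weakly informative around typical TOJ capacities; `mu_logitw ~
N(0, 0.5)` — centered on an even attention split; `sigma ~ HalfNormal(0.3)`
on both transformed scales; adaptation rate `log rate ~ N(log 0.7, 1)`.
These are deliberately broad: in the data regimes the package targets the
likelihood dominates all of them except `rho`, which stays prior-driven in
small cohorts.

Equal-relevance designs (both judged stimuli are targets) fix `w = 0.5`
(`estimate_w=False`); the weight node disappears from the model.

### Capacity adaptation

Within-sequence adaptation is modeled on the log-capacity scale, either as
an inverse-exponential curve `asym + (start − asym)·exp(−rate·r)` over the
repetition index `r` (three parameters per condition) or as free
per-repetition cell means.  The two structures are compared with
PSIS-LOO (`compare_models`, arviz backend), mirroring the choice between a
superimposed growth curve and unconstrained trial-level variation.

### Sampling

The posterior is sampled by an adaptive Metropolis-within-Gibbs scheme with
four blocks per sweep:

1. group-level means/curve parameters (random-walk with covariance adapted
   during warmup);
2. likelihood-invariant *translation* moves that shift a condition's group
   level and counter-shift its participant deviations (accepted on the
   prior ratio alone) — these decorrelate the group means from the
   deviations;
3. *rescaling* moves that multiply a condition's deviations by `exp(e)`
   while adding `e` to its log-spread (Jacobian `exp(n·e)`), crossing the
   sigma–delta funnel, plus an independence refresh of `rho` from its LKJ
   prior;
4. all participant deviations proposed jointly with per-participant
   accept/reject and per-participant adapted step sizes.

Several independent chains (default 4) are run from over-dispersed starts
seeded near a coarse-grid pooled estimate; rank-based R-hat and ESS
(arviz) are computed over chains.  Correctness was verified two ways:
against dense two-dimensional grid integration of the complete-pooling
posterior (means and sds agree to <2%; kept as a permanent test) and by
frequentist calibration — across simulated replicates the group-mean 95%
HPDs cover the generating truths at close to the nominal rate (kept as a
permanent test at 20 replicates).

Sampler defaults: 4 chains x 5000 retained draws (thin 4, warmup 2000
sweeps).  The scaled-down studies in the test suite use 4 x 500–1000.  An
ESS target (default 10,000 on the parameters of interest, matching the
headline analyses' standard) is enforced as a surfaced warning: scaled-down
runs are expected to warn, and a run whose group-block acceptance collapses
below 2% raises `DiagnosticError` instead of returning draws.

### Summaries

Point estimates are posterior modes from a Gaussian KDE (Silverman
bandwidth, argmax on a 1024-point grid over the sample range — reproducible
and deterministic); intervals are 95% highest-density intervals computed as
the shortest contiguous interval containing 95% of the sorted draws
(cross-checked against `arviz.hdi` in the tests).  Derived quantities (DL,
PSS, contrasts between conditions) are computed per posterior draw and then
summarized, so their HPDs propagate full posterior uncertainty; plug-in
evaluation at the mode is available separately for desk checks.

## Synthetic experiments

`simulate` generates complete experiments from a known population truth:

- **exp1** — 244 trials/session of alternating assertion/negation sequences
  with lengths {1, 2, 5} (per-condition counts chosen to exhaust the
  122-trial budget as evenly as possible), seven SOAs (0, ±16.7, ±50,
  ±100 ms) balanced within (condition, repetition) cells by cycling
  shuffled SOA lists, a distractor-pair flag, and `w = 0.5`.
- **exp2** — the same sequence structure with a single stimulus pair and a
  free `w`.
- **exp3** — blocked: one 220-trial single-condition session per condition
  (order counterbalanced across participants), eleven SOAs (adds ±33.3 and
  ±66.7 ms), 20 trials per SOA, shuffled.

Participants are drawn on the transformed scales from bivariate normals
with a shared assertion/negation correlation (log C and logit w blocks are
independent of each other).  Defaults anchor the population at the group
estimates of the corresponding study (e.g. 53.8/44.5 Hz and 0.576/0.504 for
the exp2 layout).  Between-participant spreads are not published; the
defaults `sd_C = 0.15` (log scale, ±15% capacity spread) and `sd_w = 0.2`
(logit scale) are typical of individual differences in TOJ capacity and
were fixed once.  Adaptation curves act on the group capacity in Hz as a
function of within-run position; participant offsets shift the whole curve
on the log scale.  The curves are applied to C only: the published
repetition drifts in `w` are an order of magnitude smaller than those in C,
and modeling them would add parameters the verification studies cannot
identify.  An optional attention-capture mixture (`mixture_eps`: respond at
random with probability eps) represents distractor capture in the exp1
layout; the default is 0 because no capture rate is published.

Responses come either from explicit exponential races (onset-anchored
exponential encoding times, probe wins if it finishes first) or from
Bernoulli draws through the closed form; the two paths are statistically
indistinguishable and are tested against each other.

What the generator does **not** emulate: stimulus rendering, audio
instruction delivery, browser/display timing jitter, reaction times,
session-level fatigue, or any response bias beyond the race model.  Passing
recovery tests therefore demonstrates the estimator is correct *under the
model's own assumptions*, not that real data meet those assumptions.

## Sequential analyses

`annotate_repetitions` assigns each trial its position in the maximal run
of same-condition trials (per participant and session), capped at 4 for
comparability across designs, with the uncapped position kept in
`position_in_run`; it is idempotent and validated against run-length
oracles.

`make_windows` produces half-open `[start, start+width)` windows stepped by
`step`; a 220-trial block with width 110 and step 22 yields exactly six
windows.  `windowed_fit` fits each window *independently*: because
consecutive windows share 80% of their trials, a joint likelihood with
window as a cell factor would count each trial in up to five windows, so
the independent-fits route (the natural one for overlapping windows) is the
default.  Window fits default to complete pooling for speed; any
`ModelSpec` can be passed for a hierarchical per-window analysis.

## Verification studies and their scales

The study routines in `tvatoj.studies` back both the test suite and the
analysis scripts; problem sizes were chosen by a-priori power reasoning:

- **Race agreement**: 10^6 races per point on C ∈ {20, 40, 60} x
  w ∈ {0.3, 0.5, 0.7} x the seven-SOA grid; agreement within 3 binomial SE.
- **Recovery**: 15 participants x 244 trials, truths 53.8/44.5 Hz and
  0.576/0.504, correlation 0.5.  At this scale the per-participant
  information floor (sd(log C-hat) ≈ 0.22 per condition) puts the posterior
  sd of the capacity contrast at ≈ 4.7 Hz against a true difference of
  9.3 Hz, i.e. the contrast sits near two posterior sds from zero; interval
  coverage of the four group means is the robust part of this check, and
  zero-exclusion of the contrast is borderline by construction at this
  cohort size (it is ~5 sd at the full published scale of 42 participants
  x 3 sessions).
- **Adaptation selection**: the negation condition's recovery curve
  (26.1 → 31.5 Hz, rate 0.8) yields an expected leave-one-out gain of
  ~0.055 nats per 244-trial session over a flat model, against a
  2-parameter complexity penalty; ~200 sessions (66 participants x 3) put
  the expected ELPD difference near two standard errors, giving the
  10-replicate study reliable discrimination — and, under a flat truth, a
  reliable *absence* of preference.
- **Windows**: 8 participants, constant truth (null) and a strong downward
  drift (80 → ~50 Hz across the block) for trend recovery.

## Numerical choices and edge cases

- Probe-first probabilities are clipped to `[1e-12, 1 − 1e-12]` inside the
  likelihood; log-capacities are clipped to `[−10, 12]` before
  exponentiation to keep early warmup finite.
- `soa = 0` takes the probe-trails branch (identical value either way).
- HPD and mode computations require ≥ 100 draws and raise otherwise; a
  constant sample's mode is that constant.
- The DL per-draw computation uses the closed form for `0.25 < w < 0.75`
  and falls back to bracketed root-finding for the (rare) draws outside.
- Cell aggregation refuses empty tables and unknown groupings; the
  validator names the offending column and row for schema violations, and
  windowed fits warn when a window lacks an SOA level.

## Known limitations

- `rho` (the between-condition effect correlation) is weakly identified in
  cohorts under ~30 participants; its posterior stays close to the prior
  and mixes slowly relative to the other parameters.  It is reported with
  its ESS so this is visible.
- The ESS ≥ 10,000 standard is met only by full-scale runs; desk-scale
  fits warn.
- PSIS-LOO Pareto-k diagnostics run high when draw autocorrelation is
  substantial; the comparison report carries the count of flagged cells.
- The OSF deposit of the original studies is not bundled; `read_trials`
  defines the documented CSV schema an ingest adapter would map onto, but
  no network access or deposit-specific parsing is included.
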