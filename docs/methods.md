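# Methods

This note documents the models, the numerical choices, and what the
synthetic cohort does and does not emulate. Section order follows the
pipeline.

## Interoception scoring

The HCT error rate is the mean absolute relative miscount across the
session's timed intervals, ×100; the TET is scored identically with the
true interval length as the reference. The divisor is the number of
intervals actually present (six in the standard design; a warning is
emitted otherwise) so partial sessions still score. Reported counts are
required to be non-negative integers — they are verbal reports. The
formula is applied as printed even when a report more than doubles the
actual count, so error rates above 100% are possible and are not clipped.

## Event-locked windows and the change-rate statistic

RR intervals are the successive differences of pulse apex times, in
milliseconds throughout. For each analysed trial, windows span
[onset − 5 s, onset + 10 s] around the onsets at 15 s and 30 s; an RR
interval belongs to a window when its *terminating* apex falls in the
span. RR0 is the last interval ending at or before the onset — an
interval ending exactly at the onset is RR0 (the tie must be fixed for
reproducibility; "immediately before" is read as inclusive). The
comparison condition is the non-vibration trial immediately preceding
each vibration trial, scored at the same nominal onsets.

The change rate uses the fixed denominator 3 slots × 10 windows per
condition; windows in which RR0–RR4 cannot all be resolved contribute
zero hits but stay in the denominator. "A change point at RRk" means a
segment boundary whose new segment starts at the position labelled RRk.
Windows around the two onsets are segmented separately (they are disjoint
spans).

## Change-point engine

Segmentation cost is the Normal −2 log maximized likelihood with
per-segment mean *and* variance (constants dropped): `n·log σ̂²` per
segment. Penalties: `mbic` (default) charges `(p+2)·log n` per change
point with `p = 2` parameters per segment plus a `log(len)` term on every
segment; `bic` charges `(p+1)·log n`; a float is a manual per-change-point
penalty. Minimum segment length is 2 so variance is estimable.

Two numerical choices matter:

* **Variance floor.** The maximized likelihood of a two-point segment
  diverges as its sample variance → 0, which makes information-criterion
  penalties useless on short windows (roughly half of length-15 i.i.d.
  windows would contain a spurious change point). Segment variances are
  floored at 0.1× the full-window variance. The floor scales with the
  data, so segmentation is invariant to unit rescaling; it holds the
  null false-positive rate below ~5% while leaving mean steps of the
  magnitude of interest fully detectable.
* **Exact pruning.** The optimizer is PELT. With a minimum segment
  length, pruning a candidate at time *t* is only valid from
  *t* + min_seg_len onwards, so removals are deferred; and because the
  floored cost is not strictly subadditive, the pruning inequality keeps
  a slack of `n·log 2 (+ log n under MBIC)`, a proven bound on the
  violation. Both choices keep the search *exact*: an independent
  exhaustive enumeration of all admissible segmentations
  (`exhaustive_changepoints`) is part of the test and acceptance suites
  and must agree on 100% of random windows.

## Thought coding

Adjacent-pair indicators are computed within block only; the pair
spanning the between-block break is never counted. Pairs touching
category 3 (peripheral stimuli, excluded for sparsity) or category 6
(absent-minded, no verbal content) are discarded without bridging: the
sequence 1, 6, 1 yields no 1→1 continuation. This non-bridging reading is
the conservative, order-preserving choice where the alternative
(counting across an excluded report) is equally defensible. "More than
half of the trials" in the correct-response exclusion is read strictly:
exactly 50% correct fails. A trial is correct when all of its three
targets were answered; misses only (not false alarms) enter the
criterion. Unusable pulse data is operationalised as >5% of RR intervals
outside (250, 3000) ms.

## HRV

The tachogram (RR against terminating apex time) over the final three
quarters of each block (closed on the left at the quarter mark) is
cubic-spline interpolated onto a 4 Hz grid, detrended with the
smoothness-priors high-pass (second-difference regularisation,
λ = 500 — the convention of standard HRV software), and analysed with
Welch's method (256-sample Hann segments, 50% overlap). Band powers are
trapezoid-integrated over VLF 0.003–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz.
A pure 0.25 Hz modulation of amplitude A recovers its closed-form power
A²/2 within a few percent, which anchors the calibration. HF power is
*modelled* on the natural-log scale (band powers are lognormal across
participants; on the raw ms² scale the scale-3 slope prior would dominate
the likelihood and any block-effect test would be vacuous); the CSV
output keeps raw ms² alongside `log_hf`.

## Hierarchical models

Each response is regressed with a per-participant random intercept:
Gaussian identity for change rate and HRV; Poisson log link for counts
(a "logit link" for Poisson is undefined; log is the canonical choice).
Covariate coding: vibration 0/1, sex 0 = men / 1 = women, score = HCT
error rate in percent, entered uncentered (centering available by flag).
Priors: slopes Normal(0, 3) with a Cauchy(0, 3) variant switchable;
intercept Student-t(3, ·, ·) and random-intercept sd half-t(3, 0, ·),
where the location/scale are 0 / 2.5 for the Poisson family (log scale)
and median(y) / max(2.5, mad(y)) for the Gaussian family — the
data-scaled convention regression tools apply internally; 2.5 is that
scale's conventional floor, and a zero-centred scale-2.5 intercept prior
on a response living at a scale of hundreds creates a spurious posterior
mode. Residual sd prior: half-t(3, 0, max(2.5, mad(y))).

Sampling is 4 chains × 2000 iterations (1000 warmup, thinning 1), 4000
retained draws. The Gaussian family integrates the random intercepts out
analytically (Sherman–Morrison per group) and samples
(β, log τ, log σ) with a joint adaptive random-walk Metropolis; with only
two observations per participant the τ–σ funnel is otherwise
near-intractable for Gibbs-style kernels. The Poisson family uses
Metropolis-within-Gibbs with a vectorised pass over the conditionally
independent intercepts, plus two reparameterisation moves (an
intercept/random-effect location swap and a (u, τ) scale move) that
traverse the posterior's ridges. Adaptation (Haario covariance for the
joint blocks, Robbins–Monro scale tuning elsewhere, with the adapted
covariance regularised by a slice of its initial value so no coordinate's
step collapses) runs during warmup only; the retained draws come from a
fixed kernel. Convergence is declared at R̂ ≤ 1.1 for every parameter
(rank-normalized R̂ and bulk/tail ESS via ArviZ); a coefficient is
"supported" when its equal-tailed 95% CI excludes 0. The test suite
cross-checks the Gaussian posterior against statsmodels MixedLM (REML) on
the same data, and the Poisson fits against their planted generative
coefficients.

## Synthetic cohort

The generator's defaults are the study conditions: 100 participants, 70%
women; vigilance task of two 20-trial blocks (42 stimuli of 500 ms +
500 ms ISI per trial → 42 s, 3 targets, ~6 s probe time appended, a
5-minute break), 5 non-consecutive vibration trials in the second block
with onsets at 15 s and 30 s; HCT intervals {25,25,35,35,45,45} s and TET
{23,23,49,49,56,56} s; 2/9/3/6 participants with, respectively, unusable
pulse data, vibration awareness, low response rates, and no core-category
reports (disjoint, 100 → 80 retained). Latent interoceptive accuracy is
Normal(0.6, 0.23) clipped to [0,1], placing the HCT error distribution
near mean 40%, sd 23%; HCT reports are `actual × accuracy + noise`,
rounded half-up (verbal counts are integers) and floored at 0. TET
reports are driven by a participant-level time bias (sd 0.27) drawn
independently of latent accuracy, so the HCT–TET correlation is ~0 by
construction. Per-participant RNG streams derive from (cohort seed,
participant index, purpose) so cohorts are reproducible under parallel
generation and no two uses share entropy.

**Cardiac process.** Apex times integrate an RR process: participant mean
(850 ± 60 ms between participants) + 0.1 Hz and 0.25 Hz sinusoids
(25/20 ms, with lognormal participant-level spread cv 0.3 and
block-to-block drift cv 0.2) + white noise (10 ms). In vibration trials,
with probability `p_vibration_cp` (default 0.6) a mean step of 120 ms —
a ~10 bpm transient deceleration — starts at the first interval ending
after the onset and decays (1.0, 0.8, 0.5, 0.0) over RR1–RR4, matching
the observation that the induced change has converged by RR4. Spontaneous
transients of the same magnitude and random sign occur at a stationary
background rate (one per 15 s tile with probability `p_spontaneous_cp`,
default 0.1) across the *whole* session, so the two blocks share the same
background. Unusable pulse traces are emulated as double-triggering
artifacts (spurious apexes 50–200 ms after real ones), which the RR
plausibility filter catches.

**Thought process.** Categories follow a participant-level first-order
Markov chain with stationary masses (0.35, 0.12, 0.03, 0.10, 0.25, 0.15)
— category 3 deliberately rare. The category-5 self-return probability is
`exp(b0 + b_score·score + b_vib·vib + b_int·score·vib)` while the entry
probability into 5 is rebalanced so the marginal category-5 rate is
constant in the covariates; the expected continuation count is then
*exactly* proportional to the exponential of the linear predictor, i.e.
the planted coefficients are the same estimand as the Poisson log-link
regression slopes. (With the conventional log-odds parameterisation —
available as `self_return_link="logit"` — the fitted coefficient is a
systematically attenuated version of the planted one and recovery
experiments would target a moving quantity.) Defaults b0 = −1.8,
b_score = 0.007, b_vib = 1.387, b_interaction = −0.02 plant the headline
interaction; high contemplation of category 5 carries the same structure
at half the size (−0.010), and high consistency is a planted null.
Category-6 reports suppress the follow-up probes, as in the task.

**What the generator does not emulate.** Raw photoplethysmogram
morphology (apex times suffice; `detect_apexes` is exercised on toy
waveforms), reaction times, respiratory sinus arrhythmia coupling to
actual breathing, non-stationary thought dynamics beyond the first-order
chain, and any dependence of exclusion-type membership on latent
accuracy. Passing tests therefore demonstrate that the pipeline measures
what the generative model plants at realistic noise levels — not that the
paper-level effects exist in human data.

## Known limitations and discovered interactions

* The vibration-locked decelerations themselves carry band power: on
  default settings the vibration block's HF is genuinely (slightly)
  elevated. The HRV null-calibration experiments therefore run with
  `p_vibration_cp = 0`; on the default cohort a small HF block effect is
  *correct* behaviour, not autonomic drift.
* With the false-positive-calibrated penalty the baseline change rate
  (~1–2%) is lower than in typical human data, where spontaneous
  physiological regime shifts are more frequent; `p_spontaneous_cp` and
  the penalty are both configurable.
* Poisson models assume equidispersion; the Markov-chain counts are mildly
  overdispersed and the random intercept absorbs most but not all of it.
* The exhaustive change-point oracle is exponential and capped at n = 20;
  windows in this design are well under that.

## Problem sizes

Default test and experiment sizes are chosen for a laptop-class single
CPU: oracle-equivalence on 500 windows of n ≤ 15; 20 cohorts of 20
participants for the condition-separation check; 20 end-to-end recovery
replicates at n = 80 with a 2-chain × 500-draw sampler; 20 HRV
null-calibration cohorts of 16 participants. The study-scale pipeline
(100 participants, full 4 × 1000 sampler for five models) runs in well
under a minute.
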