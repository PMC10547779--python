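# cardiothought

Analysis pipeline for a psychophysiology study design that asks whether
**subliminal changes in heart rate shift ongoing thought, and whether the
effect depends on interoceptive accuracy**. Participants complete a
heartbeat counting task (HCT) that scores how accurately they perceive
their own heartbeat, then a vigilance task in which thought probes sample
their mental state every trial while subliminal vibration stimuli induce
small cardiac decelerations in half the session. The pipeline covers the
full chain from raw pulse apex times to Bayesian hierarchical models, plus
a synthetic cohort generator that plants the design's key effects so every
stage can be exercised and calibrated without participant data.

## What it computes

**Interoceptive accuracy.** The HCT error rate per participant,

```
score = (1/6) Σ |actual − reported| / actual × 100
```

over six timed counting intervals (2×25, 2×35, 2×45 s), with the analogous
time-estimation task (TET) as a control; a near-zero HCT–TET Pearson
correlation shows counting is not time estimation.

**Heart-rate change rate.** RR intervals (pulse apex-to-apex, ms) are
windowed from 5 s before to 10 s after each vibration onset (15 s and 30 s
into the trial). RR0 is the interval ending at or before the onset,
RR1–RR4 the next four. Change points of segment **mean and variance** are
found by exact penalized segmentation (PELT with an exhaustive-search
oracle, modified-BIC penalty), and per block

```
change rate = (# change points at RR1, RR2 or RR3) / (3 × 10 windows) × 100 .
```

Non-vibration trials immediately preceding each vibration trial are scored
at the same nominal onsets as the comparison condition.

**Thought-state coding.** Probe responses (category 1–6, contemplation
1–3, consistency 1–3) are coded per 20-trial block into continuation
counts (same category on successive trials, per category in {1,2,4,5}),
transition counts anchored on the task-focused category, and
highly-contemplated / highly-consistent counts for category 5
(self-referential mind-wandering, "TC5"). Participant exclusions (noticed
the vibration; ≤50% correct target responses; never reported a core
category; unusable pulse data) are applied first.

**HRV.** Welch band powers of the 4 Hz-resampled, smoothness-priors
detrended RR tachogram over the last 3/4 of each block: VLF
(0.003–0.04 Hz), LF (0.04–0.15), HF (0.15–0.4) in ms², and LF/HF.

**Inference.** Bayesian GLMMs with a per-participant random intercept:
Gaussian for change rate and HRV, Poisson (log link) for counts, fixed
effects from {score, vibration, sex, score×vibration}, slopes ~ N(0, 3),
4 chains × 1000 retained draws, equal-tailed 95% credible intervals, R̂
and bulk/tail ESS per parameter. The focal quantity is the
**score×vibration interaction** on TC5 continuation: a negative
coefficient means accurate perceivers continue self-referential thought
more when heart-rate changes are induced. The MCMC engine is in-package
(marginalized adaptive Metropolis for the Gaussian family,
Metropolis-within-Gibbs for Poisson) and is cross-checked against REML
estimates in the test suite.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (100 participants, 70 women, 20 with exclusion-triggering
profiles). After `python analysis/01_simulate.py` through
`07_parameter_recovery.py`:

```
100 entering, 80 retained
mean change rate (%):
non_vib     1.38
vib        10.12
mean RR deviation profile in vibration windows (ms):
rr1_minus_rr0_ms    74.5
rr2_minus_rr0_ms    60.8
rr3_minus_rr0_ms    37.9
rr4_minus_rr0_ms    -0.1

change_rate        vibration        b = +8.109 [+6.290, +9.867]  supported
tc5_continuation   score:vibration  b = -0.023 [-0.035, -0.011]  supported
hc5                score:vibration  b = -0.002 [-0.014, +0.009]  CI includes 0
hrv_lfhf           vibration        b = -0.174 [-0.426, +0.111]  CI includes 0

20 end-to-end replicates at n = 80, truth -0.02
  posterior mean of the interaction: -0.0179 (bias +0.0021)
  negative sign recovered: 20/20
  truth inside the 95% CI: 20/20
```

Reading: the induced decelerations are visible in RR1–RR3 and gone by RR4;
the change rate is far higher in vibration windows; the planted negative
score×vibration interaction on TC5 continuation (generative value −0.02)
is recovered essentially without bias by the full
simulate → score → code → fit chain.

A CLI mirrors the stages for shell use:

```
cardiothought run-all --out results/run --seed 7
cardiothought simulate --out data --seed 7
cardiothought fit --model tc5_continuation --in results/run --out fits --seed 7
```

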