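# Methods

This note documents the models and procedures implemented in `chirpinv`:
what is simulated, how each statistic is defined, which conventions were
fixed where the problem left them open, and what the synthetic data do and
do not establish.

## Stimulus model

The beat is modeled directly as the AM envelope, a unit sinusoid at
`f_beat` (default 4 Hz); the EOD carrier is never synthesized because every
downstream statistic operates on the AM.  A small (type II) chirp is a
Gaussian excursion of instantaneous AM frequency with peak `delta_f`
(default 60 Hz) and width `sigma` (default 14 ms); the AM is the sine of
the accumulated phase `2π ∫ (f_beat + g(τ)) dτ`.  The default chirp
advances the beat by `delta_f·sigma·√(2π) ≈ 2.106` cycles — the familiar
phase reset.  Waveforms are sampled at 10 kHz; traces last 2 s with the
chirp at 1 s.

Two conventions are free in this construction and are fixed as follows:

- **Chirp onset mark.**  The Gaussian excursion has no sharp onset; the
  package places the onset mark 2.25 σ before the excursion center, where
  the excursion is at ~4% of its peak.  All analysis windows (the 30 ms
  distance window, the response window centered 15 ms after onset) are
  referenced to this mark, so the 30 ms window covers the rising front of
  the perturbation — the epoch commensurate with the chirp duration.
- **Beat-phase reference.**  Phase 0° is the beat trough (AM minimum),
  90° the upward zero crossing, 180° the beat peak.  The onset phase of a
  chirp is the total beat phase at the onset mark, and a round-trip check
  (arcsin with derivative-sign branch disambiguation) recovers it to
  < 1°.  Under these two conventions the model afferent population is
  excited by chirps at onset phases < 180° and inhibited at phases ≥ 180°,
  which defines the '+ chirp' / '− chirp' split used by the subset
  analyses.

The canonical set is eight waveforms S1…S8 at onset phases 0°–315° in 45°
steps.

## Synthetic neural data

Rate-based models drive stochastic spiking.  All stages share one AM
**drive** `H(t) = S(t) + β·S′(t)/(2π f₀)`, boxcar-smoothed, with β = 0.5
and f₀ = 30 Hz: a mild high-pass that leaves the 4 Hz beat essentially
untouched while boosting the gain during the ~60 Hz chirp sweep by ~45%.
This reflects the rising AM-frequency tuning of the electrosensory
periphery and is what makes fast chirp transients stand out from the slow
beat at every stage.

**P-unit afferents** — rate `r(t) = max(0, r₀·(1 + g·H(t)))` with baseline
r₀ drawn per unit from N(380, 72²) Hz and gain g = 0.8 (deep, faithful AM
modulation).  Spiking is an inhomogeneous **gamma renewal process of order
4** sampled by time rescaling: P-unit interspike intervals are much more
regular than Poisson (CV ≈ 0.5 here), and that regularity sets the noise
floor of pairwise correlation measures.  Time rescaling realizes the rate
trace exactly (no dead-time cap); pairs share the stimulus drive but spike
independently — afferents carry no noise correlations, so simultaneous and
recombined (trial-rotated) pairings are statistically equivalent, which
the tests verify.

**ELL pyramidal cells (ON / OFF)** — baseline N(12.1, 1.74²) Hz; dual
coding with a tracking and a burst component:

    r(t) = max(0, r₀·(1 ± [g_t·H(t) + g_b·tanh(κ/κ₀)·E(t)]))

with sign + for ON and − for OFF cells, tracking gain g_t = 0.5, burst
gain g_b = 4, burst saturation κ₀ = 0.2.  `E(t)` is the **fast-transient
envelope** of the drive (sliding RMS, 10 ms, of the drive minus its 25 ms
running mean): near zero during the beat, rising at the chirp with a
temporal shape nearly independent of onset phase — the stereotyped burst.
`κ` is the decoded drive strength, the mean of `H` over the response epoch
(15 ms window centered 15 ms after onset): positive for '+ chirps',
negative for '− chirps', so ON cells burst for '+ chirps' and are
rectified silent for '− chirps', and OFF cells mirror them.  The tanh
makes burst amplitude a threshold-like, saturating function of stimulus
strength, as bursts are.  A pure rectified-tracking pyramidal model was
evaluated first and rejected: a static function of the drive re-encodes
every waveform difference and scores at or below the afferent level,
contrary to the decoding role of these cells.  Spiking is Poisson with a
2 ms absolute refractory period (dead-time-compensated hazard).

**TS (midbrain) neurons** — baseline N(3.35, 3.27²) Hz (floored at
0.5 Hz), driven by the rectified suprathreshold deviations of the
canonical ON and OFF rate traces:

    r(t) = max(0, r₀ + w·[(r_ON − r₀,ON − θ)₊ + (r_OFF − r₀,OFF − θ)₊])

with weight w = 1.5 and rectification offset θ = 15 Hz — above the
beat-driven ELL modulation (~6 Hz) and below chirp-burst deviations
(~35–60 Hz).  The beat therefore leaves TS at baseline while chirps of
either polarity excite it through whichever pyramidal population bursts;
both '+' and '−' chirps yield positive responses.

**Echo-response recordings** — per fish, forty stimulus chirps (eight
onset phases × five repeats, shuffled) separated by 15 ± 3 s (uniform).
The EOD-frequency trace sits at 800 Hz with 1 Hz Gaussian jitter; after
each stimulus onset the fish emits an echo chirp with probability
`p_echo` (default 0.4) **independent of the onset phase**, at a latency
drawn from a gamma distribution (mean 0.4 s) truncated to (0, 1] s.  Echo
excursions are Gaussian bumps with small-chirp statistics: peaks
N(60, 15²) Hz truncated to [40, 140] Hz (all above the 30 Hz detection
criterion, ≥95% type II under the 150 Hz big-chirp boundary), widths
~12 ms.

## Analysis

**Binarization and PSTHs.**  Spike trains are binned on half-open bins
(0.5 ms default; edge spikes go right).  PSTHs use 0.1 ms bins averaged
across trials and a centered 6 ms boxcar; smoothing truncates half the
boxcar at each trace edge, and the unsmoothed histogram conserves the
spike count exactly.

**Time-varying correlation ρ(t).**  For each 31.25 ms window stepped by
0.25 ms, both trains are reduced to counts at a 2 ms coincidence timescale
(evaluated every step, so bins overlap), per-trial window means are
removed, and ρ is the absolute Pearson correlation over all (bin, trial)
samples in the window.  ρ(t) rises whenever the shared stimulus sweeps
both rates rapidly within the window — which a chirp does at every onset
phase, through excitation and inhibition alike — and sits near the null
level `E|r| ≈ √(2/πN)` during the undisturbed beat.  Windows with zero
count variance in either train are masked as undefined rather than set to
0.  An alternative estimator that correlates windowed count *deviations
across trials* was evaluated and rejected: during the multi-cycle sweep
the window-mean AM deviation averages toward zero, so that estimator
*falls* at the chirp instead of rising.  A literal, loop-based
fixed-window (40 ms) implementation serves as the oracle for the
vectorized code (agreement to 1e-12), and a plain across-trial residual
count correlation (`noise_count_correlation`) verifies the absence of
noise correlations.

**Response measure and tuning.**  `Response = ln(FR_chirp / FR_beat)`
with FR_chirp the mean PSTH over a window of 15 ms (afferents, ELL) or
20 ms (TS) centered 15 ms after chirp onset, and FR_beat the mean rate
over all samples further than 100 ms from the onset.  Rates are floored
at 0.1 Hz before the ratio (flagged when the floor binds) so silent
windows stay finite.  Natural log is the default (base 10 available);
tuning-curve shapes are base-invariant up to scale.  Tuning curves carry
per-unit values for all eight phases plus the population mean ± SEM; the
normalized variant scales the population curve to unit peak magnitude.

**Distance and invariance.**  Traces are restricted to the 30 ms window
after chirp onset, mean-subtracted and scaled by their maximum absolute
deviation, then `D(x, y) = RMS(x̃ − ỹ) / max(hr_x, hr_y)` with hr the
half-range; the literal squared-numerator variant is available via
`convention="squared"`.  Both conventions satisfy the analytic anchors
(identical responses → 1, responses equal to the stimuli → 0) because the
score ratio shares the convention between numerator and denominator.  The
score averages `D(resp_i, resp_j)/D(S_i, S_j)` over unordered pairs
(identical to the ordered mean since D is symmetric) for the `all`,
same-type (`++/--`) and opposite-type (`+-`) subsets, each with its own
pair count (56 / 24 / 32 ordered pairs for a 4+4 split).  A zero stimulus
distance for a selected pair is an error (degenerate stimulus set); a
constant-pair response distance is defined as 0.  Inputs by level: single
PSTHs, summed population PSTHs, ρ(t) traces, or behavioral PSTHs.  TS
units with score > 0.25 form the high-invariance subgroup used in
subgroup summaries.

**Behavior.**  Instantaneous EOD frequency is the inverse of the interval
between successive upward zero crossings (linearly interpolated, assigned
at the left crossing, resampled by previous-value interpolation); chirps
are contiguous excursions exceeding 30 Hz above the pre-stimulus median
baseline, marked at maximal excursion, merged when separated by < 20 ms,
and typed small/big at a configurable 150 Hz boundary.  Per presentation:
`CR_chirp` counts echo chirps in (0, 1] s after onset, `CR_beat` in
(1, 2] s, latency is the first echo in the response window, and the
response is `ln(CR/CR)` with rates floored at one event per window.  The
stated 15 ms ± 3 ms interval between stimulus chirps is treated as a slip
for 15 ± 3 s, since a millisecond gap cannot host the 1–2 s analysis
windows.  Pooled per-phase PSTHs (2 ms bins in the pipeline default,
1 s boxcar, edge bins averaged over the covered part of the boxcar) are
the behavioral response input to the invariance score.  Because echo
latencies extend to 1 s, the behavioral invariance uses the full
[−0.2, 2] s PSTH time course as the response trace (stimulus distances
are still taken over the 30 ms window); a 1 s-smoothed trace restricted
to 30 ms would be constant up to sampling noise and carry no information.
Behavioral standard errors use a moving-block bootstrap with block size
27.

## Problem sizes and reproducibility

Default populations follow the reference sample sizes: 18 single
afferents, 8 pairs, 22 ON + 9 OFF pyramidal cells, 25 TS units, 29 fish,
20 trials per waveform.  `scripts/acceptance.py` uses exactly these; the
CLI `demo` uses reduced populations (6/4/6+3/8/12) for a seconds-long
run.  Every random draw descends from the run seed through spawned
`SeedSequence` streams, so identical configurations reproduce bit-for-bit.

## What the generator does and does not emulate

Captured: baseline rates and their across-unit spread, P-unit regularity,
absence of afferent noise correlations, deep faithful AM coding at the
periphery, ON/OFF complementarity with rectification at low baselines,
burst-like transient detection, excitatory ON+OFF convergence in the
midbrain, phase-independent echo behavior with realistic latencies and
small-chirp statistics.

Not captured: EOD-cycle phase locking of P-units (the analysis operates on
AM timescales), conductance-based dynamics, adaptation, ELL feedback
pathways, the heterogeneity of real TS cell classes (all model TS units
are chirp-selective, so the high-invariance subgroup is the whole
population rather than ~half), big (type I) chirps, and free-swimming
behavior.  Passing tests therefore show that the analysis pipeline
recovers the designed population structure — faithful periphery,
synchrony-based invariance, its partial decoding in ELL and refinement in
TS, phase-blind behavior — not that these models quantitatively reproduce
any particular recorded neuron.

## Known limitations

- The invariance score is noise-sensitive at low firing rates: trace
  normalization amplifies PSTH sampling noise, so low-baseline units score
  systematically below their noise-free ceiling at 20 trials.
- The ELL burst amplitude uses the decoded drive strength over the
  response epoch, an idealization of burst dynamics rather than a causal
  membrane model.
- ρ(t) magnitudes depend on the coincidence binwidth (2 ms default);
  invariance scores, which compare normalized shapes, vary by roughly 20%
  over the 0.5–4 ms range, and correlation windows up to ~60 ms give
  invariance within 20% of the default (the latter is checked in the
  property suite).
- The big/small chirp boundary (150 Hz) and the TS rectification offset
  are free parameters with documented defaults, not measured values.
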