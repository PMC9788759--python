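# Methods

This note documents the forward model, the analysis algorithms, the
numerical choices behind them, and what the synthetic data can and cannot
establish about real traces.

## Forward model

### Substrate-processing events

A binding event is productive with probability `p_capture`.  A productive
event runs through five states in fixed order, with independent random
phase durations:

| phase | state | distribution | default (wild type) |
|---|---|---|---|
| tail insertion | `bound_preinsert` | gamma(shape `n_ins`) | mean 1.8 s, shape 2 |
| deubiquitination dwell | `inserted_highFRET` | gamma(`n_dub`) | mean 1.1 s, shape 2 |
| translocation decay | `translocating` | gamma(`n_dec`) | mean 0.74 s, shape 3 |
| unfolding | `unfolding` | exponential | mean 6 s |
| post-unfolding release | `post_translocation` | exponential | mean 7.3 s |

Gamma shapes are not experimentally constrained; shapes of 2–3 are used
because each phase lumps several sequential molecular steps, which
produces the peaked (non-exponential) duration histograms seen in this
kind of data.  A nonproductive event is a single `bound_preinsert`
segment with an exponential dwell `tau_off` (the dissociation constant of
the delivery interaction: 0.61 s for ubiquitin-receptor binding, 0.32 s
for ssrA–SspB).  The donor dwell after the decay is the sum
unfolding + release; the wild-type default (6 + 7.3 s) reproduces the
measured 13.3 s donor persistence with an unfolding share consistent
with the ~6 s estimate for the destabilized titin V15P domain.

Substrates arrive per particle as a Poisson process (`arrival_rate`)
with a busy server: a new substrate cannot bind while an event is in
progress.  The capture-assay presets use 0.035 s⁻¹, which yields ~430
encounters per 50-particle, 300-s movie — inside the 296–470 events per
movie reported for that measurement.  The conformational-processing
presets use 0.006–0.012 s⁻¹ so that consecutive processing dwells are
separated by minutes of idling and never merge within the dwell-scoring
bridge window, matching the sparse dwells in published example traces.

### Conformational switching

Substrate-free dynamics are a continuous-time two-state telegraph process
with rates `k_s1` (s1 → non-s1) and `k_non_s1` (non-s1 → s1), started
from its stationary distribution.  During degradation the trace is pinned
in non-s1 for a gamma-distributed processing dwell (mean `tau_deg`,
shape `n_deg = 3`), interrupted by brief s1 excursions — motor slips
during unfolding attempts — modeled as a Poisson process
(`excursion_rate`) of exponential visits (mean 0.15 s, so that sub-50-ms
events exist and exercise the resolution floor).  Excursions are
suppressed during the final 3 s of each dwell, reflecting the
excursion-free translocation of the already-unfolded chain.  Preset
excursion rates are derived from the published counts per processing
event divided by the excursion-eligible window (e.g. 11/44 s⁻¹ for
wild-type titin, 0.7/7.7 s⁻¹ for V15P).

### Photophysics

States map to true FRET efficiencies (conformational assay: 0.25/0.75
for s1/non-s1; processing assay: 0.45 at binding, 0.82 fully inserted,
a linear ramp 0.82 → 0.32 across the translocation segment through the
position calibration, a slow decline to 0.05 during unfolding, 0 after
the dye passes out of FRET range).  `trajectory_to_fret` rasterizes the
trajectory on the camera frame grid; by default each frame carries the
instantaneous value at its center (point sampling), which keeps the
sampled telegraph chain exactly `expm(Q·dt)` and therefore exactly
invertible by the rate correction below.  Setting `supersample > 1`
instead integrates within frames, emulating camera integration; this is
the right mode when sub-frame occupancy matters (e.g. the
fractional-occupancy excursion counter).

Rendering produces counts per frame:

    donor    = B·(1−E)·presence + bg_D + noise
    acceptor = B·E·presence + α·donor_signal + bg_A + noise

with brightness `B = 1000`, per-channel background 50, additive Gaussian
noise of SD 50 (an optional shot-noise mode scales the variance with the
signal), and donor→acceptor bleedthrough `α = 0.08`, typical for this
filter set.  Photobleaching is single-step and exponential: one donor
clock per presence block (each binding event carries a fresh donor dye,
rate 0.001 s⁻¹ of exposure) and one acceptor clock per trace whose time
base is accumulated acceptor *emission*, not wall time — the acceptor is
excited only through FRET at 532 nm, so an idle acceptor does not
bleach.  After acceptor loss the donor recovers the full brightness;
after donor loss the trace goes dark for the rest of the block.

## Analysis pipeline

### Preprocessing

Both channels are smoothed with a centered five-frame moving average
(shrinking symmetric windows at the edges; a reflect mode is available),
the acceptor is corrected by `A − α·D` floored at zero, and the total
fluorescence is the sum of the processed channels.  The apparent
efficiency `E = I_A/(I_D + I_A)` is computed from
**background-subtracted** channels — without the subtraction the
backgrounds bias the 0.82/0.32 anchors by several percent — and masked
(NaN) wherever the unsubtracted total is below twice the total
background, so E is only reported inside plausible events.  Background
levels are config inputs when known (the simulator's dark levels; in an
experiment, the dark areas of the field) with a robust per-trace
estimator as fallback: the median of the below-median frames, iterated
once within a twofold band.  A level more than 15× its own robust noise
is rejected as "no event-free frames", since a camera dark level carries
noise comparable to itself while an in-event plateau does not.

Particle QC mirrors standard practice: an intensity band on the total
fluorescence (rejecting doubly labeled particles at twice the singly
labeled brightness) and at most one downward photobleaching step.  Step
counting is binary-segmentation change-point detection with a minimum
step of 3× the robust noise SD; noise is estimated from lagged (lag-7)
differences so that pre-smoothed input does not fool it, a guard band
around each accepted split prevents a smoothing-smeared step from being
counted repeatedly, and residual splits within 8 frames are merged.

### Event detection and phase segmentation

Binding events are maximal runs of the smoothed total strictly above
twice the background (ties go to background), at least 2 frames long.
Two refinements use the unsmoothed total: a candidate run must contain
at least one raw frame above background + 5σ (at realistic SNR the 2×
threshold sits at ~3σ of the *smoothed* total, whose autocorrelated
noise otherwise produces tens of false events per movie, while a real
event always carries full-amplitude raw frames), and single raw frames
above background + 6σ outside detected runs are added as one-frame
events, so that sub-frame nonproductive encounters still enter the
capture-success denominator.

Phases are located with hysteresis and *timed* by interpolated level
crossings, which keeps durations unbiased under the five-frame
smoothing:

* event start/end: interpolated half-amplitude crossings of the total;
* high-FRET entry: first run of E ≥ 0.75 sustained 2 frames; the
  insertion boundary is then refined as the interpolated crossing of the
  midpoint between the intermediate plateau and the high plateau;
* decay: interpolated downward crossings of E = 0.70 and E = 0.44 give
  the ramp slope; the decay duration is (0.82 − 0.32)/slope and the
  decay start/end are the extrapolated anchor crossings.  Frame-snapped
  thresholding of a noisy, smoothed ramp would systematically shorten
  the 0.74-s decay by 15–20%; the two interior levels are symmetric
  about the ramp midpoint, so even decays comparable to the smoothing
  window stay nearly unbiased.

An event is productive when it has a sustained high-FRET phase, a
resolvable decay, and a donor dwell of at least 1 s; otherwise it is
nonproductive (intermediate-FRET binding).  The dwell floor only guards
against noise — the high-FRET requirement does the classification work —
and 1 s keeps genuine events with short exponential unfolding+release
dwells.  Events touching the trace boundaries are censored and excluded
from both duration fits and capture fractions.  Capture success is the
pooled productive fraction with the SD across movies as its error.

Phases shorter than about two frames (e.g. deubiquitination dwells under
~0.15 s, decays under ~0.25 s) are below the resolution floor set by the
smoothing window, as in any implementation of this measurement; they are
lost or censored, affecting a few percent of events at the default
constants.

### Processing-dwell scoring

On conformational-assay traces (analyzed at frame resolution and
truncated at the first masked frame, i.e. at photobleaching), frames are
classified high/low at E = 0.5; high fragments separated by low gaps
shorter than the 1-s bridge are merged, so excursions do not terminate a
dwell.  Leading/trailing fragments shorter than 2 s are trimmed together
with their gaps: idle non-s1 blips (mean 0.22 s at k_non-s1 = 4.5 s⁻¹)
essentially never reach 2 s, so bridged idle chains adjacent to a dwell
are removed, while genuine dwell edges (mean time to first excursion
~11 s) rarely are.  A dwell must contain one contiguous high run of at
least 2 s and last at least 3 s overall, which rejects chains of idle
switching.  Dwells adjacent to the trace boundary or to masked frames
are censored.

Excursion counting accepts either a ground-truth state path (exact
durations) or an efficiency series, where a visit's duration is the
integrated fractional occupancy of the low state — so a 40-ms excursion
that happens to dominate one 50-ms frame is not promoted to a full
frame, and the count is monotone non-increasing in the duration floor.

### Hidden Markov modeling

The two-state fit is pooled maximum-likelihood Baum–Welch with Gaussian
emissions: all traces of a condition share the two emission
distributions and the per-frame transition matrix.  (The published
analysis used an empirical-Bayes shared-prior HMM; at the SNR of these
data the pooled ML fit is simpler, deterministic, and recovers the same
rates — a deliberate design choice.)  Initialization is a deterministic
two-cluster split of the pooled efficiencies at the 25th/75th
percentiles; convergence is a relative log-likelihood change below 1e-6
(max 500 iterations; non-convergence is flagged, not raised).  Missing
frames emit probability 1.  The log-likelihood is asserted non-decreasing
across iterations, and the forward algorithm is verified against
exhaustive path enumeration on short traces.

Switching rates come from per-frame transition probabilities via the
exact two-state continuous-time correction

    λ = −ln(1 − p01 − p10)/dt,   k_ij = p_ij · λ/(p01 + p10),

which is the closed-form matrix logarithm of the sampled chain
`expm(Q·dt)` — at 20 Hz with a 4.5 s⁻¹ rate the naive `p/dt` and
elementwise `−ln(1−p)/dt` conversions underestimate the fast rate by
10–20%, while the matrix logarithm is exact for point-sampled traces.
Both alternatives remain available by config.  Dwell-based rates apply
the same correction to the inverse mean Viterbi run length.  Viterbi
ties break toward the previous state.

### Dwell-time kinetics

Gamma fits are exact MLE (shape from `ln k − ψ(k) = ln x̄ − mean(ln x)`
by Brent's method; the MLE satisfies shape·scale = sample mean to
numerical precision), with a parametric-bootstrap 95% CI on the mean
(500 replicates by default).  Exponential fits use rate = n/Σt, or the
right-censoring-aware (#uncensored)/Σall t, with the exact chi-squared
CI.  Censored dwells are excluded from gamma fits.  Survival curves are
Kaplan–Meier (the exact empirical 1-CDF when nothing is censored); the
log-rank test is the standard Mantel–Cox statistic with 1 df, verified
against lifelines and calibrated by simulation (type-I error within
[0.03, 0.07] at α = 0.05).  The position calibration maps dye
displacement (residues) to plateau efficiency by isotonic projection and
linear interpolation, anchored at ~0.82 (offset 0) and ~0.32 (offset
24); the translocation calculus (velocity = 24/τ_decay ≈ 30 aa/s,
threading 138/30 ≈ 4.6 s, unfolding = τ_deg − threading) rounds
velocity to one significant figure to match the "approximately 30"
convention.  Bulk initial rates regress the first 10% of the
polarization amplitude change (or 20 points, whichever is larger) and
normalize by the full amplitude and the enzyme:substrate ratio.

## What the synthetic data do and do not show

The generator reproduces the *kinetic structure* of the experiments —
sequential phases with realistic duration distributions, telegraph
switching, excursions, arrival statistics, bleedthrough, background,
noise and single-step bleaching.  It does not emulate spot detection or
channel registration (upstream image processing), diffusing-substrate
background fluctuations, protein-induced fluorescence enhancement, dye
blinking, or baseline drift.  Passing recovery tests therefore
establishes that the analysis is unbiased and correctly calibrated for
traces whose noise is stationary and whose states are well separated;
on real data the same code may additionally face non-stationary
backgrounds and photophysical artifacts that these tests do not probe.

## Problem sizes

Recovery studies use the published ensemble sizes where stated: 300
productive events per processing condition, 200 conformational traces of
60 s at 20 Hz, 100 conformational-processing traces (150 s, so that
late-starting dwells are rarely censored), and five 300-s movies of ~430
encounters each for capture success.  At these sizes the full acceptance
computation completes in well under a minute on one core.
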