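# Methods

## Signal model and pipeline overview

photoflux processes two-channel fiber-photometry recordings in which a
fluorescence excitation LED (490 nm, dopamine-sensitive channel) and an
isosbestic reference LED (405 nm, dopamine-independent) are sinusoidally
amplitude-modulated at 211 Hz and 531 Hz and collected on one
photodetector.  The stages are:

1. **Lock-in demodulation** — the raw trace is mixed with sine and cosine
   references at each carrier, low-pass filtered at 25 Hz with a
   second-order zero-phase Butterworth, and combined as
   `2*sqrt(I^2 + Q^2)`, returning the carrier amplitude independent of
   phase.  A sine-reference quadrature demodulator is implemented; a
   square-wave reference would differ only by a scale factor that the
   downstream reference fit absorbs.
2. **Decimation** to 382 Hz (anti-alias low-pass at 0.4 × the output rate,
   8th-order zero-phase Butterworth, then exact integer down-sampling).
3. **Isosbestic correction** — ordinary least squares of the signal
   channel on the reference channel over the whole session, then
   `dF/F = (ch490 − fitted405) / fitted405`.  Because motion and
   photobleaching are shared multiplicatively by both channels, the ratio
   cancels them to first order.
4. **Robust z-scoring** — `z = (x − median) / MAD` with **no** Gaussian
   consistency factor (a `consistency=True` flag multiplies the MAD by
   1.4826 for σ-comparable units).  This makes a fixed peak threshold mean
   the same thing across animals and sessions.
5. **Transient detection** — strict local maxima with topographic
   prominence ≥ 2 z (configurable), FWHM at half-prominence by linear
   interpolation of flank crossings, session rate/amplitude/width
   summaries plus the median of the dF/F trace.
6. **Peri-event analysis, behavior metrics, morphometry, group
   statistics** — described below.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `fs_raw` | 6112 | Hz | 16 × 382 so decimation is an exact integer factor |
| `fs_out` | 382 | Hz | acquisition standard for this rig class |
| carriers | 211 / 531 | Hz | signal / isosbestic modulation frequencies |
| lock-in cutoff | 25 | Hz | final signal bandwidth |
| `transient_rate_hz` | 0.5 | events/s | typical spontaneous striatal dopamine transient rate |
| `transient_amp` | 0.06 | dF/F | mid-range spontaneous transient size for this sensor class |
| kernel rise / decay | 0.05 / 0.5 | s | difference-of-exponentials matching sub-second sensor kinetics |
| `bleach_tau_s` | 1200 | s | ~40 % photobleaching over a 10-min session; configurable double-exponential |
| `motion_amp` | 0.02 | fractional | slow (≤ 2 Hz) shared artifact, 2 % sd |
| `noise_sd` | 0.005 | V | ~0.5 % of the carrier amplitude, see below |
| detection threshold | 2 | z | prominence threshold on the normalized trace |
| `min_separation_s` | 5/382 ≈ 0.013 | s | five-sample refractory; collapses shoulder duplicates without erasing distinct events at 100–200 ms spacing |
| Sholl `step_um` | 5 | µm | concentric shell spacing |
| lick-bout rule | 5 licks/s, 3 s gap | — | ≥ 5 licks in a sliding 1 s window opens a bout; a 3 s silence closes it |

### Detector noise and the signal-dominated regime

The robust z-score divides by the MAD of the *whole* dF/F trace.  A fixed
2 z prominence threshold therefore only separates transients from noise
when the trace's central spread is dominated by real signal dynamics, not
sensor noise — the regime in which thresholded peak analysis is used in
practice.  The default `noise_sd` (0.5 % of the carrier) puts the
synthetic data in that regime: after 25 Hz lock-in filtering the effective
dF/F-domain noise is ≈ 0.002 (the reference-channel envelope noise,
amplified by the fit slope, dominates over the signal-channel term), i.e.
a peak SNR of ≈ 30–45 for a 6 % transient, while the session MAD
(≈ 0.008) is set by the transients themselves.

## What the synthetic data emulates — and what it does not

The generator reproduces: amplitude-modulated two-carrier acquisition,
Poisson-timed transients with realistic kinetics, shared multiplicative
photobleaching, a shared slow motion artifact, Gaussian detector noise,
uniform(75, 105) s inter-trial schedules (10 s cue; reward 7 s after cue
onset for appetitive conditioning; a 1 s shock at cue offset for fear
conditioning), jittered lick trains, and toy SWC morphologies with known
geometry.

It does **not** emulate: non-stationary transient rates or amplitudes,
state-dependent kinetics, hemodynamic artifacts, wavelength-dependent
bleaching (the two channels share one bleach curve), correlated or
non-Gaussian detector noise, or lick-rate modulation by satiety.  Passing
the recovery suites therefore demonstrates correctness of the signal
processing under the stated model, not robustness to every artifact of
real recordings.

### Known bias: rate undercount from unresolvable doublets

With Poisson event timing at 0.5 Hz and ~0.5 s decay kinetics, about 10 %
of events fall within ~0.2 s of a neighbor and physically merge into a
single fluorescence peak.  Local-maximum detection (deconvolution is out
of scope) cannot split these, so the estimated spontaneous rate is biased
low by roughly that fraction (≈ 0.44–0.47 Hz measured for a 0.5 Hz
generating rate), while temporal-coverage precision and recall at a
0.25 s tolerance remain ≥ 0.95.  Detection scoring uses the coverage
convention: a true event is recalled if any detection lies within the
tolerance, and a detection is correct if any true event does — events
closer together than the tolerance are not resolvable at that
granularity by construction.

## Peri-event features

Trials are exact slices of the session-normalized z trace (no per-trial
renormalization; the heatmap normalization is the session-level robust z).
Default feature windows, all relative to the alignment event and
configurable: cue peak max over [0, 2] s; outcome peak max over [0, 1] s;
anti-peak (signed minimum) over [0.5, 2.5] s; rebound AUC (trapezoidal
integral) over [2, 8] s.  These reflect the canonical aversive-outcome
waveform: a fast positive transient, a 1–2 s dip, then a broader rebound.
In appetitive sessions the outcome time is taken from behavior — the start
of the first lick bout at or after reward delivery — because consumption,
not pump command, is the reinforcing event.

## Behavior metrics

The "exceeds five licks per second" bout rule is operationalized as ≥ 5
licks inside a sliding 1 s window (window width configurable); a bout
extends while inter-lick gaps stay under 3 s, which also merges activity
closer than that gap.  An explicitly smaller minimum bout size relaxes the
opening count with it, so bout segmentation is idempotent on its own bout
starts.  Learning rate is the OLS slope of per-trial cue-period lick
counts over 1-based trial index (per-session by default; an explicit index
supports across-session fits).  Anticipatory licks are licks in
[cue onset, outcome delivery).  Freezing acquisition is the OLS slope over
trials 1–7 with plateau means over trials 8–15 (split configurable);
freezing tables are ingested from manual scoring, never computed from
video.

## Morphometry

Sholl profiles count parent→child segments whose endpoint distances from
the soma (root node coordinates; 3D Euclidean, with a planar mode for 2D
traces) straddle each shell radius.  The boundary rule is half-open
(`min < r ≤ max`): a node lying exactly on a shell is counted once, with
its inbound segment, avoiding double-counting at exact tangencies.  Radii
run in 5 µm steps to the first multiple of the step at or beyond the most
distal node.  Total neurite length is the sum of segment lengths.  Soma
contours are simple polygons: area by the shoelace formula; major/minor
axes are the diameters of the ellipse with the polygon's normalized second
central moments (exact for elliptical contours); self-intersection is
rejected by an explicit segment-pair test.

## Group statistics

Two-sample t statistics are reconstructed from printed summaries via
`SD = SEM·√n` and pooled variance; Welch and paired variants use the
standard df/denominator changes; p-values are two-sided throughout.
Rounding of printed SEMs propagates about ±0.02 into a reconstructed t.
The Benjamini–Krieger–Yekutieli adaptive two-stage linear step-up FDR
procedure is implemented from its definition (stage 1: BH at
q′ = q/(1+q); estimate m̂₀ = m − r₁; stage 2: BH at q′·m/m̂₀) and returns
rejection flags, not adjusted p-values, because the procedure is defined
by rejection sets.  Pearson correlation and the two-sample KS statistic
delegate to scipy; the KS statistic is verified against a brute-force
ECDF supremum oracle in the test suite.  ANOVA and Mann–Whitney are
deliberately not re-implemented.

## Numerical choices and degenerate inputs

- Zero-phase filtering uses forward–backward second-order Butterworth
  (scipy `sosfiltfilt`, reflective padding), so DC gain is exactly 1 and
  gain at the cutoff is exactly 1/2.
- The first and last 1 s of demodulated envelopes are flagged
  edge-contaminated and excluded from peak sets and rate denominators.
- Peak ties on plateaus break to the earliest sample; peaks closer than
  the refractory keep the larger one.
- Constant traces are rejected by `robust_z` (MAD = 0) and by the
  reference fit (degenerate design); constant feature series return slope
  exactly 0 with r² defined as 0.
- A missing outcome (no lick bout after reward) is a value (`None`), not
  an error.
- All randomness flows from a single seed through per-component
  `SeedSequence` sub-streams; identical configurations are
  bit-reproducible.

## Problem sizes used in the verification suites

The recovery suites run one 600 s synthetic session at the default
conditions; the baseline-rate protocol in the acceptance script averages
4 subjects × 3 × 300 s epochs; the FDR null calibration uses 20 p-values
× 5000 replicates; oracle comparisons use 100 random trees (Sholl) and
200 random sample pairs (KS).
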