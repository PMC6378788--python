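# Methods

## The signal and its model

An instrumented pacifier coupled to a closed-volume pneumatic sensor
records intraoral compression pressure while a preterm infant sucks.
Nonnutritive suck (NNS) activity appears as trains of smooth upward
pressure pulses at a modal rate near 2 Hz, grouped in bursts of 2–13
cycles separated by 2–5 s respiratory pauses.  Two artifacts ride on the
signal: a slow baseline drift caused by oral heat transfer to the sensor
(periods of tens of seconds to minutes), and occasional slow, wide
pressure excursions from tongue/jaw posturing ("non-NNS events") that must
not be counted as suck cycles.

## Preprocessing

- **Calibration.**  A two-point linear map from sensor units to cm H₂O.
  The two calibration pairs are stored with each recording; their abscissa
  is in the same unit as the samples (ADC counts or volts), so quantizing
  a float-voltage recording to the 16-bit binary format rescales the
  calibration abscissa by the same counts-per-volt factor and leaves the
  pressure map unchanged.
- **Low-pass.**  4-pole Butterworth at 50 Hz, applied forward–backward
  (`sosfiltfilt`).  Zero-phase filtering is chosen so peak *times* feeding
  the burst criterion are not lag-shifted; the cost is that the applied
  magnitude response is the squared single-pass response, which is
  irrelevant at 2 Hz signal content.
- **Decimation.**  Polyphase resampling to 100 samples/s
  (`resample_poly`, `padtype="line"`).  Line padding matters: zero padding
  produces a large edge transient whenever the signal rides on drift
  (measured: 9.7 % of the drift range at the record edge, vs 3·10⁻⁵
  with line padding).
- **Baseline correction.**  Asymmetric least squares: the baseline z
  minimizes Σ wᵢ(yᵢ − zᵢ)² + λ Σ (Δ²z)², with wᵢ = p for yᵢ > zᵢ and
  1 − p otherwise, re-estimating weights for 10 rounds.  Small p makes z
  hug the lower envelope, so upward suck pulses are ignored while the
  drift is tracked.  Defaults **λ = 1e9, p = 0.01** at 100 Hz.  λ was set
  by measurement, not convention: the smoother's half-power period is
  ≈ (2π/fs)·λ^(1/4); λ = 1e6 (a common chromatography-scale choice) cuts
  at ≈ 0.5 Hz and rides up ~0.5 cm H₂O under multi-second bursts, biasing
  peak amplitudes by −4 to −6 %.  λ = 1e9 cuts near 0.03 Hz: amplitude
  bias < 1 % while the baseline still tracks linear and random-walk drift
  with RMSE ≈ 0.07–0.11 cm H₂O on the synthetic world (allowed:
  noise SD + 2 % of drift range ≈ 0.15).  A second-difference penalty is
  exact on straight lines, so linear thermal drift is recovered almost
  perfectly at any λ.

## Discrimination

Candidate peaks are local maxima with prominence ≥ 0.5 cm H₂O (noise
ripples are excluded *before* classification: sub-threshold maxima are
neither NNS nor non-NNS events).  Peak time and amplitude are refined by
parabolic interpolation through the three samples around the maximum —
at 100 Hz the raw grid quantizes peak times to 10 ms, which would smear
the 1200 ms burst boundary by ±5 ms; with refinement the boundary is
recovered to ±1 ms.  The half-height width is the distance between the
two crossings of amplitude/2 nearest the peak, linearly interpolated
between samples; when two cycles share a valley above half height, the
crossing is taken at the local minimum between them.

Classification: a peak is a **valid NNS cycle** iff amplitude
> 1.6 cm H₂O (strict) *and* half-height width < 400 ms (strict); an
above-threshold peak failing the width test is a **non-NNS event**;
at-or-below-threshold peaks are dropped.  The most active window (default
2 min) maximizes the NNS peak count over a grid of starts at multiples of
100 samples (the count variant "total" is a config switch; the choice of
metric is not fixed by convention).  Bursts are maximal runs of NNS peaks
with successive gaps ≤ 1200 ms, inclusive (a 1 ns comparison slack keeps
the boundary inclusive under binary floating point); singleton runs are
not bursts.

## Features and the spatiotemporal index

Features 1–10 are counts, rates (per minute of window), the NNS/total
compression ratio, cycles-per-burst statistics, and the mean NNS
amplitude, all restricted to the active window.  The NNS ratio is
reported absent when no compressions were retained.

The **STI** uses the first N = 5 bursts with ≥ M = 5 cycles (time order).
Each segment runs from the first cycle's onset to the Mth cycle's offset
(half-height crossings), is linearly interpolated to 10,000 points, and
z-scored per segment (population SD).  The across-burst *sample* SD
(n − 1 denominator, conventional for spatiotemporal-index work and
testable in closed form for two segments: SD = |z₀ − z₁|/√2) is evaluated
at points 0, 100, …, 9 900 and summed.  Per-segment (not pooled)
z-scoring makes the index invariant to joint amplitude scaling and time
dilation.  Fewer than two qualifying bursts yields an "insufficient"
result, not an exception.

## Spectra

A 4-pole Butterworth high-pass at 0.4 Hz removes the DC offset before
estimation.  It is applied single-pass: phase is irrelevant to a PSD, and
the applied −3 dB point then equals the design cutoff exactly (the
acceptance script measures it from the computed response at 0.01 Hz
resolution).  Four estimators share a one-sided grid (8192-point
transform, or the record's natural resolution if finer):

- **FFT**: unwindowed full-record PSD, density scaling (Parseval holds to
  < 1 %).
- **Periodogram**: flattop window, *tone-power* ("spectrum") scaling — the
  flattop's flat main lobe makes the reported peak equal A²/2 for a tone
  of amplitude A regardless of bin alignment.  Total power equals
  variance × the window's equivalent noise bandwidth (≈ 3.77 bins).
- **Welch**: segment length 50 % of the record, 90 % overlap, flattop
  window, density scaling.
- **Yule–Walker**: AR(8) fit to the flattop-tapered central 50 % of the
  record; PSD from the AR transfer function.  "Central 50 % + taper" is
  one reading of a loosely specified windowing convention; the AR peak
  frequency is insensitive to it.

`spectral_summary` reports the band peak (default band 0.4–15 Hz: lower
edge = the high-pass cutoff, upper edge covers NNS harmonics) and the
Shannon entropy (nats) of band power normalized to sum 1.

## Readiness analysis

Sessions are labeled by same-subject same-day feeding records: any oral
(PO, or mixed-with-oral) feed → 1 "ready"; exclusively tube (NG/OG) → 0;
no record → 2 "unknown".  Two of the 11 features (cycles/min and
bursts/min) are exact linear functions of their counts over the fixed
window and are dropped, leaving 9.  Per-feature two-sided Mann–Whitney U
tests (label 0 vs 1; unknowns excluded) feed a Benjamini–Yekutieli
step-up at α = 0.05 — valid under arbitrary dependence among features.
If no feature survives, clustering falls back to all 9 candidates rather
than aborting.  Kept features are min-max scaled per column (constant
columns → 0), all sessions (unknowns included) are clustered by Ward
linkage on Euclidean distance and cut at k = 2, and the partition is
scored on known labels only: the better of the two cluster→label
mappings defines accuracy (≥ 0.5 by construction) and the false-positive
ratio FP/(FP + TN) with "ready" positive; association is a Pearson χ²
(1 df, no continuity correction) on the 2×2 contingency table.

## The synthetic world

The generator emulates exactly the structure the pipeline claims to
measure, with exact ground truth:

- suck cycles: raised-cosine (Hann) pulses — a pulse of half-height width
  w has support 2w, so the classifier's width measurement is analytically
  exact; spacing 1/2 Hz with ± 20 ms uniform timing jitter; amplitude
  8 cm H₂O ± 20 % uniform;
- bursts of 2–13 cycles, pauses uniform on 2–5 s;
- 3 posturing events per record: raised-cosine pulses of 900 ms
  half-height width, 4 cm H₂O ± 20 %, centered in widened pauses so they
  never overlap bursts;
- drift: linear 1 cm H₂O/min by default (a plausible slow thermal ramp;
  random-walk and none are available), plus white Gaussian sensor noise
  (SD 0.1 cm H₂O);
- 3-minute records at 3 kHz (540,000 samples), all randomness from one
  seeded generator.

What the generator does **not** emulate: respiration coupling, amplitude
drift within a burst, non-stationary cycle rates, sensor saturation, or
realistic infant-to-infant variability.  A green detection test therefore
establishes correctness of the discrimination logic on well-formed
waveforms, not clinical performance.  The fixture feeding log assigns
feed modes independently of the waveforms, so end-to-end readiness runs
on fixtures are expected to sit near chance; the clustering machinery is
validated separately on feature matrices with planted effects.

## Numerical choices and degenerate inputs

- Burst criterion and window-count comparisons are inclusive; boundary
  cases are tested explicitly (a 1200 ms gap is one burst; amplitude
  exactly 1.6 is dropped; width exactly 400 ms is non-NNS).
- Active-window ties resolve to the earliest start.
- Zero-length or truncated recording files raise corruption errors; the
  reader never silently truncates (header count must match payload).
- A CSV time column must be uniform to a relative step tolerance of 1e-6.
- Degenerate 2×2 tables (an empty margin) score χ² = 0, p = 1.
- Empty feature lists, no-peak records, and all-unknown label sets
  produce typed absent values or explicit errors, never NaN arithmetic.

## Scaling of test workloads

The default test suite runs the full 3-minute, 3 kHz stated world where
the criterion demands it (50-record detection sweep, 20-record baseline
recovery, 30-file end-to-end batch) and completes in well under five
minutes on one CPU; the 568-file batch of the original use case is the
same code path at larger n (~0.5 s/file).
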