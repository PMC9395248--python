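# Methods

## The detection model

Neural field potentials (LFP, CSD, iEEG, MUA) contain transient,
multicycle oscillation bursts riding on an aperiodic 1/f-like background.
`oscevents` treats an *oscillation event* as a contiguous region of the
time–frequency plane in which median-normalized wavelet power is
moderate-to-high around a local spectral maximum:

1. **Transform.** Complex Morlet wavelets with a fixed cycle count
   (`wavelet_width`, default 7; the envelope has σ_t = w/(2πf)) are
   evaluated on a linear frequency grid, default 0.25–250 Hz in 0.25-Hz
   steps, over nonoverlapping 10-s windows. Power is the squared
   magnitude of the coefficient. Wavelet amplitude is normalized so a
   unit sinusoid at its tuned frequency yields power 1 at every grid
   frequency; only ratios to the median matter downstream, but this
   keeps absolute power interpretable.
2. **Normalization.** Each frequency row is divided by its median over
   the *entire* recording (pooled across windows). This flattens the 1/f
   background so a single threshold, expressed as a multiple of the
   median (default 4×), is comparable across frequencies.
3. **Peaks.** Candidate events are bins that exceed their 3×3
   neighborhood and the threshold. Exact-tie plateaus yield one peak
   (earliest time, then lowest frequency); a plateau bordering a larger
   bin is not a maximum.
4. **Bounding box.** From each peak the box grows along the peak
   frequency row (earlier/later in time) and along the peak time column
   (lower/higher in frequency) until power falls below
   min(peak_power/2, threshold); the boundary bin is the last bin at or
   above the bound, clipped to the window. A 2-D flood-fill variant
   (`box_growth="flood"`) exists for sensitivity analysis. After
   growth, the event's peak is relocated to the maximum-power bin inside
   the box, so `peak_power` is always the box maximum and `peakF` is the
   frequency of maximum power during the event.
5. **Merging.** Boxes whose intersection exceeds `merge_overlap`
   (default 0.5) of the smaller box's area are replaced by their union
   (peak re-located inside the union), repeated to a fixed point. This
   bridges events split by brief subthreshold dips.
6. **Features.** Duration = t_stop − t_start, cycle count =
   duration × peakF, frequency span Fspan = ln(maxF/minF). The window
   signal is band-passed to [minF, maxF] with a zero-phase 4th-order
   Butterworth (second-order sections, forward–backward); the filtered
   event span provides the filter-match (Pearson r between raw and
   filtered waveform; ≤0.25 weak, ≤0.5 moderate, >0.5 strong) and
   counts of strict local maxima/minima.
7. **Exclusions.** Events with Fspan > 1.5 (≈2.17 octaves) are flagged
   broadband; events matching an average ERP template (maximum
   normalized sliding cross-correlation > 0.8) with duration between 75
   and 300 ms are flagged ERP-like. Flagged events remain in the table
   but are excluded from downstream statistics. Without templates the
   ERP rule is skipped.

Band classification uses the frequency of maximum power with
open-lower/closed-upper intervals: δ (0.5,4], θ (4,9], α (9,15],
β (15,30], low-γ (30,40], γ (40,80], high-γ (80,200]. The printed
literature values leave 29–30 Hz and 80–81 Hz unassigned; we treat the
bands as contiguous half-open intervals so every frequency in
(0.5, 200] is classifiable. A combined-γ scheme merging (30,80] is
available for co-occurrence analyses.

## Event statistics

- **Rate** counts unflagged events of a band per second; **active-time
  ratio (ATR)** is the measure of the union of event spans divided by
  recording length (per band, or any-band). Per-band ATRs can sum above
  1 because events in different bands overlap and nest.
- **Rhythmicity.** Interevent intervals (peak-to-peak, or
  end-to-start with negative gaps clamped to 0) are summarized by
  CV2 = population variance / squared mean; counts in consecutive
  nonoverlapping windows give the Fano factor FF = variance / mean.
  Both are 1 for a homogeneous Poisson process, below 1 for rhythmic
  trains. Per-band window lengths (44.0, 30.0, 24.0, 10.7, 12.0, 3.6,
  1.3 s for δ…high-γ) hold roughly comparable event counts per window.
  A one-sided Wilcoxon signed-rank test against 1 assesses sub-Poisson
  regularity. Population (divide-by-n) variance is used throughout:
  the Poisson calibration is unchanged asymptotically and small hand
  examples are exact.
- **Co-occurrence** of bands a≠b: events of either band overlapping any
  event of the other, counted once each (set semantics), divided by the
  pooled event count of the two bands.
- **Band-limited fraction**: an event is band-limited when minF and
  maxF both fall inside the band of its peak; it spreads lower/higher
  otherwise (possibly both).

## Phase–amplitude coupling

Instantaneous slow phase comes from a single width-3 Morlet at the
geometric center of the phase band (δ 0.5–4 Hz or θ 4–8 Hz);
gamma amplitude is the mean width-3 envelope over a 5-Hz grid spanning
30–200 Hz. The signal is demeaned first, because a width-3 Morlet
rejects DC only by a factor e^(−w²/2) ≈ 0.011. The modulation index is
MI = |mean(Amp(t)·e^{iφ(t)})|: zero for amplitude unrelated to phase,
0.5 in the closed-form case Amp = 1 + cos φ with uniform phase.
Event/no-event comparison computes MI per low-frequency-event span and
per an equal number of equal-duration event-free segments (avoiding all
detected events, drawn uniformly without overlap from a seeded
generator), compared by unpaired two-sample t test. The paired-versus-
unpaired choice was open; unpaired matches the unmatched nature of the
segment draws.

## Synthetic data: what it emulates and what it does not

`gen_background` shapes white Gaussian noise to a 1/f^χ spectrum
(default χ = 1.5) and rescales to an exact time-domain standard
deviation. Bursts are pure sinusoids of known frequency, cycle count
and amplitude (default 1.5, in the units of the emulated CSD signal),
spliced in with sharp edges by default — the onset/offset discontinuity
transients are a deliberate part of the test conditions — with an
optional half-cycle raised-cosine taper. The background scale is
calibrated so total background RMS equals burst RMS (amplitude/√2,
time-domain SNR 1), which reproduces the visual regime in which a
1.5-amplitude burst is plainly visible above a raw field-potential
trace; the in-band SNR implied is then well above 1
(`inband_rms_fraction` reports the analytic per-band fraction).

The generator does **not** emulate: heavy-tailed, oscillation-rich
background statistics of real recordings (a Gaussian process's median
and its typical fluctuation are tied to each other, while real CSD has
medians inflated by its own oscillation events over a quieter
inter-event floor), cross-frequency structure, nonsinusoidal burst
shapes, or nonstationarity. Consequently, passing validation here shows
correct mechanics of detection and feature extraction — recall,
frequency recovery, threshold behavior — but the absolute cycle-count
accuracy on real recordings is better than on this synthetic
background (see Limitations).

Burst packing places several bursts per 10-s window when spacing
permits: each burst is preceded by a gap of at least twice its duration
and never less than 8 periods of its frequency (the footprint of a
7-cycle wavelet; closer bursts smear into one event). Detected events
are matched to ground truth by maximal temporal overlap among events
within one band of the burst's band (peak frequency is overestimated
for short bursts); flagged events are eligible for matching, since the
contaminant screens target real-data ERPs rather than scoring.

The threshold-sweep property (mean detected cycles non-increasing in
detection threshold) is evaluated on the matched planted bursts of a
fixed scenario (2–6-cycle bursts in every band, the size range typical
of real recordings). On the raw event population of a synthetic
background the property is confounded by survivor composition — higher
thresholds select stronger events, and with Gaussian noise the
surviving population's mean cycle count can drift up even as every
individual event's box shrinks; the matched-burst mean isolates the box
mechanism that the parameter study describes.

## Numerical choices

- The wavelet transform is evaluated in the frequency domain (the
  analytic Morlet is a Gaussian on the positive-frequency axis),
  zero-padded to at least twice the window so the convolution is
  effectively linear; kernels are cached per (rate, grid, width).
  Coefficients are complex64 and power float32 — only power ratios to
  the median matter, and the relative error is ~1e-7.
- Median normalization raises on an all-zero row (undefined); an
  all-zero channel short-circuits to an empty event table.
- Degenerate one-bin boxes have duration 1/fs (half-open span
  convention), so durations are always positive.
- The band-pass low edge is floored at 0.1 Hz; a zero-width box widens
  by one grid step per side. Filtering covers the event plus three
  low-edge cycles of context, so the scored span is free of filter edge
  transients; `sosfiltfilt` padding shrinks for very short segments.
- Exact-tie handling in peak finding and the strict inequality in
  merging (`intersection > merge_overlap × min area`) are specified to
  keep detection deterministic; reruns are bit-identical.
- Decimation to the 1000-Hz analysis rate (≥4× the 250-Hz maximum
  analysis frequency) uses a polyphase anti-alias FIR; acquisition
  rates like 44 kHz are never analyzed directly.

## Validation problem sizes

The bundled validation runs use one channel at 1000 Hz: 20 noise seeds
for the 11-cycle α-burst recovery (one burst per 10-s window) and 10
repetitions per band×cycle-count condition (bands θ 6, α 10, β 21,
low-γ 35, γ 57 Hz; 1–15 cycles) for the error summary, ≈180 windows in
total. Poisson calibrations use 50,000 intervals and a 10,000-s event
train. These sizes hold the standard error of the reported means well
below the effects of interest.

## Limitations

- **Cycle-count bias on Gaussian backgrounds.** The box grows until
  power falls below min(peak/2, threshold). When an embedded burst's
  normalized peak power r is far above threshold, the wavelet's
  Gaussian tail keeps the ridge above the bound for
  ≈ σ_t·√(ln(r/4)) beyond each true edge, i.e. an overhang of
  (w/π)·√(ln(r/4)) cycles independent of true burst length. Under this
  package's calibrated background r ranges ≈20–300 across bands, giving
  a systematic +2.5–4 cycle overestimate (θ–γ RMS error ≈3–5 cycles
  over 1–15-cycle bursts), while frequency recovery stays accurate
  (≈0.1 Hz mean error at α). Shrinking r toward ~5 would shrink the
  overhang, but a Gaussian background with medians that high fragments
  the ridge and randomizes the detected peak frequency; real recordings
  escape the dilemma through their non-Gaussian background statistics.
- Events never span window boundaries; oscillations crossing a window
  edge are split.
- The ERP screen requires representative templates; without them only
  the broadband screen applies.
- Statistics are per-channel; no cross-channel or traveling-wave
  analysis.
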