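# Methods

This note documents the models and numerical choices behind each stage,
what the synthetic generators emulate, and the limits of what the tests
establish.

## ICP waveform chain

The raw signal model is a baseline pressure plus an artificial-ventilation
component near 1.3 Hz, a cardiac component in the 2.5–5 Hz band, broadband
sensor noise, and occasional movement or handling spikes. The mean wave
amplitude (MWA) targets the cardiac component only.

**Artifact removal.** A sample is masked when it is non-finite, outside
the physiological range (default −10 to 100 mmHg), or a spike. Spikes are
detected on the residual against a 9-sample moving average: genuine
physiological oscillations pass through this short detrender almost
untouched (at 1 kHz a 4 Hz component loses < 0.1% amplitude), while a
w-sample spike survives at (w−1)/w of its height. The residual is scaled
by 1.4826× its rolling median absolute deviation over a 0.5 s context
window and masked above a robust z of 5. The scale is floored at
1e-3 mmHg — below sensor resolution — so noise-free stretches (where the
MAD is exactly zero) never produce false flags; the first and last five
samples are exempt because the detrender is undefined at the boundary.
Masked samples are repaired by linear interpolation from the nearest clear
neighbours; recordings with more than 20% masked samples are rejected
rather than repaired. The threshold, window, and range are all exposed in
`WaveformConfig`.

**Decimation.** A zero-phase FIR low-pass (cutoff 0.4 × target rate,
Hamming-windowed, applied forward-backward) precedes keeping every k-th
sample, taking 1 kHz acquisitions to the 100 Hz analysis rate. Cutoff and
double application give > 100 dB stop-band rejection; DC and the
pass band are preserved to well under 1%.

**Spectral band-pass.** The real-signal spectrum is multiplied by a mask
that is 1 on the inner band, rolls off to 0 at each band edge with a
raised-cosine (Tukey) taper, and is 0 elsewhere; the default taper width
is 0.25 × the 1.6–5.5 Hz band width per edge, i.e. a flat response over
2.575–4.525 Hz. The taper suppresses ringing at the cost of attenuating
heart rates in the outer quarter of the band: at 4.9 Hz the gain is
roughly 0.6, and recovered MWA scales with that gain. This is inherent to
any tapered band-pass over a physiological band; the taper fraction is a
parameter for users whose animals run fast heart rates. The output is
zero-mean by construction, which is why baseline ICP is read from the
cleaned *pre*-band-pass signal.

**Peak-to-peak extraction.** The default instantaneous peak-to-peak
amplitude is twice the analytic-signal (Hilbert) envelope — exact for
narrowband tones. A cycle-based estimate (per-cycle maximum minus
minimum, interpolated to the grid) is provided as an independent
cross-check; the two agree within 5% on narrowband signals and their
agreement is asserted in the tests. Two seconds are trimmed from each end
after filtering, where spectral edge effects live. MWA is the mean of the
retained series.

## Secretion rate

At steady state, mass balance of an impermeant dye gives
Co\* = ri·Ci/(ri + Vp), inverted per sample as Vp = ri(Ci − Co)/Co.
Triplicates are averaged as fluorescence before applying the equation —
they are replicate readings of one physical sample — with per-replicate
conversion exposed as a sensitivity option. The quantification window is
the final 30 min of the run, anchored at the end so the early
equilibration ramp (ventricular mixing volume) is excluded. Negative
per-sample rates (outflow reading above inflow) are retained in the mean
and flagged, not dropped: silent exclusion would bias the estimate
upward. The reported uncertainty is the SEM over window samples.

## Outflow resistance

The pressure response to a constant infusion step is modeled as
first-order: ICP(t) = ICPi + Rout·I·(1 − e^(−t/τ)). With 10-min steps and
τ of order 60 s the plateau is reached to ~e^(−10); the plateau estimate
is the mean over the final 2 min of each step (configurable), and ICPi is
the mean over the final 5 min of the pre-infusion baseline. All windows
are half-open and exclude the 1-min pauses, where pressure is relaxing
rather than stable. Per-rate resistances are averaged for the reported
Rout; the regression slope of plateau pressure on rate is reported
alongside and coincides with the average exactly on linear
pressure–flow data, providing a built-in consistency check.

## Imaging flow

Frames are normalized to the first frame (the measure is relative by
design), and the flow rate is the OLS slope of normalized intensity
against time in minutes over the 0–5 min acquisition. A perfectly flat
response reports slope 0 with R² defined as 0.

## Statistics

Group comparisons use the classical equal-variance two-sided Student
t-test (Welch available as an option), reported with group means and
SEMs. Correlations use simple linear regression with the slope's
two-sided t-test p-value. Outlier screening is Grubbs' two-sided test at
α = 0.05; it flags at most one index and never removes — exclusion is an
explicit analyst decision. Exact ties in extremity are not flagged.

## Synthetic generators

The generators render every input the pipeline consumes, with ground
truth recorded alongside:

* **ICP traces**: baseline + 1.3 Hz ventilation (default 1 mmHg) +
  cardiac tone with per-animal frequency drawn uniformly in 2.5–5 Hz and
  amplitude MWA/2 + white noise (default sd 0.05 mmHg) + optional Poisson
  spikes and slow drift. Acquisition defaults to 1 kHz.
* **Dilution series**: 5-min grid, ri = 9 µl/min, steady state approached
  through an exponential ramp (default τ = 8 min over a 90-min run, so
  the final-30-min window is effectively at steady state); triplicates
  carry multiplicative noise (default CV 3%).
* **Infusion experiments**: the first-order step response above,
  continuous across steps and pauses, superimposed on the oscillatory
  baseline. Cohort rendering and the acceptance script synthesize these
  at 100 Hz — the response dynamics are below 0.02 Hz, so this is purely
  a problem-size choice; the default remains the 1 kHz acquisition rate.
* **Flow series**: 11 frames at 30 s, I(t) = I₀(1 + slope·t_min) +
  additive noise (default sd 0.01 on the normalized scale).
* **Cohorts**: per-animal truths drawn from normal distributions whose
  means and sds come from published group summaries (SEM·√n with the
  printed n), with physiological floors so every drawn animal remains
  renderable. Where a measure was published for only one comparison
  (outflow resistance and flow slope exist only for the lean vs
  testosterone-treated contrast, dye-dilution secretion only for lean vs
  obese), the missing cells reuse the lean values, since no group
  difference was claimed for them. Body length is derived from weight and
  the group BMI; dry brain weight from wet weight and the water fraction.

What the generators do **not** emulate: respiration–cardiac coupling and
heart-rate variability (the cardiac tone is a fixed frequency), baseline
drift during infusion, dye loss into parenchyma, plate-reader
nonlinearity, and frame-to-frame ROI registration error. Passing tests
therefore demonstrate correctness of the estimators under the stated
signal models, not robustness to every failure mode of real recordings.

## Numerical choices and degenerate inputs

Sampling rates are inferred from median inter-sample spacing rather than
trusted metadata; non-integer decimation factors are an error rather than
silently resampled. Empty windows, constant regressors, fewer than three
frames, fewer than two samples per group, non-positive fluorescence, and
dry weight exceeding wet weight are all rejected with messages naming the
offending sample or step. Stochastic code takes explicit integer seeds
and is bit-reproducible.

## Problem sizes

The test suite and acceptance script use 300-s ICP traces at 1 kHz,
full-protocol infusion recordings at 100 Hz, 200 replicate dilution
experiments, 500 replicate imaging cohorts, and 10,000 null pairs for the
t-test calibration; the complete run takes under a minute on one CPU.
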