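# csfdyn

Analysis toolkit for cerebrospinal-fluid (CSF) hydrodynamics in rodent
physiology experiments: intracranial-pressure (ICP) waveform analysis,
dye-dilution CSF secretion rate, stepped-infusion outflow resistance,
imaging-based relative CSF flow, morphometrics, and the two-group
statistics that tie a study together. It is aimed at labs quantifying CSF
dynamics in anesthetized, ventilated rodents — for example when asking
whether obesity or hormonal state alters intracranial pressure, CSF
production, or CSF drainage.

## What it computes

**Mean wave amplitude (MWA).** The cardiac pulsation riding on the ICP
signal. A raw 1 kHz epidural recording is despiked (rolling robust
z-score, linear-interpolation repair), anti-alias filtered and decimated
to 100 Hz, spectrally band-passed over 1.6–5.5 Hz with a Tukey
(raised-cosine) edge taper, and the instantaneous peak-to-peak amplitude
is extracted as twice the analytic-signal envelope. MWA is its time
average. Baseline ICP is the mean of the cleaned signal over the final
15 min.

**CSF secretion rate (Vp).** During ventriculo-cisternal perfusion, dye
infused at rate *r*ᵢ is diluted by freshly secreted CSF, so

&nbsp;&nbsp;&nbsp;&nbsp;*V*ₚ = *r*ᵢ · (*C*ᵢ − *C*ₒ) / *C*ₒ  [µl/min],

with *C*ᵢ the inflow and *C*ₒ the outflow fluorescence. Plate-reader
triplicates are averaged per 5-min sample; the estimate is mean ± SEM over
the final 30 min, past the equilibration ramp.

**Outflow resistance (Rout).** During stepped infusion (10 min at 5, 10,
15, 20 µl/min, 1-min pauses) the pressure plateau at each rate *I* gives

&nbsp;&nbsp;&nbsp;&nbsp;*R*ₒᵤₜ = (*ICP*f − *ICP*ᵢ) / *I*  [mmHg·min/µl],

averaged across rates; the regression slope of *ICP*f against *I* is
reported alongside as a built-in cross-check.

**Relative CSF flow.** Near-infrared dye imaged at 30-s intervals for
5 min; each frame's mean ROI intensity is normalized to the first frame
and the flow rate is the OLS slope in a.u./min.

**Morphometrics & statistics.** Rodent BMI (g/cm²), brain-water
percentage, relative brain weight, percentage weight gain; unpaired
Student t-tests, simple linear regression, mean ± SEM, and Grubbs
single-outlier flagging.

Every stage has a synthetic generator with known ground truth
(`csfdyn.synthetic`), so the whole chain is verifiable without animal
data; cohort scenarios are parameterized by published group summaries.

## Worked example

```python
from csfdyn import (estimate_rout, estimate_secretion, flow_rate,
                    mean_wave_amplitude, normalize_series)
from csfdyn.synthetic import (ScenarioParams, gen_dilution_series,
                              gen_flow_series, gen_icp_trace,
                              gen_infusion_experiment)

params = ScenarioParams(baseline_icp=4.33, cardiac_amp=0.06,
                        cardiac_freq=4.0, icp_noise_sd=0.05, seed=42)

m = mean_wave_amplitude(gen_icp_trace(params, duration=300.0))
print(f"MWA = {m.mwa:.3f} mmHg, baseline ICP = {m.baseline_icp:.2f} mmHg")

e = estimate_secretion(gen_dilution_series(true_vp=4.22, ri=9.0, cv=0.03, seed=42))
print(f"Vp = {e.vp:.2f} +/- {e.sem:.2f} ul/min over {e.n_samples_used} samples")

r = estimate_rout(gen_infusion_experiment(0.74, params, tau=60.0,
                                          sampling_rate=100.0, seed=42))
print(f"Rout = {r.rout:.3f} (per-rate mean), regression {r.rout_regression:.3f}")

f = flow_rate(normalize_series(gen_flow_series(0.13, noise_sd=0.01, seed=42)))
print(f"flow slope = {f.slope:.3f} a.u./min (R^2 = {f.r_squared:.3f})")
```

prints

```
MWA = 0.120 mmHg, baseline ICP = 4.33 mmHg
Vp = 4.19 +/- 0.07 ul/min over 7 samples
Rout = 0.740 (per-rate mean), regression 0.740
flow slope = 0.130 a.u./min (R^2 = 0.998)
```

The generator truths (cardiac peak-to-peak 0.12 mmHg, Vp 4.22 µl/min,
Rout 0.74 mmHg·min/µl, slope 0.13 a.u./min) are recovered by the analysis
chain; the small deviations reflect the injected measurement noise.

The estimators are also available as scikit-learn-style classes
(`MeanWaveAmplitude`, `SecretionRateEstimator`, `OutflowResistance`,
`FlowRateEstimator`) with `fit`, `get_params`/`set_params` and fitted
attributes (`mwa_`, `vp_`, `rout_`, `slope_`).

## Command line

```
csfdyn mwa recording.txt --out mwa.json          # waveform chain
csfdyn vp dilution.csv                           # secretion rate
csfdyn rout infusion.txt                         # outflow resistance
csfdyn flow roi_series.csv                       # imaging flow slope
csfdyn simulate lean obese_tt -n 5 --seed 1 --out-dir fixture/
csfdyn cohort fixture/ --out report.json         # end-to-end comparison
```

ICP recordings are semicolon-separated `time;pressure` text (both `.` and
`,` decimal marks supported); dilution and intensity series are CSV;
image stacks are multi-frame grayscale TIFF; results leave as JSON with
provenance, tabular payloads also as CSV.

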