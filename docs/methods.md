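# Methods

## Analysis model

The pipeline compares an irregularly sampled pulse-rate stream against a
1-Hz ECG-derived heart-rate stream at the pulse-measurement times.

**Telemetry rule.** The reference heart rate at integer second *t* is
60/RR of the RR interval *completed strictly before* *t* (the rate a
telemetry monitor displays). Emission starts at the first integer second
with two beats strictly before it; there is no backfill. The strict
inequality is a documented tie-break: a beat landing exactly on a sample
second contributes from the next second on.

**Pairing.** Each pulse reading at time t_x is matched with the
heart-rate sample at the greatest integer second at or before t_x — a
trailing match, consistent with the telemetry rate itself being a
trailing-RR quantity. Readings with no reference within `max_gap`
(default 5 s, the longest admissible telemetry outage) are dropped and
counted. Neither series is interpolated or resampled: the analysis
deliberately works at the device's own measurement times.

**Trend curves.** Sliding frames of `window_size = 10` consecutive pairs
are averaged into (P, H), stepped one measurement at a time, so n pairs
yield n − 9 points. A frame is stamped with its *last* pair's time (it
summarizes the trailing ~minute, the natural stamp for on-line use) and
its duration is t_last − t_first, i.e. the span of the 9 enclosed gaps.
The frame filter drops frames with duration outside
[`min_duration` = 30 s, `max_duration` = 120 s] around the nominal 60 s —
a quantification of "largely deviating from the one-minute frame". Under
the default Fitbit-like gap model (2–5 s) the typical frame spans ~31.5 s,
so roughly a quarter of FBT frames fall just under the 30-s bound and are
filtered; this thins the trend without biasing it. Standby-mode frames
(gaps up to tens of minutes) are essentially all filtered, which is the
intended behaviour: that mode does not support the analysis. Per-event
analysis keeps only frames lying wholly inside [onset, offset], so no
frame mixes AF and sinus beats.

**CCF.** Each trend curve is regressed on time by ordinary least squares
and the Pearson correlation of the two residual series is the CCF. The
single-regression detrend is a deliberate, minimal prewhitening: it
removes a shared deterministic drift so the statistic measures
co-movement of fluctuations, not a common trend. The p-value is the
standard two-sided t test for a Pearson correlation; serial dependence of
the residuals (which the overlapping frames guarantee) is ignored, so
p-values are anti-conservative and should be read as descriptive.
Zero-variance residuals (a perfectly linear curve) raise an error rather
than returning a silent 0. Strength bins are half-open at 0.2/0.4/0.6/0.8
with negative correlations kept as their own class; the published
per-event values never fall inside the historically ambiguous
[0.19, 0.2) gap, so the convention does not affect the reproduced counts.

**Accuracy regression.** Per event, the mean and sample SD (n − 1
denominator) of P and of H; across events, OLS of the pulse statistic on
the heart-rate statistic. The orientation matters and is fixed: pulse is
the response, ECG the predictor, matching the X = a + bY / A = a + bB
convention. R² equals the squared Pearson correlation (checked in tests);
the slope p-value is the two-sided t test on the slope.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
not waveforms.

**Rhythms.** Sinus RR intervals are Gaussian around 60/`mean_hr_sinus`
(default 75 bpm) with CV `hrv_cv_sinus` (default 0.05); AF RR intervals
are i.i.d. Gamma with mean 60/`mean_hr_af` (default 110 bpm) and CV
`rr_cv_af` (default 0.25) — positive support, a clean CV
parameterization, and no serial structure, the defining feature of the
irregularly irregular AF response. Draws outside [0.2 s, 5 s] are redrawn
(at most 100 times). Both regimes ride on one slow sinusoidal rate drift
with a seed-dependent phase: instantaneous rate = base ×
(1 + m·sin(2πt/`hr_drift_period` + φ)), with modulation depth
m = `hr_drift_amplitude`/`mean_hr_af`. The modulation is multiplicative —
autonomic tone scales heart rate — so the amplitude parameter reads as
peak drift in bpm during AF (default 15 bpm over a 300-s period, the
order of the multi-minute tens-of-bpm swings bedside trend curves show
during postoperative AF) while a slower sinus rhythm drifts
proportionally less. The drift is what makes the ECG and the device see a
*shared* slow signal; without it, detrended trend curves of an i.i.d.
rhythm would correlate only through the handful of beats both happen to
average. It adds a small lag-1 RR autocorrelation (~0.1 at defaults)
on top of the otherwise independent Gamma innovations.

**Pulse deficit.** Each beat produces an effective peripheral pulse with
probability log-linearly interpolated between anchors at 80 bpm (0.968)
and 120 bpm (0.925), evaluated at the beat's instantaneous rate and
clamped to (0, 1] outside the anchors. The anchors follow animal-model
reports of effective ventricular rate as a fraction of electrical rate;
the "reduction *of*" phrasing in the source literature is read as
"reduction *to*" (a transmitted fraction), since a 96.8% loss at 80 bpm
would leave ~2.6 bpm of pulse, contradicting the context. Both anchors
are plain configuration values for anyone preferring another reading.

**Devices.** Sample times are cumulative sums of gaps: uniform on
[2, 5] s (FBT) or [5, 6] s (AWW), and log-normal (μ = 5.0, σ = 1.4,
clipped to [1 s, 39 min]) for AWS — fitted so the mean gap is ≈ 394 s
with the observed 1 s–39 min range; the true shape is unknowable from
summary statistics. A reading is the mean instantaneous rate of the beats
completed in the trailing `averaging_window` (5 s for FBT/AWW, 8 s for
AWS), times `gain` (default 1; used to plant calibration error), plus
Gaussian noise (`noise_sd`, default 2 bpm — resting-condition PPG error).
Windows holding no completed beat yield no reading; `dropout_prob`
removes readings at random. The `decorrelate` flag replaces readings with
draws around `baseline_mean` (default 70 bpm) independent of the beats,
emulating the loss of a usable peripheral signal during hypotension.

**What the generator does not model** — and hence what passing tests do
not demonstrate about real data: motion artifacts, skin-tone/perfusion
optics and luminance auto-adjustment, sensor-contact physics, realistic
HRV spectra (the drift is a single sinusoid), atrial flutter or ectopy,
and drug effects. Synthetic recovery shows the *analysis* behaves as
designed, not that any particular device meets a clinical bar.

## Study sizes and numerical choices

* Recovery studies use 100 one-hour AF episodes (CCF recovery and
  decorrelated null) and 100 replicates of 30 half-hour-episode accuracy
  studies with gain 0.85 and per-event mean AF rates uniform on
  90–130 bpm — realistic postoperative episode durations and rate spread
  that give stable per-event statistics (roughly 650 trend points per
  hour at AWW cadence).
* Deficit calibration uses 10,000-beat constant rhythms at the two anchor
  rates; the tolerance is 3 binomial standard errors.
* All operations are pure functions of (inputs, seed); composite
  operations derive child seeds from one `numpy` Generator. Reports are
  byte-identical across runs of the same configuration and seed.
* Least squares uses `numpy.linalg.lstsq` (detrend) and statsmodels OLS
  (accuracy fits); correlations use `scipy.stats.pearsonr`. Tests verify
  both against hand-written normal-equation and definition-of-Pearson
  oracles to 1e-10 or better.
* Validation bounds: rates must lie in [20, 300] bpm; times strictly
  increasing; file readers reject (naming the offending row) rather than
  repair. Times are written to 1 ms and rates to 0.1 bpm, finer than any
  modelled device emits.

## Known limitations

* The p-values inherit the residual autocorrelation problem above; the
  strength classification, not the p-value, should drive interpretation.
* The frame filter's [30, 120] s band is a configurable reading of
  "approximately 1 min"; other bands change which FBT/AWS frames survive.
* The published per-event CCF regression coefficients of the modelled
  study cannot be reproduced without its raw recordings; the package
  instead demonstrates recovery of planted parameters on synthetic data
  and reproduces the study's printed strength counts exactly.
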