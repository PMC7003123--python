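# Demo scenario: a 90-minute recording with two paroxysmal AF episodes,
# observed simultaneously by an Apple-Watch-workout-like device and a
# Fitbit-like device, with the default pulse-deficit model applied to the
# perfused beat train.
duration: 5400
seed: 11
rhythm:
  mean_hr_sinus: 75
  hrv_cv_sinus: 0.05
  mean_hr_af: 110
  rr_cv_af: 0.25
  hr_drift_amplitude: 15
  hr_drift_period: 300
events:
  - {onset: 900, offset: 2400, label: af1}
  - {onset: 3300, offset: 4500, label: af2}
devices:
  - {mode: AWW}
  - {mode: FBT}
deficit:
  transmit_frac_at_80: 0.968
  transmit_frac_at_120: 0.925
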