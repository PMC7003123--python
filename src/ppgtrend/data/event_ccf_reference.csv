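# Per-event cross-correlation values between PPG pulse-rate trend curves
# and ECG heart-rate trend curves, as reported for the 23 analyzable
# postoperative paroxysmal AF episodes in the published two-watch
# validation study this pipeline models. Empty cells mark events where a
# device was not worn or its data were unavailable (AWW events 1-7;
# FBT events 12, 13, 16), giving group sizes of 16 (AWW) and 20 (FBT).
event_id,aww_ccf,fbt_ccf
1,,0.13
2,,0.54
3,,-0.04
4,,0.20
5,,0.49
6,,0.25
7,,0.02
8,0.81,0.62
9,0.71,-0.08
10,0.68,0.41
11,0.79,0.37
12,0.45,
13,0.23,
14,0.36,0.13
15,0.59,0.02
16,0.51,
17,0.64,0.39
18,0.83,0.55
19,0.83,0.71
20,0.78,0.38
21,0.85,-0.35
22,-0.02,-0.62
23,0.02,-0.38
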