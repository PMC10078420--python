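"""Variable signal averaging: schedule construction and SNR payoff.

Builds the study schedule (42 averages on the first five time points, 3 on
the last twenty, 948 total — the budget of a constant 12-average scheme) and
compares per-time-point SNR against constant averaging for a short and a
long T1.
"""

import numpy as np

import lltherm as L

seq = L.SequenceParams()
variable = L.build_schedule(
    n_points_max=79, budget=12 * 79, head_points=5, head_na=42,
    tail_points=20, tail_na=3)
constant = L.constant_schedule(79, 12)

na = L.na_profile(variable)
print("variable schedule blocks (n_points, n_repeats):", variable.blocks)
print(f"NA profile: head {na[:5].tolist()} ... tail {na[-3:].tolist()}, "
      f"total {na.sum()} averages")
print(f"scan time, 24 lines: variable {L.scan_duration(variable, 24, seq):.0f} s, "
      f"constant {L.scan_duration(constant, 24, seq):.0f} s (~10 min each)")

for T1 in (51.0, 1005.0):
    tissue = L.TissueParams(T1=T1)
    snr_v = L.snr_profile(variable, tissue, seq, noise_sd=0.04)
    snr_c = L.snr_profile(constant, tissue, seq, noise_sd=0.04)
    print(f"T1 = {T1:6.0f} ms: SNR at point 1  variable {snr_v[0]:5.1f} vs "
          f"constant {snr_c[0]:5.1f}; at point 79  {snr_v[-1]:5.1f} vs {snr_c[-1]:5.1f}")
print("-> the extra early averages buy SNR exactly where the recovery "
      "signal is weakest, at the price of noisier late points")
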