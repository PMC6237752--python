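"""Normalize a FRAP trace and fit the mono-exponential recovery.

Simulates a three-ROI FRAP experiment with the study's acquisition
geometry (101 frames at 500 ms, 10 pre-bleach) and control-like kinetics
(half-time 8.4 s, ~75% recovery), normalizes the bleached-ROI trace
against background and acquisition photobleaching, and fits
A - B*exp(-k*t) to the post-bleach frames.
"""

import math

from halofoci import fit_recovery, normalize_trace
from halofoci.simulate import FrapSimParams, simulate_frap_trace

k_true = math.log(2) / 8.4
params = FrapSimParams(A=0.95, B=0.75, k=k_true, noise_sd=0.02, seed=6)
trace = simulate_frap_trace(params)

normalized = normalize_trace(trace)  # (I - Ib)/(Isb - Ib), pre-bleach mean = 1
fit = fit_recovery(trace.time_s, normalized, trace.bleach_index, seed=6)

print(f"fitted A = {fit.A:.3f}, B = {fit.B:.3f}, k = {fit.k:.4f} 1/s")
print(f"half-time tau_1/2 = ln(2)/k = {fit.tau_half_s:.2f} s (true 8.40 s)")
print(f"mobile fraction (B): {fit.mobile_fraction:.2f}")
print(f"immobile fraction (1 - A): {fit.immobile_fraction:.2f}")
print(f"mobile fraction, bleach-depth normalized: "
      f"{fit.mobile_fraction_normalized:.2f}")
# ~75-80% of molecules exchange into the bleached spot on a ~10 s
# timescale; the remainder stays bound over the 45 s observation window.
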