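"""Polar-bleach FRAP: simulate a recovery trace and estimate D.

Simulates bleaching one pole of a 5 um rod for both the free cytoplasm
(D = 14 um^2/s) and the mechanically compressed regime (D = 0.5), adds
1% readout noise, and fits the diffusion coefficient back.
"""

import numpy as np

from macscount import FrapExperiment, estimate_D, simulate_frap

for d_true, label in ((14.0, "agar pad (free cytoplasm)"), (0.5, "compressed (pressed cell)")):
    duration = max(3.5 / (d_true * (np.pi / 5.0) ** 2), 1.0)
    exp = FrapExperiment(D_true=d_true, duration=duration, dt=duration / 400, noise_sd=0.01)
    trace = simulate_frap(exp, np.random.default_rng(0))
    res = estimate_D(trace)
    print(f"{label}: true D {d_true:5.1f} um^2/s -> fitted {res['D_hat']:5.2f} "
          f"(recovery {trace.roi_mean[0]:.2f} -> {trace.roi_mean[-1]:.2f} over {duration:.1f} s)")
print("Slower recovery in the pressed regime is what renders single\n"
      "molecules as static diffraction-limited spots during a 30 ms exposure.")
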