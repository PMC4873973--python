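"""Population count statistics: Fano, zero fraction, size conditioning.

Simulates counts whose mean scales with cell length (extrinsic size
noise on top of Poisson production), shows that pooling inflates the
Fano factor while size classes are Poisson, and applies the maturation
correction for dark fluorophores.
"""

import numpy as np
import pandas as pd

from macscount import condition_on_size, maturation_correction, poisson_gof, summarize

rng = np.random.default_rng(3)
lengths = rng.uniform(2.0, 5.0, size=10_000)
counts = rng.poisson(2.2 * lengths)  # mean ~7.7 copies/cell
table = pd.DataFrame({"length_um": lengths, "count": counts})

pooled = summarize(table["count"])
print(f"pooled: mean {pooled.mean:.2f}, Fano {pooled.fano:.2f}, "
      f"zero fraction {pooled.zero_fraction:.4f}")
print(f"Poisson GOF on pooled counts: p = {poisson_gof(table['count'])['p']:.2e} (rejected)")

print("\nafter conditioning on cell length (5 quantile bins):")
for s in condition_on_size(table, n_bins=5):
    print(f"  bin {s.size_bin}: mean {s.mean:5.2f}, Fano {s.fano:.2f}")
print("per-bin Fano returns to ~1: the pooled overdispersion was size-driven.")

corrected = maturation_correction(pooled.mean, maturation_time_min=10.0, doubling_time_min=25.0)
print(f"\nmaturation correction (10 min maturation, 25 min doubling): "
      f"{pooled.mean:.2f} observed -> {corrected:.2f} total "
      f"({100 * pooled.mean / corrected:.0f}% of molecules are mature)")
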