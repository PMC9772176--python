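"""Compare log2 fold changes between two contrasts.

A companion contrast is simulated with planted log2FCs correlated at
r = 0.55 with the primary contrast (two mutants hitting a shared target
set). The summary gives the Pearson r with its t-distribution p-value,
sign-quadrant counts, and per-direction concordance percentages.
"""

import pandas as pd

from coopdeg.concordance import subset_compare
from coopdeg.de import call_degs
from coopdeg.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(n_genes=2000, frac_deg=0.1, baseline_mean=100,
                       baseline_sigma=0.25, seed=1)
ds = simulate_dataset(cfg)
lengths = pd.Series({g.gene_id: g.length_bp for g in ds.loci})
rx = call_degs(ds.matrix, "control", "mutant", gene_lengths=lengths)
ry = call_degs(ds.companion_matrix, "control2", "mutant2", gene_lengths=lengths)

for selection in ("all", "common_degs"):
    s = subset_compare(rx, ry, selection=selection)
    print(f"{selection}: n={s.n}, r={s.pearson_r:.3f}, p={s.p_value:.3g}")
    print(f"  quadrants {s.quadrant_counts}")
    up_up = s.concordance_percentages.get("x_up_y_up")
    if up_up is not None:
        print(f"  {up_up}% of x-up genes are also up in the companion contrast")
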