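"""Classify DEGs into the six expression-level clusters.

Each DEG is labeled by its direction of change and whether its
average-normalized expression (condition mean / mean of all expressed genes
in that condition) is below or above 1 in control and mutant. Odd clusters
hold downregulated DEGs, even clusters upregulated ones.
"""

import pandas as pd

from coopdeg.clusters import classify_contrast, cluster_counts
from coopdeg.de import call_degs
from coopdeg.simulate import Log2FCDistribution, SimulationConfig, generate_counts

cfg = SimulationConfig(
    n_genes=2000, frac_deg=0.1, baseline_mean=100, baseline_sigma=0.25,
    log2fc_distribution=Log2FCDistribution(min_abs=2.0), seed=1,
)
matrix, truth = generate_counts(cfg)
result = call_degs(matrix, "control", "mutant",
                   gene_lengths=pd.Series(1000.0, index=truth.index))

assignments = classify_contrast(result)
counts = cluster_counts(assignments)
print(counts.to_string())
down = counts[["C1", "C3", "C5"]].sum()
up = counts[["C2", "C4", "C6"]].sum()
print(f"partition check: {down} down + {up} up "
      f"(+ {counts['unclassified']} unclassified) = {counts['total']} DEGs")
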