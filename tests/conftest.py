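import numpy as np
import pandas as pd
import pytest

from coopdeg.io import ExpressionMatrix, GeneRecord
from coopdeg.simulate import Log2FCDistribution, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 2000-gene synthetic study at high-expression calibration settings."""
    cfg = SimulationConfig(
        n_genes=2000, frac_deg=0.1, baseline_mean=100, baseline_sigma=0.25,
        log2fc_distribution=Log2FCDistribution(min_abs=2.0), seed=20260920,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def tiny_matrix():
    """2 conditions × 3 replicates, 4 genes, hand-set counts."""
    values = pd.DataFrame(
        {
            "control_1": [100.0, 10.0, 0.0, 5.0],
            "control_2": [110.0, 12.0, 0.0, 6.0],
            "control_3": [90.0, 11.0, 0.0, 4.0],
            "mutant_1": [400.0, 10.0, 50.0, 5.0],
            "mutant_2": [410.0, 12.0, 55.0, 6.0],
            "mutant_3": [390.0, 11.0, 45.0, 4.0],
        },
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
    )
    design = pd.Series(
        ["control"] * 3 + ["mutant"] * 3, index=values.columns, name="condition"
    )
    return ExpressionMatrix(values=values, design=design, unit="counts")


@pytest.fixture()
def toy_loci():
    return [
        GeneRecord("g1", "chr2L", 1000, 2000, "+"),
        GeneRecord("g2", "chr2L", 5000, 6000, "+"),
        GeneRecord("g3", "chr2L", 5100 + 94900, 101000, "-"),
        GeneRecord("g4", "chr3R", 2000, 3000, "-"),
        GeneRecord("g5", "chr3R", 9000, 10000, "+"),
    ]


def brute_force_bh(p):
    """Step-up definition: q_(i) = min_{j>=i} (p_(j) * n / j), computed
    literally from sorted order."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = min(running, 1.0)
    return q
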