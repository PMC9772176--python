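"""Six-way expression-level classification of DEGs.

Each DEG is placed in one of six clusters by its direction of change and
whether its average-normalized expression (condition mean RPKM divided by
the mean RPKM of all expressed genes in that condition) is below or above 1
in each condition. The normalization tempers the very large fold changes of
low-expressed genes. Combinations the scheme does not define (e.g. a
downregulated gene below average in control but above in the mutant, or an
exact tie at 1) are reported as ``unclassified`` rather than forced into a
cluster.

Labels (a = control, b = mutant):
  C1 down, a<1, b<1    C2 up, a<1, b<1
  C3 down, a>1, b<1    C4 up, a<1, b>1
  C5 down, a>1, b>1    C6 up, a>1, b>1
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from coopdeg.de import ContrastResult

CLUSTER_LABELS = ("C1", "C2", "C3", "C4", "C5", "C6", "unclassified")
DOWN_CLUSTERS = ("C1", "C3", "C5")
UP_CLUSTERS = ("C2", "C4", "C6")


def normalize_to_average(mean_rpkm: np.ndarray | pd.Series,
                         expressed_mask: np.ndarray | pd.Series | None = None
                         ) -> np.ndarray | pd.Series:
    """Divide each gene's condition-mean RPKM by the arithmetic mean over the
    expressed genes of that condition, so the expressed-gene average is 1.

    ``expressed_mask`` defaults to mean RPKM > 0.
    """
    values = np.asarray(mean_rpkm, dtype=float)
    mask = (values > 0) if expressed_mask is None else np.asarray(expressed_mask, bool)
    if not mask.any():
        raise ValueError("no expressed genes in condition; cannot normalize")
    denom = values[mask].mean()
    if denom <= 0:
        raise ValueError("average expression of expressed genes is non-positive")
    out = values / denom
    if isinstance(mean_rpkm, pd.Series):
        return pd.Series(out, index=mean_rpkm.index)
    return out


def classify(status: str, norm_a: float, norm_b: float) -> str:
    """Assign a single DEG to its expression cluster.

    ``status`` must be "up" or "down"; norm_a/norm_b are the
    average-normalized expression in control (a) and mutant (b).
    """
    if status not in ("up", "down"):
        raise ValueError(f"only DEGs are classified, got status {status!r}")
    if norm_a < 0 or norm_b < 0:
        raise ValueError("normalized expression must be non-negative")
    lo_a, hi_a = norm_a < 1, norm_a > 1
    lo_b, hi_b = norm_b < 1, norm_b > 1
    if status == "down":
        if lo_a and lo_b:
            return "C1"
        if hi_a and lo_b:
            return "C3"
        if hi_a and hi_b:
            return "C5"
    else:
        if lo_a and lo_b:
            return "C2"
        if lo_a and hi_b:
            return "C4"
        if hi_a and hi_b:
            return "C6"
    return "unclassified"


def classify_contrast(result: ContrastResult,
                      expressed_mask_a: np.ndarray | None = None,
                      expressed_mask_b: np.ndarray | None = None) -> pd.DataFrame:
    """Cluster every DEG of a contrast.

    Returns a DataFrame indexed by gene_id with columns norm_expr_a,
    norm_expr_b, status, cluster. Normalization denominators are computed
    over all genes in the contrast table (expressed = mean RPKM > 0 by
    default), not just DEGs.
    """
    t = result.table
    norm_a = normalize_to_average(t["mean_rpkm_a"], expressed_mask_a)
    norm_b = normalize_to_average(t["mean_rpkm_b"], expressed_mask_b)
    deg_idx = result.degs()
    rows = {
        "norm_expr_a": norm_a.loc[deg_idx],
        "norm_expr_b": norm_b.loc[deg_idx],
        "status": t.loc[deg_idx, "status"],
    }
    df = pd.DataFrame(rows)
    df["cluster"] = [
        classify(s, a, b)
        for s, a, b in zip(df["status"], df["norm_expr_a"], df["norm_expr_b"])
    ]
    return df


def cluster_counts(assignments: pd.DataFrame | pd.Series) -> pd.Series:
    """Sizes per cluster label, including zero-size labels, plus a 'total' row.

    The sizes always sum to the number of DEGs (partition property); when no
    DEG is unclassified the odd clusters sum to the down-DEG count and the
    even clusters to the up-DEG count.
    """
    labels = assignments["cluster"] if isinstance(assignments, pd.DataFrame) else assignments
    counts = labels.value_counts()
    out = pd.Series({lab: int(counts.get(lab, 0)) for lab in CLUSTER_LABELS},
                    name="n_genes")
    out["total"] = int(out[list(CLUSTER_LABELS)].sum())
    return out
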