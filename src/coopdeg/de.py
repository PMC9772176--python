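"""Differential-expression calling.

A gene is a DEG when three criteria hold simultaneously: |signed fold
change| ≥ 2 between condition means, Benjamini–Hochberg q-value < 0.05 from
a two-tailed t-test across replicates, and mean RPKM > 1 in at least one
condition. Down-changes use the negative-reciprocal convention (a ratio of
1/40 is reported as −40), so |signed FC| ≥ 1 always.

A second, threshold-only call (``call_developmental_degs``) labels genes by
fold change alone — the convention used when replicate-level data for a
contrast are unavailable and only fold changes are published.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coopdeg.io import ExpressionMatrix

#: sentinel for a fold change that is undefined (both means zero, no pseudocount)
FC_UNDEFINED = float("nan")

#: p-value assigned when both groups have zero variance but different means
P_FLOOR = float(np.nextafter(0.0, 1.0))


@dataclass
class ContrastResult:
    """Per-gene differential-expression results for one contrast (b vs a)."""

    table: pd.DataFrame  # index gene_id; columns mean_rpkm_a, mean_rpkm_b,
    #                      signed_fc, log2_fc, p_value, q_value, status, zero_var_flag
    condition_a: str = "a"
    condition_b: str = "b"

    COLUMNS = ("mean_rpkm_a", "mean_rpkm_b", "signed_fc", "log2_fc",
               "p_value", "q_value", "status")

    def degs(self, direction: str | None = None) -> pd.Index:
        s = self.table["status"]
        if direction is None:
            return self.table.index[s.isin(("up", "down"))]
        return self.table.index[s == direction]

    def counts(self) -> dict[str, int]:
        c = self.table["status"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("up", "down", "ns", "filtered")}


def compute_rpkm(counts: np.ndarray, gene_length_bp: np.ndarray | int,
                 total_mapped: np.ndarray | int) -> np.ndarray:
    """RPKM = counts × 10⁹ / (gene length in bp × total mapped reads).

    ``counts`` may be a genes × samples matrix (gene_length_bp per row,
    total_mapped per column) or a per-sample vector for one gene.
    """
    counts = np.asarray(counts, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    total = np.asarray(total_mapped, dtype=float)
    if (length <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (total <= 0).any():
        raise ValueError("total mapped reads must be positive")
    if counts.ndim == 2:
        return counts * 1e9 / (length[:, None] * total[None, :])
    return counts * 1e9 / (length * total)


def signed_fold_change(mean_b: float, mean_a: float,
                       pseudocount: float = 0.0) -> tuple[float, float]:
    """Signed FC and log2 FC of mean_b over mean_a.

    With m = mean + pseudocount: ratio = m_b/m_a; the signed FC is the ratio
    itself when ≥ 1 and the negative reciprocal otherwise, so the magnitude
    is always ≥ 1 and downregulation carries a negative sign. Returns NaN
    sentinels (never raises) when both means and the pseudocount are zero.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    m_a = mean_a + pseudocount
    m_b = mean_b + pseudocount
    if m_a == 0 and m_b == 0:
        return FC_UNDEFINED, FC_UNDEFINED
    if m_a == 0:
        return math.inf, math.inf
    if m_b == 0:
        return -math.inf, -math.inf
    ratio = m_b / m_a
    signed = ratio if ratio >= 1 else -1.0 / ratio
    return signed, math.log2(ratio)


def t_test_two_tailed(group_a: np.ndarray, group_b: np.ndarray,
                      mode: str = "pooled") -> tuple[float, bool]:
    """Two-tailed two-sample t-test p-value.

    mode="pooled": Student's t with pooled variance, df = n_a + n_b − 2;
    mode="welch": Welch's t with Satterthwaite df.

    Degenerate variance policy: if both groups have zero variance the p-value
    is 1 for equal means and the smallest positive float for unequal means;
    the second element of the return flags that degenerate case.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must be finite")
    if mode not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test mode {mode!r}")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        if a.mean() == b.mean():
            return 1.0, True
        return P_FLOOR, True
    res = stats.ttest_ind(a, b, equal_var=(mode == "pooled"))
    p = float(res.pvalue)
    # t = 0 (equal means) gives p = 1; guard against tiny float excursions
    return min(p, 1.0), False


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_rpkm(matrix: ExpressionMatrix,
             gene_lengths: pd.Series | None,
             total_mapped: pd.Series | None) -> pd.DataFrame:
    if matrix.unit == "rpkm":
        return matrix.values
    if gene_lengths is None:
        raise ValueError("gene_lengths required to convert counts to RPKM")
    lengths = gene_lengths.reindex(matrix.values.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"gene lengths missing for {missing}")
    if total_mapped is None:
        totals = matrix.values.sum(axis=0)
    else:
        totals = total_mapped.reindex(matrix.values.columns)
    rpkm = compute_rpkm(matrix.values.to_numpy(), lengths.to_numpy(),
                        totals.to_numpy())
    return pd.DataFrame(rpkm, index=matrix.values.index,
                        columns=matrix.values.columns)


def call_degs(matrix: ExpressionMatrix, condition_a: str, condition_b: str,
              fc_min: float = 2.0, q_max: float = 0.05, rpkm_min: float = 1.0,
              gene_lengths: pd.Series | None = None,
              total_mapped: pd.Series | None = None,
              pseudocount: float = 0.01,
              test_mode: str = "pooled",
              test_on_log: bool = True) -> ContrastResult:
    """Call DEGs for the contrast condition_b vs condition_a.

    Counts are converted to RPKM (given per-gene lengths; library sizes
    default to column sums). The t-test runs per gene across replicates, by
    default on log2(RPKM + 1) for variance stabilization at small replicate
    numbers; Benjamini–Hochberg correction is applied across all genes.
    Status:

    - ``filtered``: mean RPKM ≤ rpkm_min in both conditions (tested but
      excluded from DEG status by the expression filter);
    - ``up`` / ``down``: |signed FC| ≥ fc_min and q < q_max and filter passed;
    - ``ns``: everything else.
    """
    for cond in (condition_a, condition_b):
        if len(matrix.samples_of(cond)) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")
    rpkm = _as_rpkm(matrix, gene_lengths, total_mapped)
    va = rpkm[matrix.samples_of(condition_a)].to_numpy()
    vb = rpkm[matrix.samples_of(condition_b)].to_numpy()
    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)

    n = rpkm.shape[0]
    signed = np.empty(n)
    log2fc = np.empty(n)
    for i in range(n):
        signed[i], log2fc[i] = signed_fold_change(mean_b[i], mean_a[i], pseudocount)

    ta = np.log2(va + 1.0) if test_on_log else va
    tb = np.log2(vb + 1.0) if test_on_log else vb
    # vectorized t-test across genes; degenerate rows patched per policy
    res = stats.ttest_ind(ta, tb, axis=1, equal_var=(test_mode == "pooled"))
    p = np.minimum(np.nan_to_num(res.pvalue, nan=1.0), 1.0)
    zero_var = (ta.var(axis=1, ddof=1) == 0) & (tb.var(axis=1, ddof=1) == 0)
    equal_means = np.isclose(ta.mean(axis=1), tb.mean(axis=1))
    p[zero_var & equal_means] = 1.0
    p[zero_var & ~equal_means] = P_FLOOR
    q = bh_adjust(p)

    expressed = (mean_a > rpkm_min) | (mean_b > rpkm_min)
    sig = (np.abs(signed) >= fc_min) & (q < q_max) & np.isfinite(log2fc)
    status = np.where(~expressed, "filtered",
                      np.where(sig & (signed >= fc_min), "up",
                               np.where(sig & (signed <= -fc_min), "down", "ns")))

    table = pd.DataFrame(
        {
            "mean_rpkm_a": mean_a,
            "mean_rpkm_b": mean_b,
            "signed_fc": signed,
            "log2_fc": log2fc,
            "p_value": p,
            "q_value": q,
            "status": status,
            "zero_var_flag": zero_var,
        },
        index=rpkm.index.rename("gene_id"),
    )
    return ContrastResult(table=table, condition_a=condition_a,
                          condition_b=condition_b)


def call_developmental_degs(signed_fc: pd.Series | np.ndarray,
                            fc_min: float = 2.0) -> pd.Series | np.ndarray:
    """Fold-change-only DEG labels: dev_up if signed FC > fc_min, dev_down if
    signed FC < −fc_min, dev_ns otherwise. No significance test is applied."""
    fc = np.asarray(signed_fc, dtype=float)
    labels = np.where(fc > fc_min, "dev_up",
                      np.where(fc < -fc_min, "dev_down", "dev_ns"))
    if isinstance(signed_fc, pd.Series):
        return pd.Series(labels, index=signed_fc.index, name="dev_status")
    return labels
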