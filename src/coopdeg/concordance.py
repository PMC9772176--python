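"""Cross-contrast concordance of log2 fold changes.

Two contrasts are compared gene-by-gene on the log2 fold-change scale: a
Pearson correlation with its two-tailed p-value from the t distribution
with n−2 degrees of freedom, sign-quadrant counts for the scatter, and
per-direction concordance percentages (of the genes moving one way in
contrast x, what fraction moves each way in contrast y). Also implements
the ΔΔCT arithmetic used to validate RNA-seq fold changes by qPCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from coopdeg.de import ContrastResult
from coopdeg.io import QpcrTable

QUADRANT_KEYS = ("x_up_y_up", "x_up_y_down", "x_down_y_up", "x_down_y_down")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (646/707 → 91.4), matching the
    usual reporting convention rather than banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConcordanceSummary:
    """Summary of one pairwise contrast comparison."""

    n: int
    pearson_r: float
    p_value: float
    quadrant_counts: dict[str, int]
    concordance_percentages: dict[str, float]
    n_on_axis: int = 0
    selection: str = "all"

    def to_series(self) -> pd.Series:
        d: dict[str, object] = {
            "selection": self.selection,
            "n": self.n,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "n_on_axis": self.n_on_axis,
        }
        d.update(self.quadrant_counts)
        d.update({f"pct_{k}": v for k, v in self.concordance_percentages.items()})
        return pd.Series(d)


def pearson_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-tailed p-value of
    t = r·sqrt((n−2)/(1−r²)) under the t distribution with n−2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def quadrant_summary(log2fc_x: np.ndarray, log2fc_y: np.ndarray,
                     selection: str = "all") -> ConcordanceSummary:
    """Quadrant counts and per-direction percentages for a pair of contrasts.

    Genes with a log2FC of exactly 0 on either axis fall in no quadrant and
    are counted separately in ``n_on_axis``. Each percentage is
    100 × (genes in the quadrant) / (genes with the stated x-direction),
    rounded half away from zero to one decimal; directions with no x-genes
    are omitted.
    """
    x = np.asarray(log2fc_x, dtype=float)
    y = np.asarray(log2fc_y, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("log2 fold changes must be finite")

    counts = {
        "x_up_y_up": int(((x > 0) & (y > 0)).sum()),
        "x_up_y_down": int(((x > 0) & (y < 0)).sum()),
        "x_down_y_up": int(((x < 0) & (y > 0)).sum()),
        "x_down_y_down": int(((x < 0) & (y < 0)).sum()),
    }
    n_x_up = int((x > 0).sum())
    n_x_down = int((x < 0).sum())
    pct: dict[str, float] = {}
    for key, denom in (("x_up_y_up", n_x_up), ("x_up_y_down", n_x_up),
                       ("x_down_y_up", n_x_down), ("x_down_y_down", n_x_down)):
        if denom > 0:
            pct[key] = round_half_away(100.0 * counts[key] / denom, 1)

    if x.size >= 3 and x.std() > 0 and y.std() > 0:
        r, p = pearson_with_pvalue(x, y)
    else:
        r, p = float("nan"), float("nan")
    return ConcordanceSummary(
        n=int(x.size), pearson_r=r, p_value=p, quadrant_counts=counts,
        concordance_percentages=pct,
        n_on_axis=int(((x == 0) | (y == 0)).sum()),
        selection=selection,
    )


def subset_compare(results_x: ContrastResult, results_y: ContrastResult,
                   gene_universe: pd.Index | None = None,
                   selection: str = "all") -> ConcordanceSummary:
    """Compare two contrasts on a named gene subset.

    selections: ``all`` (every shared gene), ``degs_x`` / ``degs_y`` (DEGs of
    one contrast), ``common_degs`` (DEG in both).
    """
    shared = results_x.table.index.intersection(results_y.table.index)
    if gene_universe is not None:
        shared = shared.intersection(pd.Index(gene_universe))
    if selection == "all":
        genes = shared
    elif selection == "degs_x":
        genes = shared.intersection(results_x.degs())
    elif selection == "degs_y":
        genes = shared.intersection(results_y.degs())
    elif selection == "common_degs":
        genes = shared.intersection(results_x.degs()).intersection(results_y.degs())
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if len(genes) == 0:
        raise ValueError(f"empty selection {selection!r}")
    lx = results_x.table.loc[genes, "log2_fc"].to_numpy()
    ly = results_y.table.loc[genes, "log2_fc"].to_numpy()
    finite = np.isfinite(lx) & np.isfinite(ly)
    return quadrant_summary(lx[finite], ly[finite], selection=selection)


@dataclass
class QpcrFoldChange:
    """ΔΔCT-derived relative expression for one target gene."""

    target_gene: str
    delta_delta_ct: float
    fold_change: float  # 2^(−ΔΔCT)
    signed_fc: float = field(init=False)
    log2_fc: float = field(init=False)

    def __post_init__(self) -> None:
        self.log2_fc = -self.delta_delta_ct
        fc = self.fold_change
        self.signed_fc = fc if fc >= 1 else -1.0 / fc


def qpcr_fold_change(table: QpcrTable, target: str, cond_b: str,
                     cond_a: str) -> QpcrFoldChange:
    """Relative expression of ``target`` in cond_b vs cond_a by the ΔΔCT
    method, each condition's ΔCT being the mean of per-replicate
    CT_target − CT_reference."""
    rows = table.rows
    sub = rows[rows["target_gene"] == target]
    if sub.empty:
        raise ValueError(f"no qPCR rows for target {target!r}")

    def delta_ct(cond: str) -> float:
        c = sub[sub["condition"] == cond]
        if c.empty:
            raise ValueError(f"no qPCR rows for target {target!r}, condition {cond!r}")
        if c["ct_reference"].isna().any():
            raise ValueError(f"missing reference CT for target {target!r}")
        return float((c["ct_target"] - c["ct_reference"]).mean())

    ddct = delta_ct(cond_b) - delta_ct(cond_a)
    return QpcrFoldChange(target_gene=target, delta_delta_ct=ddct,
                          fold_change=2.0 ** (-ddct))


def validate_qpcr(qpcr_fcs: dict[str, QpcrFoldChange] | pd.Series,
                  rnaseq_log2fc: pd.Series) -> tuple[float, float]:
    """Pearson correlation (and t-distribution p) between qPCR and RNA-seq
    fold changes for a shared gene panel, computed on the log2 scale."""
    if isinstance(qpcr_fcs, dict):
        qpcr_log2 = pd.Series({g: fc.log2_fc for g, fc in qpcr_fcs.items()})
    else:
        qpcr_log2 = qpcr_fcs
    shared = qpcr_log2.index.intersection(rnaseq_log2fc.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    return pearson_with_pvalue(qpcr_log2.loc[shared].to_numpy(),
                               rnaseq_log2fc.loc[shared].to_numpy())
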