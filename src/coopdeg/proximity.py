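"""Permutation test for genomic clustering of a gene set.

Are the loci of a gene set (e.g. the upregulated DEGs) closer together
along the genome than expected by chance? The observed statistic is a
summary (median by default) of the distances between consecutive member
TSSs per chromosome. The null keeps every real gene position fixed and
redraws which genes carry the member label, so the gene-density landscape
of the genome is preserved — a conservative randomization. The empirical
p-value is one-sided toward clustering (small distances) with the +1
correction: p = (1 + #{null ≤ observed}) / (N + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from coopdeg.io import GeneRecord

STATISTICS = ("median_nn_distance", "mean_nn_distance")


@dataclass
class ProximityResult:
    statistic_name: str
    observed: float
    null_distribution: np.ndarray
    empirical_p: float
    n_permutations: int
    seed: int
    warnings: list[str] = field(default_factory=list)
    mannwhitney_p: float | None = None  # secondary, non-canonical comparison

    def to_series(self) -> pd.Series:
        return pd.Series({
            "statistic": self.statistic_name,
            "observed_bp": self.observed,
            "null_median_bp": float(np.median(self.null_distribution)),
            "empirical_p": self.empirical_p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "mannwhitney_p": self.mannwhitney_p,
        })


def _tss_by_chrom(loci: list[GeneRecord]) -> dict[str, np.ndarray]:
    chroms: dict[str, list[int]] = {}
    for g in loci:
        chroms.setdefault(g.chrom, []).append(g.tss)
    return {c: np.asarray(v) for c, v in chroms.items()}


def nn_distances(loci: list[GeneRecord], members: set[str]) -> np.ndarray:
    """Distances (bp) between consecutive member TSSs within each chromosome.

    Member TSSs are sorted per chromosome and differenced; pairs spanning
    two chromosomes contribute nothing. Raises if no chromosome holds at
    least two members.
    """
    per_chrom: dict[str, list[int]] = {}
    ids = set()
    for g in loci:
        ids.add(g.gene_id)
        if g.gene_id in members:
            per_chrom.setdefault(g.chrom, []).append(g.tss)
    unknown = members - ids
    if unknown:
        raise ValueError(f"member ids absent from loci: {sorted(unknown)[:5]}")
    chunks = [np.diff(np.sort(np.asarray(t))) for t in per_chrom.values() if len(t) >= 2]
    if not chunks:
        raise ValueError("need >= 2 members on at least one chromosome")
    return np.concatenate(chunks)


def _stat_fn(name: str):
    if name == "median_nn_distance":
        return np.median
    if name == "mean_nn_distance":
        return np.mean
    raise ValueError(f"unknown statistic {name!r}; choose from {STATISTICS}")


def permutation_test(loci: list[GeneRecord], members: set[str],
                     n_permutations: int = 1000,
                     statistic: str = "median_nn_distance",
                     seed: int = 0) -> ProximityResult:
    """Label-permutation test for genomic clustering of ``members``.

    Each permutation draws |members| genes uniformly without replacement
    from all loci (positions fixed, labels shuffled) and recomputes the
    statistic. One-sided toward clustering: small observed distances give
    small p.
    """
    fn = _stat_fn(statistic)
    observed_d = nn_distances(loci, members)
    observed = float(fn(observed_d))
    warnings: list[str] = []
    if n_permutations < 100:
        warnings.append(
            f"n_permutations={n_permutations} < 100: p-value resolution is coarse"
        )

    # group TSSs by chromosome once; permute membership over flat gene index
    chrom_of = np.asarray([g.chrom for g in loci])
    tss = np.asarray([g.tss for g in loci], dtype=np.int64)
    n_genes = len(loci)
    k = len(members)
    order = np.lexsort((tss, chrom_of))
    chrom_sorted = chrom_of[order]
    tss_sorted = tss[order]
    # boundaries where chromosome changes: consecutive diffs across them are invalid
    same_chrom = chrom_sorted[1:] == chrom_sorted[:-1]

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    null_pool: list[np.ndarray] = []
    for i in range(n_permutations):
        pick = np.zeros(n_genes, dtype=bool)
        pick[rng.choice(n_genes, size=k, replace=False)] = True
        pick_sorted = pick[order]
        idx = np.flatnonzero(pick_sorted)
        if idx.size < 2:
            null[i] = np.inf
            continue
        d = tss_sorted[idx[1:]] - tss_sorted[idx[:-1]]
        valid = chrom_sorted[idx[1:]] == chrom_sorted[idx[:-1]]
        d = d[valid]
        if d.size == 0:
            null[i] = np.inf
            continue
        null[i] = fn(d)
        if len(null_pool) < 50:  # cap the pooled null for the secondary test
            null_pool.append(d)

    empirical_p = (1.0 + float((null <= observed).sum())) / (n_permutations + 1.0)

    mw_p = None
    if null_pool:
        pooled = np.concatenate(null_pool)
        if pooled.size >= 2 and observed_d.size >= 2:
            mw_p = float(stats.mannwhitneyu(observed_d, pooled,
                                            alternative="less").pvalue)

    return ProximityResult(
        statistic_name=statistic, observed=observed, null_distribution=null,
        empirical_p=empirical_p, n_permutations=n_permutations, seed=seed,
        warnings=warnings, mannwhitney_p=mw_p,
    )
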