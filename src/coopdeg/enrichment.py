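"""Term overrepresentation and promoter motif statistics.

The enrichment stage is the generic overrepresentation test of gene-set
analysis: for each annotation term, a one-sided upper-tail hypergeometric
p-value for the overlap between a query gene set and the term within a
background universe, with Benjamini–Hochberg correction across terms.

The motif stage counts exact occurrences of a short DNA motif (e.g. the
GATA-like "GATAAG") in promoter windows spanning 500 bp upstream to 100 bp
downstream of each TSS, in transcription orientation, and summarizes the
copy-number distribution across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coopdeg.de import bh_adjust
from coopdeg.io import GeneRecord

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_DNA = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hypergeometric_enrichment(query: set[str], background: set[str],
                              term_map: dict[str, set[str]],
                              min_term_size: int = 3) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of each term in the query.

    Terms are intersected with the background; terms smaller than
    ``min_term_size`` (within the background) are skipped. Columns: term_id,
    term_size, overlap, expected, p_value, q_value; sorted by q then p.
    """
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query genes absent from background: {extra}")
    m = len(background)
    n_query = len(query)
    rows = []
    for term_id, genes in term_map.items():
        term_genes = genes & background
        k_term = len(term_genes)
        if k_term < min_term_size:
            continue
        overlap = len(term_genes & query)
        # P(X >= overlap), X ~ Hypergeom(M=m, K=k_term, n=n_query)
        p = float(stats.hypergeom.sf(overlap - 1, m, k_term, n_query))
        rows.append({
            "term_id": term_id,
            "term_size": k_term,
            "overlap": overlap,
            "expected": n_query * k_term / m,
            "p_value": min(p, 1.0),
        })
    df = pd.DataFrame(rows, columns=["term_id", "term_size", "overlap",
                                     "expected", "p_value"])
    if len(df):
        df["q_value"] = bh_adjust(np.clip(df["p_value"].to_numpy(), 1e-300, 1.0))
        df = df.sort_values(["q_value", "p_value", "term_id"]).reset_index(drop=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


@dataclass
class PromoterSequence:
    gene_id: str
    sequence: str
    truncated: bool
    tss_offset: int  # index of the TSS base within `sequence` (upstream length)


def extract_promoter(gene: GeneRecord, genome: dict[str, str],
                     upstream: int = 500, downstream: int = 100) -> PromoterSequence:
    """Promoter window of a gene in transcription orientation.

    For a + strand gene the window is forward-strand bases
    [TSS − upstream, TSS + downstream − 1]; for a − strand gene it is the
    reverse complement of [TSS − downstream + 1, TSS + upstream]. The TSS
    base itself is position 0 of the downstream segment. Windows extending
    past a chromosome edge are truncated and flagged.
    """
    if gene.chrom not in genome:
        raise ValueError(f"chromosome {gene.chrom!r} absent from genome")
    chrom_seq = genome[gene.chrom]
    chrom_len = len(chrom_seq)
    tss = gene.tss
    if gene.strand == "+":
        lo = tss - upstream  # 1-based inclusive
        hi = tss + downstream - 1
    else:
        lo = tss - downstream + 1
        hi = tss + upstream
    truncated = lo < 1 or hi > chrom_len
    lo_c = max(lo, 1)
    hi_c = min(hi, chrom_len)
    if hi_c < lo_c:
        raise ValueError(f"gene {gene.gene_id}: promoter window outside chromosome")
    seq = str(chrom_seq[lo_c - 1:hi_c]).upper()
    if gene.strand == "+":
        tss_offset = tss - lo_c
    else:
        seq = reverse_complement(seq)
        tss_offset = hi_c - tss
    return PromoterSequence(gene_id=gene.gene_id, sequence=seq,
                            truncated=truncated, tss_offset=tss_offset)


@dataclass
class MotifCopyProfile:
    """Motif occurrences in one promoter; offsets are relative to the TSS
    (negative = upstream), within [−upstream, downstream − 1]."""

    gene_id: str
    copy_count: int
    positions: list[int]


def count_motif(promoter: PromoterSequence | str, motif: str,
                allow_overlap: bool = True,
                tss_offset: int | None = None) -> MotifCopyProfile:
    """Count exact sense-strand occurrences of ``motif`` in a promoter.

    Overlapping matches are counted when ``allow_overlap``. Raises on
    motifs with ambiguous (non-ACGT) bases; IUPAC codes are not expanded.
    """
    motif = motif.upper()
    if not motif or not set(motif) <= _DNA:
        raise ValueError(f"motif must be non-empty over A/C/G/T, got {motif!r}")
    if isinstance(promoter, PromoterSequence):
        seq = promoter.sequence
        gene_id = promoter.gene_id
        offset0 = promoter.tss_offset if tss_offset is None else tss_offset
    else:
        seq = promoter.upper()
        gene_id = ""
        offset0 = 0 if tss_offset is None else tss_offset
    if len(motif) > len(seq):
        raise ValueError("motif longer than sequence")
    positions: list[int] = []
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            break
        positions.append(i - offset0)
        start = i + 1 if allow_overlap else i + len(motif)
    return MotifCopyProfile(gene_id=gene_id, copy_count=len(positions),
                            positions=positions)


def copy_number_distribution(profiles: list[MotifCopyProfile]) -> pd.Series:
    """Fraction of genes with 0, 1, 2 and ≥3 motif copies, as one-decimal
    percentages summing to 100."""
    if not profiles:
        raise ValueError("no motif profiles supplied")
    counts = np.asarray([p.copy_count for p in profiles])
    n = counts.size
    from coopdeg.concordance import round_half_away

    frac = {
        "0": round_half_away(100.0 * (counts == 0).sum() / n, 1),
        "1": round_half_away(100.0 * (counts == 1).sum() / n, 1),
        "2": round_half_away(100.0 * (counts == 2).sum() / n, 1),
        "3+": round_half_away(100.0 * (counts >= 3).sum() / n, 1),
    }
    return pd.Series(frac, name="percent_of_genes")


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id) → term→gene-set map."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["term_id", "gene_id"], header=0)
    out: dict[str, set[str]] = {}
    for term, gene in zip(df["term_id"], df["gene_id"]):
        out.setdefault(str(term), set()).add(str(gene))
    return out
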