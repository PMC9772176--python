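"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a two-condition bulk
RNA-seq comparison in a fly larva: negative-binomial counts over three
replicates per condition, a fraction of genes carrying planted signed fold
changes spanning a wide range (including a small tail of extreme fold
changes produced by near-zero expression on one side, the way very large
fold changes arise in real data), a companion contrast whose planted log2
fold changes correlate positively with the first (shared targets of two
chromatin regulators), a developmental contrast anti-correlated with the
first among DEGs, genomic coordinates with optional tandem clustering of
DEG loci, annotation terms enriched among upregulated DEGs, promoters with
planted motif copies, and a qPCR CT table consistent with the planted fold
changes.

Every generator is deterministic given its seed; per-stage seeds are
derived from the global seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from coopdeg.enrichment import PromoterSequence, reverse_complement
from coopdeg.io import ExpressionMatrix, GeneRecord, QpcrTable

# approximate sizes (bp) of the five major Drosophila melanogaster arms
DEFAULT_CHROM_SIZES = {
    "2L": 23_500_000,
    "2R": 25_300_000,
    "3L": 28_100_000,
    "3R": 32_100_000,
    "X": 23_500_000,
}


@dataclass(frozen=True)
class Log2FCDistribution:
    """Mixture of planted effect sizes for DEGs.

    Most DEGs get a moderate |log2FC| of ``min_abs`` plus an exponential
    tail capped at ``max_abs``; a fraction ``frac_extreme`` instead gets an
    extreme |log2FC| uniform in [extreme_min, extreme_max], realised by
    near-zero expression in one condition.
    """

    min_abs: float = 1.0
    tail_scale: float = 1.2
    max_abs: float = 6.0
    frac_extreme: float = 0.05
    extreme_min: float = 7.0
    extreme_max: float = 10.5


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 13,601 genes, 3 replicates per condition,
    ~7.4% DEGs of which ~79% are upregulated; companion contrast planted at
    r = 0.55 over all genes and developmental contrast at r = −0.67 among
    DEGs."""

    n_genes: int = 13_601
    n_replicates: int = 3
    baseline_mean: float = 100.0
    baseline_sigma: float = 1.0  # log-normal spread of per-gene baselines
    nb_dispersion: float = 0.01
    frac_deg: float = 1012 / 13_601
    frac_up: float = 797 / 1012
    log2fc_distribution: Log2FCDistribution = field(default_factory=Log2FCDistribution)
    companion_r: float = 0.55
    dev_r: float = -0.67
    cluster_fraction: float = 0.5
    run_length_range: tuple[int, int] = (3, 8)
    gene_length: int = 1000
    motif: str = "GATAAG"
    size_factor_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        for name in ("frac_deg", "frac_up", "cluster_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("companion_r", "dev_r"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"|{name}| must be <= 1")

    def stage_seed(self, stage: int) -> int:
        """Derive a per-stage seed (< 2**31) from the global seed."""
        child = np.random.SeedSequence(self.seed).spawn(stage + 1)[stage]
        return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = μ + dispersion·μ²; Poisson in the
    zero-dispersion limit."""
    mean = np.maximum(mean, 1e-12)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def plant_log2fc(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Choose DEGs, directions and planted log2 fold changes.

    Returns a frame with columns planted_log2fc, is_deg, direction,
    is_extreme indexed by gene_id g0000..; non-DEGs get log2FC exactly 0.
    """
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    n_deg = int(round(config.frac_deg * n))
    deg_idx = rng.choice(n, size=n_deg, replace=False)
    is_deg = np.zeros(n, dtype=bool)
    is_deg[deg_idx] = True

    dist = config.log2fc_distribution
    up = rng.random(n_deg) < config.frac_up
    extreme = rng.random(n_deg) < dist.frac_extreme
    mag = np.minimum(dist.min_abs + rng.exponential(dist.tail_scale, n_deg),
                     dist.max_abs)
    mag[extreme] = rng.uniform(dist.extreme_min, dist.extreme_max, extreme.sum())
    e = np.where(up, mag, -mag)

    log2fc = np.zeros(n)
    log2fc[deg_idx] = e
    is_extreme = np.zeros(n, dtype=bool)
    is_extreme[deg_idx] = extreme
    direction = np.full(n, "none", dtype=object)
    direction[deg_idx] = np.where(up, "up", "down")
    return pd.DataFrame(
        {"planted_log2fc": log2fc, "is_deg": is_deg, "direction": direction,
         "is_extreme": is_extreme},
        index=pd.Index(gene_ids, name="gene_id"),
    )


def generate_counts(config: SimulationConfig,
                    log2fc: np.ndarray | None = None,
                    seed: int | None = None,
                    condition_a: str = "control",
                    condition_b: str = "mutant",
                    ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial count matrix for two conditions with planted effects.

    A gene with planted log2FC e has its higher-expressed condition mean at
    the gene's baseline m and the other condition at m·2^(−|e|): the fold
    change B/A is 2^e while extreme effects show near-zero expression on
    one side. Per-sample library-size factors are drawn uniformly from
    ``size_factor_range``. Returns the matrix and the truth table.
    """
    seed = config.stage_seed(0) if seed is None else seed
    rng = np.random.default_rng(seed)
    truth = plant_log2fc(config, rng)
    if log2fc is not None:
        log2fc = np.asarray(log2fc, dtype=float)
        if log2fc.shape != (config.n_genes,):
            raise ValueError("log2fc vector length must equal n_genes")
        truth = truth.copy()
        truth["planted_log2fc"] = log2fc
        truth["is_deg"] = np.abs(log2fc) >= 1.0
        truth["direction"] = np.where(log2fc >= 1.0, "up",
                                      np.where(log2fc <= -1.0, "down", "none"))
    e = truth["planted_log2fc"].to_numpy()

    mu = np.log(config.baseline_mean) - config.baseline_sigma**2 / 2.0
    base = rng.lognormal(mu, config.baseline_sigma, config.n_genes)
    mean_a = np.where(e >= 0, base * 2.0 ** (-e), base)
    mean_b = np.where(e >= 0, base, base * 2.0 ** e)

    lo, hi = config.size_factor_range
    n_rep = config.n_replicates
    factors = rng.uniform(lo, hi, 2 * n_rep)
    cols, data = [], []
    for j in range(n_rep):
        cols.append(f"{condition_a}_{j + 1}")
        data.append(_nb_draw(rng, mean_a * factors[j], config.nb_dispersion))
    for j in range(n_rep):
        cols.append(f"{condition_b}_{j + 1}")
        data.append(_nb_draw(rng, mean_b * factors[n_rep + j], config.nb_dispersion))
    values = pd.DataFrame(np.column_stack(data).astype(float),
                          index=truth.index, columns=cols)
    design = pd.Series([condition_a] * n_rep + [condition_b] * n_rep,
                       index=cols, name="condition")
    matrix = ExpressionMatrix(values=values, design=design, unit="counts")
    truth = truth.assign(baseline_mean=base, mean_a=mean_a, mean_b=mean_b)
    return matrix, truth


# ---------------------------------------------------------------------------
# correlated companion contrasts


def generate_companion_log2fc(base_log2fc: np.ndarray, target_r: float,
                              seed: int) -> np.ndarray:
    """A vector whose expected Pearson correlation with ``base_log2fc`` is
    ``target_r``: the standardized input scaled by target_r plus independent
    Gaussian noise of variance 1 − target_r², rescaled to the input's spread.

    With |target_r| = 1 the output is an exact affine transform of the
    input. The empirical correlation concentrates within ±0.05 of the
    target for vectors of length ≥ 2000.
    """
    x = np.asarray(base_log2fc, dtype=float)
    if x.size < 3:
        raise ValueError("need a vector of length >= 3")
    if abs(target_r) > 1:
        raise ValueError(f"|target_r| must be <= 1, got {target_r}")
    sd = x.std()
    if sd == 0:
        raise ValueError("base vector has zero variance")
    z = (x - x.mean()) / sd
    if abs(target_r) == 1.0:
        return target_r * x
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(x.size)
    y = target_r * z + np.sqrt(1.0 - target_r**2) * eps
    return y * sd


# ---------------------------------------------------------------------------
# genomic positions


def generate_positions(gene_ids: list[str], deg_mask: np.ndarray,
                       chrom_sizes: dict[str, int] | None = None,
                       cluster_fraction: float = 0.5,
                       run_length_range: tuple[int, int] = (3, 8),
                       gene_length: int = 1000,
                       gap_range: tuple[int, int] = (2000, 6000),
                       seed: int = 0,
                       ) -> tuple[list[GeneRecord], pd.Series]:
    """Non-overlapping ordered gene loci with optional tandem DEG clustering.

    Genes are laid down in genome order with random intergenic gaps (the
    minimum gap exceeds the promoter window, so promoter regions never
    overlap a neighbouring gene body). A fraction ``cluster_fraction`` of
    the DEG labels is then placed in runs of 3–8 adjacent position slots;
    the remaining DEG labels and all non-DEG labels go to random free slots,
    so with cluster_fraction=0 DEG labels are independent of position.

    Returns the records (genome order within the input id set) and a Series
    mapping gene_id → tandem-run id (−1 for genes outside any planted run).
    """
    if chrom_sizes is None:
        chrom_sizes = DEFAULT_CHROM_SIZES
    if any(s <= 0 for s in chrom_sizes.values()):
        raise ValueError("chromosome sizes must be positive")
    n = len(gene_ids)
    deg_mask = np.asarray(deg_mask, dtype=bool)
    if deg_mask.shape != (n,):
        raise ValueError("deg_mask length must match gene_ids")
    rng = np.random.default_rng(seed)

    # apportion slot counts to chromosomes by size
    chroms = list(chrom_sizes)
    sizes = np.asarray([chrom_sizes[c] for c in chroms], dtype=float)
    counts = np.floor(sizes / sizes.sum() * n).astype(int)
    counts[0] += n - counts.sum()

    slots: list[tuple[str, int, int]] = []  # (chrom, start, end), genome order
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        gaps = rng.integers(gap_range[0], gap_range[1] + 1, size=k)
        starts = np.cumsum(gaps) + np.arange(k) * gene_length + 1
        ends = starts + gene_length - 1
        if ends[-1] > chrom_sizes[chrom]:
            raise ValueError(
                f"{k} genes do not fit on chromosome {chrom} "
                f"({ends[-1]} > {chrom_sizes[chrom]} bp)"
            )
        slots.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))

    # choose which slots carry DEG labels
    deg_ids = [g for g, d in zip(gene_ids, deg_mask) if d]
    other_ids = [g for g, d in zip(gene_ids, deg_mask) if not d]
    n_deg = len(deg_ids)
    n_clustered = int(round(cluster_fraction * n_deg))

    free = np.ones(n, dtype=bool)
    deg_slots: list[int] = []
    run_of_slot: dict[int, int] = {}
    run_id = 0
    lo_run, hi_run = run_length_range
    placed = 0
    attempts = 0
    while placed < n_clustered and attempts < 100 * n:
        attempts += 1
        run_len = min(int(rng.integers(lo_run, hi_run + 1)), n_clustered - placed)
        run_len = max(run_len, 1)
        start = int(rng.integers(0, n - run_len + 1))
        block = range(start, start + run_len)
        if not all(free[i] for i in block):
            continue
        if slots[start][0] != slots[start + run_len - 1][0]:
            continue  # run must stay on one chromosome
        for i in block:
            free[i] = False
            deg_slots.append(i)
            run_of_slot[i] = run_id
        run_id += 1
        placed += run_len
    if placed < n_clustered:
        raise ValueError("could not place clustered DEG runs; genome too dense")

    free_idx = np.flatnonzero(free)
    scatter = rng.choice(free_idx, size=n_deg - placed, replace=False)
    for i in scatter:
        free[i] = False
        deg_slots.append(int(i))
    other_slots = np.flatnonzero(free)

    deg_ids_shuffled = list(deg_ids)
    rng.shuffle(deg_ids_shuffled)
    other_ids_shuffled = list(other_ids)
    rng.shuffle(other_ids_shuffled)

    id_of_slot: dict[int, str] = {}
    for slot, gid in zip(sorted(deg_slots), deg_ids_shuffled):
        id_of_slot[slot] = gid
    for slot, gid in zip(other_slots, other_ids_shuffled):
        id_of_slot[int(slot)] = gid

    strands = rng.choice(["+", "-"], size=n)
    records: list[GeneRecord] = []
    cluster_ids = {}
    for i, (chrom, start, end) in enumerate(slots):
        gid = id_of_slot[i]
        records.append(GeneRecord(gene_id=gid, chrom=chrom, start=start,
                                  end=end, strand=str(strands[i]),
                                  length_bp=gene_length))
        cluster_ids[gid] = run_of_slot.get(i, -1)
    return records, pd.Series(cluster_ids, name="tandem_run")


# ---------------------------------------------------------------------------
# promoters


def _motif_free_background(rng: np.random.Generator, length: int,
                           motif: str) -> str:
    bases = np.array(list("ACGT"))
    while True:
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        if motif not in seq:
            return seq


def generate_promoters(genes: list[GeneRecord], motif: str,
                       copy_plan: dict[str, int], seed: int = 0,
                       upstream: int = 500, downstream: int = 100,
                       ) -> tuple[dict[str, PromoterSequence], pd.DataFrame]:
    """Promoter sequences with exactly the planned number of motif copies.

    Each promoter is ``upstream + downstream`` bases of motif-free random
    background with the planned copies planted at non-overlapping offsets
    (re-sampled if a junction accidentally creates an extra occurrence).
    Returns gene_id → PromoterSequence plus a truth table of planted counts
    and TSS-relative offsets.
    """
    motif = motif.upper()
    if not motif or not set(motif) <= set("ACGT"):
        raise ValueError(f"motif must be non-empty over A/C/G/T, got {motif!r}")
    window = upstream + downstream
    if len(motif) > window:
        raise ValueError("motif longer than promoter window")
    rng = np.random.default_rng(seed)
    promoters: dict[str, PromoterSequence] = {}
    rows = []
    for gene in genes:
        plan = int(copy_plan.get(gene.gene_id, 0))
        if plan < 0:
            raise ValueError(f"negative copy plan for {gene.gene_id}")
        if plan * len(motif) > window:
            raise ValueError(f"{plan} copies of {motif!r} do not fit the window")
        while True:
            seq = list(_motif_free_background(rng, window, motif))
            # place copies at non-overlapping offsets
            offsets: list[int] = []
            tries = 0
            while len(offsets) < plan and tries < 1000:
                tries += 1
                pos = int(rng.integers(0, window - len(motif) + 1))
                if all(abs(pos - q) >= len(motif) for q in offsets):
                    offsets.append(pos)
            if len(offsets) < plan:
                continue
            for pos in offsets:
                seq[pos:pos + len(motif)] = motif
            joined = "".join(seq)
            # junctions may create extra (possibly overlapping) occurrences;
            # verify with an overlap-aware scan
            n_found, pos = 0, joined.find(motif)
            while pos >= 0:
                n_found += 1
                pos = joined.find(motif, pos + 1)
            if n_found == plan:
                break
        promoters[gene.gene_id] = PromoterSequence(
            gene_id=gene.gene_id, sequence=joined, truncated=False,
            tss_offset=upstream,
        )
        rows.append({"gene_id": gene.gene_id, "planted_copies": plan,
                     "offsets": ",".join(str(o - upstream) for o in sorted(offsets))})
    truth = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["planted_copies", "offsets"])
    return promoters, truth


def generate_genome(genes: list[GeneRecord],
                    promoters: dict[str, PromoterSequence],
                    chrom_sizes: dict[str, int], seed: int = 0,
                    upstream: int = 500, downstream: int = 100,
                    ) -> dict[str, str]:
    """Random chromosome sequences with each gene's promoter window
    overwritten by its generated promoter (reverse-complemented for − strand
    genes), so promoter extraction from this genome returns the planted
    sequences exactly. Intended for small test genomes."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genome = {
        c: np.array(list("".join(bases[rng.integers(0, 4, size=size)])))
        for c, size in chrom_sizes.items()
    }
    for gene in genes:
        prom = promoters[gene.gene_id]
        tss = gene.tss
        if gene.strand == "+":
            lo = tss - upstream
            insert = prom.sequence
        else:
            lo = tss - downstream + 1
            insert = reverse_complement(prom.sequence)
        if lo < 1 or lo - 1 + len(insert) > len(genome[gene.chrom]):
            raise ValueError(f"promoter window of {gene.gene_id} outside chromosome")
        genome[gene.chrom][lo - 1:lo - 1 + len(insert)] = list(insert)
    return {c: "".join(arr) for c, arr in genome.items()}


# ---------------------------------------------------------------------------
# qPCR and annotation terms


def generate_qpcr_table(log2fc: pd.Series, condition_a: str = "control",
                        condition_b: str = "mutant", n_replicates: int = 3,
                        noise_sd: float = 0.1, seed: int = 0,
                        reference_gene: str = "rpL32") -> QpcrTable:
    """CT table whose ΔΔCT fold changes match the given log2 fold changes up
    to Gaussian CT noise (sd in cycles). The reference gene CT sits near 16
    cycles; target ΔCTs in the control condition are drawn in [2, 10]."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene, lfc in log2fc.items():
        dct_a = rng.uniform(2.0, 10.0)
        for cond, dct in ((condition_a, dct_a), (condition_b, dct_a - lfc)):
            for rep in range(1, n_replicates + 1):
                ct_ref = 16.0 + rng.normal(0.0, noise_sd)
                ct_tgt = ct_ref + dct + rng.normal(0.0, noise_sd)
                rows.append({
                    "target_gene": gene, "condition": cond, "replicate": rep,
                    "ct_target": round(ct_tgt, 4), "ct_reference": round(ct_ref, 4),
                    "reference_gene": reference_gene,
                })
    return QpcrTable(rows=pd.DataFrame(rows))


def generate_term_map(gene_ids: list[str], favored: set[str],
                      n_terms: int = 30, n_enriched: int = 3,
                      term_size_range: tuple[int, int] = (20, 80),
                      enrichment_factor: float = 5.0, seed: int = 0,
                      ) -> tuple[dict[str, set[str]], set[str]]:
    """Annotation terms, ``n_enriched`` of which oversample the ``favored``
    gene set by ``enrichment_factor`` relative to its background share."""
    rng = np.random.default_rng(seed)
    gene_arr = np.asarray(gene_ids)
    fav_mask = np.isin(gene_arr, list(favored))
    base_p = np.ones(len(gene_arr))
    term_map: dict[str, set[str]] = {}
    enriched: set[str] = set()
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        w = base_p.copy()
        name = f"T{t:03d}"
        if t < n_enriched and fav_mask.any():
            w[fav_mask] *= enrichment_factor
            enriched.add(name)
        w /= w.sum()
        members = rng.choice(gene_arr, size=size, replace=False, p=w)
        term_map[name] = set(members.tolist())
    return term_map, enriched


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus the planted truth."""

    config: SimulationConfig
    matrix: ExpressionMatrix
    companion_matrix: ExpressionMatrix
    truth: pd.DataFrame
    loci: list[GeneRecord]
    promoters: dict[str, PromoterSequence]
    promoter_truth: pd.DataFrame
    qpcr: QpcrTable
    qpcr_panel: list[str]
    term_map: dict[str, set[str]]
    enriched_terms: set[str]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the complete synthetic study.

    Truth columns: planted_log2fc, is_deg, direction, is_extreme,
    companion_log2fc, companion_is_deg, dev_log2fc, dev_signed_fc,
    tandem_run, planted_motif_copies.
    """
    matrix, truth = generate_counts(config, seed=config.stage_seed(0))
    base = truth["planted_log2fc"].to_numpy()

    # companion contrast: planted log2FCs correlated with the primary ones
    comp = generate_companion_log2fc(base, config.companion_r,
                                     seed=config.stage_seed(1))
    companion_matrix, comp_truth = generate_counts(
        config, log2fc=comp, seed=config.stage_seed(2),
        condition_a="control2", condition_b="mutant2")
    truth["companion_log2fc"] = comp
    truth["companion_is_deg"] = comp_truth["is_deg"].to_numpy()

    # developmental contrast: anti-correlated among DEGs, uncorrelated noise
    # elsewhere (the anti-correlation concentrates in the regulated genes)
    rng_dev = np.random.default_rng(config.stage_seed(3))
    dev = rng_dev.standard_normal(config.n_genes) * max(base.std(), 1.0)
    deg_mask = truth["is_deg"].to_numpy()
    if deg_mask.sum() >= 3 and base[deg_mask].std() > 0:
        dev[deg_mask] = generate_companion_log2fc(
            base[deg_mask], config.dev_r, seed=config.stage_seed(4))
    truth["dev_log2fc"] = dev
    truth["dev_signed_fc"] = np.where(dev >= 0, 2.0 ** dev, -(2.0 ** (-dev)))

    loci, runs = generate_positions(
        list(truth.index), deg_mask,
        cluster_fraction=config.cluster_fraction,
        run_length_range=config.run_length_range,
        gene_length=config.gene_length,
        seed=config.stage_seed(5),
    )
    truth["tandem_run"] = runs.reindex(truth.index)

    # motif copy plan: upregulated DEGs mostly carry 1–2 copies, background
    # genes mostly none
    rng_m = np.random.default_rng(config.stage_seed(6))
    up_mask = (truth["direction"] == "up").to_numpy()
    plan_arr = np.zeros(config.n_genes, dtype=int)
    plan_arr[up_mask] = rng_m.choice([0, 1, 2], size=up_mask.sum(),
                                     p=[0.15, 0.65, 0.20])
    bg = ~up_mask
    plan_arr[bg] = rng_m.choice([0, 1], size=bg.sum(), p=[0.9, 0.1])
    copy_plan = dict(zip(truth.index, plan_arr.tolist()))
    promoters, promoter_truth = generate_promoters(
        loci, config.motif, copy_plan, seed=config.stage_seed(7))
    truth["planted_motif_copies"] = pd.Series(copy_plan).reindex(truth.index)

    # qPCR panel: a spread of planted fold changes, like a validation panel
    order = np.argsort(base)
    panel_idx = [order[0], order[len(order) // 8], order[len(order) // 4],
                 order[len(order) // 2], order[-len(order) // 4],
                 order[-len(order) // 8], order[-1]]
    panel = [truth.index[i] for i in dict.fromkeys(panel_idx)]
    qpcr = generate_qpcr_table(truth.loc[panel, "planted_log2fc"],
                               seed=config.stage_seed(8))

    up_ids = set(truth.index[up_mask])
    term_map, enriched = generate_term_map(list(truth.index), up_ids,
                                           seed=config.stage_seed(9))

    return SyntheticDataset(
        config=config, matrix=matrix, companion_matrix=companion_matrix,
        truth=truth, loci=loci, promoters=promoters,
        promoter_truth=promoter_truth, qpcr=qpcr, qpcr_panel=panel,
        term_map=term_map, enriched_terms=enriched,
    )
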