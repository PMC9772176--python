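import numpy as np
import pandas as pd
import pytest

from coopdeg.enrichment import count_motif, extract_promoter
from coopdeg.simulate import (
    DEFAULT_CHROM_SIZES,
    Log2FCDistribution,
    SimulationConfig,
    generate_companion_log2fc,
    generate_counts,
    generate_genome,
    generate_positions,
    generate_promoters,
    generate_qpcr_table,
    generate_term_map,
    simulate_dataset,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genes=0),
            dict(n_replicates=1),
            dict(baseline_mean=0.0),
            dict(nb_dispersion=-0.1),
            dict(frac_deg=1.5),
            dict(companion_r=1.2),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestCounts:
    def test_null_config_plants_no_effects(self):
        cfg = SimulationConfig(n_genes=500, frac_deg=0.0, seed=1)
        _, truth = generate_counts(cfg)
        assert (truth["planted_log2fc"] == 0).all()
        assert not truth["is_deg"].any()

    def test_same_seed_identical_matrices(self):
        cfg = SimulationConfig(n_genes=300, seed=11)
        m1, t1 = generate_counts(cfg)
        m2, t2 = generate_counts(cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_dispersion_limit_is_poisson(self):
        # var/mean across replicates → 1 in the dispersion→0 limit
        cfg = SimulationConfig(n_genes=5000, n_replicates=10, frac_deg=0.0,
                               nb_dispersion=0.0, baseline_sigma=0.0,
                               size_factor_range=(1.0, 1.0), seed=5)
        m, _ = generate_counts(cfg)
        va = m.condition_values("control")
        ratio = (va.var(axis=1) / va.mean(axis=1)).mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_planted_effect_sets_condition_means(self):
        cfg = SimulationConfig(n_genes=4000, frac_deg=0.3, seed=3)
        _, truth = generate_counts(cfg)
        e = truth["planted_log2fc"]
        ratio = np.log2(truth["mean_b"] / truth["mean_a"])
        np.testing.assert_allclose(ratio, e, atol=1e-9)
        # extreme effects sit at near-zero expression on one side
        extreme = truth[truth["is_extreme"]]
        if len(extreme):
            low = np.minimum(extreme["mean_a"], extreme["mean_b"])
            high = np.maximum(extreme["mean_a"], extreme["mean_b"])
            assert (low < high / 100).all()


class TestCompanion:
    def test_target_one_is_affine(self):
        x = np.random.default_rng(0).normal(size=100)
        y = generate_companion_log2fc(x, 1.0, seed=1)
        assert abs(np.corrcoef(x, y)[0, 1] - 1.0) < 1e-12

    @pytest.mark.parametrize("target", [0.0, -0.67, 0.55])
    def test_empirical_r_within_tolerance_at_5000(self, target):
        x = np.random.default_rng(2).normal(0, 2, 5000)
        y = generate_companion_log2fc(x, target, seed=7)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(target, abs=0.05)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            generate_companion_log2fc(np.ones(10) + np.arange(10), 1.5, seed=0)


class TestPositions:
    def _mask(self, n, k, seed=0):
        rng = np.random.default_rng(seed)
        m = np.zeros(n, dtype=bool)
        m[rng.choice(n, k, replace=False)] = True
        return m

    def test_loci_ordered_and_non_overlapping(self):
        ids = [f"g{i}" for i in range(500)]
        recs, _ = generate_positions(ids, self._mask(500, 50), seed=4)
        by_chrom: dict = {}
        for r in recs:
            by_chrom.setdefault(r.chrom, []).append(r)
        for rs in by_chrom.values():
            for a, b in zip(rs, rs[1:]):
                assert b.start > a.end

    def test_full_clustering_places_runs_of_adjacent_degs(self):
        ids = [f"g{i}" for i in range(400)]
        mask = self._mask(400, 40, seed=1)
        recs, runs = generate_positions(ids, mask, cluster_fraction=1.0,
                                        run_length_range=(4, 4), seed=2)
        deg_ids = {g for g, m in zip(ids, mask) if m}
        # every clustered DEG shares its run with >= 1 adjacent DEG slot
        pos_order = [r.gene_id for r in recs]
        idx = {g: i for i, g in enumerate(pos_order)}
        for g in deg_ids:
            assert runs[g] >= 0
            neighbors = {pos_order[j] for j in (idx[g] - 1, idx[g] + 1)
                         if 0 <= j < len(pos_order)}
            assert neighbors & deg_ids

    def test_fixed_seed_identical_coordinates(self):
        ids = [f"g{i}" for i in range(200)]
        mask = self._mask(200, 20)
        r1, _ = generate_positions(ids, mask, seed=9)
        r2, _ = generate_positions(ids, mask, seed=9)
        assert r1 == r2

    def test_genome_too_small_rejected(self):
        ids = [f"g{i}" for i in range(100)]
        with pytest.raises(ValueError, match="fit"):
            generate_positions(ids, np.zeros(100, bool),
                               chrom_sizes={"mini": 10_000}, seed=0)


class TestPromoters:
    def test_planted_copy_plan_recovered_by_scanning(self):
        ids = [f"g{i}" for i in range(30)]
        recs, _ = generate_positions(ids, np.zeros(30, bool),
                                     chrom_sizes={"c1": 10**6}, seed=1)
        plan = {g: i % 4 for i, g in enumerate(ids)}
        promoters, truth = generate_promoters(recs, "GATAAG", plan, seed=2)
        for g in ids:
            assert count_motif(promoters[g], "GATAAG").copy_count == plan[g]
            assert truth.loc[g, "planted_copies"] == plan[g]

    def test_promoter_window_is_600_bases(self):
        ids = ["g0"]
        recs, _ = generate_positions(ids, np.zeros(1, bool),
                                     chrom_sizes={"c1": 10**5}, seed=1)
        promoters, _ = generate_promoters(recs, "GATAAG", {"g0": 1}, seed=3)
        assert len(promoters["g0"].sequence) == 600

    def test_fixed_seed_identical_fasta(self):
        ids = [f"g{i}" for i in range(5)]
        recs, _ = generate_positions(ids, np.zeros(5, bool),
                                     chrom_sizes={"c1": 10**5}, seed=1)
        p1, _ = generate_promoters(recs, "GATAAG", {g: 1 for g in ids}, seed=8)
        p2, _ = generate_promoters(recs, "GATAAG", {g: 1 for g in ids}, seed=8)
        assert {g: p.sequence for g, p in p1.items()} == \
               {g: p.sequence for g, p in p2.items()}

    def test_motif_longer_than_window_rejected(self):
        ids = ["g0"]
        recs, _ = generate_positions(ids, np.zeros(1, bool),
                                     chrom_sizes={"c1": 10**5}, seed=1)
        with pytest.raises(ValueError):
            generate_promoters(recs, "A" * 700, {}, seed=0)

    def test_genome_embedding_round_trips_through_extraction(self):
        # promoter extracted from the synthetic genome == generated promoter,
        # for both strands
        ids = [f"g{i}" for i in range(20)]
        recs, _ = generate_positions(ids, np.zeros(20, bool),
                                     chrom_sizes={"c1": 5 * 10**5}, seed=6)
        assert {r.strand for r in recs} == {"+", "-"}
        plan = {g: (i % 3) for i, g in enumerate(ids)}
        promoters, _ = generate_promoters(recs, "GATAAG", plan, seed=7)
        genome = generate_genome(recs, promoters, {"c1": 5 * 10**5}, seed=8)
        for r in recs:
            extracted = extract_promoter(r, genome)
            assert extracted.sequence == promoters[r.gene_id].sequence
            assert count_motif(extracted, "GATAAG").copy_count == plan[r.gene_id]


class TestQpcrAndTerms:
    def test_qpcr_table_recovers_planted_log2fc(self):
        lfc = pd.Series({"gX": 3.0, "gY": -2.0, "gZ": 0.0})
        table = generate_qpcr_table(lfc, noise_sd=0.0, seed=1)
        from coopdeg.concordance import qpcr_fold_change

        for g, e in lfc.items():
            fc = qpcr_fold_change(table, g, "mutant", "control")
            assert fc.log2_fc == pytest.approx(e, abs=1e-3)

    def test_term_map_marks_enriched_terms(self):
        ids = [f"g{i}" for i in range(500)]
        favored = set(ids[:50])
        term_map, enriched = generate_term_map(ids, favored, n_terms=10,
                                               n_enriched=2, seed=3)
        assert len(term_map) == 10 and len(enriched) == 2
        # enriched terms oversample the favored set relative to the others
        def share(t):
            return len(term_map[t] & favored) / len(term_map[t])
        mean_enr = np.mean([share(t) for t in enriched])
        mean_bg = np.mean([share(t) for t in term_map if t not in enriched])
        assert mean_enr > mean_bg


class TestDataset:
    def test_truth_covers_every_gene_once(self, small_dataset):
        truth = small_dataset.truth
        assert len(truth) == small_dataset.config.n_genes
        assert truth.index.is_unique
        assert set(truth.index) == set(small_dataset.matrix.gene_ids)
        assert {r.gene_id for r in small_dataset.loci} == set(truth.index)

    def test_dataset_determinism(self):
        cfg = SimulationConfig(n_genes=200, seed=42)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.matrix.values, d2.matrix.values)
        pd.testing.assert_frame_equal(d1.truth, d2.truth)
        assert d1.loci == d2.loci
        assert {g: p.sequence for g, p in d1.promoters.items()} == \
               {g: p.sequence for g, p in d2.promoters.items()}
        pd.testing.assert_frame_equal(d1.qpcr.rows, d2.qpcr.rows)
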