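import numpy as np
import pytest

from regcl import (
    GenomicInterval,
    IDBCParams,
    LabelConfig,
    SimConfig,
    bray_curtis,
    crispr_labels,
    design_site,
    gen_expression,
    gen_ipwm,
    gen_knockdown,
    gen_promoters,
    idbc,
    iPWM,
    run_planted_benchmark,
    scan,
    score_site,
)
from regcl.scanning import Promoter, matrix_r_sequence


class TestGenIpwm:
    def test_information_within_tolerance(self):
        for target in (6.0, 12.0, 20.0):
            f = gen_ipwm(11, target, seed=3)
            assert abs(f.r_sequence_meta - target) <= 0.5
            recomputed = matrix_r_sequence(iPWM(tf="x", weights=f.weights))
            assert recomputed == pytest.approx(f.r_sequence_meta, abs=0.3)

    def test_deterministic_under_seed(self):
        a = gen_ipwm(11, 12.0, seed=9)
        b = gen_ipwm(11, 12.0, seed=9)
        assert np.array_equal(a.weights, b.weights)
        assert not np.array_equal(a.weights, gen_ipwm(11, 12.0, seed=10).weights)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            gen_ipwm(11, 23.0, seed=1)  # > 2 bits/position
        with pytest.raises(ValueError):
            gen_ipwm(11, 0.0, seed=1)


class TestDesignSite:
    def test_realized_score_brackets_target(self, sim_ipwm, rng):
        r_seq = sim_ipwm.r_sequence
        for frac in (0.2, 0.5, 0.8, 1.0):
            target = frac * r_seq
            kmer = design_site(sim_ipwm, target, rng)
            got = score_site(sim_ipwm, kmer)
            assert target <= got + 1e-9 <= sim_ipwm.max_score + 1e-9

    def test_unattainable_target_returns_consensus(self, sim_ipwm, rng):
        kmer = design_site(sim_ipwm, sim_ipwm.max_score + 5.0, rng)
        assert kmer == sim_ipwm.consensus


@pytest.fixture(scope="module")
def small_sim(sim_ipwm):
    cfg = SimConfig(n_genes=40, n_positives=15)
    return cfg, gen_promoters(cfg, [sim_ipwm], np.random.default_rng(100))


class TestGenPromoters:
    def test_deterministic_under_seed(self, sim_ipwm):
        cfg = SimConfig(n_genes=6, n_positives=3)
        a = gen_promoters(cfg, [sim_ipwm], np.random.default_rng(5))
        b = gen_promoters(cfg, [sim_ipwm], np.random.default_rng(5))
        assert a.genome == b.genome

    def test_planted_cluster_recovered_by_scan_and_idbc(self, sim_ipwm, small_sim):
        cfg, sim = small_sim
        params = IDBCParams(d=cfg.cluster_radius, I=sim_ipwm.r_sequence)
        recovered = 0
        for gene in sim.positives:
            prom = sim.promoters[gene]
            clusters = idbc(scan(sim_ipwm, prom, sim.genome), params)
            planted = sim.truth_clusters[sim.truth_clusters.gene == gene]
            spans = [GenomicInterval(gene, int(r.start), int(r.end))
                     for r in planted.itertuples()]
            if any(c.span.overlaps(s) for c in clusters for s in spans):
                recovered += 1
        assert recovered >= 0.9 * len(sim.positives)

    def test_plants_lie_inside_accessible_intervals(self, small_sim):
        cfg, sim = small_sim
        for row in sim.truth_sites.itertuples():
            prom = sim.promoters[row.gene]
            width = len(row.sequence)
            assert any(iv.start <= row.start and row.start + width <= iv.end
                       for iv in prom.accessible)

    def test_background_rarely_forms_passing_clusters(self, sim_ipwm):
        """Calibration contract: a negative promoter's background accessibility
        yields a threshold-passing cluster in < 5% of genes."""
        cfg = SimConfig(n_genes=120, n_positives=1)
        sim = gen_promoters(cfg, [sim_ipwm], np.random.default_rng(2024))
        params = IDBCParams(d=cfg.cluster_radius, I=sim_ipwm.r_sequence)
        hits = sum(
            bool(idbc(scan(sim_ipwm, sim.promoters[g], sim.genome), params))
            for g in sim.negatives
        )
        assert hits / len(sim.negatives) < 0.05

    def test_peaks_cover_all_plants(self, small_sim):
        _, sim = small_sim
        peak_genes = {p.contig for p in sim.peaks}
        assert set(sim.truth_clusters.gene) <= peak_genes


class TestGenExpression:
    def test_within_group_similarity_exceeds_between(self, rng):
        groups = {"a": [f"a{i}" for i in range(8)], "b": [f"b{i}" for i in range(8)]}
        m = gen_expression(20, groups, rng)
        within, between = [], []
        for g1 in m.genes:
            for g2 in m.genes:
                if g1 < g2:
                    s = bray_curtis(m.profile(g1), m.profile(g2))
                    (within if g1[0] == g2[0] else between).append(s)
        assert np.mean(within) > np.mean(between)

    def test_zero_noise_identical_members(self, rng):
        m = gen_expression(10, {"a": ["x", "y"]}, rng, scale_sigma=0.0,
                           noise_sigma=0.0)
        assert bray_curtis(m.profile("x"), m.profile("y")) == 1.0

    def test_dimensions(self, rng):
        m = gen_expression(7, {"a": ["x", "y", "z"]}, rng)
        assert m.data.shape == (3, 7)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            gen_expression(5, {"a": []}, rng)


class TestGenKnockdown:
    genes = [f"g{i}" for i in range(20)]
    targets = genes[:8]

    def _promoters(self):
        return {g: Promoter(g, "c", 1000, "+", GenomicInterval("c", 0, 1000))
                for g in self.genes}

    def test_planted_targets_satisfy_labeling_criteria(self, rng):
        for eps in (1.01, 1.05, 1.1):
            k = gen_knockdown(self.genes, self.targets, 4, eps, rng)
            peaks = [GenomicInterval("c", 0, 1000)]  # binding evidence everywhere
            ls = crispr_labels(k, LabelConfig(epsilon=eps), peaks, self._promoters())
            assert set(ls.positives) == set(self.targets)

    def test_non_targets_exact_zero_and_negative(self, rng):
        k = gen_knockdown(self.genes, self.targets, 4, 1.1, rng)
        for g in self.genes[8:]:
            assert (k.row(g) == 0.0).all()
        ls = crispr_labels(k, LabelConfig(epsilon=1.1), [], self._promoters())
        assert set(ls.negatives) == set(self.genes[8:])

    def test_decoys_are_unlabeled(self, rng):
        k = gen_knockdown(self.genes, self.targets, 4, 1.1, rng, decoy_fraction=0.5)
        ls = crispr_labels(k, LabelConfig(epsilon=1.1),
                           [GenomicInterval("c", 0, 1000)], self._promoters())
        n_decoys = round(0.5 * 12)
        assert len(ls.negatives) == 12 - n_decoys
        assert set(ls.positives) == set(self.targets)

    def test_invalid_epsilon(self, rng):
        with pytest.raises(ValueError):
            gen_knockdown(self.genes, self.targets, 4, 1.0, rng)


class TestBenchmark:
    def test_deterministic_per_seed(self):
        cfg = SimConfig(n_genes=30, n_positives=12)
        a = run_planted_benchmark(3, cfg=cfg, rounds=2, folds=5)
        b = run_planted_benchmark(3, cfg=cfg, rounds=2, folds=5)
        assert a.report.mean_accuracy == b.report.mean_accuracy
        assert np.array_equal(a.features.X, b.features.X)

    def test_balanced_classes(self, small_benchmark):
        res = small_benchmark
        assert len(res.labels.positives) == len(res.labels.negatives)
        assert res.y.sum() * 2 == len(res.y)

    def test_feature_ablation_reduces_accuracy(self, small_benchmark):
        """Dropping everything except the per-TF site counts must not improve
        the classifier (cluster geometry and information carry signal)."""
        from regcl.modeling import cross_validate

        fm, y = small_benchmark.features, small_benchmark.y
        count_cols = [i for i, (s, n, t) in enumerate(fm.schema) if n == "n_sites"]
        full = cross_validate(fm.X, y, rounds=3, folds=5, seed=0).mean_accuracy
        ablated = cross_validate(fm.X[:, count_cols], y, rounds=3, folds=5,
                                 seed=0).mean_accuracy
        assert ablated <= full + 0.02
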