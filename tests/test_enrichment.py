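import itertools

import numpy as np
import pytest

from oracles import bitmask_coverage
from repeatscape.enrichment import (
    EnrichmentParams,
    bh_adjust,
    enrichment_test,
    flank_regions,
    region_density,
    region_set_test,
    scan_categories,
)
from repeatscape.io_formats import GeneRecord, GenomeIndex, RepeatHit
from repeatscape.synthetic import PlantedEnrichment, SimulationConfig, plant_genome


def hit(seq, s, e, cls="LINE/BovB"):
    return RepeatHit(seq, s, e, "+", "fam", cls, 1.0, 100.0)


class TestFlankRegions:
    def test_simple_flank(self):
        index = GenomeIndex("g", {"chr1": 100_000})
        regions = flank_regions([GeneRecord("g1", "chr1", 5000, 6000)], 1000, index)
        assert regions["chr1"].tolist() == [[4000, 7000]]

    def test_clipped_at_sequence_start(self):
        index = GenomeIndex("g", {"chr1": 100_000})
        regions = flank_regions([GeneRecord("g1", "chr1", 200, 900)], 1000, index)
        assert regions["chr1"].tolist() == [[0, 1900]]

    def test_close_genes_merge(self):
        index = GenomeIndex("g", {"chr1": 100_000})
        genes = [
            GeneRecord("g1", "chr1", 10_000, 11_000),
            GeneRecord("g2", "chr1", 11_500, 12_500),  # 500 bp apart
        ]
        regions = flank_regions(genes, 1000, index)
        assert len(regions["chr1"]) == 1
        assert regions["chr1"].tolist() == [[9000, 13_500]]


class TestRegionDensity:
    def test_fully_covered(self):
        regions = {"chr1": np.array([[100, 200]])}
        assert region_density(regions, [hit("chr1", 0, 500)]) == 1.0

    def test_no_hits(self):
        regions = {"chr1": np.array([[100, 200]])}
        assert region_density(regions, [hit("chr1", 300, 400)], "DNA/TcMar-Tc1") == 0.0

    def test_random_fixture_matches_bitmask(self, rng):
        hits = [hit("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 9500, 200), rng.integers(1, 300, 200))]
        mask = bitmask_coverage([(h.start, h.end) for h in hits], 10_000)
        regions = {"chr1": np.array([[100, 2500], [4000, 9000]])}
        expected = (mask[100:2500].sum() + mask[4000:9000].sum()) / (2400 + 5000)
        assert region_density(regions, hits) == pytest.approx(expected)


class TestBH:
    def test_hand_computed_example(self):
        # thresholds i*q/m = 0.0333, 0.0667, 0.1 at q = 0.1
        q = bh_adjust([0.002, 0.02, 0.9])
        assert q[0] == pytest.approx(0.006)
        assert q[1] == pytest.approx(0.03)
        assert q[2] == pytest.approx(0.9)
        assert (q[:2] <= 0.1).all() and q[2] > 0.1

    def test_all_ones_no_discoveries(self):
        assert (bh_adjust([1.0] * 5) == 1.0).all()

    def test_single_category_equals_raw(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def toy_setup():
    """4 genes with exactly enumerable flank densities; flank 100."""
    index = GenomeIndex("g", {"chr1": 100_000})
    genes = [
        GeneRecord("g1", "chr1", 10_000, 11_000),
        GeneRecord("g2", "chr1", 30_000, 31_000),
        GeneRecord("g3", "chr1", 50_000, 51_000),
        GeneRecord("g4", "chr1", 70_000, 71_000),
    ]
    # densities over each 1200-bp flanked region: g1=600, g2=120, g3=300, g4=0 bp
    hits = [
        hit("chr1", 10_000, 10_600),
        hit("chr1", 30_000, 30_120),
        hit("chr1", 50_000, 50_300),
    ]
    return index, genes, hits


class TestEnrichmentTest:
    def test_p_floor_with_499_resamples(self):
        # observed exceeds every null value -> p = 1/(N+1) = 0.002
        config = SimulationConfig(
            seed=4, seq_lengths={"chr1": 1_500_000},
            classes={"LINE/BovB": 0.004, "Unknown": 0.01}, n_genes=120,
            family_length_range=(150, 400),
            enrichments=[PlantedEnrichment("fs", 6, "LINE/BovB", 40.0)],
        )
        sim = plant_genome(config)
        focal = sim.focal_genes("fs")
        params = EnrichmentParams(n_resamples=499, seed=11)
        res = enrichment_test(
            focal, sim.hits, sim.genes, "LINE/BovB", sim.index, params,
        )
        assert (res.null_densities < res.observed_density).all()
        assert res.p_emp == pytest.approx(1 / 500)

    def test_observed_equal_to_all_nulls_gives_p_one(self):
        index, genes, _ = toy_setup()
        params = EnrichmentParams(flank=100, n_resamples=3, seed=0)
        res = enrichment_test(
            [genes[3]], [], genes, "LINE/BovB", index, params,
        )  # no hits anywhere: observed == null == 0, ties count as >=
        assert res.p_emp == 1.0
        assert res.fold_enrichment == 0.0

    def test_exhaustive_enumeration_oracle(self):
        index, genes, hits = toy_setup()
        params = EnrichmentParams(flank=100, n_resamples=3, seed=5)
        focal = [genes[0]]
        null_groups = [[g] for g in genes[1:]]  # all possible m=1 groups
        res = enrichment_test(
            focal, hits, genes, "LINE/BovB", index, params,
            null_groups=null_groups,
        )
        # hand enumeration: region bp = 1200; densities by per-base count
        assert res.observed_density == pytest.approx(600 / 1200)
        expected_null = np.array([120, 300, 0]) / 1200
        np.testing.assert_allclose(np.sort(res.null_densities), np.sort(expected_null))
        assert res.fold_enrichment == pytest.approx(0.5 / expected_null.mean())
        assert res.p_emp == pytest.approx((0 + 1) / (3 + 1))

    def test_p_in_valid_range(self, small_sim):
        params = EnrichmentParams(n_resamples=19, seed=3)
        res = enrichment_test(
            small_sim.genes[:5], small_sim.hits, small_sim.genes, "Unknown",
            small_sim.index, params,
        )
        assert 1 / 20 <= res.p_emp <= 1.0

    def test_seed_determinism(self, small_sim):
        focal = small_sim.focal_genes("fs")
        params = EnrichmentParams(n_resamples=49, seed=99)
        a = enrichment_test(focal, small_sim.hits, small_sim.genes, "LINE/BovB",
                            small_sim.index, params)
        b = enrichment_test(focal, small_sim.hits, small_sim.genes, "LINE/BovB",
                            small_sim.index, params)
        np.testing.assert_array_equal(a.null_densities, b.null_densities)
        assert (a.p_emp, a.fold_enrichment) == (b.p_emp, b.fold_enrichment)

    def test_monotonicity_adding_focal_hits(self, small_sim):
        focal = small_sim.focal_genes("fs")
        params = EnrichmentParams(n_resamples=49, seed=1)
        base = enrichment_test(focal, small_sim.hits, small_sim.genes, "LINE/BovB",
                               small_sim.index, params)
        g = focal[0]
        extra = small_sim.hits + [hit(g.seq_id, g.start, g.end)]
        more = enrichment_test(focal, extra, small_sim.genes, "LINE/BovB",
                               small_sim.index, params)
        assert more.observed_density >= base.observed_density

    def test_null_pool_smaller_than_focal_errors(self):
        index, genes, hits = toy_setup()
        params = EnrichmentParams(n_resamples=3, seed=0)
        with pytest.raises(ValueError, match="pool"):
            enrichment_test(genes, hits, genes, "LINE/BovB", index, params)

    def test_zero_null_mean_gives_inf_fold(self):
        index, genes, _ = toy_setup()
        hits = [hit("chr1", 10_000, 10_600)]  # only inside g1's region
        params = EnrichmentParams(flank=100, n_resamples=3, seed=0)
        res = enrichment_test([genes[0]], hits, genes, "LINE/BovB", index, params)
        assert res.fold_enrichment == np.inf
        assert res.p_emp == pytest.approx(0.25)


class TestScanCategories:
    def test_bh_attached_and_shared_nulls(self, small_sim):
        focal = small_sim.focal_genes("fs")
        params = EnrichmentParams(n_resamples=99, seed=21)
        results = scan_categories(
            focal, small_sim.hits, small_sim.genes,
            ["LINE/BovB", "DNA/TcMar-Tc1", "Unknown", "total"],
            small_sim.index, params,
        )
        assert [r.category for r in results] == [
            "LINE/BovB", "DNA/TcMar-Tc1", "Unknown", "total"
        ]
        qs = bh_adjust([r.p_emp for r in results])
        np.testing.assert_allclose([r.q_bh for r in results], qs)
        # planted class is the clear discovery
        assert results[0].p_emp == pytest.approx(0.01)
        assert results[0].q_bh <= params.fdr_level

    def test_scan_matches_single_tests_given_same_groups(self, small_sim):
        focal = small_sim.focal_genes("fs")
        params = EnrichmentParams(n_resamples=29, seed=5)
        results = scan_categories(
            focal, small_sim.hits, small_sim.genes, ["LINE/BovB", "Unknown"],
            small_sim.index, params,
        )
        # same seed => same draws => same null densities for a single test
        single = enrichment_test(
            focal, small_sim.hits, small_sim.genes, "LINE/BovB",
            small_sim.index, params,
        )
        np.testing.assert_allclose(results[0].null_densities, single.null_densities)


class TestRegionSetTest:
    def test_consistent_with_gene_version(self, small_sim):
        focal = small_sim.focal_genes("fs")
        params = EnrichmentParams(n_resamples=29, seed=8)
        regions = flank_regions(focal, params.flank, small_sim.index)
        by_gene = enrichment_test(focal, small_sim.hits, small_sim.genes,
                                  "LINE/BovB", small_sim.index, params)
        by_region = region_set_test(regions, small_sim.hits, small_sim.genes,
                                    small_sim.index, params, category="LINE/BovB")
        assert by_region.observed_density == pytest.approx(by_gene.observed_density)

    def test_planted_fold_recovered(self, small_sim):
        focal = small_sim.focal_genes("fs")
        params = EnrichmentParams(n_resamples=199, seed=13)
        regions = flank_regions(focal, params.flank, small_sim.index)
        res = region_set_test(regions, small_sim.hits, small_sim.genes,
                              small_sim.index, params, category="LINE/BovB",
                              n_regions=len(focal))
        realized = small_sim.truth["enrichments"][0]["realized_fold"]
        assert res.fold_enrichment == pytest.approx(realized, rel=0.25)

    def test_empty_region_list_errors(self, small_sim):
        params = EnrichmentParams(seed=0)
        with pytest.raises(ValueError, match="empty"):
            region_set_test({}, small_sim.hits, small_sim.genes,
                            small_sim.index, params)


class TestNullCalibration:
    def test_p_values_uniform_under_null(self):
        # no planted enrichment: focal sets drawn from the same background
        config = SimulationConfig(
            seed=7, seq_lengths={"chr1": 1_500_000}, n_genes=120,
        )
        sim = plant_genome(config)
        N = 19
        alpha = 1 / (N + 1)
        pvals = []
        master = np.random.default_rng(2024)
        for i in range(400):
            picks = master.choice(len(sim.genes), size=6, replace=False)
            focal = [sim.genes[j] for j in picks]
            params = EnrichmentParams(n_resamples=N, seed=int(master.integers(2**31)))
            res = enrichment_test(focal, sim.hits, sim.genes, "LINE/BovB",
                                  sim.index, params)
            pvals.append(res.p_emp)
        pvals = np.array(pvals)
        assert (pvals >= alpha - 1e-12).all() and (pvals <= 1.0).all()
        rejection = (pvals <= alpha + 1e-12).mean()
        assert rejection <= alpha + 0.03  # alpha + Monte-Carlo epsilon
        assert abs(pvals.mean() - (0.5 + alpha / 2)) < 0.05  # discrete-uniform mean
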