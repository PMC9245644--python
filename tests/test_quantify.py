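import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bitmask_coverage, bitmask_total
from repeatscape.io_formats import GenomeIndex, RepeatHit
from repeatscape.quantify import (
    GenomeIntervals,
    OccupancyTable,
    category_occupancy,
    merge_intervals,
    relative_class_frequencies,
    window_density,
)

intervals_strategy = st.lists(
    st.tuples(st.integers(0, 900), st.integers(1, 100)).map(lambda t: (t[0], t[0] + t[1])),
    min_size=0,
    max_size=60,
)


def make_hits(intervals, seq="chr1", cls="LINE/BovB"):
    return [RepeatHit(seq, s, e, "+", "fam", cls, 1.0, 100.0) for s, e in intervals]


class TestMergeIntervals:
    def test_overlap_union(self):
        merged, total = merge_intervals([(10, 20), (15, 30)])
        assert merged.tolist() == [[10, 30]]
        assert total == 20

    def test_disjoint(self):
        merged, total = merge_intervals([(0, 5), (10, 15)])
        assert merged.tolist() == [[0, 5], [10, 15]]
        assert total == 10

    def test_zero_gap_adjacent_merges(self):
        merged, _ = merge_intervals([(0, 5), (5, 9)])
        assert merged.tolist() == [[0, 9]]

    def test_empty(self):
        merged, total = merge_intervals([])
        assert total == 0 and len(merged) == 0

    def test_thousand_random_intervals_match_bitmask(self, rng):
        iv = [(int(s), int(s + l)) for s, l in
              zip(rng.integers(0, 9000, 1000), rng.integers(1, 400, 1000))]
        _, total = merge_intervals(iv)
        assert total == bitmask_total(iv, 10_000)

    @settings(max_examples=60, deadline=None)
    @given(intervals_strategy)
    def test_property_matches_bitmask_and_disjoint(self, iv):
        merged, total = merge_intervals(iv)
        assert total == bitmask_total(iv, 1001)
        # disjoint, sorted, no zero-gap neighbors
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert e1 < s2


class TestCoverage:
    def test_random_queries_match_bitmask(self, rng):
        iv = [(int(s), int(s + l)) for s, l in
              zip(rng.integers(0, 50_000, 300), rng.integers(1, 500, 300))]
        gi = GenomeIntervals({"chr1": merge_intervals(iv)[0]})
        mask = bitmask_coverage(iv, 60_000)
        qs = rng.integers(0, 55_000, 500)
        qe = qs + rng.integers(1, 5000, 500)
        got = gi.coverage("chr1", qs, qe)
        expected = np.array([mask[a:b].sum() for a, b in zip(qs, qe)])
        np.testing.assert_array_equal(got, expected)

    def test_unknown_sequence_is_zero(self):
        gi = GenomeIntervals({"chr1": np.array([[0, 10]])})
        assert gi.coverage("chrX", [0], [100])[0] == 0


class TestCategoryOccupancy:
    def test_single_class_tenth_of_genome(self):
        index = GenomeIndex("g", {"chr1": 1_000_000})
        hits = make_hits([(i * 2000, i * 2000 + 1000) for i in range(100)])
        row = category_occupancy(hits, index)
        assert row.proportions["LINE/BovB"] == pytest.approx(0.10)
        assert row.total_repeat_proportion == pytest.approx(0.10)

    def test_fully_overlapping_classes_union_total(self):
        index = GenomeIndex("g", {"chr1": 1_000_000})
        hits = make_hits([(0, 100_000)], cls="LINE/BovB") + make_hits(
            [(0, 100_000)], cls="DNA/TcMar-Tc1"
        )
        row = category_occupancy(hits, index)
        assert row.proportions["LINE/BovB"] == pytest.approx(0.10)
        assert row.proportions["DNA/TcMar-Tc1"] == pytest.approx(0.10)
        assert row.total_repeat_proportion == pytest.approx(0.10)

    def test_random_fixture_matches_bitmask_per_category(self, rng):
        index = GenomeIndex("g", {"chr1": 20_000})
        classes = ["LINE/BovB", "DNA/TcMar-Tc1", "Unknown"]
        hits, per_class = [], {c: [] for c in classes}
        for _ in range(300):
            s = int(rng.integers(0, 19_000))
            e = s + int(rng.integers(1, 800))
            e = min(e, 20_000)
            c = classes[int(rng.integers(3))]
            hits += make_hits([(s, e)], cls=c)
            per_class[c].append((s, e))
        row = category_occupancy(hits, index)
        for c in classes:
            assert row.proportions[c] == pytest.approx(
                bitmask_total(per_class[c], 20_000) / 20_000
            )
        all_iv = [iv for c in classes for iv in per_class[c]]
        assert row.total_repeat_proportion == pytest.approx(
            bitmask_total(all_iv, 20_000) / 20_000
        )

    def test_union_bound_and_max_cell(self, small_sim):
        row = category_occupancy(small_sim.hits, small_sim.index)
        assert row.total_repeat_proportion <= sum(row.proportions.values()) + 1e-12
        assert row.total_repeat_proportion >= max(row.proportions.values()) - 1e-12
        assert all(0 <= v <= 1 for v in row.proportions.values())

    def test_monotonicity_adding_hit(self, toy_hits, toy_index):
        before = category_occupancy(toy_hits, toy_index)
        extra = toy_hits + make_hits([(5000, 5500)], cls="LINE/BovB")
        after = category_occupancy(extra, toy_index)
        for cat, v in before.proportions.items():
            assert after.proportions[cat] >= v - 1e-15
        assert after.total_repeat_proportion >= before.total_repeat_proportion

    def test_cluster_grouping_requires_cluster_ids(self, toy_index):
        hits = make_hits([(0, 100)])
        with pytest.raises(ValueError, match="cluster_id"):
            category_occupancy(hits, toy_index, group_by="cluster")

    def test_sequence_filter_chromosomes_only(self):
        index = GenomeIndex("g", {"chr1": 100_000, "scaf1": 50_000})
        hits = make_hits([(0, 10_000)]) + make_hits([(0, 25_000)], seq="scaf1")
        full = category_occupancy(hits, index)
        chrom = category_occupancy(hits, index, sequences=["chr1"])
        assert full.total_repeat_proportion == pytest.approx(35_000 / 150_000)
        assert chrom.total_repeat_proportion == pytest.approx(0.10)

    def test_exclude_classes(self):
        index = GenomeIndex("g", {"chr1": 100_000})
        hits = make_hits([(0, 10_000)]) + make_hits(
            [(50_000, 60_000)], cls="Simple_repeat"
        )
        row = category_occupancy(hits, index, exclude_classes=["Simple_repeat"])
        assert "Simple_repeat" not in row.proportions
        assert row.total_repeat_proportion == pytest.approx(0.10)

    def test_zero_assembly_size_errors(self):
        with pytest.raises(ValueError):
            GenomeIndex("g", {"chr1": 0})


class TestRelativeFrequencies:
    def test_normalization(self):
        table = pd.DataFrame({"A": [30.0], "B": [10.0], "C": [20.0]}, index=["g1"])
        rel = relative_class_frequencies(table)
        assert rel.loc["g1"].tolist() == pytest.approx([0.5, 1 / 6, 1 / 3])

    def test_single_class_genome(self):
        table = pd.DataFrame({"A": [0.4, 0.0], "B": [0.0, 0.2]}, index=["g1", "g2"])
        rel = relative_class_frequencies(table)
        assert rel.loc["g1", "A"] == 1.0
        assert rel.loc["g2", "B"] == 1.0

    def test_row_sums_one_random(self, rng):
        table = pd.DataFrame(rng.uniform(0.001, 0.3, size=(6, 8)))
        rel = relative_class_frequencies(table)
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-12)


class TestWindowDensity:
    def test_full_and_empty_windows(self):
        index = GenomeIndex("g", {"chr1": 300})
        hits = make_hits([(0, 100)])
        track = window_density(hits, index, window_size=100)
        props = track.windows["proportion"].tolist()
        assert props == [1.0, 0.0, 0.0]

    def test_hit_split_across_windows(self):
        index = GenomeIndex("g", {"chr1": 200})
        track = window_density(make_hits([(50, 150)]), index, window_size=100)
        assert track.windows["proportion"].tolist() == [0.5, 0.5]

    def test_partial_window_true_length_denominator(self):
        index = GenomeIndex("g", {"chr1": 140_000})
        hits = make_hits([(100_000, 110_000)])
        track = window_density(hits, index, window_size=100_000)
        last = track.windows.iloc[-1]
        assert last["end"] - last["start"] == 40_000
        assert last["proportion"] == pytest.approx(0.25)

    def test_window_sums_conserve_totals(self, small_sim):
        track = window_density(small_sim.hits, small_sim.index, window_size=100_000)
        per_seq = track.windows.groupby("seq_id")["occupied_bp"].sum()
        from repeatscape.quantify import merge_hits_by_sequence

        merged = merge_hits_by_sequence(small_sim.hits)
        for seq, arr in merged.items():
            assert per_seq[seq] == int((arr[:, 1] - arr[:, 0]).sum())

    def test_category_filter(self, toy_hits, toy_index):
        track = window_density(toy_hits, toy_index, window_size=100_000,
                               category="DNA/TcMar-Tc1")
        chr2 = track.windows[track.windows.seq_id == "chr2"]
        assert chr2["occupied_bp"].sum() == 400


class TestOccupancyTable:
    def test_from_rows_aligns_categories(self, toy_hits, toy_index):
        r1 = category_occupancy(toy_hits, toy_index)
        r2 = category_occupancy(toy_hits[:2], GenomeIndex("g2", {"chr1": 200_000}))
        table = OccupancyTable.from_rows([r1, r2])
        assert table.proportions.loc["g2", "Unknown"] == 0.0
        assert (table.proportions.values >= 0).all()
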