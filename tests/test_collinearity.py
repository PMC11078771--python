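import itertools

import numpy as np
import pytest

from wgdkit import collinearity, ksdist, ratecorr, synthetic
from wgdkit.formats import GeneLocus
from wgdkit.synthetic import SegmentDuplication


def _matches(segments):
    return [(s.region_a, s.region_b, s.n_anchors) for s in segments]


class TestDetectSegments:
    def test_recovers_implanted_diagonal(self, small_genome, small_genome_pairs):
        segs = collinearity.detect_segments(
            small_genome.loci, small_genome.loci, small_genome_pairs, max_gap=3)
        true = {(s.region_a, s.region_b) for s in small_genome.true_segments}
        got = {(s.region_a, s.region_b) for s in segs}
        assert got == true
        # anchor-level precision: every detected anchor is an implanted one
        true_anchors = {frozenset(p) for s in small_genome.true_segments
                        for p in s.anchors}
        got_anchors = collinearity.anchor_pairs(segs)
        assert got_anchors == true_anchors

    def test_no_pairs_empty(self, small_genome):
        assert collinearity.detect_segments(small_genome.loci, small_genome.loci,
                                            [], max_gap=3) == []

    def test_antidiagonal_recovered(self):
        # inverted duplicated block: ranks ascending on A, descending on B
        loci = []
        for r in range(30):
            loci.append(GeneLocus(f"a{r}", "c1", r * 20000, r * 20000 + 1000, "+", r))
        pairs = [(f"a{r}", f"a{29 - r}") for r in range(8)]  # 0..7 vs 29..22
        segs = collinearity.detect_segments(loci, loci, pairs, max_gap=2,
                                            min_length_bp=10000)
        assert len(segs) == 1
        assert segs[0].n_anchors == 8

    def test_min_genes_threshold(self, small_genome, small_genome_pairs):
        segs = collinearity.detect_segments(
            small_genome.loci, small_genome.loci, small_genome_pairs,
            max_gap=3, min_genes=11)
        assert all(s.n_anchors >= 11 for s in segs)

    def test_min_length_filter_drops_short(self, small_genome, small_genome_pairs):
        segs = collinearity.detect_segments(
            small_genome.loci, small_genome.loci, small_genome_pairs,
            max_gap=3, min_length_bp=10**9)
        assert segs == []

    def test_anchor_containment(self, small_genome, small_genome_pairs):
        segs = collinearity.detect_segments(
            small_genome.loci, small_genome.loci, small_genome_pairs, max_gap=3)
        rank_of = {l.gene_id: (l.chromosome, l.rank) for l in small_genome.loci}
        for s in segs:
            for a, b in s.anchors:
                for g, region in ((a, s.region_a), (b, s.region_b)):
                    # anchors may sit on either side of an intra relation
                    c, r = rank_of[g]
                    in_a = (c == s.region_a[0] and
                            s.region_a[1] <= r <= s.region_a[2])
                    in_b = (c == s.region_b[0] and
                            s.region_b[1] <= r <= s.region_b[2])
                    assert in_a or in_b

    def test_invariance_to_relabel_and_translation(self, small_genome,
                                                   small_genome_pairs):
        base = collinearity.detect_segments(
            small_genome.loci, small_genome.loci, small_genome_pairs, max_gap=3)
        relabeled = [GeneLocus(l.gene_id, "X" + l.chromosome, l.start + 10**6,
                               l.end + 10**6, l.strand, l.rank)
                     for l in small_genome.loci]
        moved = collinearity.detect_segments(relabeled, relabeled,
                                             small_genome_pairs, max_gap=3)
        assert sorted(s.n_anchors for s in base) == sorted(s.n_anchors for s in moved)

    def test_background_noise_precision(self):
        genome = synthetic.build_genome(
            2, 100, [SegmentDuplication("chr1", 10, 15, copies=2, ks=0.8)], seed=9)
        pairs = [p for m in genome.true_families.values()
                 for p in itertools.combinations(sorted(m), 2)]
        rng = np.random.default_rng(9)
        genes = sorted(genome.cds)
        noise = [tuple(rng.choice(genes, 2, replace=False)) for _ in range(40)]
        segs = collinearity.detect_segments(genome.loci, genome.loci,
                                            pairs + noise, max_gap=3)
        true_anchors = {frozenset(p) for s in genome.true_segments for p in s.anchors}
        got = collinearity.anchor_pairs(segs)
        assert len(got & true_anchors) / len(got) >= 0.95
        assert true_anchors <= got  # full recall


class TestSyndepth:
    def test_two_copy_level(self, small_genome):
        two = [s for s in small_genome.true_segments if s.region_a[0] == "chr1"]
        assert collinearity.syndepth(two).counts == {2: 1}

    def test_three_copy_collapses_to_level3(self, small_genome):
        three = [s for s in small_genome.true_segments if s.region_a[0] == "chr2"]
        assert collinearity.syndepth(three).counts == {3: 1}

    def test_mixed_implants(self, small_genome):
        assert collinearity.syndepth(small_genome.true_segments).counts == {2: 1, 3: 1}


class TestDupstack:
    def test_single_segment_single_lane(self, small_genome):
        seg = small_genome.true_segments[0]
        table = collinearity.dupstack([seg], small_genome.loci)
        assert set(table["lane"]) == {0}
        assert len(table) == 2  # both regions project onto chr1

    def test_overlapping_segments_two_lanes(self):
        loci = [GeneLocus(f"g{r}", "c1", r * 1000, r * 1000 + 500, "+", r)
                for r in range(20)]
        seg1 = collinearity.CollinearSegment("s1", ("c1", 0, 5), ("c1", 10, 15),
                                             [("g0", "g10")])
        seg2 = collinearity.CollinearSegment("s2", ("c1", 2, 7), ("c1", 12, 17),
                                             [("g2", "g12")])
        table = collinearity.dupstack([seg1, seg2], loci)
        assert table["lane"].max() == 1

    def test_triplicate_rows(self, small_genome):
        three = [s for s in small_genome.true_segments if s.region_a[0] == "chr2"]
        table = collinearity.dupstack(three, small_genome.loci)
        # 3 pairwise segments x 2 projections each
        assert len(table) == 6


class TestDotplot:
    def test_single_pair(self):
        loci = [GeneLocus("g0", "c1", 0, 100, "+", 0),
                GeneLocus("g1", "c1", 200, 300, "+", 1)]
        table = collinearity.dotplot_table(loci, loci, [("g0", "g1")])
        assert list(table[["x", "y"]].iloc[0]) == [0, 1]

    def test_anchor_flag_and_ks(self):
        loci = [GeneLocus("g0", "c1", 0, 100, "+", 0),
                GeneLocus("g1", "c1", 200, 300, "+", 1)]
        table = collinearity.dotplot_table(
            loci, loci, [("g0", "g1")], anchor_set={frozenset(("g0", "g1"))},
            ks_lookup={("g0", "g1"): 0.7})
        assert bool(table["is_anchor"].iloc[0])
        assert table["ks"].iloc[0] == 0.7

    def test_anchor_dot_count_matches_segments(self, small_genome,
                                               small_genome_pairs):
        segs = collinearity.detect_segments(
            small_genome.loci, small_genome.loci, small_genome_pairs, max_gap=3)
        anchors = collinearity.anchor_pairs(segs)
        table = collinearity.dotplot_table(small_genome.loci, small_genome.loci,
                                           small_genome_pairs, anchor_set=anchors)
        assert int(table["is_anchor"].sum()) == sum(s.n_anchors for s in segs)


class TestAnchorKs:
    def test_two_copy_mode_near_truth(self, small_genome):
        segs = [s for s in small_genome.true_segments if s.region_a[0] == "chr1"]
        dist = collinearity.anchor_ks(segs, cds=small_genome.cds)
        assert len(dist) == segs[0].n_anchors
        mode = ratecorr.kde_mode(dist.values, weights=dist.weights)
        assert abs(mode - 1.0) <= 0.15

    def test_no_segments_empty(self):
        assert len(collinearity.anchor_ks([])) == 0

    def test_triplicate_all_relations_contribute(self, small_genome):
        segs = [s for s in small_genome.true_segments if s.region_a[0] == "chr2"]
        dist = collinearity.anchor_ks(segs, cds=small_genome.cds)
        n_anchor_pairs = len({frozenset(p) for s in segs for p in s.anchors})
        assert len(dist) == n_anchor_pairs
        # per-node weights still sum to 1
        sums = {}
        for ks, w, nid, _ in dist.entries:
            sums[nid] = sums.get(nid, 0.0) + w
        for s in sums.values():
            assert s == pytest.approx(1.0, abs=1e-9)


def test_segment_table_round_trip(tmp_path, small_genome, small_genome_pairs):
    segs = collinearity.detect_segments(
        small_genome.loci, small_genome.loci, small_genome_pairs, max_gap=3)
    path = tmp_path / "segments.tsv"
    collinearity.segments_to_table(segs).to_csv(path, sep="\t", index=False)
    back = collinearity.read_segments_table(path)
    assert _matches(back) == _matches(segs)
    assert [s.anchors for s in back] == [s.anchors for s in segs]
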