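"""Interval algebra, coordinate conventions, and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromduet.core import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Peak,
    merge_intervals,
    overlap_length,
    overlaps,
    read_bed,
    read_bedgraph,
    read_genes_tsv,
    tss_window,
    write_bed,
    write_bedgraph,
    write_genes_tsv,
)

from conftest import random_intervals


def bp_union(intervals, span=12_000):
    """Brute-force per-basepair union oracle."""
    grids = {}
    for iv in intervals:
        grids.setdefault(iv.chrom, np.zeros(span, dtype=bool))[iv.start : iv.end] = True
    out = []
    for chrom in sorted(grids):
        g = grids[chrom]
        edges = np.flatnonzero(np.diff(np.concatenate([[0], g.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


class TestGenomicInterval:
    @pytest.mark.parametrize("start,end", [(200, 100), (100, 100), (-5, 10)])
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_midpoint_floors(self):
        assert GenomicInterval("chr1", 10, 21).midpoint == 15


class TestOverlaps:
    def test_one_bp_overlap_and_half_open_abutment(self):
        a = GenomicInterval("chr1", 100, 200)
        assert overlaps(a, GenomicInterval("chr1", 199, 300))
        assert not overlaps(a, GenomicInterval("chr1", 200, 300))
        assert not overlaps(a, GenomicInterval("chr2", 100, 200))

    def test_symmetric_and_matches_arithmetic(self):
        rng = np.random.default_rng(0)
        ivs = random_intervals(rng, 2000)
        for a, b in zip(ivs[::2], ivs[1::2]):
            expected = max(0, min(a.end, b.end) - max(a.start, b.start)) if a.chrom == b.chrom else 0
            assert overlap_length(a, b) == expected == overlap_length(b, a)
            assert overlaps(a, b) == (expected >= 1) == overlaps(b, a)


class TestMergeIntervals:
    def test_examples(self):
        a = GenomicInterval("chr1", 100, 200)
        assert merge_intervals([a, GenomicInterval("chr1", 150, 250)]) == [
            GenomicInterval("chr1", 100, 250)
        ]
        # half-open abutment merges at min_gap=0
        assert merge_intervals([a, GenomicInterval("chr1", 200, 300)]) == [
            GenomicInterval("chr1", 100, 300)
        ]
        assert merge_intervals([a]) == [a]

    def test_matches_bp_sweep_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            ivs = random_intervals(rng, int(rng.integers(1, 30)))
            assert merge_intervals(ivs) == bp_union(ivs)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)), min_size=1, max_size=20
        )
    )
    def test_output_sorted_disjoint_and_union_preserving(self, raw):
        ivs = [GenomicInterval("chr1", s, s + l) for s, l in raw]
        merged = merge_intervals(ivs)
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start  # strictly disjoint, non-abutting
        assert sum(m.length for m in merged) == sum(m.length for m in bp_union(ivs))


class TestTssWindow:
    def test_plus_strand(self):
        g = GeneModel("g", "chr1", "+", 20_000, 40_000)
        assert tss_window(g, 15_000, 10_000) == GenomicInterval("chr1", 5_000, 30_000)

    def test_minus_strand_mirrors(self):
        g = GeneModel("g", "chr1", "-", 1_000, 20_001)  # tss = 20000
        assert tss_window(g, 15_000, 10_000) == GenomicInterval("chr1", 10_001, 35_001)

    def test_degenerate_window_contains_tss(self):
        for strand in "+-":
            g = GeneModel("g", "chr1", strand, 5_000, 6_000)
            w = tss_window(g, 0, 0)
            assert w.start <= g.tss < w.end and w.length == 1

    def test_clipped_at_origin(self):
        g = GeneModel("g", "chr1", "+", 1_000, 2_000)
        assert tss_window(g, 5_000, 1_000).start == 0


class TestBedIO:
    def test_round_trip(self, tmp_path):
        peaks = [
            Peak(GenomicInterval("chr1", 100, 200), auc=5.0, source="A"),
            Peak(GenomicInterval("chr2", 0, 50), auc=1.5, source="B"),
            Peak(GenomicInterval("chr2", 60, 61), auc=0.0),
        ]
        path = tmp_path / "x.bed"
        write_bed(peaks, path)
        back = read_bed(path)
        assert [(p.interval, p.auc, p.source) for p in back] == [
            (p.interval, p.auc, p.source) for p in peaks
        ]

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t200\nchr1\t50\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(path)

    def test_inverted_interval_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t200\t100\n")
        with pytest.raises(ValueError):
            read_bed(path)


class TestBedgraphIO:
    def test_adjacent_equal_runs_merge(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t0\t10\t1\nchr1\t10\t20\t1\n")
        track = read_bedgraph(path)
        s, e, v = track.runs("chr1")
        assert list(s) == [0] and list(e) == [20] and list(v) == [1.0]
        assert track.library_size == 20

    def test_library_size_is_mass(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t0\t10\t2\n")
        assert read_bedgraph(path).library_size == 20

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.bedgraph"
        path.write_text("")
        track = read_bedgraph(path)
        assert track.library_size == 0 and track.chroms == []

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "n.bedgraph"
        path.write_text("chr1\t0\t10\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            read_bedgraph(path)

    def test_overlapping_runs_rejected(self, tmp_path):
        path = tmp_path / "o.bedgraph"
        path.write_text("chr1\t0\t10\t1\nchr1\t5\t15\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            read_bedgraph(path)

    def test_round_trip_random_tracks(self, tmp_path):
        rng = np.random.default_rng(2)
        for i in range(10):
            # canonical form: sorted, gapped, positive, distinct neighbours
            pos = np.sort(rng.choice(np.arange(1, 500), 2 * 8, replace=False))
            starts, ends = pos[::2], pos[1::2]
            values = rng.integers(1, 9, 8).astype(float)
            track = CoverageTrack({"chr1": (starts, ends, values)})
            path = tmp_path / f"r{i}.bedgraph"
            write_bedgraph(track, path)
            back = read_bedgraph(path)
            s2, e2, v2 = back.runs("chr1")
            s1, e1, v1 = track.runs("chr1")
            assert (s1 == s2).all() and (e1 == e2).all() and (v1 == v2).all()

    def test_region_mass_and_binned_means(self):
        track = CoverageTrack(
            {"chr1": (np.array([100, 300]), np.array([200, 350]), np.array([2.0, 4.0]))}
        )
        assert track.region_mass(GenomicInterval("chr1", 0, 1000)) == 400
        assert track.region_mass(GenomicInterval("chr1", 150, 320)) == 2 * 50 + 4 * 20
        means = track.binned_means("chr1", 100, 400, 100)
        assert np.allclose(means, [2.0, 0.0, 4 * 50 / 100])


class TestGeneModelIO:
    def test_round_trip(self, tmp_path, toy_genes):
        path = tmp_path / "genes.tsv"
        write_genes_tsv(toy_genes, path)
        back = read_genes_tsv(path)
        assert [(g.gene_id, g.chrom, g.strand, g.tx_start, g.tx_end, g.exons) for g in back] == [
            (g.gene_id, g.chrom, g.strand, g.tx_start, g.tx_end, g.exons) for g in toy_genes
        ]

    def test_strand_derived_anchors(self):
        plus = GeneModel("p", "chr1", "+", 100, 501)
        minus = GeneModel("m", "chr1", "-", 100, 501)
        assert (plus.tss, plus.tts) == (100, 500)
        assert (minus.tss, minus.tts) == (500, 100)

    def test_exon_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneModel(
                "g",
                "chr1",
                "+",
                0,
                100,
                [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 40, 100)],
            )
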