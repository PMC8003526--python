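"""Genome tiling, segment/bin conversion, and text I/O."""

import math

import numpy as np
import pytest

from ctmtf.genome import (
    GAIN,
    LOSS,
    NEUTRAL,
    Segment,
    SegmentSet,
    build_genome_bins,
    call_for,
    load_default_chrom_sizes,
    rasterize,
    rasterize_calls,
    segments_from_states,
)
from ctmtf.io import ParseError, read_bin_table, read_segments, write_bin_table, write_segments


class TestTiling:
    def test_single_chromosome_with_short_terminal_bin(self):
        bins = build_genome_bins({"chr1": 3_500_000}, window=1_000_000)
        assert bins.n_bins == 4
        assert bins.lengths.tolist() == [1_000_000] * 3 + [500_000]

    def test_bundled_genome_bin_count_matches_size_table(self, genome):
        sizes = load_default_chrom_sizes()
        expected = sum(math.ceil(s / 1e6) for s in sizes.values())
        assert genome.n_bins == expected
        assert "chrY" not in genome.chrom_order
        assert "chrX" in genome.chrom_order

    def test_tiling_conserves_genome_length(self, genome):
        assert int(genome.lengths.sum()) == genome.genome_length

    @pytest.mark.parametrize("window", [0, -5])
    def test_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            build_genome_bins({"chr1": 1_000_000}, window=window)

    def test_empty_size_table_rejected(self):
        with pytest.raises(ValueError, match="no chromosomes"):
            build_genome_bins({}, window=1_000_000)


class TestRasterize:
    def test_empty_profile_is_all_reference(self, mini_genome):
        segs = SegmentSet("s", [], reference_ploidy=2.0)
        vec = rasterize(segs, mini_genome)
        assert (vec.values == 2).all()

    def test_midpoint_rule_on_exact_bin_span(self, mini_genome):
        # gain spanning bins 3-5 of chr1 exactly
        seg = Segment("chr1", 3_000_000, 6_000_000, 3, GAIN)
        vec = rasterize(SegmentSet("s", [seg]), mini_genome)
        chr1 = vec.values[mini_genome.chrom_slice("chr1")]
        assert chr1[2] == 2 and chr1[6] == 2
        assert (chr1[3:6] == 3).all()

    def test_unknown_chromosome_named_in_error(self, mini_genome):
        seg = Segment("chrZ", 0, 1_000_000, 3, GAIN)
        with pytest.raises(ValueError, match="chrZ"):
            rasterize(SegmentSet("s", [seg]), mini_genome)

    def test_rasterize_segment_roundtrip_is_idempotent(self, mini_genome, rng):
        """rasterize(segment(rasterize(S))) == rasterize(S) on random profiles."""
        for _ in range(100):
            n_segs = rng.integers(1, 6)
            segs = []
            used = {c: 0 for c in mini_genome.chrom_order}
            for _ in range(n_segs):
                chrom = str(rng.choice(mini_genome.chrom_order))
                size = mini_genome.chrom_sizes[chrom]
                if used[chrom] + 2_000_000 >= size:
                    continue
                start = int(rng.integers(used[chrom], size - 1_000_000))
                end = int(rng.integers(start + 500_000, size + 1))
                used[chrom] = end
                copy = int(rng.choice([0, 1, 3, 4, 5]))
                segs.append(Segment(chrom, start, end, copy, call_for(copy, 2)))
            segset = SegmentSet("s", segs)
            first = rasterize(segset, mini_genome)
            resegmented = segments_from_states(first.values, mini_genome, "s")
            second = rasterize(resegmented, mini_genome)
            np.testing.assert_array_equal(first.values, second.values)

    def test_call_track_signs(self, mini_genome):
        segs = SegmentSet(
            "s",
            [
                Segment("chr1", 0, 2_000_000, 1, LOSS),
                Segment("chr1", 5_000_000, 7_000_000, 5, GAIN),
            ],
        )
        calls = rasterize_calls(segs, mini_genome)
        sl = mini_genome.chrom_slice("chr1")
        assert calls[sl][0] == -1 and calls[sl][5] == 1 and calls[sl][3] == 0


class TestSegmentValidation:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SegmentSet(
                "s",
                [
                    Segment("chr1", 0, 2_000_000, 3, GAIN),
                    Segment("chr1", 1_000_000, 3_000_000, 1, LOSS),
                ],
            )

    @pytest.mark.parametrize(
        "start,end", [(5, 5), (10, 2), (-1, 5)], ids=["empty", "inverted", "negative"]
    )
    def test_bad_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            Segment("chr1", start, end, 2, NEUTRAL)

    def test_call_consistency_helper(self):
        assert call_for(3, 2.0) == GAIN
        assert call_for(1, 2.0) == LOSS
        assert call_for(4, 4.2) == NEUTRAL  # round(4.2) == 4


class TestIO:
    def test_segment_roundtrip_canonical(self, tmp_path):
        segset = SegmentSet(
            "s",
            [
                Segment("chr1", 0, 2_000_000, 3, GAIN),
                Segment("chr1", 4_000_000, 5_000_000, 1, LOSS),
                Segment("chr2", 0, 1_000_000, 2, NEUTRAL),
            ],
        )
        p = tmp_path / "segs.bed"
        write_segments(segset, p)
        text1 = p.read_text()
        back = read_segments(p, sample_id="s")
        write_segments(back, p)
        assert p.read_text() == text1
        assert back.segments == segset.segments

    def test_out_of_order_sorted_with_warning(self, tmp_path, caplog):
        p = tmp_path / "segs.bed"
        p.write_text(
            "chr2\t0\t1000000\t3\tgain\n"
            "chr1\t0\t1000000\t1\tloss\n"
        )
        with caplog.at_level("WARNING"):
            segset = read_segments(p)
        assert "out of order" in caplog.text
        assert [s.chrom for s in segset.segments] == ["chr1", "chr2"]

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t5\t5\t2\tneutral",        # start == end
            "chr1\t-3\t5\t2\tneutral",       # negative start
            "chr1\t0\t10\t2\twobble",        # unknown call
            "chr1\t0\t10\t2",                # wrong column count
        ],
    )
    def test_parse_errors_carry_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("# comment\n" + line + "\n")
        with pytest.raises(ParseError, match=r":2:"):
            read_segments(p)

    def test_bin_table_roundtrip_masks_missing_bins(self, tmp_path, mini_genome):
        from ctmtf.genome import BinVector

        values = np.arange(mini_genome.n_bins, dtype=float)
        mask = np.ones(mini_genome.n_bins, dtype=bool)
        mask[5] = False
        p = tmp_path / "t.tsv"
        write_bin_table(BinVector(mini_genome, values, mask), p)
        back = read_bin_table(p, mini_genome)
        assert not back.mask[5]
        np.testing.assert_array_equal(back.values[back.mask], values[mask])
        # second write is byte-identical
        q = tmp_path / "t2.tsv"
        write_bin_table(back, q)
        assert q.read_text() == p.read_text()

    def test_bin_table_rejects_misaligned_interval(self, tmp_path, mini_genome):
        p = tmp_path / "t.tsv"
        p.write_text("chr1\t500\t1000500\t3.0\n")
        with pytest.raises(ParseError, match="tiling"):
            read_bin_table(p, mini_genome)
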