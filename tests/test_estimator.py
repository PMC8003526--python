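"""TGF estimator, profile/CTM classification, and QC rules."""

import numpy as np
import pytest

from ctmtf.estimator import (
    CTM_ABERRANT,
    CTM_NORMAL,
    CTM_UNCLEAR,
    EstimatorConfig,
    classify_ctm,
    classify_profile,
    compute_eat,
    estimate_tgf,
    normalize_bins,
    qc_filter,
    uniform_reference,
)
from ctmtf.genome import (
    GAIN,
    LOSS,
    BinVector,
    Segment,
    SegmentSet,
    build_genome_bins,
)
from ctmtf.simulate import expected_bin_weights, simulate_mixture_counts


def noise_free_counts(profile, tf, genome, total=800_000.0):
    w = expected_bin_weights(profile, tf, genome)
    return BinVector(genome, w / w.sum() * total)


class TestNormalize:
    def test_identity_counts_give_zero_ratios(self, genome, reference):
        out = normalize_bins(reference.copy(), reference)
        assert np.allclose(out.values[out.mask], 0.0)

    def test_doubled_bin_is_one_log2_before_centering(self, mini_genome):
        ref = uniform_reference(mini_genome)
        counts = ref.copy()
        counts.values = counts.values.copy()
        counts.values[3] *= 2
        out = normalize_bins(counts, ref)
        deltas = out.values[out.mask] - np.median(out.values[out.mask])
        # relative spacing between the doubled bin and any untouched bin
        assert out.values[3] - out.values[4] == pytest.approx(1.0, abs=1e-9)

    def test_region_ratio_matches_closed_form(self, genome, cell_lines, reference):
        """Pure hyperdiploid sample: copy-4 region sits at log2(4/4.2)."""
        line = cell_lines[1]  # mean copy 4.2
        from ctmtf.genome import rasterize

        counts = noise_free_counts(line.profile, 1.0, genome)
        out = normalize_bins(counts, reference)
        states = rasterize(line.profile, genome).values
        sel = out.mask & (states == 4)
        # exact closed form uses the bin-rasterized mean copy of the profile
        raster_mean = np.average(states, weights=genome.lengths)
        centred_expected = np.log2(4 / raster_mean) - np.median(
            np.log2(states[out.mask] / raster_mean)
        )
        assert np.allclose(out.values[sel], centred_expected, atol=1e-9)
        # and sits near the nominal log2(4/4.2) = -0.070 before centering
        assert np.log2(4 / raster_mean) == pytest.approx(np.log2(4 / 4.2), abs=2e-3)

    def test_all_masked_is_error(self, mini_genome):
        ref = uniform_reference(mini_genome)
        zero = BinVector(mini_genome, np.zeros(mini_genome.n_bins))
        with pytest.raises(ValueError, match="no usable bins"):
            normalize_bins(zero, ref)


class TestEstimateTGF:
    def test_pure_normal_is_exactly_zero(self, genome, cell_lines, reference):
        cfg = EstimatorConfig().fixed_ploidy(cell_lines[0].target_mean_copy)
        counts = noise_free_counts(cell_lines[0].profile, 0.0, genome)
        res = estimate_tgf(normalize_bins(counts, reference), cfg)
        assert res.tgf == 0.0
        assert res.profile_class == "normal"

    @pytest.mark.parametrize("line_idx", [0, 1])
    def test_noise_free_recovery_spot_checks(self, genome, cell_lines, reference, line_idx):
        line = cell_lines[line_idx]
        cfg = EstimatorConfig().fixed_ploidy(line.target_mean_copy)
        for tf in (0.4, 1.0):
            counts = noise_free_counts(line.profile, tf, genome)
            res = estimate_tgf(normalize_bins(counts, reference), cfg)
            assert abs(res.tgf - tf) <= 0.05

    def test_sampled_counts_within_band(self, genome, cell_lines, reference):
        """Multinomial counts at 800k reads, tf=0.6: estimate lands in [0.45, 0.75]."""
        line = cell_lines[1]
        cfg = EstimatorConfig().fixed_ploidy(line.target_mean_copy)
        hits = 0
        for seed in range(20):
            counts = simulate_mixture_counts(line, 0.6, 800_000, 1000 + seed, genome)
            res = estimate_tgf(normalize_bins(counts, reference), cfg)
            hits += 0.45 <= res.tgf <= 0.75
        assert hits >= 18

    def test_never_positive_tgf_with_neutral_path(self, genome, reference, rng):
        """Flat noisy profiles give TGF 0 with an all-neutral segmentation."""
        flat = SegmentSet("flat", [], reference_ploidy=2.0)
        for seed in (1, 2, 3):
            counts = simulate_mixture_counts(flat, 0.0, 600_000, seed, genome)
            res = estimate_tgf(normalize_bins(counts, reference), EstimatorConfig())
            altered = [s for s in res.segments.segments if s.call != "neutral"]
            if not altered:
                assert res.tgf == 0.0
            else:
                assert res.tgf > 0.0

    def test_profile_too_short_error(self):
        tiny = build_genome_bins({"chr1": 50_000_000}, window=1_000_000)
        ref = uniform_reference(tiny)
        with pytest.raises(ValueError, match="profile too short"):
            estimate_tgf(normalize_bins(ref.copy(), ref), EstimatorConfig())

    def test_coverage_and_qc_fields(self, genome, cell_lines, reference):
        cfg = EstimatorConfig().fixed_ploidy(2.65)
        counts = noise_free_counts(cell_lines[0].profile, 0.5, genome)
        res = estimate_tgf(normalize_bins(counts, reference), cfg, aligned_reads=800_000)
        assert res.coverage == pytest.approx(800_000 * 150 / genome.genome_length)
        assert res.qc_pass


def _mb_segments(spec):
    """[(chrom, start_mb, len_mb, copy)] -> SegmentSet."""
    segs = [
        Segment(c, int(s * 1e6), int((s + l) * 1e6), cp, GAIN if cp > 2 else LOSS)
        for c, s, l, cp in spec
    ]
    return SegmentSet("s", segs)


class TestClassifyProfile:
    def test_no_alterations_is_normal(self, genome):
        assert classify_profile(SegmentSet("s", []), genome) == "normal"

    def test_single_small_region_is_unclear(self, genome):
        segs = _mb_segments([("chr1", 10, 100, 4)])
        assert classify_profile(segs, genome) == "unclear"

    def test_single_region_at_threshold_is_aberrant(self, genome):
        assert classify_profile(_mb_segments([("chr1", 10, 125, 4)]), genome) == "aberrant"
        assert classify_profile(_mb_segments([("chr1", 10, 124, 4)]), genome) == "unclear"

    def test_multi_region_sum_rule(self, genome):
        below = _mb_segments(
            [("chr1", 0, 150, 4), ("chr2", 0, 150, 1), ("chr3", 0, 74, 4)]
        )
        assert classify_profile(below, genome) == "unclear"
        at = _mb_segments(
            [("chr1", 0, 150, 4), ("chr2", 0, 150, 1), ("chr3", 0, 100, 4)]
        )
        assert classify_profile(at, genome) == "aberrant"

    def test_chr19_excluded(self, genome):
        chr19_only = _mb_segments([("chr19", 0, 50, 1)])
        assert classify_profile(chr19_only, genome) == "normal"

    def test_invariant_to_order_and_splitting(self, genome):
        whole = _mb_segments([("chr1", 10, 100, 4), ("chr2", 5, 60, 1)])
        split = _mb_segments(
            [("chr2", 5, 60, 1), ("chr1", 10, 50, 4), ("chr1", 60, 50, 4)]
        )
        assert classify_profile(whole, genome) == classify_profile(split, genome)

    def test_adjacent_gain_loss_merge_into_one_region(self, genome):
        # 60 Mb gain directly followed by 60 Mb loss: one 120 Mb region
        mixed = _mb_segments([("chr1", 0, 60, 4), ("chr1", 60, 60, 1)])
        assert classify_profile(mixed, genome) == "unclear"


class TestClassifyCTM:
    @pytest.mark.parametrize(
        "tgf,profile,expected",
        [
            (0.0, "normal", CTM_NORMAL),
            (0.0, "aberrant", CTM_NORMAL),
            (0.03, "aberrant", CTM_NORMAL),
            (0.05, "aberrant", CTM_NORMAL),   # boundary inclusive
            (0.05, "unclear", CTM_NORMAL),
            (0.050001, "aberrant", CTM_ABERRANT),
            (0.30, "aberrant", CTM_ABERRANT),
            (1.0, "aberrant", CTM_ABERRANT),
            (0.30, "unclear", CTM_UNCLEAR),
            (0.30, "normal", CTM_NORMAL),
        ],
    )
    def test_truth_table(self, tgf, profile, expected):
        assert classify_ctm(tgf, profile) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_ctm(1.2, "aberrant")


class TestQC:
    def test_read_threshold_boundary(self):
        assert not qc_filter(399_999)
        assert qc_filter(400_000)
        with pytest.raises(ValueError):
            qc_filter(-1)

    @pytest.mark.parametrize(
        "qc,di,n,eat,passes",
        [(0.5, 1.0, 100, 50.0, True), (0.2, 1.0, 100, 20.0, False),
         (0.3, 1.0, 100, 30.0, True)],
    )
    def test_eat_product_and_threshold(self, qc, di, n, eat, passes):
        res = compute_eat(qc, di, n)
        assert res.eat == pytest.approx(eat)
        assert res.passes is passes

    def test_negative_eat_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_eat(-0.1, 1.0, 10)
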