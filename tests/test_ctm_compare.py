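"""Shared/private CNA calculus, alteration frequencies, clustering."""

import numpy as np
import pytest

from ctmtf.ctm_compare import (
    LABEL_CTM_PRIVATE,
    LABEL_SHARED,
    LABEL_TUMOR_PRIVATE,
    LABEL_UNALTERED,
    PatientProfileSet,
    alteration_frequency,
    correlation_cluster,
    recurrent_ctm_private,
    shared_private_regions,
)
from ctmtf.genome import (
    GAIN,
    LOSS,
    BinVector,
    Segment,
    SegmentSet,
    build_genome_bins,
    rasterize_calls,
    segments_from_states,
)

# a tiny genome without chr19 complications for the toy cases
TOY = build_genome_bins({"chr1": 3_000_000}, window=1_000_000)


def _toy_segset(name, states):
    return segments_from_states(np.asarray(states), TOY, name, reference_ploidy=2.0)


class TestSharedPrivateToy:
    def test_three_bin_example(self):
        """Tumors gain bin1; CTM-A gains bins1-2; CTM-B gains bin2."""
        tumors = _toy_segset("t", [3, 2, 2])
        ctm_a = _toy_segset("a", [3, 3, 2])
        ctm_b = _toy_segset("b", [2, 3, 2])
        rep = shared_private_regions(
            PatientProfileSet("p", tumors, tumors, [ctm_a, ctm_b]),
            TOY, exclude_chroms=(),
        )
        assert rep.shared_frac == pytest.approx(1 / 3)
        assert rep.private_ctm_frac == pytest.approx(1 / 3)
        assert rep.private_tumor_frac == 0.0

    def test_identical_ctms_give_zero_private(self):
        tumors = _toy_segset("t", [3, 1, 2])
        rep = shared_private_regions(
            PatientProfileSet("p", tumors, tumors, [_toy_segset("c", [3, 1, 2])]),
            TOY, exclude_chroms=(),
        )
        assert rep.shared_frac == pytest.approx(2 / 3)
        assert rep.private_ctm_frac == 0.0 and rep.private_tumor_frac == 0.0

    def test_type_mismatch_is_tumor_private(self):
        """Tumor gain vs CTM loss at the same bin: not shared."""
        tumors = _toy_segset("t", [3, 2, 2])
        ctm = _toy_segset("c", [1, 2, 2])
        rep = shared_private_regions(
            PatientProfileSet("p", tumors, tumors, [ctm]), TOY, exclude_chroms=()
        )
        assert rep.labels[0] == LABEL_TUMOR_PRIVATE
        assert rep.private_tumor_frac == pytest.approx(1 / 3)
        assert rep.private_ctm_frac == 0.0

    def test_tumor_disagreement_goes_to_ctm_private(self):
        """T1 neutral where T2 gains: no consensus, CTM alteration is private."""
        t1 = _toy_segset("t1", [2, 2, 2])
        t2 = _toy_segset("t2", [3, 2, 2])
        ctm = _toy_segset("c", [3, 2, 2])
        rep = shared_private_regions(
            PatientProfileSet("p", t2, t1, [ctm]), TOY, exclude_chroms=()
        )
        assert rep.labels[0] == LABEL_CTM_PRIVATE

    def test_single_tumor_mode(self):
        t2 = _toy_segset("t2", [3, 2, 2])
        rep = shared_private_regions(
            PatientProfileSet("p", t2, None, [_toy_segset("c", [3, 2, 2])]),
            TOY, exclude_chroms=(),
        )
        assert rep.shared_frac == pytest.approx(1 / 3)

    def test_needs_a_ctm(self):
        with pytest.raises(ValueError):
            PatientProfileSet("p", _toy_segset("t", [2, 2, 2]), None, [])


def _random_patient(rng, genome):
    def random_track():
        states = np.full(genome.n_bins, 2)
        for _ in range(rng.integers(0, 6)):
            a = int(rng.integers(0, genome.n_bins - 1))
            b = int(rng.integers(a + 1, min(a + 30, genome.n_bins) + 1))
            states[a:b] = int(rng.choice([0, 1, 3, 4, 5]))
        return states

    t2 = random_track()
    t1 = t2.copy()
    if rng.uniform() < 0.5:  # partial disagreement
        a = int(rng.integers(0, genome.n_bins - 5))
        t1[a : a + 5] = 2
    n_ctms = int(rng.integers(1, 5))
    ctms = [random_track() for _ in range(n_ctms)]
    return t1, t2, ctms


def _oracle_labels(t1, t2, ctms, analyzable):
    labels = np.full(t1.size, -1)
    s1, s2 = np.sign(t1 - 2), np.sign(t2 - 2)
    cs = [np.sign(c - 2) for c in ctms]
    for i in range(t1.size):
        if not analyzable[i]:
            continue
        tumor = s1[i] if s1[i] == s2[i] else 0
        if tumor != 0:
            labels[i] = LABEL_SHARED if any(c[i] == tumor for c in cs) else LABEL_TUMOR_PRIVATE
        elif any(c[i] != 0 for c in cs):
            labels[i] = LABEL_CTM_PRIVATE
        else:
            labels[i] = LABEL_UNALTERED
    return labels


class TestSharedPrivateOracle:
    def test_matches_brute_force_on_random_instances(self, rng):
        genome = build_genome_bins(
            {"chr1": 120_000_000, "chr2": 90_000_000, "chr19": 50_000_000},
            window=1_000_000,
        )
        analyzable = ~genome.chrom_mask(["chr19"])
        for _ in range(100):
            t1s, t2s, ctm_states = _random_patient(rng, genome)
            pps = PatientProfileSet(
                "p",
                segments_from_states(t2s, genome, "t2"),
                segments_from_states(t1s, genome, "t1"),
                [segments_from_states(c, genome, f"c{i}") for i, c in enumerate(ctm_states)],
            )
            rep = shared_private_regions(pps, genome)
            expected = _oracle_labels(t1s, t2s, ctm_states, analyzable)
            np.testing.assert_array_equal(rep.labels, expected)
            # fractions partition the analyzable territory
            lengths = genome.lengths
            total = lengths[analyzable].sum()
            unalt = lengths[rep.labels == LABEL_UNALTERED].sum() / total
            assert (
                rep.shared_frac + rep.private_ctm_frac + rep.private_tumor_frac + unalt
                == pytest.approx(1.0)
            )

    def test_removing_a_ctm_never_increases_shared(self, rng):
        genome = build_genome_bins({"chr1": 100_000_000}, window=1_000_000)
        for _ in range(20):
            t1s, t2s, ctm_states = _random_patient(rng, genome)
            if len(ctm_states) < 2:
                continue
            def shared(states_list):
                pps = PatientProfileSet(
                    "p",
                    segments_from_states(t2s, genome, "t2"),
                    segments_from_states(t1s, genome, "t1"),
                    [segments_from_states(c, genome, f"c{i}") for i, c in enumerate(states_list)],
                )
                return shared_private_regions(pps, genome, exclude_chroms=()).shared_frac

            assert shared(ctm_states[:-1]) <= shared(ctm_states) + 1e-12


class TestAlterationFrequency:
    def test_unanimous_gain_flagged(self):
        samples = [_toy_segset(f"s{i}", [3, 2, 2]) for i in range(4)]
        ft = alteration_frequency(samples, TOY, threshold=0.7, exclude_chroms=())
        assert ft.gain_frac[0] == 1.0
        assert len(ft.regions) == 1
        assert ft.regions.iloc[0]["type"] == "gain"

    def test_minority_not_flagged(self):
        samples = [_toy_segset("a", [3, 2, 2]), _toy_segset("b", [3, 2, 2])] + [
            _toy_segset(f"n{i}", [2, 2, 2]) for i in range(3)
        ]
        ft = alteration_frequency(samples, TOY, threshold=0.5, exclude_chroms=())
        assert ft.gain_frac[0] == pytest.approx(0.4)
        assert ft.regions.empty

    def test_matches_counting_oracle(self, rng):
        genome = build_genome_bins({"chr1": 50_000_000}, window=1_000_000)
        tracks = [
            np.where(rng.uniform(size=genome.n_bins) < 0.3,
                     rng.choice([1, 3], size=genome.n_bins), 2)
            for _ in range(6)
        ]
        samples = [segments_from_states(t, genome, f"s{i}") for i, t in enumerate(tracks)]
        ft = alteration_frequency(samples, genome, exclude_chroms=())
        arr = np.stack(tracks)
        np.testing.assert_allclose(ft.gain_frac, (arr > 2).mean(axis=0))
        np.testing.assert_allclose(ft.loss_frac, (arr < 2).mean(axis=0))


class TestRecurrentScreen:
    def _reports(self, shared_bin=None):
        """Two patients with no tumor alterations except optionally one shared bin."""
        genome = TOY
        reports = []
        for p in range(2):
            if shared_bin is not None and p == 0:
                t = _toy_segset("t", [3, 2, 2])
                c = _toy_segset("c", [3, 2, 2])
            else:
                t = _toy_segset("t", [2, 2, 2])
                c = _toy_segset("c", [2, 2, 2])
            reports.append(
                shared_private_regions(
                    PatientProfileSet(f"p{p}", t, t, [c]), genome, exclude_chroms=()
                )
            )
        return reports

    def test_shared_in_one_patient_excluded(self):
        reports = self._reports(shared_bin=0)
        # every CTM altered at bin 0, but patient 0 saw it shared with tissue
        ctms = [_toy_segset(f"c{i}", [3, 2, 2]) for i in range(4)]
        ft = recurrent_ctm_private(reports, ctms, TOY, exclude_chroms=())
        assert ft.regions.empty

    def test_54_percent_excluded_60_reported(self):
        reports = self._reports()
        below = [_toy_segset(f"c{i}", [3, 2, 2]) for i in range(54)] + [
            _toy_segset(f"d{i}", [2, 2, 2]) for i in range(46)
        ]
        assert recurrent_ctm_private(reports, below, TOY, exclude_chroms=()).regions.empty
        above = [_toy_segset(f"c{i}", [3, 2, 2]) for i in range(60)] + [
            _toy_segset(f"d{i}", [2, 2, 2]) for i in range(40)
        ]
        regions = recurrent_ctm_private(reports, above, TOY, exclude_chroms=()).regions
        assert len(regions) == 1
        assert regions.iloc[0]["frequency"] == pytest.approx(0.6)


class TestCorrelationClustering:
    def _vectors(self, genome, rows):
        return {k: BinVector(genome, np.asarray(v, float)) for k, v in rows.items()}

    def test_duplicate_samples_merge_at_zero(self):
        genome = build_genome_bins({"chr1": 6_000_000}, window=1_000_000)
        base = [0.1, -0.2, 0.3, 0.0, -0.1, 0.2]
        cc = correlation_cluster(
            self._vectors(genome, {"a": base, "b": base, "c": [-x for x in base]})
        )
        assert cc.correlation[0, 1] == pytest.approx(1.0)
        assert cc.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_profiles_near_zero_correlation(self, rng):
        genome = build_genome_bins({"chr1": 40_000_000}, window=1_000_000)
        x = np.tile([1.0, -1.0], 20)
        y = np.tile([1.0, 1.0, -1.0, -1.0], 10)
        cc = correlation_cluster(self._vectors(genome, {"a": x, "b": y}))
        expected = np.corrcoef(x, y)[0, 1]
        assert cc.correlation[0, 1] == pytest.approx(expected, abs=1e-12)
        assert abs(cc.correlation[0, 1]) < 1e-9

    def test_permutation_invariant_merge_heights(self, rng):
        genome = build_genome_bins({"chr1": 30_000_000}, window=1_000_000)
        data = {f"s{i}": rng.normal(size=genome.n_bins) for i in range(5)}
        cc1 = correlation_cluster(self._vectors(genome, data))
        shuffled = dict(reversed(list(data.items())))
        cc2 = correlation_cluster(self._vectors(genome, shuffled))
        np.testing.assert_allclose(
            np.sort(cc1.linkage_matrix[:, 2]), np.sort(cc2.linkage_matrix[:, 2])
        )

    def test_constant_profile_dropped_with_warning(self):
        genome = build_genome_bins({"chr1": 5_000_000}, window=1_000_000)
        vecs = self._vectors(
            genome,
            {"a": [1, 2, 3, 4, 5], "b": [2, 1, 4, 3, 5], "flat": [1, 1, 1, 1, 1]},
        )
        with pytest.warns(UserWarning, match="flat"):
            cc = correlation_cluster(vecs)
        assert cc.sample_ids == ["a", "b"]
        assert cc.dropped == ["flat"]
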