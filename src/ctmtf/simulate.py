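"""Synthetic low-pass WGS read-count data with known truth.

Two kinds of datasets are generated, both mirroring a cell-mixture
calibration experiment and a small clinical cohort:

* **Titration sets** — mixtures of an aberrant cell-line genome with diploid
  cells at known tumor fractions (0, 0.1, ..., 0.8, 1.0; three replicates),
  for two virtual cell lines with length-weighted mean copy numbers 2.65
  (mildly hyperdiploid) and 4.2 (strongly hyperdiploid).
* **Patient scenarios** — per patient: two pure tumor fractions sharing most
  alterations (a pseudodiploid/hyperdiploid pair), one stromal sample with a
  flat genome, and a set of CTMs, each mixing a tumor-derived profile (a
  subset of the tumor's alterations plus private ones) with normal cells at
  a tumor fraction drawn from 0.08-0.48.

Read counts are drawn from a single multinomial over bins with per-bin
weight proportional to ``bin_length * (tf * tumor_copy + (1 - tf) * 2)``,
which conserves the requested total read count exactly.  Optional
Dirichlet-multinomial overdispersion and an optional chr19 deflation factor
(to exercise the chr19-exclusion rule downstream) are off by default.
Everything is deterministic given the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    BinVector,
    GenomeBins,
    Segment,
    SegmentSet,
    build_genome_bins,
    call_for,
    rasterize,
    rasterize_calls,
)

# Printed aligned-read regime of the emulated experiment (min, max); samples
# draw totals log-uniformly from this range.
DEFAULT_READS_RANGE = (415_519, 1_955_726)
DEFAULT_TF_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0)
MAX_EVENT_COPY = 7


def _child_seed(master_seed: int, *path: int) -> int:
    """Deterministic per-sample integer seed derived from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, path)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class CellLineSpec:
    """A virtual aneuploid cell line: a fixed segmental copy-number profile."""

    name: str
    target_mean_copy: float
    profile: SegmentSet


@dataclass
class TitrationSample:
    cell_line: str
    true_tf: float
    replicate: int
    total_reads: int
    seed: int
    counts: BinVector

    @property
    def sample_id(self) -> str:
        return f"{self.cell_line}_tf{self.true_tf:.1f}_r{self.replicate}"


# ---------------------------------------------------------------------------
# event placement


def _place_events(
    rng: np.random.Generator,
    free: list[tuple[str, int, int]],
    n_events: int,
    length_range: tuple[int, int],
) -> list[tuple[str, int, int]]:
    """Place ``n_events`` non-overlapping intervals inside the free space."""
    lmin, lmax = int(length_range[0]), int(length_range[1])
    free = list(free)
    placed: list[tuple[str, int, int]] = []
    for _ in range(n_events):
        want = int(rng.integers(lmin, lmax + 1))
        fits = [iv for iv in free if iv[2] - iv[1] >= want]
        if not fits:
            longest = max((iv[2] - iv[1] for iv in free), default=0)
            if longest < lmin:
                raise ValueError(
                    "not enough free genomic territory to place events; "
                    "reduce n_events or event lengths"
                )
            want = longest
            fits = [iv for iv in free if iv[2] - iv[1] >= want]
        weights = np.array([iv[2] - iv[1] for iv in fits], dtype=float)
        iv = fits[rng.choice(len(fits), p=weights / weights.sum())]
        chrom, lo, hi = iv
        start = int(rng.integers(lo, hi - want + 1))
        placed.append((chrom, start, start + want))
        free.remove(iv)
        if start - lo > 0:
            free.append((chrom, lo, start))
        if hi - (start + want) > 0:
            free.append((chrom, start + want, hi))
    return placed


def make_cell_line_profile(
    seed: int,
    target_mean_copy: float,
    n_events: int = 18,
    event_length_range: tuple[int, int] = (30_000_000, 120_000_000),
    genome: GenomeBins | None = None,
    name: str = "cellline",
) -> CellLineSpec:
    """Draw a random segmental profile with a prescribed mean copy number.

    Gains and losses are placed collision-free; event copy levels are then
    raised (or lowered) stepwise and one event's length fine-tuned so the
    length-weighted mean copy over the genome hits ``target_mean_copy``
    exactly (to within bp rounding).  At least one gain and one loss are
    always present when ``n_events >= 2``.
    """
    if not (1.5 <= target_mean_copy <= 6.0):
        raise ValueError("target_mean_copy must be in [1.5, 6]")
    if genome is None:
        genome = build_genome_bins()
    rng = np.random.default_rng(seed)
    if n_events == 0:
        if abs(target_mean_copy - 2.0) > 1e-12:
            raise ValueError("empty profile only attainable for target 2.0")
        return CellLineSpec(name, 2.0, SegmentSet(name, [], reference_ploidy=2.0))
    if n_events < 2:
        raise ValueError("n_events must be >= 2 (or 0 for a flat profile)")

    free = [(c, 0, genome.chrom_sizes[c]) for c in genome.chrom_order]
    placed = _place_events(rng, free, n_events, event_length_range)
    rng.shuffle(placed)

    # one event of the minority direction, the rest in the majority direction
    gaining = target_mean_copy >= 2.0
    copies = [3 if gaining else 1] * len(placed)
    copies[int(rng.integers(len(placed)))] = 1 if gaining else 3

    G = genome.genome_length
    target_excess = (target_mean_copy - 2.0) * G

    def excess() -> float:
        return sum((e - s) * (c - 2) for (ch, s, e), c in zip(placed, copies))

    # raise/lower copy levels until the target is overshot
    guard = 0
    while (excess() < target_excess) if gaining else (excess() > target_excess):
        adjustable = [
            i
            for i, c in enumerate(copies)
            if ((2 < c < MAX_EVENT_COPY) if gaining else (0 < c < 2))
        ]
        if not adjustable:
            raise ValueError(
                f"target mean copy {target_mean_copy} infeasible with "
                f"n_events={n_events}; increase n_events or event lengths"
            )
        i = adjustable[int(rng.integers(len(adjustable)))]
        copies[i] += 1 if gaining else -1
        guard += 1
        if guard > 100_000:  # pragma: no cover
            raise RuntimeError("copy adjustment did not terminate")

    # shrink same-direction events until the excess matches exactly
    over = excess() - target_excess
    for i in sorted(range(len(placed)), key=lambda k: -(placed[k][2] - placed[k][1])):
        if abs(over) < 1:
            break
        c = copies[i]
        if (c - 2 > 0) != (over > 0) or c == 2:
            continue
        chrom, s, e = placed[i]
        shrink = min(e - s - 1, int(round(over / (c - 2))))
        if shrink <= 0:
            continue
        placed[i] = (chrom, s, e - shrink)
        over -= shrink * (c - 2)

    segs = [
        Segment(ch, s, e, c, call_for(c, 2.0))
        for (ch, s, e), c in zip(placed, copies)
    ]
    profile = SegmentSet(name, segs, reference_ploidy=2.0)
    spec = CellLineSpec(name, target_mean_copy, profile)
    achieved = profile.mean_copy(genome)
    if abs(achieved - target_mean_copy) > 0.05:
        raise ValueError(
            f"could not reach mean copy {target_mean_copy} (got {achieved:.3f}); "
            f"increase n_events"
        )
    has_gain = any(s.call == "gain" for s in segs)
    has_loss = any(s.call == "loss" for s in segs)
    if not (has_gain and has_loss):  # pragma: no cover - construction guarantees
        raise ValueError("profile lacks a gain or a loss")
    return spec


def default_cell_lines(genome: GenomeBins | None = None) -> list[CellLineSpec]:
    """The two virtual lines of the titration design (mean copy 2.65 and 4.2).

    Profiles are drawn once from fixed seeds so every titration set uses the
    same pair of genomes, as a real cell-line experiment would.
    """
    if genome is None:
        genome = build_genome_bins()
    mild = make_cell_line_profile(
        seed=20361,
        target_mean_copy=2.65,
        n_events=18,
        event_length_range=(30_000_000, 120_000_000),
        genome=genome,
        name="LINE361",
    )
    high = make_cell_line_profile(
        seed=20453,
        target_mean_copy=4.2,
        n_events=26,
        event_length_range=(50_000_000, 150_000_000),
        genome=genome,
        name="LINE453",
    )
    return [mild, high]


# ---------------------------------------------------------------------------
# read-count simulation


def expected_bin_weights(
    profile: SegmentSet,
    true_tf: float,
    genome: GenomeBins,
    chr19_deflation: float | None = None,
) -> np.ndarray:
    """Unnormalised expected read weight per bin for a tumor/normal mixture."""
    tumor_copy = rasterize(profile, genome).values.astype(float)
    mixture_copy = true_tf * tumor_copy + (1.0 - true_tf) * 2.0
    w = genome.lengths.astype(float) * mixture_copy
    if chr19_deflation is not None:
        w = w * np.where(genome.chrom_mask(["chr19"]), float(chr19_deflation), 1.0)
    return w


def simulate_mixture_counts(
    profile: CellLineSpec | SegmentSet,
    true_tf: float,
    total_reads: int,
    seed: int | np.random.Generator,
    genome: GenomeBins | None = None,
    chr19_deflation: float | None = None,
    overdispersion: float | None = None,
) -> BinVector:
    """Multinomial read counts over bins for a tumor/normal mixture.

    ``overdispersion`` (a Dirichlet concentration; larger = closer to plain
    multinomial) adds extra-multinomial noise when set.
    """
    if not 0.0 <= true_tf <= 1.0:
        raise ValueError("true_tf must be in [0, 1]")
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if genome is None:
        genome = build_genome_bins()
    segset = profile.profile if isinstance(profile, CellLineSpec) else profile
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    w = expected_bin_weights(segset, true_tf, genome, chr19_deflation)
    p = w / w.sum()
    if overdispersion is not None:
        alpha = np.clip(p * float(overdispersion), 1e-12, None)
        p = rng.dirichlet(alpha)
    counts = rng.multinomial(int(total_reads), p)
    return BinVector(genome, counts.astype(np.int64))


def _draw_total_reads(rng: np.random.Generator, reads_range: tuple[int, int]) -> int:
    lo, hi = reads_range
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def generate_titration_set(
    master_seed: int,
    cell_lines: list[CellLineSpec] | None = None,
    tf_grid: tuple[float, ...] = DEFAULT_TF_GRID,
    replicates: int = 3,
    reads_range: tuple[int, int] = DEFAULT_READS_RANGE,
    genome: GenomeBins | None = None,
    overdispersion: float | None = None,
) -> tuple[list[TitrationSample], pd.DataFrame]:
    """One sample per (cell line x tumor fraction x replicate), with truth.

    Returns the samples and a truth table (``sample_id, cell_line, role,
    true_tf, replicate, total_reads, seed``).  Fully deterministic in
    ``master_seed``; each sample has its own derived seed so replicates
    differ.
    """
    if not tf_grid:
        raise ValueError("tf_grid must not be empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if genome is None:
        genome = build_genome_bins()
    if cell_lines is None:
        cell_lines = default_cell_lines(genome)
    samples: list[TitrationSample] = []
    rows = []
    for li, line in enumerate(cell_lines):
        for ti, tf in enumerate(tf_grid):
            for rep in range(1, replicates + 1):
                seed = _child_seed(master_seed, li, ti, rep)
                rng = np.random.default_rng(seed)
                total = _draw_total_reads(rng, reads_range)
                counts = simulate_mixture_counts(
                    line, tf, total, rng, genome, overdispersion=overdispersion
                )
                s = TitrationSample(line.name, float(tf), rep, total, seed, counts)
                samples.append(s)
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "cell_line": line.name,
                        "role": "titration",
                        "true_tf": float(tf),
                        "replicate": rep,
                        "total_reads": total,
                        "seed": seed,
                    }
                )
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# patient scenarios


@dataclass
class CTMTruth:
    ctm_id: str
    true_tf: float
    shared_event_ids: list[int]        # indices into the T2 event list
    private_segments: list[Segment]
    profile: SegmentSet


@dataclass
class PatientScenario:
    patient_id: str
    tumor_t1: SegmentSet
    tumor_t2: SegmentSet
    stroma: SegmentSet
    ctms: list[CTMTruth]
    counts: dict[str, BinVector]
    truth: pd.DataFrame
    # per-bin truth labels over analyzable territory:
    # 0 unaltered, 1 shared, 2 tumor_private, 3 ctm_private, -1 excluded
    truth_labels: np.ndarray = field(repr=False)


TRUTH_UNALTERED, TRUTH_SHARED, TRUTH_TUMOR_PRIVATE, TRUTH_CTM_PRIVATE = 0, 1, 2, 3
DEFAULT_HOTSPOT = ("chr2", 60_000_000, 80_000_000)


def _truth_label_track(
    tumor_tracks: list[np.ndarray],
    ctm_tracks: list[np.ndarray],
    analyzable: np.ndarray,
) -> np.ndarray:
    """Brute-force per-bin shared/private labelling (the generator's truth).

    Tumor consensus requires every available tumor sample to agree on the
    alteration type; a bin is shared when the consensus alteration type is
    carried by at least one CTM.
    """
    n = analyzable.size
    labels = np.full(n, -1, dtype=np.int8)
    for i in range(n):
        if not analyzable[i]:
            continue
        tcalls = {int(t[i]) for t in tumor_tracks}
        tumor_call = tcalls.pop() if len(tcalls) == 1 else 0
        ctm_calls = [int(c[i]) for c in ctm_tracks]
        if tumor_call != 0:
            if any(c == tumor_call for c in ctm_calls):
                labels[i] = TRUTH_SHARED
            else:
                labels[i] = TRUTH_TUMOR_PRIVATE
        else:
            if any(c != 0 for c in ctm_calls):
                labels[i] = TRUTH_CTM_PRIVATE
            else:
                labels[i] = TRUTH_UNALTERED
    return labels


def generate_patient_scenario(
    seed: int,
    patient_id: str = "PT1",
    n_ctms: int = 6,
    tf_range: tuple[float, float] = (0.08, 0.48),
    shared_fraction_range: tuple[float, float] = (0.5, 0.9),
    private_events_range: tuple[int, int] = (1, 4),
    private_length_range: tuple[int, int] = (5_000_000, 30_000_000),
    n_tumor_events: int = 16,
    tumor_mean_copy_range: tuple[float, float] = (2.5, 3.5),
    tumor_tf_range: tuple[float, float] = (0.6, 0.95),
    t1_t2_diff_events: int = 2,
    hotspot: tuple[str, int, int] | None = DEFAULT_HOTSPOT,
    hotspot_prob: float = 0.4,
    reads_range: tuple[int, int] = DEFAULT_READS_RANGE,
    genome: GenomeBins | None = None,
    exclude_chroms: tuple[str, ...] = ("chr19",),
) -> PatientScenario:
    """A matched tumor/stroma/CTM sample set with bin-level truth.

    The hyperdiploid tumor fraction (T2) carries all tumor events; the
    pseudodiploid fraction (T1) drops up to ``t1_t2_diff_events`` of them.
    Each CTM inherits a random subset of the tumor events and gains private
    events placed (bin-aligned) in tumor-unaltered territory, optionally
    biased toward a recurrent hotspot region so that a cross-patient screen
    for recurrent CTM-private alterations has something to find.
    """
    if n_ctms < 1:
        raise ValueError("n_ctms must be >= 1")
    if genome is None:
        genome = build_genome_bins()
    rng = np.random.default_rng(seed)

    target = float(rng.uniform(*tumor_mean_copy_range))
    t2 = make_cell_line_profile(
        seed=_child_seed(seed, 2),
        target_mean_copy=target,
        n_events=n_tumor_events,
        event_length_range=(30_000_000, 120_000_000),
        genome=genome,
        name=f"{patient_id}_T2",
    ).profile
    if hotspot is not None:
        # keep the recurrent CTM-private hotspot free of tumor events in
        # every patient, so a cross-patient screen can see it
        hc, hs, he = hotspot
        t2 = SegmentSet(
            t2.sample_id,
            [s for s in t2.segments if not (s.chrom == hc and s.start < he and s.end > hs)],
            reference_ploidy=2.0,
        )
    events = list(t2.segments)

    n_drop = int(rng.integers(0, t1_t2_diff_events + 1))
    drop = set(rng.choice(len(events), size=n_drop, replace=False).tolist())
    t1 = SegmentSet(
        f"{patient_id}_T1",
        [s for i, s in enumerate(events) if i not in drop],
        reference_ploidy=2.0,
    )
    stroma = SegmentSet(f"{patient_id}_S", [], reference_ploidy=2.0)

    # territory available for private events: bins that do not intersect any
    # tumor event at all (so bin-aligned private segments can never overlap a
    # tumor segment), off the excluded chromosomes
    tumor_bins = np.zeros(genome.n_bins, dtype=bool)
    for seg in t2.segments:
        sl = genome.chrom_slice(seg.chrom)
        hit = (genome.start[sl] < seg.end) & (genome.end[sl] > seg.start)
        tumor_bins[sl][:] = tumor_bins[sl] | hit
    excluded = genome.chrom_mask(exclude_chroms)
    free_bins = ~tumor_bins & ~excluded
    window = genome.window

    def place_private(rng: np.random.Generator, taken: np.ndarray) -> Segment | None:
        """One bin-aligned private event in free, untaken territory."""
        want_bins = max(1, int(rng.integers(
            private_length_range[0] // window, private_length_range[1] // window + 1
        )))
        candidates = free_bins & ~taken
        if hotspot is not None and rng.uniform() < hotspot_prob:
            hmask = np.zeros_like(candidates)
            sl = genome.chrom_slice(hotspot[0])
            hsel = (genome.start[sl] >= hotspot[1]) & (genome.end[sl] <= hotspot[2])
            hmask[sl][:] = hsel
            if (candidates & hmask).any():
                candidates = candidates & hmask
                # recurrent events cover the whole available hotspot run so
                # they stack across CTMs and patients
                want_bins = int(hmask.sum())
        # runs of candidate bins within a chromosome
        runs: list[tuple[int, int]] = []
        i = 0
        n = genome.n_bins
        while i < n:
            if not candidates[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and candidates[j + 1] and genome.chrom[j + 1] == genome.chrom[i]:
                j += 1
            runs.append((i, j + 1))
            i = j + 1
        runs = [r for r in runs if r[1] - r[0] >= 1]
        if not runs:
            return None
        lo, hi = runs[int(rng.integers(len(runs)))]
        k = min(want_bins, hi - lo)
        b0 = int(rng.integers(lo, hi - k + 1))
        copy = int(rng.choice([1, 3, 4, 5], p=[0.25, 0.35, 0.25, 0.15]))
        return Segment(
            str(genome.chrom[b0]),
            int(genome.start[b0]),
            int(genome.end[b0 + k - 1]),
            copy,
            call_for(copy, 2.0),
        )

    ctms: list[CTMTruth] = []
    counts: dict[str, BinVector] = {}
    rows = []

    def add_sample(sid: str, role: str, profile: SegmentSet, tf: float, path: int):
        sseed = _child_seed(seed, 9, path)
        srng = np.random.default_rng(sseed)
        total = _draw_total_reads(srng, reads_range)
        counts[sid] = simulate_mixture_counts(profile, tf, total, srng, genome)
        rows.append(
            {
                "sample_id": sid,
                "patient_id": patient_id,
                "role": role,
                "true_tf": float(tf),
                "total_reads": total,
                "seed": sseed,
            }
        )

    add_sample(stroma.sample_id, "stroma", stroma, 0.0, 0)
    add_sample(t1.sample_id, "tumor", t1, float(rng.uniform(*tumor_tf_range)), 1)
    add_sample(t2.sample_id, "tumor", t2, float(rng.uniform(*tumor_tf_range)), 2)

    for j in range(1, n_ctms + 1):
        crng = np.random.default_rng(_child_seed(seed, 5, j))
        shared_frac = float(crng.uniform(*shared_fraction_range))
        keep = [i for i in range(len(events)) if crng.uniform() < shared_frac]
        if not keep:
            keep = [int(crng.integers(len(events)))]
        n_priv = int(crng.integers(private_events_range[0], private_events_range[1] + 1))
        taken = np.zeros(genome.n_bins, dtype=bool)
        privates: list[Segment] = []
        for _ in range(n_priv):
            seg = place_private(crng, taken)
            if seg is None:
                raise ValueError(
                    "insufficient tumor-unaltered territory for private events"
                )
            privates.append(seg)
            sl = genome.chrom_slice(seg.chrom)
            hit = (genome.start[sl] < seg.end) & (genome.end[sl] > seg.start)
            taken[sl][:] = taken[sl] | hit
        ctm_id = f"{patient_id}_CTM{j}"
        profile = SegmentSet(
            ctm_id,
            [events[i] for i in keep] + privates,
            reference_ploidy=2.0,
        )
        tf = float(crng.uniform(*tf_range))
        ctms.append(CTMTruth(ctm_id, tf, keep, privates, profile))
        add_sample(ctm_id, "ctm", profile, tf, 10 + j)

    analyzable = ~excluded
    labels = _truth_label_track(
        [rasterize_calls(t1, genome), rasterize_calls(t2, genome)],
        [rasterize_calls(c.profile, genome) for c in ctms],
        analyzable,
    )
    return PatientScenario(
        patient_id=patient_id,
        tumor_t1=t1,
        tumor_t2=t2,
        stroma=stroma,
        ctms=ctms,
        counts=counts,
        truth=pd.DataFrame(rows),
        truth_labels=labels,
    )


def generate_patient_cohort(
    master_seed: int,
    n_patients: int = 6,
    n_ctms_range: tuple[int, int] = (2, 14),
    genome: GenomeBins | None = None,
    **scenario_kwargs,
) -> list[PatientScenario]:
    """A cohort of patient scenarios with per-patient CTM counts drawn from a range."""
    if genome is None:
        genome = build_genome_bins()
    rng = np.random.default_rng(_child_seed(master_seed, 77))
    out = []
    for k in range(1, n_patients + 1):
        n_ctms = int(rng.integers(n_ctms_range[0], n_ctms_range[1] + 1))
        out.append(
            generate_patient_scenario(
                seed=_child_seed(master_seed, 78, k),
                patient_id=f"PT{k}",
                n_ctms=n_ctms,
                genome=genome,
                **scenario_kwargs,
            )
        )
    return out
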