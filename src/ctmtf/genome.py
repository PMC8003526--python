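"""Genome tiling and copy-number interval primitives.

Everything downstream of the read-count simulator and the TGF estimator works
at the resolution of a fixed tiling of the genome into equal-sized windows
(1 Mb by default, matching megabase-scale low-pass WGS copy-number analysis).
This module owns that tiling (:class:`GenomeBins`), the segment-level
representation of a copy-number profile (:class:`Segment`, :class:`SegmentSet`),
the per-bin numeric track (:class:`BinVector`), and the conversion between the
two (:func:`rasterize` / :func:`segments_from_states`).

Coordinates are 0-based, half-open (BED convention) throughout.  The bundled
chromosome-size table covers chr1-chr22 and chrX of an hg19-like genome; chrY
is deliberately absent (female breast-cancer context).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_WINDOW = 1_000_000

GAIN = "gain"
NEUTRAL = "neutral"
LOSS = "loss"
_CALLS = frozenset({GAIN, NEUTRAL, LOSS})


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural ordering: chr1..chr22 numerically, then chrX, then the rest."""
    name = chrom.removeprefix("chr")
    if name.isdigit():
        return (int(name), "")
    if name == "X":
        return (1000, "")
    return (2000, name)


def call_for(copy_number: float, reference_ploidy: float) -> str:
    """Classify a copy number as gain/neutral/loss relative to round(ploidy)."""
    ref = round(reference_ploidy)
    if copy_number > ref:
        return GAIN
    if copy_number < ref:
        return LOSS
    return NEUTRAL


def load_default_chrom_sizes() -> dict[str, int]:
    """Bundled hg19-like chromosome sizes (chr1-22, chrX; no chrY)."""
    text = (
        importlib.resources.files("ctmtf.data")
        .joinpath("hg19_chrom_sizes.tsv")
        .read_text()
    )
    sizes: dict[str, int] = {}
    for line in text.strip().splitlines():
        chrom, length = line.split("\t")
        sizes[chrom] = int(length)
    return sizes


@dataclass(frozen=True)
class GenomeBins:
    """A fixed tiling of a genome into adjacent, non-overlapping windows.

    Bins are ordered by (chromosome order, start).  All bins have length
    ``window`` except the terminal bin of each chromosome, which may be
    shorter.
    """

    chrom_order: tuple[str, ...]
    chrom_sizes: dict[str, int]
    window: int
    chrom: np.ndarray = field(repr=False)       # per-bin chromosome label
    start: np.ndarray = field(repr=False)       # per-bin start (bp)
    end: np.ndarray = field(repr=False)         # per-bin end (bp)

    @property
    def n_bins(self) -> int:
        return self.start.size

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) // 2

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_sizes[c] for c in self.chrom_order))

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_mask(self, chroms: Iterable[str]) -> np.ndarray:
        """Boolean array marking bins on any of the given chromosomes."""
        wanted = set(chroms)
        return np.isin(self.chrom, sorted(wanted))


def build_genome_bins(
    chrom_sizes: Mapping[str, int] | None = None,
    window: int = DEFAULT_WINDOW,
    chrom_order: Sequence[str] | None = None,
) -> GenomeBins:
    """Tile chromosomes into fixed windows.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome -> length in bp.  Defaults to the bundled
        hg19-like table.
    window
        Window length in bp (default 1 Mb).
    chrom_order
        Order in which chromosomes are laid out; defaults to the mapping's
        insertion order.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if chrom_sizes is None:
        chrom_sizes = load_default_chrom_sizes()
    if not chrom_sizes:
        raise ValueError("no chromosomes")
    order = tuple(chrom_order) if chrom_order is not None else tuple(chrom_sizes)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for c in order:
        size = int(chrom_sizes[c])
        if size <= 0:
            raise ValueError(f"chromosome {c!r} has non-positive size")
        edges = list(range(0, size, window)) + [size]
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(c)
            starts.append(s)
            ends.append(e)
    return GenomeBins(
        chrom_order=order,
        chrom_sizes={c: int(chrom_sizes[c]) for c in order},
        window=window,
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
    )


@dataclass(frozen=True)
class Segment:
    """One constant-copy-number genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    copy_number: int
    call: str

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted segment {self.chrom}:{self.start}-{self.end}"
            )
        if self.copy_number < 0:
            raise ValueError("copy_number must be non-negative")
        if self.call not in _CALLS:
            raise ValueError(f"unknown call {self.call!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentSet:
    """A sample's copy-number profile as sorted, non-overlapping segments.

    ``reference_ploidy`` is the copy level treated as neutral for this
    profile (2 for a profile expressed relative to a diploid genome).
    """

    sample_id: str
    segments: list[Segment]
    reference_ploidy: float = 2.0

    def __post_init__(self):
        self.sort()
        self.validate()

    def sort(self) -> None:
        self.segments.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start))

    def validate(self) -> None:
        by_chrom: dict[str, int] = {}
        for seg in self.segments:
            prev_end = by_chrom.get(seg.chrom, -1)
            if seg.start < prev_end:
                raise ValueError(
                    f"overlapping segments on {seg.chrom} near {seg.start} "
                    f"(sample {self.sample_id})"
                )
            by_chrom[seg.chrom] = seg.end

    @property
    def altered(self) -> list[Segment]:
        return [s for s in self.segments if s.call != NEUTRAL]

    def mean_copy(self, genome: GenomeBins) -> float:
        """Length-weighted mean copy number over the whole genome.

        Territory not covered by any segment counts at ``reference_ploidy``.
        """
        total = genome.genome_length
        acc = float(self.reference_ploidy) * total
        for seg in self.segments:
            acc += seg.length * (seg.copy_number - self.reference_ploidy)
        return acc / total


@dataclass
class BinVector:
    """One numeric value per bin of a :class:`GenomeBins`, with a usable mask."""

    bins: GenomeBins
    values: np.ndarray
    mask: np.ndarray | None = None  # True = usable

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (self.bins.n_bins,):
            raise ValueError(
                f"values length {self.values.size} != bin count {self.bins.n_bins}"
            )
        if self.mask is None:
            self.mask = np.ones(self.bins.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.bins.n_bins,):
                raise ValueError("mask length mismatch")

    def copy(self) -> "BinVector":
        return BinVector(self.bins, self.values.copy(), self.mask.copy())


def rasterize(segments: SegmentSet, bins: GenomeBins) -> BinVector:
    """Project a segment profile onto the tiling as integer copy states.

    A bin takes the copy number of the segment covering its midpoint; bins
    covered by no segment take ``round(reference_ploidy)``.
    """
    states = np.full(bins.n_bins, round(segments.reference_ploidy), dtype=np.int64)
    mids_by_chrom: dict[str, tuple[slice, np.ndarray]] = {}
    for seg in segments.segments:
        if seg.chrom not in bins.chrom_sizes:
            raise ValueError(f"segment on unknown chromosome {seg.chrom!r}")
        if seg.chrom not in mids_by_chrom:
            sl = bins.chrom_slice(seg.chrom)
            mids_by_chrom[seg.chrom] = (sl, bins.midpoints[sl])
        sl, mids = mids_by_chrom[seg.chrom]
        lo = int(np.searchsorted(mids, seg.start, side="left"))
        hi = int(np.searchsorted(mids, seg.end, side="left"))
        states[sl.start + lo : sl.start + hi] = seg.copy_number
    return BinVector(bins, states)


def rasterize_calls(segments: SegmentSet, bins: GenomeBins) -> np.ndarray:
    """Per-bin call track: -1 loss, 0 neutral, +1 gain (midpoint rule)."""
    states = rasterize(segments, bins).values
    ref = round(segments.reference_ploidy)
    return np.sign(states - ref).astype(np.int8)


def segments_from_states(
    states: np.ndarray,
    bins: GenomeBins,
    sample_id: str,
    reference_ploidy: float = 2.0,
    mask: np.ndarray | None = None,
) -> SegmentSet:
    """Merge runs of equal per-bin copy states into a :class:`SegmentSet`.

    Masked-out bins break runs and are not covered by any emitted segment.
    """
    states = np.asarray(states)
    if mask is None:
        mask = np.ones(bins.n_bins, dtype=bool)
    segs: list[Segment] = []
    i = 0
    n = bins.n_bins
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and mask[j + 1]
            and bins.chrom[j + 1] == bins.chrom[i]
            and states[j + 1] == states[i]
        ):
            j += 1
        segs.append(
            Segment(
                chrom=str(bins.chrom[i]),
                start=int(bins.start[i]),
                end=int(bins.end[j]),
                copy_number=int(states[i]),
                call=call_for(int(states[i]), reference_ploidy),
            )
        )
        i = j + 1
    return SegmentSet(sample_id=sample_id, segments=segs, reference_ploidy=reference_ploidy)
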