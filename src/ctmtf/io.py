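"""Readers and writers for the package's plain-text interchange formats.

Formats
-------
segments (BED-like TSV)
    ``chrom  start  end  copy_number  call`` with optional ``#`` comment
    lines.  Coordinates 0-based half-open.
bin table (BedGraph-like TSV)
    ``chrom  start  end  value`` aligned to the standard tiling; bins absent
    from the file are masked on read.
chromosome sizes
    two-column TSV ``chrom  length``.

``write . read`` is the identity on canonical-form files.  Out-of-order
segment files are accepted, sorted and a warning is logged; overlapping
segments, negative coordinates and unknown call labels are parse errors that
name the offending line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .genome import (
    BinVector,
    GenomeBins,
    Segment,
    SegmentSet,
    chrom_sort_key,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            sizes[parts[0]] = int(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    if not sizes:
        raise ParseError(f"{path}: no chromosomes")
    return sizes


def read_segments(
    path: str | Path,
    sample_id: str | None = None,
    reference_ploidy: float = 2.0,
) -> SegmentSet:
    path = Path(path)
    segs: list[Segment] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
        chrom, start_s, end_s, cn_s, call = parts
        try:
            seg = Segment(chrom, int(start_s), int(end_s), int(cn_s), call)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        segs.append(seg)
    ordered = sorted(segs, key=lambda s: (chrom_sort_key(s.chrom), s.start))
    if ordered != segs:
        logger.warning("%s: segments out of order; sorted on read", path)
    try:
        return SegmentSet(
            sample_id=sample_id or path.stem,
            segments=ordered,
            reference_ploidy=reference_ploidy,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_segments(segset: SegmentSet, path: str | Path) -> None:
    lines = [
        f"{s.chrom}\t{s.start}\t{s.end}\t{s.copy_number}\t{s.call}"
        for s in segset.segments
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bin_table(path: str | Path, bins: GenomeBins) -> BinVector:
    """Read a BedGraph-like value table aligned to the standard tiling.

    Rows must match bin boundaries exactly; bins with no row are masked.
    """
    path = Path(path)
    values = np.full(bins.n_bins, np.nan)
    seen = np.zeros(bins.n_bins, dtype=bool)
    # index from (chrom, start) -> bin number
    index = {(str(c), int(s)): i for i, (c, s) in enumerate(zip(bins.chrom, bins.start))}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        chrom, start_s, end_s, value_s = parts
        try:
            start, end = int(start_s), int(end_s)
            value = float(value_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        key = (chrom, start)
        if key not in index:
            raise ParseError(
                f"{path}:{lineno}: interval {chrom}:{start}-{end} does not match tiling"
            )
        i = index[key]
        if int(bins.end[i]) != end:
            raise ParseError(
                f"{path}:{lineno}: end {end} does not match bin end {int(bins.end[i])}"
            )
        if seen[i]:
            raise ParseError(f"{path}:{lineno}: duplicate bin {chrom}:{start}")
        values[i] = value
        seen[i] = True
    return BinVector(bins, values, mask=seen)


def _format_value(v: float) -> str:
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return format(float(v), ".10g")


def write_bin_table(vec: BinVector, path: str | Path) -> None:
    """Write unmasked bins as a BedGraph-like TSV (masked bins omitted)."""
    bins = vec.bins
    lines = [
        f"{bins.chrom[i]}\t{bins.start[i]}\t{bins.end[i]}\t{_format_value(vec.values[i])}"
        for i in range(bins.n_bins)
        if vec.mask[i]
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
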