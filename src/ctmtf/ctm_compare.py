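"""Shared/private copy-number comparison between CTMs and matched tumors.

All set algebra happens at bin resolution on the common tiling: each sample's
segments are projected to a per-bin call track (loss / neutral / gain), the
excluded chromosomes (chr19 by default) are removed, and each remaining bin
receives exactly one label:

* ``shared`` — the tumor consensus is altered and at least one CTM carries
  the same alteration type (a gain matches a gain of any amplitude);
* ``tumor_private`` — the tumor consensus is altered and no CTM matches;
* ``ctm_private`` — the tumor consensus is unaltered but some CTM is altered;
* ``unaltered`` — neither.

When both tumor fractions are available they must agree on the alteration
type for a bin to count as tumor-altered; with a single tumor sample that
sample alone defines the tumor calls.  Fractions are labelled bin length
over total analyzable genome length.

The module also provides cross-sample alteration frequencies (with the
tissue >70% / CTM >50% reporting thresholds), the cross-patient screen for
recurrent CTM-private regions (>= 55% of pooled CTMs, never shared with
tissue in any patient), and Pearson-correlation hierarchical clustering of
profiles (Euclidean distance, complete linkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .genome import BinVector, GenomeBins, SegmentSet, rasterize_calls

LABEL_UNALTERED = 0
LABEL_SHARED = 1
LABEL_TUMOR_PRIVATE = 2
LABEL_CTM_PRIVATE = 3
LABEL_EXCLUDED = -1

LABEL_NAMES = {
    LABEL_UNALTERED: "unaltered",
    LABEL_SHARED: "shared",
    LABEL_TUMOR_PRIVATE: "tumor_private",
    LABEL_CTM_PRIVATE: "ctm_private",
    LABEL_EXCLUDED: "excluded",
}


@dataclass
class PatientProfileSet:
    """Matched profiles of one patient: tumor fraction(s) plus CTMs."""

    patient_id: str
    tumor_t2: SegmentSet
    tumor_t1: SegmentSet | None = None   # absent for single-tumor patients
    ctms: list[SegmentSet] | None = None

    def __post_init__(self):
        if not self.ctms:
            raise ValueError("need at least one CTM profile")

    @property
    def tumor_profiles(self) -> list[SegmentSet]:
        out = [self.tumor_t2]
        if self.tumor_t1 is not None:
            out.insert(0, self.tumor_t1)
        return out


@dataclass
class OverlapReport:
    patient_id: str
    private_tumor_frac: float
    private_ctm_frac: float
    shared_frac: float
    labels: np.ndarray            # per-bin label track (LABEL_* codes)
    analyzable_length: int

    def as_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "cna_private_tumor": self.private_tumor_frac,
            "cna_private_ctm": self.private_ctm_frac,
            "cna_shared": self.shared_frac,
        }


def _tumor_consensus(tracks: list[np.ndarray]) -> np.ndarray:
    """Per-bin tumor call; all available tumor samples must agree on the type."""
    stacked = np.stack(tracks)
    agree = np.all(stacked == stacked[0], axis=0)
    return np.where(agree, stacked[0], 0)


def shared_private_regions(
    profiles: PatientProfileSet,
    bins: GenomeBins,
    exclude_chroms: tuple[str, ...] = ("chr19",),
) -> OverlapReport:
    """Label every analyzable bin as shared / tumor-private / CTM-private."""
    excluded = bins.chrom_mask(exclude_chroms)
    tumor = _tumor_consensus([rasterize_calls(t, bins) for t in profiles.tumor_profiles])
    ctm_tracks = np.stack([rasterize_calls(c, bins) for c in profiles.ctms])

    labels = np.full(bins.n_bins, LABEL_EXCLUDED, dtype=np.int8)
    ana = ~excluded
    tumor_altered = tumor != 0
    ctm_matches = (ctm_tracks == tumor[None, :]).any(axis=0) & tumor_altered
    ctm_any = (ctm_tracks != 0).any(axis=0)

    labels[ana & tumor_altered & ctm_matches] = LABEL_SHARED
    labels[ana & tumor_altered & ~ctm_matches] = LABEL_TUMOR_PRIVATE
    labels[ana & ~tumor_altered & ctm_any] = LABEL_CTM_PRIVATE
    labels[ana & ~tumor_altered & ~ctm_any] = LABEL_UNALTERED

    lengths = bins.lengths
    total = int(lengths[ana].sum())
    frac = lambda code: float(lengths[labels == code].sum() / total)
    return OverlapReport(
        patient_id=profiles.patient_id,
        private_tumor_frac=frac(LABEL_TUMOR_PRIVATE),
        private_ctm_frac=frac(LABEL_CTM_PRIVATE),
        shared_frac=frac(LABEL_SHARED),
        labels=labels,
        analyzable_length=total,
    )


@dataclass
class FrequencyTable:
    """Per-bin alteration frequencies plus merged above-threshold regions."""

    gain_frac: np.ndarray
    loss_frac: np.ndarray
    threshold: float
    regions: pd.DataFrame      # chrom, start, end, type, frequency
    n_samples: int


def _merge_flagged(
    flagged: np.ndarray, freq: np.ndarray, bins: GenomeBins, kind: str
) -> list[dict]:
    rows = []
    i = 0
    n = bins.n_bins
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flagged[j + 1] and bins.chrom[j + 1] == bins.chrom[i]:
            j += 1
        rows.append(
            {
                "chrom": str(bins.chrom[i]),
                "start": int(bins.start[i]),
                "end": int(bins.end[j]),
                "type": kind,
                "frequency": float(freq[i : j + 1].mean()),
            }
        )
        i = j + 1
    return rows


def alteration_frequency(
    samples: list[SegmentSet],
    bins: GenomeBins,
    threshold: float = 0.7,
    exclude_chroms: tuple[str, ...] = ("chr19",),
) -> FrequencyTable:
    """Fraction of samples carrying a gain / a loss at each bin.

    Contiguous bins whose frequency exceeds ``threshold`` (strict) are merged
    into regions; use 0.7 for tissue cohorts and 0.5 for CTM cohorts.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    tracks = np.stack([rasterize_calls(s, bins) for s in samples])
    excluded = bins.chrom_mask(exclude_chroms)
    gain = (tracks > 0).mean(axis=0)
    loss = (tracks < 0).mean(axis=0)
    gain[excluded] = 0.0
    loss[excluded] = 0.0
    rows = _merge_flagged(gain > threshold, gain, bins, "gain")
    rows += _merge_flagged(loss > threshold, loss, bins, "loss")
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "frequency"])
    return FrequencyTable(gain, loss, threshold, regions, len(samples))


def recurrent_ctm_private(
    reports: list[OverlapReport],
    ctm_profiles: list[SegmentSet],
    bins: GenomeBins,
    min_ctm_fraction: float = 0.55,
    exclude_chroms: tuple[str, ...] = ("chr19",),
) -> FrequencyTable:
    """Cross-patient screen for recurrent CTM-private alterations.

    Candidate bins are altered in at least ``min_ctm_fraction`` of all CTMs
    pooled across patients AND never labelled shared (with tissue) in any
    patient.  Altered means any non-neutral call; merged candidate regions
    are reported with their pooled frequency.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 patients")
    tracks = np.stack([rasterize_calls(c, bins) for c in ctm_profiles])
    excluded = bins.chrom_mask(exclude_chroms)
    altered_frac = (tracks != 0).mean(axis=0)
    altered_frac[excluded] = 0.0
    ever_shared = np.zeros(bins.n_bins, dtype=bool)
    for rep in reports:
        ever_shared |= rep.labels == LABEL_SHARED
    candidate = (altered_frac >= min_ctm_fraction) & ~ever_shared
    rows = _merge_flagged(candidate, altered_frac, bins, "ctm_private")
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "frequency"])
    gain = (tracks > 0).mean(axis=0)
    loss = (tracks < 0).mean(axis=0)
    gain[excluded] = 0.0
    loss[excluded] = 0.0
    return FrequencyTable(gain, loss, min_ctm_fraction, regions, tracks.shape[0])


@dataclass
class CorrelationClustering:
    sample_ids: list[str]
    correlation: np.ndarray
    linkage_matrix: np.ndarray     # scipy linkage format
    dropped: list[str]


def correlation_cluster(
    samples: dict[str, BinVector] | list[tuple[str, BinVector]],
) -> CorrelationClustering:
    """Pearson correlation matrix of profiles + complete-linkage clustering.

    Correlations use the bins unmasked in every sample; the correlation
    matrix's rows are then clustered with Euclidean distance and complete
    linkage.  Constant profiles (undefined correlation) are dropped with a
    warning.  Input order does not affect merge heights; sample ids are
    sorted for a deterministic layout.
    """
    items = sorted(samples.items() if isinstance(samples, dict) else samples)
    if len(items) < 2:
        raise ValueError("need at least 2 samples")
    common = items[0][1].mask.copy()
    for _, v in items[1:]:
        common &= v.mask
    if common.sum() < 2:
        raise ValueError("fewer than 2 jointly unmasked bins")
    kept, dropped = [], []
    for sid, v in items:
        vals = v.values[common].astype(float)
        if np.ptp(vals) == 0:
            dropped.append(sid)
        else:
            kept.append((sid, vals))
    if len(kept) < 2:
        raise ValueError("fewer than 2 non-constant profiles")
    if dropped:
        warnings.warn(f"dropped constant profiles: {', '.join(dropped)}", stacklevel=2)
    ids = [sid for sid, _ in kept]
    mat = np.corrcoef(np.stack([vals for _, vals in kept]))
    Z = linkage(mat, method="complete", metric="euclidean")
    return CorrelationClustering(ids, mat, Z, dropped)
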