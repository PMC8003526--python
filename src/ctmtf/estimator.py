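"""Tumor genome fraction (TGF) estimation from binned read counts.

The model is a normal-contamination mixture: a sample is a fraction ``n`` of
diploid genome plus ``1 - n`` of tumor genome whose copy number takes
integer states ``0..max_copy_state`` along the genome.  For copy state ``c``,
normal fraction ``n`` and tumor ploidy ``P`` the expected log2 ratio of a bin
(relative to the sample's mean copy) is::

    mu_c = log2( (2 n + (1 - n) c) / (2 n + (1 - n) P) )

Copy states follow a hidden Markov chain with a high self-transition
probability (segments span many 1 Mb bins at low-pass coverage); emissions
are Gaussian around ``mu_c`` with a single shared variance.  For each tumor
ploidy on the configured grid, EM refines the normal fraction and the shared
variance starting from each value of the normal-fraction grid; the
(``n``, ``P``) pair with the highest data log-likelihood wins, ties going to
the larger normal fraction (the conservative, lower-TGF choice).  The TGF is
``1 - n``, forced to zero whenever the decoded copy-state path is constant:
a flat profile carries no aberration evidence and its absolute copy level is
unidentifiable from relative ratios, so it is reported as diploid-neutral.
Gain/loss calls on the decoded segments are read relative to the modal
(baseline) copy state of the decoded path.

The module also owns the downstream sample-level rules: the CNA-profile
classes (normal / unclear / aberrant via the 125 Mb single-region and 375 Mb
total-altered thresholds, chr19 excluded for its systematic GC-driven
deletion bias), the CTM label mapping, the 400,000 aligned-read QC filter,
and the effectively-amplifiable-template (EAT) wet-lab QC calculator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from ._hmm import forward_backward, viterbi
from .genome import BinVector, GenomeBins, SegmentSet, segments_from_states

PROFILE_NORMAL = "normal"
PROFILE_ABERRANT = "aberrant"
PROFILE_UNCLEAR = "unclear"

CTM_NORMAL = "Normal CTM"
CTM_ABERRANT = "Aberrant CTM"
CTM_UNCLEAR = "Unclear CTM"

_MIN_MIX_COPY = 1e-2  # floor on mixture copy so state 0 has a finite mean


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings of the TGF estimator and the sample-level rules.

    ``ploidy_grid`` holds the candidate tumor ploidies; pass a single value
    for the fixed-ploidy (titration) mode.  ``normal_grid`` values are EM
    initialisations for the normal fraction, which is then refined
    continuously.
    """

    normal_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    ploidy_grid: tuple[float, ...] = (2.0, 2.65, 3.0, 3.5, 4.0, 4.2)
    # clinical mode refines tumor ploidy continuously from the grid values
    # (the grid is a set of initialisations); fixed-ploidy mode pins it
    estimate_ploidy: bool = True
    ploidy_bounds: tuple[float, float] = (1.5, 5.5)
    max_copy_state: int = 7
    self_transition: float = 0.998
    min_aligned_reads: int = 400_000
    exclude_chroms: tuple[str, ...] = ("chr19",)
    single_region_mb: float = 125.0
    total_altered_mb: float = 375.0
    tgf_floor: float = 0.05
    read_length: int = 150
    eat_threshold: float = 30.0
    # numerical knobs
    em_tol: float = 1e-6
    em_max_iter: int = 60
    em_screen_iters: int = 4
    em_keep: int = 5
    emission_var_floor: float = 1e-7
    min_usable_bins: int = 100
    # detection floor: decoded altered territory below this many bins is
    # treated as noise and relabelled neutral (the normal fraction is not
    # identifiable from a handful of outlier bins at 0.04x coverage)
    min_altered_bins: int = 25
    # ploidy self-consistency: the length-weighted mean of the decoded copy
    # states must lie within this distance of the candidate tumor ploidy,
    # which suppresses the genome-doubling ambiguity (a mixture's fractional
    # copy ladder re-read as integer states at near-zero normal fraction)
    ploidy_consistency_tol: float = 0.5

    def __post_init__(self):
        if not self.normal_grid or not self.ploidy_grid:
            raise ValueError("grids must be non-empty")
        if not all(0.0 < n < 1.0 for n in self.normal_grid):
            raise ValueError("normal_grid values must be in (0, 1)")
        if self.single_region_mb <= 0 or self.total_altered_mb <= 0:
            raise ValueError("classification thresholds must be positive")

    def fixed_ploidy(self, ploidy: float) -> "EstimatorConfig":
        return replace(self, ploidy_grid=(float(ploidy),), estimate_ploidy=False)


@dataclass
class TGFResult:
    sample_id: str
    tgf: float
    normal_fraction: float
    ploidy_used: float
    loglik: float
    segments: SegmentSet
    profile_class: str
    qc_pass: bool
    coverage: float
    n_bins_used: int


@dataclass(frozen=True)
class WetLabQC:
    qc_score: float
    dna_index: float
    n_cells: int
    eat: float
    passes: bool


def uniform_reference(genome: GenomeBins) -> BinVector:
    """Ideal diploid reference track: expected counts proportional to bin length."""
    return BinVector(genome, genome.lengths.astype(float))


def normalize_bins(counts: BinVector, reference: BinVector) -> BinVector:
    """Log2 ratio of observed to reference relative abundance per bin.

    ``value_i = log2((count_i / total) / (ref_i / ref_total))`` with totals
    over the jointly usable bins; bins with zero reference (or zero count,
    where the log ratio is undefined) are masked.  The output is
    median-centered to 0 over usable bins.
    """
    if counts.bins is not reference.bins and counts.bins.n_bins != reference.bins.n_bins:
        raise ValueError("counts and reference are on different tilings")
    mask = counts.mask & reference.mask & (reference.values > 0) & (counts.values > 0)
    if not mask.any():
        raise ValueError("no usable bins")
    total = counts.values[mask].sum()
    ref_total = reference.values[mask].sum()
    ratios = np.full(counts.bins.n_bins, np.nan)
    ratios[mask] = np.log2(
        (counts.values[mask] / total) / (reference.values[mask] / ref_total)
    )
    ratios[mask] -= np.median(ratios[mask])
    return BinVector(counts.bins, ratios, mask=mask)


# ---------------------------------------------------------------------------
# the HMM fit


def _state_means(states: np.ndarray, n: float, ploidy: float) -> np.ndarray:
    mix = 2.0 * n + (1.0 - n) * states
    denom = 2.0 * n + (1.0 - n) * ploidy
    return np.log2(np.maximum(mix, _MIN_MIX_COPY) / max(denom, _MIN_MIX_COPY))


@dataclass
class _Candidate:
    n: float
    ploidy: float
    sigma2: float
    loglik: float
    iters: int


def _fit_candidate(
    r: np.ndarray,
    states: np.ndarray,
    ploidy: float,
    n0: float,
    cfg: EstimatorConfig,
    max_iter: int,
    n_start: float | None = None,
    sigma2_start: float | None = None,
) -> _Candidate:
    n = float(n_start if n_start is not None else n0)
    P = float(ploidy)
    sigma2 = float(
        sigma2_start
        if sigma2_start is not None
        else max(np.var(r), 10 * cfg.emission_var_floor)
    )
    ll_prev = -np.inf
    ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        mu = _state_means(states, n, P)
        ll, gamma = forward_backward(r, mu, sigma2, cfg.self_transition)
        # sufficient statistics per state
        N_c = gamma.sum(axis=0)
        M1 = gamma.T @ r
        M2 = gamma.T @ (r * r)
        N = r.size

        def q_of(n_: float, P_: float) -> float:
            mu_ = _state_means(states, n_, P_)
            return float(np.sum(M2 - 2.0 * mu_ * M1 + mu_ * mu_ * N_c))

        n = float(
            minimize_scalar(
                lambda n_: q_of(n_, P), bounds=(1e-3, 0.999), method="bounded",
                options={"xatol": 1e-5},
            ).x
        )
        if cfg.estimate_ploidy:
            P = float(
                minimize_scalar(
                    lambda P_: q_of(n, P_), bounds=cfg.ploidy_bounds,
                    method="bounded", options={"xatol": 1e-4},
                ).x
            )
        sigma2 = max(q_of(n, P) / N, cfg.emission_var_floor)
        if it >= 3 and abs(ll - ll_prev) < cfg.em_tol * max(1.0, abs(ll_prev)):
            break
        ll_prev = ll
    return _Candidate(n=n, ploidy=P, sigma2=sigma2, loglik=float(ll), iters=it)


def estimate_tgf(
    ratios: BinVector,
    config: EstimatorConfig | None = None,
    sample_id: str = "sample",
    aligned_reads: int | None = None,
) -> TGFResult:
    """Fit the normal-contamination copy-state model and return the TGF.

    ``ratios`` are median-centered log2 ratios as produced by
    :func:`normalize_bins`; ``aligned_reads`` (if given) feeds the coverage
    field and the 400k-read QC flag.
    """
    cfg = config or EstimatorConfig()
    genome = ratios.bins
    mask = ratios.mask & ~genome.chrom_mask(cfg.exclude_chroms)
    mask &= np.isfinite(np.where(mask, ratios.values, 0.0))
    if mask.sum() < cfg.min_usable_bins:
        raise ValueError(
            f"profile too short: {int(mask.sum())} usable bins "
            f"(need >= {cfg.min_usable_bins})"
        )
    r = ratios.values[mask].astype(float)
    lengths = genome.lengths[mask].astype(float)
    # re-center so the length-weighted linear-scale mean is 1, matching the
    # model's normalisation by the sample's mean copy number
    r = r - np.log2(np.sum(lengths * np.exp2(r)) / lengths.sum())

    states = np.arange(0, cfg.max_copy_state + 1, dtype=float)

    # screening pass over the full (ploidy x normal) lattice, then refine the
    # most promising candidates to convergence
    screened: list[_Candidate] = []
    for P in cfg.ploidy_grid:
        for n0 in cfg.normal_grid:
            screened.append(
                _fit_candidate(r, states, P, n0, cfg, max_iter=cfg.em_screen_iters)
            )
    screened.sort(key=lambda c: c.loglik, reverse=True)
    keep = max(cfg.em_keep, 1)
    finished = [
        _fit_candidate(
            r, states, c.ploidy, c.n, cfg, max_iter=cfg.em_max_iter,
            n_start=c.n, sigma2_start=c.sigma2,
        )
        for c in screened[:keep]
    ]

    def decode(c: _Candidate) -> np.ndarray:
        return viterbi(
            r, _state_means(states, c.n, c.ploidy), c.sigma2, cfg.self_transition
        )

    paths = {id(c): decode(c) for c in finished}
    consistent = [
        c
        for c in finished
        if abs(np.average(paths[id(c)], weights=lengths) - c.ploidy)
        <= cfg.ploidy_consistency_tol
    ]
    pool = consistent or finished
    best = max(pool, key=lambda c: (c.loglik, c.n))
    path = paths[id(best)].copy()
    # a (near-)constant path carries no evidence of aberration: the absolute
    # copy level of a flat profile is unidentifiable from relative ratios,
    # so it is re-anchored to the diploid state and the TGF forced to zero
    modal = int(
        np.argmax(np.bincount(path, weights=lengths, minlength=states.size))
    )
    if 0 < int(np.sum(path != modal)) < cfg.min_altered_bins:
        path[:] = modal
    flat = bool(np.all(path == modal))
    if flat:
        path[:] = 2
    # gain/loss calls are read relative to the modal (length-weighted
    # baseline) copy state of the decoded path, which keeps the labels
    # invariant across scale-degenerate solutions of the mixture model
    call_ref = 2.0 if flat else float(modal)
    full_states = np.full(genome.n_bins, round(call_ref), dtype=np.int64)
    full_states[mask] = path
    segments = segments_from_states(
        full_states, genome, sample_id, reference_ploidy=call_ref, mask=mask
    )
    tgf = 0.0 if flat else 1.0 - best.n
    profile_class = classify_profile(segments, genome, cfg)

    coverage = float("nan")
    qc_pass = True
    if aligned_reads is not None:
        coverage = aligned_reads * cfg.read_length / genome.genome_length
        qc_pass = qc_filter(aligned_reads, cfg)
    return TGFResult(
        sample_id=sample_id,
        tgf=float(tgf),
        normal_fraction=float(best.n),
        ploidy_used=float(best.ploidy),
        loglik=float(best.loglik),
        segments=segments,
        profile_class=profile_class,
        qc_pass=qc_pass,
        coverage=coverage,
        n_bins_used=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# profile and CTM classification


def _altered_regions(
    segments: SegmentSet, genome: GenomeBins, cfg: EstimatorConfig
) -> list[int]:
    """Lengths (bp) of maximal runs of consecutive altered bins, any call type.

    Territory on excluded chromosomes is removed before runs are formed.
    """
    altered = np.zeros(genome.n_bins, dtype=bool)
    mids_cache: dict[str, tuple[slice, np.ndarray]] = {}
    for seg in segments.segments:
        if seg.call == "neutral":
            continue
        if seg.chrom not in mids_cache:
            sl = genome.chrom_slice(seg.chrom)
            mids_cache[seg.chrom] = (sl, genome.midpoints[sl])
        sl, mids = mids_cache[seg.chrom]
        lo = int(np.searchsorted(mids, seg.start, side="left"))
        hi = int(np.searchsorted(mids, seg.end, side="left"))
        altered[sl.start + lo : sl.start + hi] = True
    altered &= ~genome.chrom_mask(cfg.exclude_chroms)
    regions: list[int] = []
    i = 0
    n = genome.n_bins
    lengths = genome.lengths
    while i < n:
        if not altered[i]:
            i += 1
            continue
        j = i
        acc = int(lengths[i])
        while j + 1 < n and altered[j + 1] and genome.chrom[j + 1] == genome.chrom[i]:
            j += 1
            acc += int(lengths[j])
        regions.append(acc)
        i = j + 1
    return regions


def classify_profile(
    segments: SegmentSet, genome: GenomeBins, config: EstimatorConfig | None = None
) -> str:
    """Normal / unclear / aberrant CNA-profile call.

    A profile with no altered territory (outside the excluded chromosomes)
    is normal.  A single altered region shorter than the single-region
    threshold, or several regions whose summed length stays below the
    total-altered threshold, is unclear; anything at or above the thresholds
    is aberrant.
    """
    cfg = config or EstimatorConfig()
    regions = _altered_regions(segments, genome, cfg)
    if not regions:
        return PROFILE_NORMAL
    if len(regions) == 1:
        if regions[0] < cfg.single_region_mb * 1e6:
            return PROFILE_UNCLEAR
        return PROFILE_ABERRANT
    if sum(regions) < cfg.total_altered_mb * 1e6:
        return PROFILE_UNCLEAR
    return PROFILE_ABERRANT


def classify_ctm(
    tgf: float, profile_class: str, config: EstimatorConfig | None = None
) -> str:
    """Final CTM label from the TGF value and the CNA-profile class.

    TGF at or below the floor (default 0.05) means no detectable tumor
    genome: Normal CTM whatever the profile looks like.  Above the floor the
    profile class decides; an (unusual) normal profile with non-zero TGF is
    still reported as Normal CTM.
    """
    cfg = config or EstimatorConfig()
    if not 0.0 <= tgf <= 1.0:
        raise ValueError("tgf must be in [0, 1]")
    if tgf <= cfg.tgf_floor:
        return CTM_NORMAL
    if profile_class == PROFILE_ABERRANT:
        return CTM_ABERRANT
    if profile_class == PROFILE_UNCLEAR:
        return CTM_UNCLEAR
    return CTM_NORMAL


def qc_filter(aligned_reads: int, config: EstimatorConfig | None = None) -> bool:
    """Sample-level sequencing QC: pass iff aligned reads reach the minimum."""
    cfg = config or EstimatorConfig()
    if aligned_reads < 0:
        raise ValueError("aligned_reads must be non-negative")
    return aligned_reads >= cfg.min_aligned_reads


def compute_eat(
    qc_score: float,
    dna_index: float,
    n_cells: int,
    threshold: float = 30.0,
) -> WetLabQC:
    """Effectively amplifiable template: QC score x DNAIndex x cell count."""
    if qc_score < 0 or dna_index < 0 or n_cells < 0:
        raise ValueError("inputs must be non-negative")
    eat = qc_score * dna_index * n_cells
    return WetLabQC(qc_score, dna_index, int(n_cells), eat, eat >= threshold)
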