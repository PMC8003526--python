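# Methods

## Problem setting

A circulating tumor microembolus (CTM) is a cluster of cells that contains
malignant cells mixed with normal accessory cells in unknown proportion.
Low-pass whole-genome sequencing (lpWGS, ~0.02–0.09×) of a CTM yields
megabase-scale read-depth profiles from which copy-number alterations (CNAs)
can be called, and from the *amount* of aberration a tumor genome fraction
(TGF) can be inferred.  The TGF is a biased readout of the biologically
interesting quantity — the tumor *cell* fraction (TF) — because it depends
on how aberrant the tumor genome is and on sequencing coverage.  The package
therefore separates three layers: (i) TGF estimation from binned counts,
(ii) a calibration experiment with known mixtures that maps TGF to TF, and
(iii) downstream sample classification and CNA comparison.

## Genome representation

All analysis happens on a fixed tiling of an hg19-like genome (chr1–chr22 and
chrX; chrY is excluded, reflecting the female breast-cancer setting) into
1 Mb windows — 3,053 bins over 3.04 Gb.  Coordinates are 0-based, half-open.
Segment↔bin conversion uses the bin-midpoint rule: a bin belongs to the
segment covering its midpoint.  This makes interval algebra exact at the
resolution the data actually support and is idempotent under
rasterize→merge→rasterize.  chr19 is masked throughout the estimator and the
comparisons because of its strong GC-associated deletion bias in this data
type; it is also removed from denominators when genome fractions are
reported.

## Synthetic data generator

The generator defines the study conditions; its defaults are not tuning
knobs.

**Cell-line profiles.**  Two virtual lines emulate a mildly and a strongly
hyperdiploid breast-cancer genome: random, collision-free segmental events
whose copy levels are raised stepwise and whose lengths are fine-tuned until
the length-weighted mean copy number equals 2.65 and 4.2 exactly (tolerance
±0.05 is asserted; the construction lands within rounding).  Each profile
contains at least one gain and one loss.  Event counts and length ranges
(18 events of 30–120 Mb; 26 of 50–150 Mb) were chosen so that the required
mean copy is reachable with per-event copies ≤ 7, the estimator's state
cap.

**Read counts.**  A sample with tumor fraction *tf* has per-bin expected
weight ∝ bin_length × (tf·c_tumor + (1 − tf)·2); counts are one multinomial
draw over bins, so the printed total-read regime (415,519–1,955,726 aligned
reads, drawn log-uniformly) is conserved exactly.  No GC or mappability bias
is simulated by default; optional Dirichlet-multinomial overdispersion and
an optional chr19 deflation factor exist so the corresponding rules can be
exercised.  The 10-cell discreteness of real micromanipulated mixtures is
not modelled: *tf* is treated as exact, as the calibration model also
assumes.

**Titrations.**  2 cell lines × TF ∈ {0, 0.1, …, 0.8, 1.0} × 3 replicates =
60 samples, each with its own seed derived deterministically from the master
seed (replicate coverages are re-drawn independently; the real experiment's
coverage-to-replicate pairing is unknown).

**Patient scenarios.**  Per patient: a hyperdiploid tumor profile T2 (mean
copy drawn from 2.5–3.5, 16 events), a pseudodiploid twin T1 that drops up
to 2 events, an empty stromal profile, and 2–14 CTMs.  Each CTM inherits a
random subset of tumor events (per-event probability drawn from 0.5–0.9),
gains 1–4 private bin-aligned events placed in territory free of tumor
events, and mixes with normal cells at TF ~ U(0.08, 0.48); tumor samples
are simulated at purity 0.6–0.95 (microdissected fractions are not perfectly
pure).  To make the cross-patient recurrent-private screen exercisable, a
fixed hotspot (chr2:60–80 Mb) is kept free of tumor events in every patient
and private events are placed inside it with probability 0.4, spanning the
available run — emulating a recurrent dissemination-associated region.  The
generator emits a per-bin truth labelling (shared / tumor-private /
CTM-private / unaltered) computed by direct per-bin evaluation of the same
consensus rules the comparison module implements, which the test suite uses
as a round-trip oracle.

What passing tests on these data do **not** show: robustness to GC/
mappability artifacts, whole-genome-amplification noise, replication-timing
waves, or real breakpoint fine structure.  The generator's noise is pure
multinomial sampling, which at 0.04× coverage yields ~0.09 sd on per-bin
log2 ratios — comparable to, but cleaner than, real lpWGS noise.

## TGF estimator

Binned counts are normalized against a reference track (an ideal
length-proportional diploid expectation by default, standing in for a
normal-panel median) as log2 ratios, median-centered.  Internally the
estimator re-centers so the length-weighted linear-scale mean is 1, matching
the model's normalisation by the sample's mean copy.

The model: tumor copy states c ∈ {0,…,7} follow a hidden Markov chain with
exchangeable transitions (self-transition 0.998) over the unmasked bins;
emissions are Gaussian with shared variance around

  μ_c = log2( (2n + (1−n)c) / (2n + (1−n)P) ),

the expected ratio for a mixture of normal fraction *n* and a tumor of mean
ploidy *P* (mixture copy is floored at 0.01 so the homozygous-deletion state
stays finite).  For each candidate ploidy (fixed for titrations: the cell
line's known mean copy; a grid {2, 2.65, 3, 3.5, 4, 4.2} of initial values
in clinical mode) and each normal-fraction initialisation (0.1–0.9), EM
alternates forward–backward E-steps with M-step updates of *n* (bounded 1-D
minimisation of the expected squared residual), of *P* (same, clinical mode
only), and of the shared variance (floored at 1e-7 so noise-free input does
not degenerate).  At least 3 iterations, relative tolerance 1e-6, cap 60;
all lattice points are screened for 4 iterations and the best 5 refined to
convergence.  TGF = 1 − n̂ of the highest-likelihood candidate; exact
likelihood ties go to the larger normal fraction (the conservative choice,
which also reproduces the underestimation at TF = 1 that purity estimators
of this family show: at high TF the mixture ladder is consistent with more
than one (n, P) reading).

Three safeguards address the identifiability structure of purity/ploidy
inference from relative ratios:

- **Ploidy self-consistency:** candidates whose decoded mean copy state
  differs from their ploidy by more than 0.5 are discarded (unless none
  survive).  This suppresses genome-doubling re-interpretations of the
  copy ladder.
- **Detection floor:** decoded altered territory below 25 bins (25 Mb) is
  relabelled neutral — at 0.04× coverage a handful of outlier bins cannot
  pin the normal fraction, and without this rule a flat stromal profile can
  be assigned an arbitrary TGF by two noise bins.
- **Flat-profile anchor:** a constant decoded path carries no aberration
  evidence and its absolute level is unidentifiable, so it is re-anchored
  to diploid and TGF is forced to exactly 0.

Gain/loss calls on the decoded segments are read relative to the modal
(length-weighted baseline) copy state, which is invariant across the
scale-degenerate solution families and keeps calls comparable between
samples of one patient.  Emission variance is shared across states;
per-state variances were rejected as unstable at this coverage.

**Classification.**  A profile with no altered territory (chr19 excluded)
is *normal*; one altered region (a maximal run of consecutive altered bins,
any call type) shorter than 125 Mb, or several regions summing to less than
375 Mb, is *unclear*; anything at or above those thresholds is *aberrant*
(the thresholds are exclusive: exactly 125/375 Mb counts as aberrant).  CTM
labels: TGF ≤ 0.05 → Normal CTM regardless of profile; above the floor the
profile class decides (aberrant → Aberrant CTM, unclear → Unclear CTM); the
unusual combination TGF > 0.05 with a normal profile — a case the rule table
leaves open — maps to Normal CTM, since a fraction without any supporting
alteration is not evidence of tumor content.  Samples under 400,000 aligned
reads fail QC.  Coverage is computed as reads × 150 bp / genome length
(single-read 150-cycle chemistry; configurable).  The effectively
amplifiable template, EAT = QC score × DNAIndex × cell count with pass
threshold 30, is provided as a wet-lab QC calculator.

## Agreement statistics

CCC uses population (1/n) moments: CCC = 2·cov / (var_x + var_y + Δμ²); the
implementation is tested against direct moment evaluation to 1e-12 and
satisfies CCC ≤ |r| and symmetry.  Bland–Altman reports mean difference and
mean ± k·sd limits (sample sd; k = 2 by default to match the
two-standard-deviations convention, 1.96 selectable) plus a least-squares
trend of differences on pair means.  `compare_estimates` scores one or two
per-sample tables against truth — the second table may be an external
tool's output, which is how a competing estimator is benchmarked without
re-implementing it.

## Calibration and inverse prediction

Model: logit(TGF*) = a + b·logit(TF*) + u_line + ε, with u ~ N(0, σu²),
ε_i ~ N(0, σe²/w_i), w_i = 1/MAE(coverage_i) (weight rule configurable to
1/MAE²), and p* = clamp(p, 0.005, 0.995) guarding boundary proportions.
Both response and predictor are logit-transformed: this keeps a bounded
response linear and makes (a, b) ≈ (0, 1) read as "TGF is an unbiased
readout".  The fit profiles REML over θ = σu²/σe², inverting the
random-intercept covariance by the Woodbury identity; with a single cell
line it falls back to WLS with σu² = 0 and a warning.  The MAE anchors
bundled as defaults are synthetic placeholders spanning 0.01–0.10×
coverage; users with an empirically measured error table should supply it.

Prediction for a new sample inverts the population line (u = 0), since a
CTM belongs to no calibration cell line: x̂ = (logit(TGF) − a)/b.  Intervals
invert the forward band g(x) ± z·s(x) numerically (Fieller-style root
finding; delta-method fallback if the band does not bracket), with band
variance var(â) + x²·var(b̂) + 2x·cov(â,b̂), plus σu² + σe²/w_new for the
prediction interval — the new sample's unknown line-like offset and its own
residual.  Back-transformation by the inverse logit keeps every bound in
(0, 1) and preserves interval nesting (PI ⊇ CI).

## Shared/private CNA comparison

All comparisons are at bin resolution on call tracks (loss/neutral/gain),
chr19 removed.  A bin is tumor-altered only if every available tumor sample
agrees on the alteration type (one tumor sample decides alone when the
pseudodiploid fraction is missing); it is *shared* if at least one CTM
carries the same type (amplitude is ignored: copy 3 and copy 5 are both
"gain"), *tumor-private* if no CTM matches, *CTM-private* if the tumor
consensus is unaltered but some CTM is altered.  Fractions divide labelled
bin length by total analyzable genome length (chr19 excluded from the
denominator for consistency).  The frequency screens flag bins whose gain
or loss frequency strictly exceeds the threshold (0.7 tissue, 0.5 CTM) and
merge contiguous flagged bins; the recurrent CTM-private screen keeps bins
altered in ≥55 % of all pooled CTMs that were never labelled shared in any
patient.  Correlation clustering computes Pearson correlations over jointly
unmasked bins and clusters the correlation matrix's rows with Euclidean
distance and complete linkage; constant profiles are dropped with a
warning, and sample ids are sorted so the layout is deterministic.

## Pipeline

`run_calibration_experiment` chains simulation → fixed-ploidy estimation →
agreement → calibration fit; `run_patient_analysis` chains cohort
simulation → clinical-mode estimation → CTM classification → TF prediction
→ overlap/frequency/clustering reports, with CONSORT-style accounting
(CTMs = QC-failed + Normal + Unclear + Aberrant).  Every output table
carries the package version, master seed and a config hash; the whole run
is byte-identical under a fixed seed.  Problem sizes used by the default
configuration — 60 titration samples and a 6-patient cohort with 2–14 CTMs
each — complete in about half a minute on one CPU; the simulation sizes in
the recovery experiments (repetition counts, seeds per grid point) were
chosen as the smallest that make the corresponding checks statistically
stable.

## Known limitations

- No GC/mappability correction or panel-of-normals beyond the ideal
  reference track; real data would need the bias layers the simulator
  deliberately omits.
- Purity/ploidy inference from relative coverage alone is not identifiable
  at high tumor fraction (scale-degenerate readings) or at very low tumor
  fraction (signal below noise); the safeguards above make failure modes
  conservative rather than impossible.  Clinical-mode accuracy on single
  CTMs is correspondingly rougher than fixed-ploidy titration accuracy.
- The calibration transfers only as far as the two virtual cell lines span
  the aberration spectrum; tumors with few CNAs can escape detection
  entirely, and allele-frequency (BAF) information is out of scope.
- Segment breakpoints are bin-quantised; events shorter than ~1 Mb are
  invisible by construction.
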