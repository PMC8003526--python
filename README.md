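# ctmtf — tumor fraction of circulating tumor microemboli from low-pass WGS

Circulating tumor microemboli (CTMs) are clusters of two or more cells shed
into the bloodstream by a tumor.  They are heterotypic: malignant cells are
mixed with normal "accessory" cells, so any bulk measurement on a CTM is
diluted by an unknown normal fraction.  `ctmtf` implements a complete,
tested pipeline for quantifying that dilution from low-pass whole-genome
sequencing (~0.02–0.09× coverage) copy-number data, for researchers working
on CTC/CTM genomics or on tumor-purity estimation from sparse sequencing:

1. **Synthetic titrations and patient scenarios** with known truth — mixtures
   of aneuploid genomes (mean copy number 2.65 and 4.2) with diploid cells on
   a tumor-fraction grid, and matched tumor/stroma/CTM sample sets.
2. **Tumor genome fraction (TGF) estimation.**  Reads are counted in 1 Mb
   bins, normalized to log2 ratios, and fitted with a normal-contamination
   copy-state hidden Markov model: for copy state *c*, normal fraction *n*
   and tumor ploidy *P*, the expected log2 ratio is

   ```
   mu_c = log2( (2n + (1 − n)c) / (2n + (1 − n)P) )
   ```

   Gaussian emissions share one variance; EM refines *n* (and, in clinical
   mode, *P*) from a grid of initializations, and TGF = 1 − n̂, forced to 0
   when the decoded path is constant.  Samples with fewer than 400,000
   aligned reads are excluded; chr19 is masked for its GC-driven deletion
   bias.
3. **Agreement statistics** — Lin's concordance correlation coefficient
   CCC = 2·cov(x,y) / (σx² + σy² + (μx − μy)²) and Bland–Altman limits of
   agreement (mean difference ± 2 sd), overall and per group, for scoring
   estimators against titration truth or against each other.
4. **Calibration from TGF to tumor fraction (TF).**  A weighted linear mixed
   model on the logit scale, logit(TGF) = a + b·logit(TF) + u_line + ε with
   a random intercept per cell line and weights 1/MAE(coverage) interpolated
   from a coverage-to-error curve; REML fit, and inverse estimation with
   confidence and prediction intervals for new samples.
5. **CTM classification** (TGF ≤ 0.05 → Normal CTM; otherwise by CNA profile
   class, where profiles are unclear below the 125 Mb single-region / 375 Mb
   total-alteration thresholds) and **shared/private CNA comparison** of CTMs
   against matched tumor profiles at bin resolution, alteration-frequency
   summaries (>70 % tissue, >50 % CTM), a cross-patient screen for recurrent
   CTM-private regions (≥55 % of pooled CTMs, never shared with tissue), and
   Pearson-correlation hierarchical clustering (Euclidean, complete linkage).

## Worked example

```sh
python examples/02_estimate_tgf.py
```

```
LINE361: multinomial counts at 800,000 reads (~0.04x coverage)
 true TF      TGF  ploidy     class
     0.0    0.000    2.65    normal
     0.2    0.200    2.65  aberrant
     0.4    0.406    2.65  aberrant
     0.6    0.597    2.65  aberrant
     0.8    0.802    2.65  aberrant
     1.0    0.999    2.65  aberrant
```

Each row is one simulated mixture of the mildly hyperdiploid virtual cell
line with diploid cells: the estimated TGF tracks the known mixing fraction
to within a few thousandths at 0.04× coverage, the pure-normal sample is
forced to exactly 0, and profiles with real alterations are classed
aberrant.  `examples/04_calibrate_and_predict.py` then fits the calibration
on a full 60-sample titration (CCC 0.9999, logit-scale intercept 0.016,
slope 1.001 on this synthetic data) and inverts it, and
`examples/05_patient_analysis.py` runs a six-patient cohort end to end,
printing per-patient stroma/tumor TGF, predicted CTM tumor fractions with
prediction intervals, shared/private alteration fractions, and the
recurrent CTM-private region the generator plants on chr2.

The same functionality is exposed as a thin CLI:

```sh
ctmtf run-all --seed 1 --out results/
ctmtf estimate-tgf --counts sample.counts.tsv --ploidy 2.65 --out sample
ctmtf fit-calibration --samples titration.tsv --out model.json
ctmtf predict-tf --model model.json --tgf-table ctms.tsv --out predictions.tsv
```

All file formats are plain text (BED-like segment TSVs, BedGraph-like bin
tables, JSON models); see `ctmtf --help`.

## Layout

- `src/ctmtf/genome.py` — 1 Mb genome tiling, segments, rasterization, with
  `io.py` for the text formats
- `src/ctmtf/simulate.py` — titration and patient-scenario generators
- `src/ctmtf/estimator.py` + `_hmm.py` — the TGF estimator and
  classification/QC rules
- `src/ctmtf/agreement.py` — CCC and Bland–Altman
- `src/ctmtf/calibration.py` — weighted mixed calibration and inverse
  prediction
- `src/ctmtf/ctm_compare.py` — shared/private calculus, frequency screens,
  clustering
- `src/ctmtf/pipeline.py`, `cli.py` — orchestration and the command line
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
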