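"""Fit the TGF-to-TF calibration and invert it for new samples.

The calibration is a weighted linear mixed model on the logit scale:
logit(TGF) = a + b logit(TF) + u_cellline + eps, with observation weights
1/MAE(coverage) from a coverage-to-error curve.  Prediction for a new
sample (a CTM from no calibration cell line) inverts the population line
and reports confidence and prediction intervals.
"""

from ctmtf.pipeline import RunConfig, run_calibration_experiment
from ctmtf.calibration import predict_tf
from ctmtf.genome import build_genome_bins

genome = build_genome_bins()
cal = run_calibration_experiment(RunConfig(master_seed=1), genome)
m = cal.model

print(f"titration: {len(cal.tgf_table)} samples, CCC(truth, TGF) = "
      f"{cal.agreement.ccc_overall:.4f}")
print(f"calibration (logit scale): intercept={m.intercept:.4f} "
      f"slope={m.slope:.4f}")
print(f"variance components: sigma_u^2={m.sigma_u2:.4g} (cell line), "
      f"sigma_e^2={m.sigma_e2:.4g} (residual)")
print(f"cell-line offsets (BLUPs): "
      f"{ {k: round(v, 4) for k, v in m.blups.items()} }")

print(f"\n{'TGF':>6} {'TF':>7} {'95% CI':>17} {'95% PI':>17}")
for tgf in (0.1, 0.2, 0.3, 0.5):
    p = predict_tf(m, tgf, coverage=0.04)
    print(f"{tgf:6.2f} {p.tf_hat:7.3f} "
          f"[{p.ci_low:6.3f}, {p.ci_high:6.3f}] "
          f"[{p.pi_low:6.3f}, {p.pi_high:6.3f}]")
print("\nA slope near 1 and intercept near 0 mean TGF is close to an")
print("unbiased readout of TF on these cell lines; the prediction interval")
print("(wider than the CI) is what a single new CTM should be judged by.")
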