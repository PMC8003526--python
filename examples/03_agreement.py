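"""Score agreement between true tumor fractions and TGF estimates.

Lin's concordance correlation coefficient (CCC) measures agreement around
the identity line; Bland-Altman limits of agreement summarise the paired
differences (mean +/- 2 sd).
"""

import numpy as np
import pandas as pd

from ctmtf.agreement import agreement_report, compare_estimates

rng = np.random.default_rng(0)
truth = pd.DataFrame({
    "sample_id": [f"s{i}" for i in range(60)],
    "true_tf": np.tile(np.repeat([0, .1, .2, .3, .4, .5, .6, .7, .8, 1.], 3), 2),
    "cell_line": np.repeat(["A", "B"], 30),
})

good = truth.assign(tgf=np.clip(truth.true_tf + rng.normal(0, .04, 60), 0, 1))
biased = truth.assign(tgf=np.clip(.25 + .6 * truth.true_tf + rng.normal(0, .15, 60), 0, 1))

rep_a, rep_b, winner = compare_estimates(
    good[["sample_id", "tgf"]], biased[["sample_id", "tgf"]], truth,
    group_col="cell_line",
)
for name, rep in [("accurate", rep_a), ("biased", rep_b)]:
    print(f"{name:>9}: CCC={rep.ccc_overall:.3f} "
          f"LoA=[{rep.ba.loa_low:+.3f}, {rep.ba.loa_high:+.3f}] "
          f"mean diff={rep.ba.mean_diff:+.3f}")
print(f"winner by CCC: table '{winner}' (the accurate estimator)")
print("\nPer cell line CCC:", {k: round(v, 3) for k, v in rep_a.ccc_by_group.items()})
print("A CCC near 1 with narrow limits of agreement means the estimator can")
print("be trusted across the whole titration range; a high correlation with")
print("a trend or offset (the biased table) is penalised by CCC.")
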