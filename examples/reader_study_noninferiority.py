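"""Full reader-study analysis on a synthesized two-arm score table.

Simulates 69 subjects scored on the seven anatomical landmarks by two
readers in two sessions, with a small true quality loss (0.15 points) in
the low-dose arm, then runs the complete statistical chain: aggregation,
inter-observer ICC, Shapiro-gated paired non-inferiority tests per item
(margin 0.5; 3.5 for the 7-item total), and dose accounting.
"""

import numpy as np

from radnoise import (DoseRecord, ReaderStudyConfig, aggregate_scores,
                      icc_inter_observer, noninferiority_table,
                      reduction_rate, synthesize_reader_scores)

cfg = ReaderStudyConfig(n_subjects=69, arm_shift=0.15,
                        sigma_subject=0.4, sigma_session=0.3)
table = synthesize_reader_scores(cfg, seed=1)
agg = aggregate_scores(table)

icc = icc_inter_observer(table)
print(f"inter-observer ICC (two-way random, absolute agreement): "
      f"{icc.icc_value:.3f} -> {icc.band} (n = {icc.n} images)")

result = noninferiority_table(agg)
print("\nnon-inferiority of low dose vs baseline (d = baseline - low):")
print(result[["n", "estimate", "ci_lower", "ci_upper", "margin", "test",
              "non_inferior"]].to_string(
                  float_format=lambda v: f"{v:.3f}"))

rec = DoseRecord("worked-example", baseline_ese=42.9, low_ese=21.2, group="C")
print(f"\nworked dose example: {rec.low_ese} / {rec.baseline_ese} uGy = "
      f"{reduction_rate(rec)}% of the baseline entrance skin exposure")
print("\nA CI upper bound below the margin concludes non-inferiority: a "
      "true 0.15-point loss sits well inside the 0.5-point margin.")
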