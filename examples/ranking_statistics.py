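"""Evaluation statistics for quality predictors on a model ensemble.

Simulates an ensemble of 100 models with known iRMSDs and two predictors
(one informative, one random), then prints ranking loss, combined
Z-scores, top-3 summed Z and quantile-based selection metrics for each.
"""

import numpy as np

from rnpqa.evaluation import (
    ZScorePanel,
    quantile_scores,
    ranking_loss,
    selection_metrics,
    topk_sum_z,
    z_casp16,
    zscores,
)

rng = np.random.default_rng(0)
n = 100
irmsd = rng.uniform(0.5, 25.0, size=n)
true_quality = 1.0 / (1.0 + irmsd)

good = true_quality + rng.normal(scale=0.02, size=n)  # informative predictor
rand = rng.normal(size=n)  # uninformative predictor

# combined Z over six metric channels (here simulated as noisy copies)
panel = ZScorePanel(*[zscores(true_quality + rng.normal(scale=0.01, size=n))
                      for _ in range(6)])
z = z_casp16(panel)

print(f"{'predictor':>10} {'RL':>7} {'top3 sum Z':>11} {'success':>8} "
      f"{'recall%':>8} {'avgQ':>7} {'bestQ':>7}")
for name, pred in (("good", good), ("random", rand)):
    rl = ranking_loss(true_quality, pred)
    t3 = topk_sum_z(pred, z, k=3)
    succ, rec, avg_q, best_q = selection_metrics(pred, irmsd, k=5)
    print(f"{name:>10} {rl:7.3f} {t3:11.2f} {succ:8.0f} {rec:8.1f} "
          f"{avg_q:7.1f} {best_q:7.1f}")

q = quantile_scores(irmsd)
print(f"\nbest model quantile = {q[np.argmin(irmsd)]:.0f} (always 100); "
      f"true-top set (Q>=99) has {int((q >= 99).sum())} model(s).")
print("An informative predictor drives ranking loss toward 0 and the "
      "selection quantiles toward 100.")
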