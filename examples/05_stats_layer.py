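"""The statistics layer on the study's printed group summaries.

Reproduces the penetrance comparison between two 5HT-targeting lines from
their printed means/SEMs, shows the Spearman variance gate + Box-Cox route,
and BH-adjusts a family of p-values.
"""

import numpy as np

from raphequant import stats

# summary-based Welch test from printed penetrance summaries
r = stats.welch_t_from_summaries(323.8, 43.3, 5, 166.8, 29.9, 5)
print(f"penetrance comparison: t({r.df:.3f}) = {r.statistic:.3f}, "
      f"p = {r.p:.3f} {r.stars}")
print("  (one line labels roughly twice as many marker-positive cells)")

# variance gate -> Box-Cox on right-skewed data
rng = np.random.default_rng(0)
fitted = np.repeat([10.0, 40.0, 160.0], 20)
values = np.array([rng.lognormal(np.log(f), 0.4) for f in fitted])
gate = stats.spearman_hetero_test(values - fitted, fitted)
print(f"variance gate: Spearman rho = {gate.statistic:.2f}, p = {gate.p:.2g}"
      f" -> {'transform' if gate.p < 0.05 else 'proceed untransformed'}")
fit = stats.boxcox(values)
print(f"Box-Cox MLE lambda = {fit.lmbda:.2f} "
      "(near 0 = log transform, as expected for log-normal spread)")

# BH adjustment of one comparison family
family = [stats.TestResult(f"region {i}", 2.0, 8.0, p)
          for i, p in enumerate([0.004, 0.021, 0.029, 0.034, 0.21])]
stats.adjust_family(family)
for t in family:
    print(f"  {t.name}: p = {t.p:.3f} -> adjusted {t.p_adjusted:.3f} {t.stars}")
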