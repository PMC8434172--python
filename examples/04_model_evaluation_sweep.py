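"""The multicriteria model-evaluation measure on a synthetic model.

Simulates a classifier whose correctness is positively associated with
its confidence level, then sweeps the CCL percentile cutoff p = 1..99.
At each p the dataset is limited to samples with CCL above the p-th
percentile and the measure m_p = a_p * (n_p/N) * t_p balances partial
accuracy, retained coverage and the confidence threshold. The model's
score is the maximum over p.
"""

import numpy as np

from usconf import evaluate_model

rng = np.random.default_rng(0)
N = 500
ccl = rng.beta(4, 2, N) * 3.0          # confidence levels in [0, 3]
correct = rng.random(N) < 0.55 + 0.15 * ccl

res = evaluate_model(ccl, correct)
opt = res.at_opt()
print(f"full-dataset accuracy: {correct.mean():.3f}")
print(f"m = {res.m:.3f} at p_opt = {res.p_opt}")
print(f"  partial accuracy a = {opt.a_p:.3f}")
print(f"  coverage n/N       = {opt.n_p / res.N:.1%}")
print(f"  CCL threshold t    = {opt.t_p:.3f}")
# Raising the cutoff drops low-confidence (more error-prone) samples, so
# partial accuracy exceeds the full-dataset accuracy at the optimum while
# coverage shrinks; m locates the best three-way trade-off.
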