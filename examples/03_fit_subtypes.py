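"""Fit the joint SVM / fuzzy-c-means mixture-of-experts and inspect it.

Four sparse linear experts each separate AD from CN while a fuzzy-c-means
term clusters the AD subjects; alternating minimization drives the joint
objective monotonically downward.  Hard subtype labels are the argmax of
the fitted memberships.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from admoe import (
    MOEConfig,
    fit_moe,
    generate_cohort,
    hard_assign,
    residualize_pipeline,
)
from admoe.selection import bezdek_partition_coefficient

density, _, truth, _ = generate_cohort(n_cn=200, n_ad=180, seed=42)
residuals, _ = residualize_pipeline(density)

config = MOEConfig(K=4, C=2.0**-3, t=2.0, seed=0)
model = fit_moe(residuals, config)
solution = hard_assign(model)

trace = model.objective_trace
print(f"objective: {trace[0]:.1f} -> {trace[-1]:.1f} "
      f"in {len(trace) - 1} outer iterations (non-increasing)")
print(f"Bezdek partition coefficient: "
      f"{bezdek_partition_coefficient(model.memberships):.3f} "
      "(1 = crisp, 0.25 = uniform at K=4)")
sizes = np.bincount(solution.labels, minlength=5)[1:]
print("subtype sizes:", dict(enumerate(sizes, start=1)))
ari = adjusted_rand_score(truth.labels("density"), solution.labels)
print(f"adjusted Rand index vs generator truth: {ari:.3f} "
      "(1 = exact recovery up to relabeling)")
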