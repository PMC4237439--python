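"""Prune the 64-rule grid to a compact, interpretable rule base.

Rules are ranked by activation-weighted contribution on a validation block
and removed greedily while validation RMSE stays within 1% of the full
model; the survivors are the sub-regions the data actually needs.
"""

import numpy as np

from tsimpact import DOMAINS, GeneratorConfig, fit_ts, generate_areas, prune, scores_matrix

areas = generate_areas(GeneratorConfig(seed=1))
X, y = scores_matrix(areas), areas["eur"].to_numpy()

rng = np.random.default_rng(1)
idx = rng.permutation(len(areas))
val, train = idx[:200], idx[200:]

model = fit_ts(X[train], y[train], DOMAINS, seed=1)
compact, report = prune(model, X[train], y[train], X[val], y[val])

print(f"full grid: {len(model.rules)} rules -> compact model: {len(compact.rules)} rules")
print(f"validation RMSE: {report.baseline_rmse / 100:.4f} -> {report.final_rmse / 100:.4f} "
      "(proportion scale)")
print("\nsurviving rules (D = highly deprived, - = non-deprived; "
      "domain order: " + " ".join(d[:2] for d in DOMAINS) + "):")
for rule in compact.rules:
    slopes = " ".join(f"{c:+.2f}" for c in rule.slopes)
    print(f"  {rule.pattern()}   intercept {rule.intercept:5.1f}   slopes {slopes}")

# Each surviving pattern names a deprivation context; its slopes say how the
# under-attainment rate responds to each domain within that context.
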