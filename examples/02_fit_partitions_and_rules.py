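"""Learn fuzzy partitions and fit the full 64-rule TS model.

Fuzzy c-means on the joint standardized score space, projected per domain,
yields a "non-deprived" / "highly deprived" fuzzy set pair per domain; the
2^6 = 64 antecedent combinations each carry a local linear model fitted by
weighted least squares.
"""

from tsimpact import (
    CORE_BOUNDS,
    DOMAINS,
    GeneratorConfig,
    fit_ts,
    generate_areas,
    scores_matrix,
    summarize_coefficients,
)

areas = generate_areas(GeneratorConfig(seed=1))
X, y = scores_matrix(areas), areas["eur"].to_numpy()

model = fit_ts(X, y, DOMAINS, seed=1)

print("learned core cut-off points (configured generative values in brackets):")
for part in model.partitions:
    a, b = CORE_BOUNDS[part.domain_name]
    print(f"  {part.domain_name:12s} low [0, {part.a:5.2f}]  ({a:5.2f})   "
          f"high [{part.b:5.2f}, 100]  ({b:5.2f})")

print(f"\nrules fitted: {len(model.rules)}")
print("\nacross-rule coefficient summary (percentage points per score unit):")
print(summarize_coefficients(model).round(2).to_string())

# The Minimum/Maximum rows show how strongly a domain's effect varies between
# sub-regions: a domain can raise under-attainment in one deprivation context
# and lower it in another.
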