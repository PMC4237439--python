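"""Generate a synthetic small-area deprivation cohort.

Builds the default 1896-area table: six correlated domain scores per area
(0-100 deprivation scale, bimodal around the published core cut-offs) and an
education under-attainment rate (eur, percent) produced by a known 8-rule
ground-truth model plus noise.
"""

from tsimpact import CORE_BOUNDS, DOMAINS, GeneratorConfig, generate_areas, scores_matrix

cfg = GeneratorConfig(seed=1)
areas = generate_areas(cfg)

print(areas.head().round(2).to_string(index=False))
print(f"\n{len(areas)} areas; mean under-attainment {areas['eur'].mean():.1f}% "
      f"(sd {areas['eur'].std():.1f})")

X = scores_matrix(areas)
print("\nfraction of areas inside each published core (low / high):")
for j, name in enumerate(DOMAINS):
    a, b = CORE_BOUNDS[name]
    print(f"  {name:12s} {(X[:, j] <= a).mean():.2f} / {(X[:, j] >= b).mean():.2f}")

# Every domain keeps substantial mass in both its non-deprived and highly
# deprived core, which is what lets fuzzy c-means rediscover the cut-offs.
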