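# Methods

This note records the modelling choices behind `tsimpact`: the TS fuzzy
system, how its pieces are estimated, what the synthetic cohorts do and do
not emulate, and the numerical conventions.

## Fuzzy partitions

Each deprivation domain is described by two overlapping fuzzy sets,
*non-deprived* with core [0, a] and *highly deprived* with core [b, 100]
(membership exactly 1 on the core), joined by Gaussian flanks
μ(x) = exp(−(x−edge)²/2σ²) outside it. Gaussian flanks were chosen over
complementary linear ones because intermediate areas genuinely belong to
both categories at once — a score between the cores can have, say, degree
0.3 in the low set and 0.8 in the high set simultaneously; triangular
complementary memberships cannot express that.

Partitions are learned in three steps:

1. **Fuzzy c-means** (Bezdek alternating optimization; fuzzifier m = 2,
   tolerance 1e-6, max 300 iterations, seeded initial memberships, optional
   multi-start keeping the lowest objective) on the jointly min–max
   standardized score matrix. Min–max standardization equalizes each
   domain's leverage on the Euclidean distances. A data point coincident
   with a prototype receives full membership in that cluster — the standard
   singularity rule.
2. **Prototype projection.** Each prototype is projected onto each domain
   axis. With two clusters the two coordinates act directly as the low/high
   cluster positions v_l < v_h; with more clusters the coordinates are
   split into a low and a high group by the optimal 1-D two-group
   (k-means-style) split and the group means are used. The multi-prototype
   variant exists because a two-cluster fit organises areas along a single
   general-deprivation gradient, and a domain whose geography runs against
   that gradient (poor access to services in otherwise affluent rural
   areas) then projects a meaningless low/high split; one prototype per
   data sub-region fixes that.
3. **Core extraction and flanks.** Along each axis the 1-D FCM membership
   curve between v_l and v_h is known in closed form; the low core edge a is
   the largest score whose projected low membership is ≥ 0.95 (symmetric
   for b). Flank widths are fitted by least squares to the decaying stretch
   of that projected curve (`flank_mode="projected"`, the default), or set
   to a fraction of the extracted core gap (`flank_mode="gap_fraction"`),
   which keeps each rule's influence concentrated in its own sub-region and
   is used in the parameter-recovery experiment.

## The rule base and its estimation

The initial rule base is the full 2^d grid over the per-domain label pairs
(64 rules for six domains), ordered lexicographically with domains in
alphabetical order (access, community, environment, health, housing,
income) and "low" before "high".

Consequents are estimated per rule by weighted least squares. Two weighting
conventions are provided:

* `weighting="normalized"` (default): observation weights are the rule's
  normalized firing strengths v_i(x). This minimizes each rule's share of
  the global prediction error.
* `weighting="membership"`: weights are the raw membership products w_i(x).
  Points on the boundary between sub-regions — whose outcome is a blend of
  neighbouring local models — are down-weighted, which keeps each local
  model unbiased for its own sub-region. This is the estimator used when
  the goal is interpreting individual rule coefficients (e.g. the recovery
  experiment), at a small cost in global fit.

A rule whose total weight mass falls below d + 2 keeps zero slopes and a
weighted-mean intercept: an unsupported sub-region should not extrapolate.
Ill-conditioned local designs (condition number > 1e10) fall back to a
ridge of 1e-6 on the weighted normal equations. A single global
least-squares solve over all rules (`joint=True`) is available; it is the
better predictor once the rule base is compact, but with the full 64-rule
grid it is heavily over-parameterized and is not the default.

Coefficient confidence intervals use the weighted-regression convention
with effective sample size n_i = Σ v_i and df = n_i − (d+1) (t quantiles);
a seeded nonparametric bootstrap is the robust alternative. With df ≤ 0 the
interval is reported as unbounded with a warning.

## Rule selection

Rule importance is the mean over a validation block of v_i(x)·|y_i(x)| —
how strongly the rule fires times the magnitude of what it asserts. Pruning
visits rules in ascending importance (computed once on the full model) and
accepts a removal only if the re-fitted reduced model's validation RMSE
stays within a tolerance (default 1%) of the full model's; elimination
stops at `min_rules`.

An important empirical property of this model class, found during
development and verified in the tests: the global-RMSE guard alone cannot
pin down the *identity* of the final rules. The x-dependent blend of two
neighbouring local models is flexible enough to absorb a removed rule's
sub-region at sub-noise cost, so even generative rules can be eliminated
with almost no validation penalty. What is robust is the importance
*ranking*: on cohorts generated from 8 rules, those 8 occupy the top 8
ranks. The recovery experiment therefore prunes with `min_rules=8`; the
scientific claim is "the generative rules are the 8 most important ones and
their coefficients are recovered", not "the RMSE guard alone stops at 8".

## MiD and CoD

MiD fuses the rules' unit-normalized slope vectors with the normalized
firing strengths; its Euclidean norm is therefore at most 1 (convex
combination of unit vectors), its sign carries the effect direction, and it
is continuous in x. A support-starved rule with an all-zero slope vector
contributes the zero vector (unit normalization is undefined at zero, and
silently dropping the rule would break the convex-weight accounting). CoD
is exactly MiD times the observed score.

Contribution shares divide CoD by Σ|CoD| (signed shares; the absolute
shares sum to 1 whenever any contribution is non-zero); dividing by the
predicted outcome instead is available as an option. The strongest domain
is the argmax of |MiD| with ties resolved in canonical domain order and an
explicit "none" sentinel when every component is zero.

## Evaluation protocol

The cohort of n areas is split into train/validation/test blocks of fixed
sizes (1400/200/296 for n = 1896), nine times, by rotating a single seeded
permutation by n // 9 positions per fold — with nine 296-area test blocks
the test sets necessarily overlap across folds; within a fold the blocks
are disjoint and exhaust the cohort. RMSE is reported on the 0–1 proportion
scale; the across-fold 95% CI is mean ± t₀.₉₇₅,₈·sd/√9. The linear baseline
is ordinary least squares (statsmodels) on the six domain scores, fitted on
train+validation of each fold (the TS pipeline consumes both blocks) and
scored on the same test blocks.

## The synthetic cohorts

**Default cohort** (`GeneratorConfig()`, n = 1896). Scores are a Gaussian
copula over per-domain two-component truncated-normal mixtures: a
non-deprived and a highly deprived component per domain, coupled by a
latent correlation of 0.65 among the socio-economic domains (community,
health, housing, income) and 0.40 for access and environment, with
P(high) = 0.40. Component centres are placed by inverting the FCM
projection relation around the published core cut-offs, pushed outward by a
factor 1.25 to compensate for the inward pull of soft memberships, and
their locations are solved so the *realized* (truncation-adjusted) means
hit the placement — so a two-cluster FCM fit on the generated scores
rediscovers the configured cut-offs to within a few score units. Outcomes
are the 8-rule ground-truth TS model (antecedent patterns over the six
domains; slopes inside realistic per-domain ranges; intercepts calibrated
once so the cohort mean lands near 22.7%) plus Gaussian noise of 2
percentage points, clipped to [0, 100]. Truth flanks default to half the
core gap, giving broadly overlapping linguistic terms.

**Recovery cohort** (`recovery_config()`, n = 1900). Designed for
parameter identifiability rather than realism: each area first draws one of
the 8 generative antecedent patterns (uniformly) and samples every domain
from the component that pattern names; symmetric wide cores (25, 45),
independent within-cluster variation, well-separated components
(separation 2.2, variance-preserving floor 9, sds 8/12) and near-crisp
truth flanks (σ = 5). Under the default correlated cohort even an oracle
estimator (true region assignment + per-cluster OLS) misses the ±0.1
per-slope band in roughly a fifth of replicates — correlation-inflated
variance, not method error — so the recovery experiment is run where the
question is statistically answerable. The pipeline there uses c = 8
clusters, membership weighting and gap-fraction flanks, all public options.

**What the generator does not emulate:** real Welsh geography, spatial
autocorrelation, the heavy right skew of some real domain distributions,
measurement error in the scores, and any real linkage artefacts. Passing
tests therefore demonstrate correctness and statistical behaviour of the
method, not substantive findings about any real cohort.

## Numerical conventions and limitations

* Outcomes are percentage points (0–100) internally; RMSE is divided by
  100 at reporting time.
* Firing strengths that underflow to zero for every rule (possible only
  after pruning) fall back to a uniform split over the maximal rules, with
  a warning.
* Dominant-rule and strongest-domain ties resolve to the lowest rule id /
  first canonical domain.
* Model and partition files are plain text with `repr` floats, so
  round-trips are bit-exact.
* Problem sizes in the test suite (cohorts of 400–1900 areas, 2–9 folds,
  20 recovery replicates) were chosen so the full pipeline is exercised at
  the study's published scale while each experiment stays comfortably
  within interactive runtimes.
* Known limitations: with the full 64-rule grid and wide flanks the
  default per-rule estimator lets weakly-firing rules dilute predictions
  near core centres (visible as a cross-validated RMSE ~2x the noise floor
  on the default cohort; the 64-rule un-pruned fit bottoms out near 0.041
  against a 0.020 floor, the pruned pipeline near 0.044); no antecedent
  tuning (membership parameters are never optimized against the outcome);
  two linguistic terms per domain only.
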