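"""Synthetic small-area deprivation cohorts.

The restricted study data (per-LSOA deprivation domain scores linked to
education under-attainment rates) cannot be redistributed, so this module
generates structurally comparable tables from a *known* sparse TS model:

* six domain scores per area (Income, Health, Access, Housing, Environment,
  Community), each on the 0-100 scale, drawn from a two-component truncated-
  normal mixture per domain (a "non-deprived" and a "highly deprived"
  component, each centred inside the corresponding published core interval)
  coupled across domains by a Gaussian copula;
* an outcome (education under-attainment rate, percent) produced by
  evaluating a configurable ground-truth TS rule base at the scores and
  adding Gaussian noise.

Because the generative rule base is known, every downstream stage --
partition recovery, consequent estimation, rule pruning, MiD/CoD -- can be
tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .model import HIGH, LOW, Rule, TSModel, predict
from .partition import partitions_from_bounds

#: canonical (alphabetical) domain order used throughout the package
DOMAINS = ("access", "community", "environment", "health", "housing", "income")

#: column order of the external CSV representation
CSV_COLUMNS = ("area_id", "income", "health", "access", "housing", "environment", "community", "eur")

#: published core cut-off points (a, b): low core [0, a], high core [b, 100]
CORE_BOUNDS = {
    "access": (14.66, 26.05),
    "community": (12.24, 36.63),
    "environment": (18.80, 25.91),
    "health": (13.14, 35.20),
    "housing": (14.77, 31.77),
    "income": (11.71, 36.56),
}

# Level of the projected-membership curve that defines a core edge; the
# component placement below inverts that relation so a 2-cluster FCM fit on
# the generated scores rediscovers the configured cores.
_R_CORE = (0.05 / 0.95) ** 0.5

# Soft FCM memberships pull projected prototypes toward the grand mean, so the
# component centres are pushed outward from the core-gap midpoint by this
# factor to compensate (set so recovered cut-offs land near the configured
# ones on the default cohort).
_SEPARATION = 1.25


def _component_means(a: float, b: float, separation: float = _SEPARATION,
                     floor: float = 1.0) -> tuple[float, float]:
    """Place the low/high component centres so FCM projection recovers (a, b).

    ``floor`` keeps a component's realized mean away from the scale ends so
    its within-cluster variance is not destroyed by truncation.
    """
    low = (a - _R_CORE * b) / (1.0 - _R_CORE)
    high = (b - _R_CORE * a) / (1.0 - _R_CORE)
    mid = (low + high) / 2.0
    low = mid + separation * (low - mid)
    high = mid + separation * (high - mid)
    return max(low, floor), min(high, 100.0 - floor)


def _truncnorm_with_mean(target_mean: float, sd: float) -> tuple[float, float, float, float]:
    """Truncated-normal parameters on [0, 100] whose realized mean hits target.

    Truncation at the scale ends shifts the mean away from the location
    parameter (strongly so for components near 0), so the location is solved
    for numerically; returns (a, b, loc, scale) in scipy's convention.
    """
    from scipy.optimize import brentq

    def realized(loc: float) -> float:
        return stats.truncnorm.mean((0.0 - loc) / sd, (100.0 - loc) / sd, loc=loc, scale=sd)

    lo_bracket, hi_bracket = -6.0 * sd, 100.0
    target = float(np.clip(target_mean, realized(lo_bracket) + 1e-6, realized(hi_bracket) - 1e-6))
    loc = brentq(lambda m: realized(m) - target, lo_bracket, hi_bracket, xtol=1e-6)
    return (0.0 - loc) / sd, (100.0 - loc) / sd, loc, sd


def default_correlation(domains: tuple[str, ...] = DOMAINS) -> np.ndarray:
    """Default latent score correlation: a general deprivation gradient.

    Strong positive correlation (0.65) among the socio-economic domains
    (community, health, housing, income) and weaker coupling (0.40) for
    access and environment, whose geography differs from the rest.
    """
    core = {"community", "health", "housing", "income"}
    d = len(domains)
    C = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            rho = 0.65 if (domains[i] in core and domains[j] in core) else 0.40
            C[i, j] = C[j, i] = rho
    return C


#: ground-truth antecedent patterns, one per rule, in canonical domain order
#: (access, community, environment, health, housing, income); True = high
_TRUTH_PATTERNS = [
    (0, 0, 0, 0, 0, 0),
    (1, 0, 0, 0, 0, 0),
    (0, 0, 1, 0, 0, 0),
    (1, 0, 0, 0, 1, 0),
    (1, 0, 1, 0, 0, 0),
    (0, 1, 0, 1, 1, 1),
    (0, 1, 1, 1, 1, 1),
    (0, 1, 0, 1, 0, 1),
]

#: ground-truth consequents: intercept followed by slopes in canonical order.
#: Slopes sit inside the published per-domain coefficient ranges; intercepts
#: are calibrated so the default cohort mean outcome lands near 22.7%.
_TRUTH_COEFFICIENTS = [
    (8.1, 0.05, 0.18, -0.05, 0.08, 0.15, 0.70),
    (7.8, 0.28, 0.40, 0.02, 0.32, 0.05, 0.55),
    (8.2, -0.10, 0.05, 0.28, 0.10, 0.20, 0.55),
    (9.9, 0.10, -0.10, 0.15, 0.50, 0.10, 0.10),
    (7.8, 0.32, 0.10, 0.20, 0.10, 0.05, 0.28),
    (8.8, 0.15, -0.20, -0.10, 0.28, 0.10, 0.28),
    (9.6, -0.20, -0.30, -0.26, 0.30, 0.22, 0.40),
    (7.8, 0.05, 0.10, 0.05, 0.22, 0.08, 0.15),
]


def default_truth_rules() -> list[Rule]:
    """The 8-rule generative model used as the default ground truth."""
    rules = []
    for i, (pattern, coefs) in enumerate(zip(_TRUTH_PATTERNS, _TRUTH_COEFFICIENTS)):
        antecedent = tuple(HIGH if flag else LOW for flag in pattern)
        rules.append(
            Rule(rule_id=i, antecedent=antecedent, intercept=coefs[0],
                 slopes=np.array(coefs[1:], dtype=float))
        )
    return rules


@dataclass
class GeneratorConfig:
    """Everything needed to generate a reproducible synthetic cohort."""

    n_areas: int = 1896
    domains: tuple[str, ...] = DOMAINS
    core_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CORE_BOUNDS)
    )
    truth_rules: list[Rule] = field(default_factory=default_truth_rules)
    noise_sd: float = 2.0
    correlation: np.ndarray = field(default_factory=default_correlation)
    p_high: float = 0.40
    low_sd: float = 5.0
    high_sd: float = 10.0
    component_separation: float = _SEPARATION
    component_floor: float = 1.0
    pattern_weights: np.ndarray | None = None
    truth_flank: float | dict[str, float] | None = None
    seed: int = 0

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def validate(self) -> None:
        if self.n_areas < 1:
            raise ConfigurationError("n_areas must be at least 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0 < self.p_high < 1:
            raise ConfigurationError("p_high must lie strictly between 0 and 1")
        for name in self.domains:
            if name not in self.core_bounds:
                raise ConfigurationError(f"missing core bounds for domain {name!r}")
            a, b = self.core_bounds[name]
            if not (0 <= a < b <= 100):
                raise ConfigurationError(f"{name}: core bounds must satisfy 0 <= a < b <= 100")
        C = np.asarray(self.correlation, dtype=float)
        d = self.n_domains
        if C.shape != (d, d):
            raise ConfigurationError(f"correlation matrix must be {d}x{d}")
        if not np.allclose(C, C.T):
            raise ConfigurationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ConfigurationError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ConfigurationError("correlation matrix must be positive semi-definite")
        if not self.truth_rules:
            raise ConfigurationError("truth_rules must be non-empty")
        if self.pattern_weights is not None:
            w = np.asarray(self.pattern_weights, dtype=float)
            if w.shape != (len(self.truth_rules),) or w.min() < 0 or w.sum() <= 0:
                raise ConfigurationError(
                    "pattern_weights must be non-negative, one per truth rule"
                )
        for rule in self.truth_rules:
            if len(rule.antecedent) != d:
                raise ConfigurationError(f"rule {rule.rule_id}: antecedent length != n_domains")
            if not rule.is_fitted:
                raise ConfigurationError(f"rule {rule.rule_id}: truth rules need coefficients")

    def truth_model(self) -> TSModel:
        """The generative TS model (configured partitions + truth rules).

        ``truth_flank`` controls the Gaussian flank width of the generative
        fuzzy sets; the default (half the core gap) gives broadly overlapping
        linguistic terms, smaller values give near-crisp sub-regions.
        """
        bounds = {name: self.core_bounds[name] for name in self.domains}
        parts = partitions_from_bounds(bounds, self.truth_flank)
        rules = [
            Rule(r.rule_id, r.antecedent, r.intercept, np.array(r.slopes, dtype=float))
            for r in self.truth_rules
        ]
        return TSModel(self.domains, parts, rules, fitted=True)


def _mixture_ppf(u: np.ndarray, a: float, b: float, p_high: float,
                 low_sd: float, high_sd: float,
                 separation: float = _SEPARATION,
                 floor: float = 1.0) -> np.ndarray:
    """Quantile function of the per-domain two-component truncated-normal mixture."""
    mu_low, mu_high = _component_means(a, b, separation, floor)
    grid = np.linspace(0.0, 100.0, 2001)
    cdf = np.zeros_like(grid)
    for mu, sd, wgt in ((mu_low, low_sd, 1.0 - p_high), (mu_high, high_sd, p_high)):
        ta, tb, loc, scale = _truncnorm_with_mean(mu, sd)
        cdf += wgt * stats.truncnorm.cdf(grid, ta, tb, loc=loc, scale=scale)
    # strictly increasing for interpolation
    cdf = np.maximum.accumulate(cdf) + np.arange(grid.size) * 1e-12
    cdf /= cdf[-1]
    return np.interp(u, cdf, grid)


def _component_ppf(u: np.ndarray, mu: float, sd: float) -> np.ndarray:
    ta, tb, loc, scale = _truncnorm_with_mean(mu, sd)
    return stats.truncnorm.ppf(u, ta, tb, loc=loc, scale=scale)


def generate_scores(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Correlated domain scores, shape (n_areas, n_domains), canonical order.

    Default mode: each domain is an independent (copula-coupled) mixture of
    its low/high component.  With ``pattern_weights`` set, each area first
    draws one of the truth-rule antecedent patterns and every domain samples
    from the component that pattern names -- concentrating the cohort in the
    generative sub-regions, the regime used for parameter-recovery studies.
    """
    C = np.asarray(config.correlation, dtype=float)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(config.n_domains))
    Z = rng.standard_normal((config.n_areas, config.n_domains)) @ L.T
    U = stats.norm.cdf(Z)
    X = np.empty_like(U)
    if config.pattern_weights is None:
        for j, name in enumerate(config.domains):
            a, b = config.core_bounds[name]
            X[:, j] = _mixture_ppf(U[:, j], a, b, config.p_high,
                                   config.low_sd, config.high_sd,
                                   config.component_separation,
                                   config.component_floor)
        return X

    w = np.asarray(config.pattern_weights, dtype=float)
    choice = rng.choice(len(config.truth_rules), size=config.n_areas, p=w / w.sum())
    patterns = np.array(
        [[lab == HIGH for lab in rule.antecedent] for rule in config.truth_rules]
    )
    is_high = patterns[choice]
    for j, name in enumerate(config.domains):
        a, b = config.core_bounds[name]
        mu_low, mu_high = _component_means(a, b, config.component_separation,
                                           config.component_floor)
        X[:, j] = np.where(
            is_high[:, j],
            _component_ppf(U[:, j], mu_high, config.high_sd),
            _component_ppf(U[:, j], mu_low, config.low_sd),
        )
    return X


def generate_areas(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic area table.

    Returns a DataFrame with columns ``area_id``, the six domain scores (in
    the external CSV order: income, health, access, housing, environment,
    community) and ``eur``, the education under-attainment rate in percent.
    The outcome is the ground-truth TS model evaluated at the scores plus
    Gaussian noise, clipped to [0, 100].  Fully reproducible from the seed.
    """
    if config is None:
        config = GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    X = generate_scores(config, rng)
    truth = config.truth_model()
    y = predict(truth, X) + rng.normal(0.0, config.noise_sd, size=config.n_areas)
    y = np.clip(y, 0.0, 100.0)

    frame = pd.DataFrame(X, columns=list(config.domains))
    frame.insert(0, "area_id", [f"A{i:05d}" for i in range(config.n_areas)])
    frame["eur"] = y
    return frame[list(CSV_COLUMNS)]


def scores_matrix(areas: pd.DataFrame, domains: tuple[str, ...] = DOMAINS) -> np.ndarray:
    """Extract the score matrix in canonical domain order from an area table."""
    return areas.loc[:, list(domains)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Case-study fixtures
# ---------------------------------------------------------------------------

#: scores in canonical order (access, community, environment, health,
#: housing, income); profiles mirror the six narrated area archetypes
_CASE_PROFILES = {
    "case_1": ("affluent, only poor access to services",
               (80.0, 5.0, 8.0, 6.0, 7.0, 5.0)),
    "case_2": ("very poor access, moderate health, otherwise affluent",
               (95.0, 10.0, 12.0, 24.0, 10.0, 9.0)),
    "case_3": ("deprived income/health/community, good access",
               (8.0, 50.0, 20.0, 55.0, 22.0, 60.0)),
    "case_4": ("moderate deprivation across all domains",
               (20.0, 24.0, 22.0, 24.0, 23.0, 24.0)),
    "case_5": ("very low income/health/community, average housing/environment/access",
               (20.0, 3.0, 22.0, 3.0, 23.0, 3.0)),
    "case_6": ("affluent rural, high environment and access deprivation",
               (50.0, 6.0, 40.0, 7.0, 8.0, 5.0)),
}


def fixture_case_studies(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Six labelled archetype areas with noise-free ground-truth outcomes.

    The profiles are deterministic: case 1 has every score inside its
    non-deprived core except Access (inside the highly-deprived core); case 4
    sits strictly between the cores on every domain; and so on.
    """
    if config is None:
        config = GeneratorConfig()
    config.validate()
    truth = config.truth_model()
    rows = []
    for area_id, (label, scores) in _CASE_PROFILES.items():
        x = np.asarray(scores, dtype=float)
        row = {"area_id": area_id, "label": label}
        row.update(dict(zip(config.domains, x)))
        row["eur"] = float(predict(truth, x))
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame[["area_id", "label"] + [c for c in CSV_COLUMNS if c not in ("area_id",)]]


def recovery_config(seed: int = 0, n_areas: int = 1900) -> GeneratorConfig:
    """Configuration of the parameter-recovery experiment.

    The cohort concentrates areas in the eight generative sub-regions
    (uniform pattern weights), uses wide symmetric cores with well-separated
    components, independent within-cluster variation and near-crisp
    generative flanks -- the regime in which the identity and the local
    coefficients of every generative rule are statistically identifiable
    from n areas at the default outcome noise.
    """
    bounds = {name: (25.0, 45.0) for name in DOMAINS}
    return GeneratorConfig(
        n_areas=n_areas,
        core_bounds=bounds,
        correlation=np.eye(len(DOMAINS)),
        pattern_weights=np.ones(len(_TRUTH_PATTERNS)),
        component_separation=2.2,
        component_floor=9.0,
        low_sd=8.0,
        high_sd=12.0,
        truth_flank={name: 5.0 for name in DOMAINS},
        seed=seed,
    )
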