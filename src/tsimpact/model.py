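"""Takagi-Sugeno fuzzy system core.

A TS model is a set of if-then rules.  Rule *i* reads "if domain 1 is
:math:`A_1^i` and ... and domain d is :math:`A_d^i`, then
:math:`y_i = c_0^i + c_1^i x_1 + ... + c_d^i x_d`", where each antecedent set
:math:`A_j^i` is one of the two fuzzy sets of that domain's partition.  A
point's *firing strength* for rule *i* is the product of its antecedent
membership degrees, :math:`w_i(x) = \\prod_j \\mu_{A_j^i}(x_j)`; normalizing
over rules gives the convex weights :math:`v_i(x) = w_i / \\sum_k w_k`.  The
global prediction fuses the local linear models,
:math:`\\hat y(x) = \\sum_i v_i(x)\\, y_i(x)`.

Consequent coefficients are estimated per rule by weighted least squares with
that rule's normalized firing strengths as observation weights, so each local
model describes its own fuzzy sub-region and stays interpretable on its own.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import NotFittedError, ValidationError
from .partition import DomainPartition, fit_partitions

logger = logging.getLogger(__name__)

LOW, HIGH = "low", "high"

#: ridge added to the weighted normal equations when the local design is
#: ill-conditioned (condition number above _COND_THRESHOLD)
_RIDGE = 1e-6
_COND_THRESHOLD = 1e10


@dataclass
class Rule:
    """One if-then rule: an antecedent label per domain plus a local linear model."""

    rule_id: int
    antecedent: tuple[str, ...]
    intercept: float = np.nan
    slopes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(lab not in (LOW, HIGH) for lab in self.antecedent):
            raise ValidationError(f"rule {self.rule_id}: antecedent labels must be low/high")
        if self.slopes is not None:
            self.slopes = np.asarray(self.slopes, dtype=float)

    @property
    def is_fitted(self) -> bool:
        return self.slopes is not None and np.isfinite(self.intercept)

    def linear_output(self, X: np.ndarray) -> np.ndarray:
        """The rule's local linear prediction c0 + c^T x."""
        if not self.is_fitted:
            raise NotFittedError(f"rule {self.rule_id} has no fitted consequent")
        return self.intercept + np.asarray(X, dtype=float) @ self.slopes

    def pattern(self) -> str:
        """Antecedent in 'D'/'-' notation (D = highly deprived)."""
        return "".join("D" if lab == HIGH else "-" for lab in self.antecedent)


@dataclass
class TSModel:
    """Fuzzy partitions plus the rule base."""

    domains: tuple[str, ...]
    partitions: list[DomainPartition]
    rules: list[Rule]
    fitted: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.partitions) != len(self.domains):
            raise ValidationError("one partition per domain is required")
        if not self.rules:
            raise ValidationError("a TS model needs at least one rule")
        for rule in self.rules:
            if len(rule.antecedent) != len(self.domains):
                raise ValidationError(
                    f"rule {rule.rule_id}: antecedent length does not match domains"
                )

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def rule_by_id(self, rule_id: int) -> Rule:
        for rule in self.rules:
            if rule.rule_id == rule_id:
                return rule
        raise KeyError(f"no rule with id {rule_id}")

    def copy(self, rules: list[Rule] | None = None) -> "TSModel":
        new_rules = [replace(r, slopes=None if r.slopes is None else r.slopes.copy())
                     for r in (rules if rules is not None else self.rules)]
        return TSModel(self.domains, list(self.partitions), new_rules,
                       fitted=self.fitted, meta=dict(self.meta))


def build_rule_grid(partitions: list[DomainPartition]) -> list[Rule]:
    """All 2^d label combinations, in deterministic lexicographic order.

    Domain order follows the partitions as given (canonically alphabetical:
    access, community, environment, health, housing, income); within that,
    "low" sorts before "high", so rule 0 is the all-non-deprived rule.
    """
    d = len(partitions)
    rules = []
    for i in range(2**d):
        labels = tuple(HIGH if (i >> (d - 1 - j)) & 1 else LOW for j in range(d))
        rules.append(Rule(rule_id=i, antecedent=labels))
    return rules


def _as_matrix(x, d: int) -> tuple[np.ndarray, bool]:
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != d:
        raise ValidationError(f"expected {d} domain scores per point, got {X.shape[1]}")
    return X, single


def membership_table(model: TSModel, X: np.ndarray) -> np.ndarray:
    """Per-point, per-domain membership degrees, shape (n, d, 2) as [low, high]."""
    X, _ = _as_matrix(X, model.n_domains)
    out = np.empty((X.shape[0], model.n_domains, 2))
    for j, part in enumerate(model.partitions):
        out[:, j, 0] = part.low_set.membership(X[:, j])
        out[:, j, 1] = part.high_set.membership(X[:, j])
    return out


def firing_strengths(model: TSModel, x) -> tuple[np.ndarray, np.ndarray]:
    """Raw (w) and normalized (v) rule firing strengths at x.

    ``w_i`` is the product of the rule's antecedent memberships; ``v`` rows
    sum to one.  If every rule's raw strength underflows to zero (possible
    only after pruning, since a full grid with Gaussian flanks is strictly
    positive everywhere), the mass is spread uniformly over the rules with
    maximal raw strength and a warning is emitted.
    """
    X, single = _as_matrix(x, model.n_domains)
    M = membership_table(model, X)
    n, r = X.shape[0], len(model.rules)
    W = np.ones((n, r))
    for i, rule in enumerate(model.rules):
        for j, lab in enumerate(rule.antecedent):
            W[:, i] *= M[:, j, 1 if lab == HIGH else 0]
    totals = W.sum(axis=1)
    dead = totals <= 0.0
    V = np.empty_like(W)
    ok = ~dead
    V[ok] = W[ok] / totals[ok, None]
    if dead.any():
        warnings.warn(
            "all rule firing strengths are zero at some points; "
            "falling back to a uniform split over maximal rules",
            RuntimeWarning,
            stacklevel=2,
        )
        for i in np.where(dead)[0]:
            mask = W[i] == W[i].max()
            V[i] = mask / mask.sum()
    if single:
        return W[0], V[0]
    return W, V


def predict(model: TSModel, x) -> np.ndarray | float:
    """Fused global prediction: the v-weighted average of the local models."""
    if not model.fitted:
        raise NotFittedError("model consequents have not been fitted")
    X, single = _as_matrix(x, model.n_domains)
    _, V = firing_strengths(model, X)
    Y = np.column_stack([rule.linear_output(X) for rule in model.rules])
    y = (V * Y).sum(axis=1)
    return float(y[0]) if single else y


def fit_consequents(
    model: TSModel,
    X: np.ndarray,
    y: np.ndarray,
    min_support: float | None = None,
    joint: bool = False,
    weighting: str = "normalized",
) -> TSModel:
    """Estimate every rule's local linear model from training data.

    Default estimator: per-rule weighted least squares with the rule's
    normalized firing strengths (``weighting="normalized"``) as observation
    weights; ``weighting="membership"`` uses the raw membership products
    instead, which down-weights points on the boundary between sub-regions
    and keeps each local model anchored to its own region.  Rules whose
    total weight mass falls below ``min_support`` (default d + 2) keep zero
    slopes and a weighted-mean intercept -- an unsupported sub-region should
    not extrapolate.  Ill-conditioned local designs fall back to a small
    ridge on the weighted normal equations.  ``joint=True`` instead solves
    one global least-squares problem over all rules' coefficients
    simultaneously.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise ValidationError("fit_consequents: X must be n x d with matching non-empty y")
    if weighting not in ("normalized", "membership"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    d = model.n_domains
    if min_support is None:
        min_support = d + 2
    model.meta["fit_options"] = {"joint": joint, "weighting": weighting,
                                 "min_support": min_support}

    W, V = firing_strengths(model, X)
    X1 = np.column_stack([np.ones(len(y)), X])

    if joint:
        blocks = [V[:, [i]] * X1 for i in range(len(model.rules))]
        A = np.hstack(blocks)
        G = A.T @ A
        if np.linalg.cond(G) > _COND_THRESHOLD:
            beta = np.linalg.solve(G + _RIDGE * np.eye(G.shape[0]), A.T @ y)
        else:
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        for i, rule in enumerate(model.rules):
            b = beta[i * (d + 1) : (i + 1) * (d + 1)]
            rule.intercept, rule.slopes = float(b[0]), b[1:].copy()
        model.fitted = True
        return model

    weight_matrix = V if weighting == "normalized" else W
    for i, rule in enumerate(model.rules):
        w = weight_matrix[:, i]
        mass = w.sum()
        if mass < min_support:
            rule.slopes = np.zeros(d)
            rule.intercept = float((w @ y) / mass) if mass > 0 else float(y.mean())
            continue
        sw = np.sqrt(w)
        Xw = X1 * sw[:, None]
        yw = y * sw
        if np.linalg.cond(Xw) > _COND_THRESHOLD:
            A = Xw.T @ Xw + _RIDGE * np.eye(d + 1)
            beta = np.linalg.solve(A, Xw.T @ yw)
            logger.debug("rule %d: ridge fallback applied", rule.rule_id)
        else:
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rule.intercept, rule.slopes = float(beta[0]), beta[1:].copy()
    model.fitted = True
    return model


def fit_ts(
    scores: np.ndarray,
    outcome: np.ndarray,
    domains: list[str] | tuple[str, ...],
    n_clusters: int = 2,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    partitions: list[DomainPartition] | None = None,
    joint: bool = False,
    weighting: str = "normalized",
    flank_mode: str = "projected",
    flank_fraction: float = 0.25,
) -> TSModel:
    """Full initial fit: partitions (FCM + projection), 2^d grid, consequents.

    Pass ``partitions`` to skip the data-driven partitioning step and use
    configured cut-offs instead.
    """
    scores = np.asarray(scores, dtype=float)
    if partitions is None:
        partitions, fcm = fit_partitions(
            scores, list(domains), n_clusters=n_clusters, fuzzifier=fuzzifier,
            tol=tol, max_iter=max_iter, seed=seed,
            flank_mode=flank_mode, flank_fraction=flank_fraction,
        )
        meta = {"fcm_iterations": fcm.n_iter, "fcm_converged": fcm.converged}
    else:
        meta = {}
    rules = build_rule_grid(partitions)
    model = TSModel(tuple(domains), partitions, rules, meta=meta)
    return fit_consequents(model, scores, np.asarray(outcome, dtype=float),
                           joint=joint, weighting=weighting)


# ---------------------------------------------------------------------------
# Coefficient uncertainty
# ---------------------------------------------------------------------------


@dataclass
class CoefficientCI:
    """Confidence intervals for one rule's consequent coefficients."""

    rule_id: int
    names: list[str]
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self) -> None:
        ok = (self.lower <= self.estimate + 1e-12) & (self.estimate <= self.upper + 1e-12)
        if not np.all(ok | ~np.isfinite(self.lower) | ~np.isfinite(self.upper)):
            raise ValidationError("CI bounds must bracket the point estimate")


def coefficient_cis(
    model: TSModel,
    X: np.ndarray,
    y: np.ndarray,
    level: float = 0.95,
    method: str = "analytic",
    n_boot: int = 500,
    seed: int = 0,
) -> list[CoefficientCI]:
    """Per-rule confidence intervals for the local linear model coefficients.

    ``analytic``: weighted-least-squares standard errors with effective sample
    size ``n_i = sum_x v_i(x)`` and ``df = n_i - (d + 1)``; a rule with
    non-positive effective degrees of freedom gets unbounded intervals and a
    warning.  ``bootstrap``: seeded nonparametric resampling of training rows
    with percentile intervals.
    """
    if not model.fitted:
        raise NotFittedError("fit the model before computing coefficient CIs")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    d = model.n_domains
    names = ["intercept"] + list(model.domains)
    _, V = firing_strengths(model, X)
    X1 = np.column_stack([np.ones(len(y)), X])

    if method == "bootstrap":
        return _bootstrap_cis(model, X, y, level, n_boot, seed, names)
    if method != "analytic":
        raise ValidationError(f"unknown CI method {method!r}")

    alpha = 1.0 - level
    out = []
    for i, rule in enumerate(model.rules):
        est = np.concatenate([[rule.intercept], rule.slopes])
        w = V[:, i]
        n_eff = float(w.sum())
        df = n_eff - (d + 1)
        if df <= 0:
            warnings.warn(
                f"rule {rule.rule_id}: effective degrees of freedom <= 0; CI unbounded",
                RuntimeWarning,
                stacklevel=2,
            )
            lo = np.full(d + 1, -np.inf)
            hi = np.full(d + 1, np.inf)
        else:
            resid = y - X1 @ est
            sigma2 = float(w @ resid**2) / df
            A = X1.T @ (w[:, None] * X1)
            cov = sigma2 * np.linalg.pinv(A)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            tq = stats.t.ppf(1.0 - alpha / 2.0, df)
            lo, hi = est - tq * se, est + tq * se
        out.append(CoefficientCI(rule.rule_id, names, est, lo, hi, level))
    return out


def _bootstrap_cis(model, X, y, level, n_boot, seed, names):
    rng = np.random.default_rng(seed)
    n = len(y)
    r, d = len(model.rules), model.n_domains
    draws = np.empty((n_boot, r, d + 1))
    work = model.copy()
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        fit_consequents(work, X[idx], y[idx])
        for i, rule in enumerate(work.rules):
            draws[b, i] = np.concatenate([[rule.intercept], rule.slopes])
    alpha = 1.0 - level
    out = []
    for i, rule in enumerate(model.rules):
        est = np.concatenate([[rule.intercept], rule.slopes])
        lo = np.quantile(draws[:, i], alpha / 2.0, axis=0)
        hi = np.quantile(draws[:, i], 1.0 - alpha / 2.0, axis=0)
        out.append(
            CoefficientCI(rule.rule_id, names, est, np.minimum(lo, est), np.maximum(hi, est), level)
        )
    return out


def summarize_coefficients(model: TSModel, level: float = 0.95):
    """Across-rule summary of the local linear model coefficients.

    Returns a DataFrame with rows Minimum / Maximum / Mean / CI lower /
    CI upper and columns Baseline (the intercepts) plus one per domain.  The
    confidence interval is the t-based interval for the across-rule mean.
    """
    import pandas as pd

    if not model.fitted:
        raise NotFittedError("fit the model before summarizing coefficients")
    coefs = np.array(
        [np.concatenate([[rule.intercept], rule.slopes]) for rule in model.rules]
    )
    r = coefs.shape[0]
    mean = coefs.mean(axis=0)
    if r > 1:
        half = stats.t.ppf(0.5 + level / 2.0, r - 1) * coefs.std(axis=0, ddof=1) / np.sqrt(r)
    else:
        half = np.zeros_like(mean)
    cols = ["Baseline"] + [name.capitalize() for name in model.domains]
    return pd.DataFrame(
        [coefs.min(axis=0), coefs.max(axis=0), mean, mean - half, mean + half],
        index=["Minimum", "Maximum", "Mean", "CI lower", "CI upper"],
        columns=cols,
    )
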