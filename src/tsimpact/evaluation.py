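"""Evaluation protocol: rotated k-fold scheme, RMSE with a fold-based CI,
and a plain linear-regression comparator.

The study protocol splits n areas into train / validation / test blocks of
fixed sizes (1400 / 200 / 296 for the 1896-area cohort) and repeats this 9
times.  Since 9 x 296 exceeds 1896, the test blocks cannot be disjoint
across folds; each fold therefore rotates a single seeded permutation so the
test windows cycle through the data.  Within a fold the three blocks are
disjoint and exhaust the cohort.

RMSE is computed on the 0-1 proportion scale (outcomes are stored as
percentages and divided by 100 at evaluation time); the across-fold 95%
confidence interval uses the t distribution with k-1 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .model import TSModel, fit_ts, predict
from .selection import prune

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    fold_id: int
    train_ids: np.ndarray
    validation_ids: np.ndarray
    test_ids: np.ndarray
    seed: int

    def validate(self, n: int) -> None:
        ids = np.concatenate([self.train_ids, self.validation_ids, self.test_ids])
        if len(ids) != n or len(np.unique(ids)) != n:
            raise ConfigurationError(
                f"fold {self.fold_id}: blocks must be disjoint and cover all {n} areas"
            )


def partition_folds(
    n: int,
    n_folds: int,
    sizes: tuple[int, int, int],
    seed: int = 0,
) -> list[FoldPlan]:
    """Rotated-permutation fold plans with fixed block sizes.

    A single seeded permutation of ``0..n-1`` is rotated by ``n // n_folds``
    positions per fold and cut into (train, validation, test) blocks of the
    stated sizes.  Test blocks may overlap *across* folds when
    ``n_folds * test > n``; within each fold the three blocks are disjoint.
    """
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test != n:
        raise ConfigurationError(
            f"sizes {sizes} must sum to n={n} (got {n_train + n_val + n_test})"
        )
    if n_folds < 1:
        raise ConfigurationError("n_folds must be at least 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shift = max(n // n_folds, 1)
    plans = []
    for k in range(n_folds):
        rotated = np.roll(perm, -k * shift)
        plans.append(
            FoldPlan(
                fold_id=k,
                train_ids=rotated[:n_train].copy(),
                validation_ids=rotated[n_train : n_train + n_val].copy(),
                test_ids=rotated[n_train + n_val :].copy(),
                seed=seed,
            )
        )
        plans[-1].validate(n)
    return plans


def rmse(predictions, observations) -> float:
    """Root-mean-squared error of two equal-length vectors."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValidationError("rmse: inputs must be non-empty and of equal length")
    return float(np.sqrt(np.mean((p - o) ** 2)))


@dataclass
class CVResult:
    """Cross-validation outcome on the 0-1 proportion scale."""

    fold_rmse: np.ndarray
    mean_rmse: float
    ci: tuple[float, float]
    rule_counts: list[int] = field(default_factory=list)
    failures: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo <= self.mean_rmse <= hi):
            raise ValidationError("CI bounds must bracket the mean RMSE")


def _aggregate(fold_rmse: list[float], rule_counts: list[int],
               failures: list[int], level: float = 0.95) -> CVResult:
    arr = np.asarray(fold_rmse, dtype=float)
    mean = float(arr.mean())
    if arr.size > 1:
        half = stats.t.ppf(0.5 + level / 2.0, arr.size - 1) * arr.std(ddof=1) / np.sqrt(arr.size)
    else:
        half = 0.0
    return CVResult(arr, mean, (mean - half, mean + half), rule_counts, failures)


def cross_validate(
    areas: pd.DataFrame,
    fold_plans: list[FoldPlan],
    domains: tuple[str, ...] | None = None,
    rmse_tolerance: float = 0.01,
    min_rules: int = 1,
    prune_rules: bool = True,
    fuzzifier: float = 2.0,
    seed: int = 0,
    **fit_kwargs,
) -> CVResult:
    """Full-pipeline cross-validation of the TS model.

    Per fold: learn partitions and fit the 2^d grid on the training block,
    prune against the validation block, and score test-block RMSE on the
    proportion scale.  A fold that fails outright is recorded and excluded
    from the aggregate with a warning.
    """
    if domains is None:
        from .synthetic import DOMAINS

        domains = DOMAINS
    X = areas.loc[:, list(domains)].to_numpy(dtype=float)
    y = areas["eur"].to_numpy(dtype=float)
    fold_rmse, rule_counts, failures = [], [], []
    for plan in fold_plans:
        try:
            Xt, yt = X[plan.train_ids], y[plan.train_ids]
            Xv, yv = X[plan.validation_ids], y[plan.validation_ids]
            Xs, ys = X[plan.test_ids], y[plan.test_ids]
            model = fit_ts(Xt, yt, domains, fuzzifier=fuzzifier,
                           seed=seed + plan.fold_id, **fit_kwargs)
            if prune_rules:
                model, _ = prune(model, Xt, yt, Xv, yv,
                                 rmse_tolerance=rmse_tolerance, min_rules=min_rules)
            pred = predict(model, Xs)
            fold_rmse.append(rmse(pred / 100.0, ys / 100.0))
            rule_counts.append(len(model.rules))
        except Exception:  # noqa: BLE001 - a failed fold is reported, not fatal
            logger.warning("fold %d failed; excluded from the aggregate",
                           plan.fold_id, exc_info=True)
            failures.append(plan.fold_id)
    if not fold_rmse:
        raise ValidationError("every fold failed; no RMSE to aggregate")
    return _aggregate(fold_rmse, rule_counts, failures)


def baseline_linear_regression(
    areas: pd.DataFrame,
    fold_plans: list[FoldPlan],
    domains: tuple[str, ...] | None = None,
) -> CVResult:
    """Ordinary least squares on the six domain scores, same folds, same metric.

    The baseline consumes the train and validation blocks together (the TS
    pipeline uses both), then scores the test block on the proportion scale.
    """
    if domains is None:
        from .synthetic import DOMAINS

        domains = DOMAINS
    X = areas.loc[:, list(domains)].to_numpy(dtype=float)
    y = areas["eur"].to_numpy(dtype=float)
    fold_rmse = []
    for plan in fold_plans:
        fit_ids = np.concatenate([plan.train_ids, plan.validation_ids])
        design = sm.add_constant(X[fit_ids])
        res = sm.OLS(y[fit_ids], design).fit()
        pred = res.predict(sm.add_constant(X[plan.test_ids]))
        fold_rmse.append(rmse(pred / 100.0, y[plan.test_ids] / 100.0))
    return _aggregate(fold_rmse, [0] * len(fold_rmse), [])
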